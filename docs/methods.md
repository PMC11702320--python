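# Methods

## Model and estimators

A binary classifier h evaluated on n i.i.d. subjects induces a
multinomial observation over the four confusion cells, with cell
probabilities p = (p11, p10, p01, p00) = (TP, FP, FN, TN) as population
fractions.  The MCC is the functional

    φ(p) = (p11 p00 − p10 p01) / √(M1 M2 M3 M4),

with margins M1 = p11+p10, M2 = p11+p01, M3 = p00+p10, M4 = p00+p01.
The plug-in estimator is φ(p̂), p̂ = counts/n.  Since n·p̂ is
multinomial, √n (p̂ − p) ⇝ N(0, Σ(p)) with Σ(p) = diag(p) − ppᵀ, and the
delta method gives the asymptotic variance ∇h(p)ᵀ Σ(p) ∇h(p) for any
smooth h.  In a paired design the same machinery runs on the 8-cell
joint p[i][j][k] indexed by (prediction of h1, prediction of h2, actual
label); the two marginal 2×2 tables are fixed 0/1 linear maps J1, J2 of
the joint, so every paired gradient reduces to Jᵀ-lifted single-table
gradients.

## Gradients

∇φ is implemented in closed form from the quotient rule,

    ∂φ/∂p11 = p00/D − (φ/2)(1/M1 + 1/M2),   D = √(M1 M2 M3 M4),

and its three siblings by the symmetry of the formula.  Chain rules give
∇(f∘φ) = ∇φ/(1−φ²) for f = artanh and ∇(g∘ψ) = ∇ψ · 2/(4−ψ²) for
g(x) = artanh(x/2), ψ = φ(J1 p) − φ(J2 p).  The gradients are taken of
the unconstrained formulas on an open box around the simplex (no
tangent-space projection): Σ(p) annihilates the constant direction, so
the quadratic form is unaffected, and this is the convention the
interval formulas assume.  A central finite-difference oracle
(`fd_gradient`, h = 1e−6, no simplex renormalization) is the correctness
authority in the tests; analytic and numeric gradients agree to 1e−5
relative at hundreds of random interior points.

Quadratic forms against the multinomial covariance are evaluated without
materializing Σ:  gᵀΣ(p)g = Σₐ pₐgₐ² − (Σₐ pₐgₐ)², which is what lets
the Monte-Carlo engine push 10⁶ replicates through vectorized numpy.

## Interval constructions and NA rules

All intervals use z = Φ⁻¹(1 − α/2) (default level 0.95) and plug-in
variances; no small-sample or continuity corrections.  Simple-method
limits are deliberately not truncated to the parameter range: the
method *is* the unconstrained normal interval, and truncation would
misrepresent its coverage accounting.  Fisher-type limits are strictly
inside (−1, 1) (single) or (−2, 2) (difference) by construction.

An interval is NA when it cannot be built:

* MCC undefined — any zero margin (the φ denominator vanishes).  The
  natural sampling cause is a sample with no actual positives; the rule
  is applied to all four margins so that φ is total on its domain.
* Fisher/naive: additionally |MCĈ| = 1 (artanh diverges).
* Paired Simple/MT: a zero margin in either marginal table; MT also at
  the unreachable boundary |ψ̂| = 2.
* Zou: additionally a unit marginal MCC (its marginal Fisher intervals
  then do not exist).
* Degenerate zero-variance estimates (e.g. two identical prediction
  columns) return NA rather than a width-0 interval: the normal
  approximation is vacuous there.

Boundary detection is exact: |φ| = 1 is decided from the zero cells
(both off-diagonal or both diagonal cells empty), not from the floating
value of φ, which can land one ulp below 1 and silently corrupt both NA
accounting and back-transformed limits.  Estimates are snapped to ±1 in
that case.  Estimated correlations are clamped to [−1, 1] and Zou
radicands clipped at 0 against floating excursions; negative
quadratic-form values above −1e−12 are clipped to 0.

Zou's marginal intervals use the same confidence level as the target
difference interval.  The correlation between the two MCC estimates
comes from the delta method via the 8×2 Jacobian of (MCC₁, MCC₂) —
not from normal-theory approximation formulas for correlations, which
presume bivariate-normal data and do not hold for binary labels.

## Scenario construction

Single-MCC simulation scenarios are specified by prevalence
π = P(Y=1) ∈ {0.1, 0.5} and true MCC ρ ∈ {0.4, 0.6, 0.8}, under the
balance constraint TP/FN = TN/FP, which is equivalent to
sensitivity = specificity = s.  The cells are then
(πs, (1−π)(1−s), π(1−s), (1−π)s) and

    φ = π(1−π)(2s−1) / √(π(1−π)(πs+(1−π)(1−s))((1−π)s+π(1−s))),

strictly increasing in s on (1/2, 1), so s is unique: s = (1+ρ)/2 in the
balanced case, otherwise a Brent root solve to |φ−ρ| ≤ 1e−12.  These
constraints determine the cells exactly, with no further free choices.

Paired scenarios are built from per-classifier sensitivity/specificity
plus two conditional agreement probabilities, P(h1=1, h2=1 | Y=1) and
P(h1=0, h2=0 | Y=0), each validated against its Fréchet bounds.  The
convenience constructor `paired_scenario_from_mccs` gives both
classifiers the balance-constrained accuracy for their target MCCs and
interpolates agreement between conditional independence and the Fréchet
upper bound; tests span both prevalences, all MCC pairs and both
dependence regimes.  Under prevalence 1/2 and conditional independence
the asymptotic correlation of the two MCC estimates is exactly zero;
under imbalance it is not (the shared prevalence estimate correlates
them), which is why the paired methods must model the correlation.

## Monte-Carlo engine

`run_coverage` draws m multinomial samples of size n from the true
cells, builds every requested interval on the *same* draws (so methods
are compared replicate-for-replicate), omits NA replicates per the rules
above, and reports conditional coverage, the NA count, the binomial
Monte-Carlo standard error and the mean width.  Replicates are generated
in fixed chunks of 2¹⁷ draws, each chunk from its own
`SeedSequence(seed, spawn_key=(chunk,))` stream: results are
deterministic in the seed, independent of chunk scheduling, and the
chunk granularity keeps generator setup negligible at m = 10⁶.

Default study sizes: the full coverage study runs m = 10⁶ replicates at
n = 50 per scenario (a few seconds per scenario, vectorized); the
large-n nominal-coverage checks use n = 10⁴ with m = 10⁵, where the
Monte-Carlo standard error (~7e−4) is far inside the asserted ±0.004
band.

What the generator emulates — and does not: samples are i.i.d.
multinomial draws from exact cell probabilities.  Real evaluation data
add clustering, covariate shift between benchmark and deployment, and
classifiers tuned on the same data they are scored on; none of that is
modeled, so nominal coverage here demonstrates correctness of the
asymptotics, not robustness to those violations.

## Joint reconstruction

Published comparisons often report only (sensitivity, specificity) per
classifier on a benchmark with n_pos/n_neg known truths.  Those
marginals leave the 8-cell joint two degrees of freedom, parametrized as
p001 (both classifiers miss a positive) and p110 (both false-alarm on a
negative).  Cell nonnegativity yields a rectangular feasibility box,
e.g. p001 ∈ [max(0, π(1−s1−s2)), π·min(1−s1, 1−s2)].  `mt_grid` sweeps
the closed box (default steps 0.025 in p001, 0.001 in p110, endpoints
included), reconstructs each joint, and computes the MT interval
treating the cells as exact plug-in probabilities with effective sample
size n_pos+n_neg.  The point difference MCC₁−MCC₂ is a function of the
marginals alone and is therefore constant across the box; only the
interval varies.  The shipped example marginals are synthetic (chosen to
make the box [0, 0.1]×[0, 0.1275] and the difference small), since the
source accuracies of real published predictors are user inputs, not
package data.

## Known limitations

* All intervals are first-order asymptotic; none are exact or
  bootstrap-calibrated, and small-n undercoverage of the Simple method
  is expected behavior, not a defect.
* Multi-class MCC is out of scope.
* Coverage is conditional on definedness; scenarios where NA replicates
  are frequent (tiny n, extreme imbalance) estimate a conditional
  coverage that can differ from unconditional guarantees.
* The naive 1/(n−3) method is included only as a cautionary baseline.
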