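# mccstats

Asymptotic confidence intervals for the Matthews correlation coefficient
(MCC), for a single binary classifier and for the difference of two
classifiers evaluated on the same subjects (paired design), with a
Monte-Carlo engine for studying finite-sample coverage.

## Who this is for

The MCC (phi coefficient) of a 2×2 confusion table,

    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

is the Pearson correlation between binary actual and predicted labels
and is widely preferred over accuracy or F1 on imbalanced data.  Most
applied work, however, compares bare point estimates.  This package is
for anyone who wants an interval (or a paired-difference interval) to go
with the point estimate — e.g. to say whether one diagnostic classifier
is *significantly* better than another on the same benchmark.

## Methods

Writing p = (p11, p10, p01, p00) for the multinomial cell probabilities
of the table and φ(p) for the MCC, the CLT gives
√n (p̂ − p) ⇝ N(0, Σ(p)) with Σ(p) = diag(p) − ppᵀ, and the delta method
turns any smooth statistic h(p̂) into a normal interval with variance
∇h(p̂)ᵀ Σ(p̂) ∇h(p̂) / n.

Single MCC:

* **Simple** — h = φ: MCĈ ± z·√(∇φᵀΣ∇φ/n).  Symmetric.
* **Fisher's z** — h = f∘φ with f = artanh: interval built on the z
  scale, back-transformed by tanh.  Respects the skewness of the MCC
  sampling distribution; markedly better small-sample coverage.
* **Naive 1/(n−3)** — Fisher transform with the bivariate-normal-theory
  variance 1/(n−3).  Included as a baseline; its coverage is poor for
  binary data and it should not be used in practice.

Paired difference ψ = MCC₁ − MCC₂ (8-cell joint table over
(pred1, pred2, actual)):

* **Simple** — normal interval with variance ∇ψᵀΣ∇ψ/n.
* **Zou's method (MOVER)** — combines the two marginal Fisher's z
  intervals with the estimated correlation of the two MCC estimates
  (itself obtained by the delta method via the Jacobian of
  (MCC₁, MCC₂)).
* **Modified Transformation (MT)** — Fisher-type interval on the
  g(x) = artanh(x/2) scale, since a difference of correlations lives in
  (−2, 2); back-transformed by 2·tanh.

A scenario/simulation module reproduces coverage studies (balanced and
imbalanced prevalence, MCC 0.4–0.8, the balance constraint
TP/FN = TN/FP), and a reconstruction module rebuilds the 8-cell joint
from published sensitivities/specificities up to two free cells
(p001, p110), sweeping MT intervals over their feasibility box.

## Worked example

The canonical imbalanced example — a classifier that predicts almost
everything positive (tp=90, fp=9, fn=1, tn=0):

```
$ mcc metrics --counts 90,9,1,0
{
  "mcc": -0.0316069770620507,
  "accuracy": 0.9,
  "balanced_accuracy": 0.4945054945054945,
  "f1": 0.9473684210526315,
  "tpr": 0.989010989010989,
  "tnr": 0.0,
  "precision": 0.9090909090909091
}
```

Accuracy 0.900 and F1 0.947 look excellent, but the MCC of −0.032 says
the predictions are slightly *anti*-correlated with the truth — the
classifier is useless on the minority class (TNR = 0).

A Fisher's z interval for a balanced table with MCĈ = 0.4 (n = 100):

```
$ mcc ci --counts 35,15,15,35 --method fisher
{
  "lower": 0.2067744149639868,
  "upper": 0.5631939261304187,
  ...
  "estimate": 0.3999999999999999
}
```

Note the asymmetry (0.193 below the estimate, 0.163 above): the
back-transformed interval reflects the left-skewed sampling distribution
of a positive MCC.

A quick coverage experiment (100 000 replicates, seconds):

```
$ mcc simulate --prevalence 0.5 --true-mcc 0.4 --n 50 --reps 100000 \
      --methods simple,fisher,naive --seed 1
method  n   m       n_na  coverage  mc_se        mean_width  seed
simple  50  100000  0     0.93418   0.000784141  0.499207    1
fisher  50  100000  0     0.95174   0.000677724  0.492189    1
naive   50  100000  0     0.92954   0.000809292  0.46366     1
```

At n = 50 the Simple interval undercovers (0.934), Fisher's z is close
to nominal (0.952), and the naive 1/(n−3) variance is already off —
and it degrades badly as the true MCC grows.

Paired comparisons work from label files or 8-cell count files
(`mcc diff-ci --labels data.csv --method mt`), and
`mcc reconstruct --n-pos 200 --n-neg 200 --sens1 ... --spec2 ...` sweeps
MT intervals over the unidentified agreement cells of a published
comparison.

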