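"""Scenario construction and the Monte-Carlo coverage engine.

Single-MCC scenarios are pinned down by three constraints: the
prevalence pi = P(Y=1), the true MCC rho, and the balance condition
TP/FN = TN/FP, which forces sensitivity = specificity = s.  The cells
are then

    (p11, p10, p01, p00) = (pi s, (1-pi)(1-s), pi (1-s), (1-pi) s)

and s in (1/2, 1) solves phi(cells) = rho (closed form s = (1+rho)/2
when pi = 1/2; a bracketed root solve otherwise).

Paired scenarios are parametrized by prevalence, per-classifier
sensitivity/specificity, and two agreement probabilities
P(h1=1, h2=1 | Y=1) and P(h1=0, h2=0 | Y=0), each constrained by its
Frechet bounds.

The coverage engine draws m multinomial samples of size n from the true
cells, builds each requested interval per replicate, omits replicates
where the interval is undefined (NA), and reports the conditional
coverage of the true MCC (or true difference), the NA count, the
Monte-Carlo standard error and the mean interval width.  Replicates are
generated in fixed-size chunks of 2^17, each chunk from its own
spawned SeedSequence stream, so results are deterministic in the seed
and independent of how the chunks are executed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import brentq

from . import _kernels, ci_paired, ci_single
from .confusion import CellProbs, PairedCellProbs
from .errors import InfeasibleError, InputError

__all__ = [
    "Scenario",
    "PairedScenario",
    "CoverageResult",
    "solve_single_scenario",
    "build_paired_scenario",
    "paired_scenario_from_mccs",
    "run_coverage",
    "SINGLE_METHODS",
    "PAIRED_METHODS",
]

_CHUNK = 1 << 17

SINGLE_METHODS = ("simple", "fisher", "naive")
PAIRED_METHODS = ("simple", "zou", "mt")


@dataclass(frozen=True)
class Scenario:
    """True cell probabilities of a single-classifier simulation."""

    prevalence: float
    true_mcc: float
    accuracy_param: float  # shared sensitivity = specificity
    cells: CellProbs


@dataclass(frozen=True)
class PairedScenario:
    """True joint cell probabilities of a paired-design simulation."""

    prevalence: float
    sens1: float
    spec1: float
    sens2: float
    spec2: float
    agree_pos: float
    agree_neg: float
    cells: PairedCellProbs
    true_mcc1: float
    true_mcc2: float
    true_diff: float


@dataclass(frozen=True)
class CoverageResult:
    """Monte-Carlo coverage estimate for one interval method.

    ``coverage`` is conditional on the ``m - n_na`` replicates where the
    interval exists; ``mc_se`` is the binomial standard error on that
    conditional estimate.
    """

    method: str
    n: int
    m: int
    n_na: int
    coverage: float
    mc_se: float
    mean_width: float
    seed: int


def _single_cells(prevalence: float, s: float) -> np.ndarray:
    pi = prevalence
    return np.array([pi * s, (1 - pi) * (1 - s), pi * (1 - s), (1 - pi) * s])


def solve_single_scenario(prevalence: float, true_mcc: float) -> Scenario:
    """Solve the balance-constrained cells reaching a given true MCC.

    Requires prevalence in (0, 1) and true_mcc in (0, 1); the shared
    accuracy s is found to |phi - rho| <= 1e-12.
    """
    if not 0 < prevalence < 1:
        raise InputError(f"prevalence must be in (0, 1), got {prevalence}")
    if not 0 < true_mcc < 1:
        raise InputError(f"true_mcc must be in (0, 1), got {true_mcc}")

    def f(s: float) -> float:
        return float(_kernels.phi(_single_cells(prevalence, s))) - true_mcc

    lo, hi = 0.5 + 1e-12, 1.0 - 1e-12
    if not (f(lo) < 0 < f(hi)):
        raise InfeasibleError(
            f"no accuracy in (0.5, 1) reaches MCC {true_mcc} at prevalence {prevalence}"
        )
    s = float(brentq(f, lo, hi, xtol=1e-15, rtol=8.9e-16))
    cells = _single_cells(prevalence, s)
    if abs(float(_kernels.phi(cells)) - true_mcc) > 1e-12:
        raise InfeasibleError("root solve failed to reach the requested MCC")
    return Scenario(
        prevalence=prevalence,
        true_mcc=true_mcc,
        accuracy_param=s,
        cells=CellProbs.from_array(cells),
    )


def _check_frechet(name: str, agree: float, a: float, b: float) -> None:
    lo, hi = max(0.0, a + b - 1.0), min(a, b)
    if not (lo - 1e-12 <= agree <= hi + 1e-12):
        raise InfeasibleError(
            f"{name}={agree} violates its Frechet bounds [{lo}, {hi}]"
        )


def build_paired_scenario(
    prevalence: float,
    sens1: float,
    spec1: float,
    sens2: float,
    spec2: float,
    agree_pos: float,
    agree_neg: float,
) -> PairedScenario:
    """Assemble the 8-cell joint from marginal accuracies and agreement.

    ``agree_pos`` = P(h1=1, h2=1 | Y=1) and ``agree_neg`` =
    P(h1=0, h2=0 | Y=0) must respect their Frechet bounds given the
    sensitivities/specificities.
    """
    pi = prevalence
    if not 0 < pi < 1:
        raise InputError(f"prevalence must be in (0, 1), got {pi}")
    for name, v in (
        ("sens1", sens1), ("spec1", spec1), ("sens2", sens2), ("spec2", spec2),
        ("agree_pos", agree_pos), ("agree_neg", agree_neg),
    ):
        if not 0 <= v <= 1:
            raise InputError(f"{name} must be in [0, 1], got {v}")
    _check_frechet("agree_pos", agree_pos, sens1, sens2)
    _check_frechet("agree_neg", agree_neg, spec1, spec2)

    p = np.zeros((2, 2, 2))
    p[1, 1, 1] = pi * agree_pos
    p[1, 0, 1] = pi * (sens1 - agree_pos)
    p[0, 1, 1] = pi * (sens2 - agree_pos)
    p[0, 0, 1] = pi * (1.0 - sens1 - sens2 + agree_pos)
    p[0, 0, 0] = (1 - pi) * agree_neg
    p[0, 1, 0] = (1 - pi) * (spec1 - agree_neg)
    p[1, 0, 0] = (1 - pi) * (spec2 - agree_neg)
    p[1, 1, 0] = (1 - pi) * (1.0 - spec1 - spec2 + agree_neg)
    p = np.clip(p, 0.0, None)
    p /= p.sum()

    flat = p.ravel()
    r1 = float(_kernels.phi(flat @ _kernels.J1.T))
    r2 = float(_kernels.phi(flat @ _kernels.J2.T))
    return PairedScenario(
        prevalence=pi,
        sens1=sens1,
        spec1=spec1,
        sens2=sens2,
        spec2=spec2,
        agree_pos=agree_pos,
        agree_neg=agree_neg,
        cells=PairedCellProbs.from_array(p),
        true_mcc1=r1,
        true_mcc2=r2,
        true_diff=r1 - r2,
    )


def paired_scenario_from_mccs(
    prevalence: float,
    mcc1: float,
    mcc2: float,
    agreement: float = 0.0,
) -> PairedScenario:
    """Paired scenario with balance-constrained marginals at given MCCs.

    Each classifier gets sensitivity = specificity solving its target
    MCC at the common prevalence.  ``agreement`` in [0, 1) interpolates
    the conditional agreement probabilities between independence (0)
    and their Frechet upper bounds (1); the upper bound itself would
    make the two classifiers coincide when the accuracies are equal.
    """
    if not 0 <= agreement < 1:
        raise InputError(f"agreement must be in [0, 1), got {agreement}")
    s1 = solve_single_scenario(prevalence, mcc1).accuracy_param
    s2 = solve_single_scenario(prevalence, mcc2).accuracy_param
    a_pos = (1 - agreement) * s1 * s2 + agreement * min(s1, s2)
    a_neg = (1 - agreement) * s1 * s2 + agreement * min(s1, s2)
    return build_paired_scenario(prevalence, s1, s1, s2, s2, a_pos, a_neg)


# ---------------------------------------------------------------------------
# Coverage engine
# ---------------------------------------------------------------------------


def _chunk_rng(seed: int, chunk_index: int) -> np.random.Generator:
    """Independent, reproducible stream for one replicate chunk."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(chunk_index,)))


def _single_method_bounds(method, phat, n, z):
    if method == "simple":
        return ci_single._simple_bounds(phat, n, z)
    if method == "fisher":
        return ci_single._fisher_bounds(phat, n, z)
    if method == "naive":
        return ci_single._naive_bounds(phat, n, z)
    raise InputError(f"unknown single-MCC method {method!r}")


def _run_single(scenario, n, m, methods, level, seed):
    cells = scenario.cells.as_array()
    true = scenario.true_mcc
    z = ci_single.z_quantile(level)
    if "naive" in methods and n < 4:
        raise InputError("naive method requires n >= 4")
    covered = {meth: 0 for meth in methods}
    n_def = {meth: 0 for meth in methods}
    width = {meth: 0.0 for meth in methods}
    done = 0
    chunk_index = 0
    while done < m:
        c = min(_CHUNK, m - done)
        rng = _chunk_rng(seed, chunk_index)
        counts = rng.multinomial(n, cells, size=c).astype(float)
        phat = counts / n
        for meth in methods:
            lo, hi, _, defined = _single_method_bounds(meth, phat, n, z)
            n_def[meth] += int(defined.sum())
            hit = defined & (lo <= true) & (true <= hi)
            covered[meth] += int(hit.sum())
            width[meth] += float(np.nansum(np.where(defined, hi - lo, 0.0)))
        done += c
        chunk_index += 1
    return _summaries(methods, covered, n_def, width, n, m, seed)


def _paired_method_bounds(method, stats, n, z):
    """Vectorized paired bounds from the shared per-replicate statistics."""
    defined = stats["defined"]
    d = stats["diff"]
    with np.errstate(divide="ignore", invalid="ignore"):
        if method == "simple":
            half = z * np.sqrt(stats["var_psi"] / n)
            return d - half, d + half, defined
        if method == "mt":
            ok = defined & ~(stats["unit1"] & stats["unit2"] & (stats["r1"] * stats["r2"] < 0))
            se_g = np.sqrt(stats["var_psi"] / n) * 2.0 / (4.0 - d * d)
            center = np.arctanh(np.where(ok, d, 0.0) / 2.0)
            center = np.where(ok, center, np.nan)
            return (
                2.0 * np.tanh(center - z * se_g),
                2.0 * np.tanh(center + z * se_g),
                ok,
            )
        if method == "zou":
            r1, r2 = stats["r1"], stats["r2"]
            ok = defined & ~stats["unit1"] & ~stats["unit2"]
            se1 = np.sqrt(stats["var1"] / n) / (1.0 - r1 * r1)
            se2 = np.sqrt(stats["var2"] / n) / (1.0 - r2 * r2)
            z1 = np.arctanh(np.where(ok, r1, 0.0))
            z2 = np.arctanh(np.where(ok, r2, 0.0))
            z1 = np.where(ok, z1, np.nan)
            z2 = np.where(ok, z2, np.nan)
            l1, u1 = np.tanh(z1 - z * se1), np.tanh(z1 + z * se1)
            l2, u2 = np.tanh(z2 - z * se2), np.tanh(z2 + z * se2)
            corr = ci_paired._corr_from_stats(stats)
            lo, hi = ci_paired._zou_bounds(r1, r2, l1, u1, l2, u2, corr)
            return lo, hi, ok
    raise InputError(f"unknown paired method {method!r}")


def _run_paired(scenario, n, m, methods, level, seed):
    cells = scenario.cells.as_array()
    true = scenario.true_diff
    z = ci_single.z_quantile(level)
    covered = {meth: 0 for meth in methods}
    n_def = {meth: 0 for meth in methods}
    width = {meth: 0.0 for meth in methods}
    done = 0
    chunk_index = 0
    while done < m:
        c = min(_CHUNK, m - done)
        rng = _chunk_rng(seed, chunk_index)
        counts = rng.multinomial(n, cells, size=c).astype(float)
        stats = ci_paired._paired_stats(counts / n)
        for meth in methods:
            lo, hi, defined = _paired_method_bounds(meth, stats, n, z)
            n_def[meth] += int(defined.sum())
            hit = defined & (lo <= true) & (true <= hi)
            covered[meth] += int(hit.sum())
            width[meth] += float(np.nansum(np.where(defined, hi - lo, 0.0)))
        done += c
        chunk_index += 1
    return _summaries(methods, covered, n_def, width, n, m, seed)


def _summaries(methods, covered, n_def, width, n, m, seed):
    out = []
    for meth in methods:
        defined = n_def[meth]
        cov = covered[meth] / defined if defined else math.nan
        se = math.sqrt(cov * (1 - cov) / defined) if defined else math.nan
        mean_w = width[meth] / defined if defined else math.nan
        out.append(
            CoverageResult(
                method=meth,
                n=n,
                m=m,
                n_na=m - defined,
                coverage=cov,
                mc_se=se,
                mean_width=mean_w,
                seed=seed,
            )
        )
    return out


def run_coverage(
    scenario: Union[Scenario, PairedScenario],
    n: int,
    m: int,
    methods: Optional[Sequence[str]] = None,
    level: float = 0.95,
    seed: int = 0,
) -> list:
    """Monte-Carlo coverage of the requested interval methods.

    Draws ``m`` multinomial samples of size ``n`` from the scenario's
    true cells and reports one :class:`CoverageResult` per method.
    Deterministic in ``seed``; the same draws are reused across methods
    so methods are compared on identical replicates.
    """
    if n < 2:
        raise InputError(f"sample size must be >= 2, got {n}")
    if m < 1:
        raise InputError(f"replicate count must be >= 1, got {m}")
    if not 0 < level < 1:
        raise InputError(f"level must be in (0, 1), got {level}")
    if isinstance(scenario, Scenario):
        methods = tuple(methods) if methods is not None else SINGLE_METHODS
        for meth in methods:
            if meth not in SINGLE_METHODS:
                raise InputError(f"unknown single-MCC method {meth!r}")
        return _run_single(scenario, n, m, methods, level, seed)
    if isinstance(scenario, PairedScenario):
        methods = tuple(methods) if methods is not None else PAIRED_METHODS
        for meth in methods:
            if meth not in PAIRED_METHODS:
                raise InputError(f"unknown paired method {meth!r}")
        return _run_paired(scenario, n, m, methods, level, seed)
    raise InputError(f"expected Scenario or PairedScenario, got {type(scenario).__name__}")
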