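"""Confidence intervals for the difference of two MCCs in a paired design.

Both classifiers are evaluated on the same subjects, so the two MCC
estimates are correlated; the 8-cell joint table p[i][j][k] (pred1,
pred2, actual) carries all the information.  Three constructions:

* Simple method — normal interval for psi(p) = MCC1 - MCC2 with the
  delta-method variance grad psi^T Sigma grad psi / n.
* Zou's method (MOVER) — recovers asymmetry by combining the two
  marginal Fisher's z intervals (l_l, u_l) with the estimated
  correlation c of the two MCC estimates:

      L = d - sqrt((r1-l1)^2 + (u2-r2)^2 - 2 c (r1-l1)(u2-r2))
      U = d + sqrt((u1-r1)^2 + (r2-l2)^2 - 2 c (u1-r1)(r2-l2))

  with d = r1 - r2.  The correlation comes from the delta method via
  the Jacobian of (MCC1, MCC2) — not from normal-theory approximation
  formulas, which presume bivariate-normal data.
* Modified Transformation (MT) method — Fisher-type interval on the
  g(x) = artanh(x/2) scale (the difference lives in (-2, 2)),
  back-transformed by 2 tanh.

NA convention: zero margin in either marginal table, degenerate (zero)
variance, |difference| = 2 for MT, and additionally |marginal MCC| = 1
for Zou (whose marginal Fisher intervals then do not exist).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .ci_single import ConfidenceInterval, _na, z_quantile
from .confusion import PairedCounts
from .errors import InputError

__all__ = [
    "PairedEstimate",
    "paired_estimate",
    "simple_diff_ci",
    "zou_ci",
    "mt_ci",
    "mt_ci_from_probs",
]


@dataclass(frozen=True)
class PairedEstimate:
    """Joint summary of two correlated MCC estimates.

    ``var1``/``var2`` are the estimated asymptotic variances of the two
    MCC estimates (already divided by n); ``corr`` is their estimated
    correlation, clamped to [-1, 1].  All fields nan with ``na=True``
    when a marginal margin is zero.
    """

    r1: float
    r2: float
    diff: float
    corr: float
    var1: float
    var2: float
    na: bool = False
    na_reason: str = ""


# ---------------------------------------------------------------------------
# Vectorized internals (shape (..., 8) plug-in probabilities), shared with
# the Monte-Carlo engine.
# ---------------------------------------------------------------------------


def _paired_stats(phat8: np.ndarray):
    """Per-row paired statistics at plug-in probabilities.

    Returns dict of arrays: r1, r2, diff, var1, var2, cov12, var_psi
    (all unit-n scale: divide by n for sampling variances) and the
    margins-positive mask ``defined``.
    """
    phat8 = np.asarray(phat8, dtype=float)
    m1 = phat8 @ _kernels.J1.T
    m2 = phat8 @ _kernels.J2.T
    defined = np.all(_kernels.margins4(m1) > 0, axis=-1) & np.all(
        _kernels.margins4(m2) > 0, axis=-1
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        r1 = _kernels.snap_unit_phi(_kernels.phi(m1), m1)
        r2 = _kernels.snap_unit_phi(_kernels.phi(m2), m2)
        g1 = _kernels.grad_phi(m1) @ _kernels.J1
        g2 = _kernels.grad_phi(m2) @ _kernels.J2
        var1 = np.clip(_kernels.mult_quad(g1, phat8), 0.0, None)
        var2 = np.clip(_kernels.mult_quad(g2, phat8), 0.0, None)
        cov12 = _kernels.mult_cross(g1, g2, phat8)
        var_psi = np.clip(_kernels.mult_quad(g1 - g2, phat8), 0.0, None)
    from .ci_single import _unit_phi

    nanify = lambda a: np.where(defined, a, np.nan)
    return {
        "r1": nanify(r1),
        "r2": nanify(r2),
        "diff": nanify(r1 - r2),
        "var1": nanify(var1),
        "var2": nanify(var2),
        "cov12": nanify(cov12),
        "var_psi": nanify(var_psi),
        "defined": defined,
        # exact |MCC_l| = 1 masks, from the cells rather than computed phi
        "unit1": _unit_phi(m1),
        "unit2": _unit_phi(m2),
    }


def _corr_from_stats(stats):
    """Estimated correlation of (r1, r2), clamped to [-1, 1]."""
    with np.errstate(divide="ignore", invalid="ignore"):
        c = stats["cov12"] / np.sqrt(stats["var1"] * stats["var2"])
    return np.clip(c, -1.0, 1.0)


def _zou_bounds(r1, r2, l1, u1, l2, u2, corr):
    """Zou's MOVER limits from marginal limits and correlation.

    Radicands are clipped at zero to guard floating-point excursions.
    """
    d = r1 - r2
    rad_l = (r1 - l1) ** 2 + (u2 - r2) ** 2 - 2.0 * corr * (r1 - l1) * (u2 - r2)
    rad_u = (u1 - r1) ** 2 + (r2 - l2) ** 2 - 2.0 * corr * (u1 - r1) * (r2 - l2)
    return d - np.sqrt(np.clip(rad_l, 0.0, None)), d + np.sqrt(np.clip(rad_u, 0.0, None))


# ---------------------------------------------------------------------------
# Scalar API
# ---------------------------------------------------------------------------


def _check_paired(counts: PairedCounts) -> np.ndarray:
    if not isinstance(counts, PairedCounts):
        raise InputError(f"expected PairedCounts, got {type(counts).__name__}")
    if counts.n < 2:
        raise InputError(f"paired interval requires n >= 2, got n = {counts.n}")
    return counts.as_array() / counts.n


def paired_estimate(counts: PairedCounts) -> PairedEstimate:
    """Point estimates, variances and correlation of the two MCCs."""
    phat = _check_paired(counts)
    s = _paired_stats(phat)
    if not bool(s["defined"]):
        return PairedEstimate(
            *(math.nan,) * 6, na=True, na_reason="zero margin in a marginal table"
        )
    n = counts.n
    return PairedEstimate(
        r1=float(s["r1"]),
        r2=float(s["r2"]),
        diff=float(s["diff"]),
        corr=float(_corr_from_stats(s)),
        var1=float(s["var1"]) / n,
        var2=float(s["var2"]) / n,
    )


def simple_diff_ci(counts: PairedCounts, level: float = 0.95) -> ConfidenceInterval:
    """Delta-method normal interval for MCC1 - MCC2 (Simple method)."""
    phat = _check_paired(counts)
    s = _paired_stats(phat)
    if not bool(s["defined"]):
        return _na("simple-diff", level, "zero margin in a marginal table")
    d = float(s["diff"])
    var = float(s["var_psi"]) / counts.n
    if not math.isfinite(var) or var <= 0:
        return _na("simple-diff", level, "zero or non-finite variance estimate", estimate=d)
    half = z_quantile(level) * math.sqrt(var)
    return ConfidenceInterval(d - half, d + half, level, "simple-diff", d)


def zou_ci(counts: PairedCounts, level: float = 0.95) -> ConfidenceInterval:
    """Zou's MOVER interval for MCC1 - MCC2.

    The marginal intervals are Fisher's z intervals at the same level
    as the target interval.
    """
    phat = _check_paired(counts)
    s = _paired_stats(phat)
    if not bool(s["defined"]):
        return _na("zou", level, "zero margin in a marginal table")
    r1, r2 = float(s["r1"]), float(s["r2"])
    d = r1 - r2
    for tag, r, unit in (("1", r1, bool(s["unit1"])), ("2", r2, bool(s["unit2"]))):
        if unit:
            return _na(
                "zou", level,
                f"marginal MCC {tag} equals {math.copysign(1.0, r):g}: Fisher interval undefined",
                estimate=d,
            )
    var1, var2 = float(s["var1"]), float(s["var2"])
    if min(var1, var2) <= 0 or not (math.isfinite(var1) and math.isfinite(var2)):
        return _na("zou", level, "degenerate marginal variance estimate", estimate=d)
    z = z_quantile(level)
    n = counts.n
    se1 = math.sqrt(var1 / n) / (1.0 - r1 * r1)
    se2 = math.sqrt(var2 / n) / (1.0 - r2 * r2)
    l1, u1 = math.tanh(math.atanh(r1) - z * se1), math.tanh(math.atanh(r1) + z * se1)
    l2, u2 = math.tanh(math.atanh(r2) - z * se2), math.tanh(math.atanh(r2) + z * se2)
    corr = float(_corr_from_stats(s))
    lo, hi = _zou_bounds(r1, r2, l1, u1, l2, u2, corr)
    return ConfidenceInterval(float(lo), float(hi), level, "zou", d)


def mt_ci(counts: PairedCounts, level: float = 0.95) -> ConfidenceInterval:
    """Modified Transformation interval: Fisher-type on the (-2, 2) scale."""
    phat = _check_paired(counts)
    return mt_ci_from_probs(phat, counts.n, level)


def mt_ci_from_probs(probs, n: int, level: float = 0.95) -> ConfidenceInterval:
    """MT interval treating ``probs`` as plug-in cell probabilities with
    effective sample size ``n``.

    Used directly by the joint-reconstruction sweep, where the cells are
    reconstructed probabilities rather than observed counts.
    """
    if hasattr(probs, "as_array"):
        probs = probs.as_array()
    phat = np.asarray(probs, dtype=float).ravel()
    if phat.shape != (8,):
        raise InputError(f"expected 8 cell probabilities, got shape {phat.shape}")
    if n < 2:
        raise InputError(f"mt interval requires n >= 2, got n = {n}")
    s = _paired_stats(phat)
    if not bool(s["defined"]):
        return _na("mt", level, "zero margin in a marginal table")
    d = float(s["diff"])
    at_boundary = bool(s["unit1"]) and bool(s["unit2"]) and float(s["r1"]) * float(s["r2"]) < 0
    if at_boundary or abs(d) >= 2:
        return _na("mt", level, "difference at boundary |diff| = 2", estimate=d)
    var = float(s["var_psi"]) / n
    if not math.isfinite(var) or var <= 0:
        return _na("mt", level, "zero or non-finite variance estimate", estimate=d)
    se_g = math.sqrt(var) * 2.0 / (4.0 - d * d)
    center = math.atanh(d / 2.0)
    z = z_quantile(level)
    return ConfidenceInterval(
        2.0 * math.tanh(center - z * se_g), 2.0 * math.tanh(center + z * se_g), level, "mt", d
    )
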