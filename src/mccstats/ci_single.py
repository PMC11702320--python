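"""Confidence intervals for a single MCC.

Three constructions, all asymptotic and all evaluated at the plug-in
cell probabilities p-hat = counts / n:

* Simple method — normal interval directly on the MCC scale,
  MCC-hat +/- z * sqrt(grad phi^T Sigma grad phi / n).  Symmetric; the
  limits are deliberately not truncated to [-1, 1].
* Fisher's z method — normal interval on the artanh scale with the
  delta-method variance of f o phi, back-transformed by tanh.  Respects
  the skewness of the MCC sampling distribution; limits lie strictly
  inside (-1, 1).
* Naive 1/(n-3) method — Fisher's transform with the classical
  normal-theory variance 1/(n-3).  That variance is derived for
  bivariate-normal data and is unreliable for binary data; the method
  is included as the comparison baseline.

NA convention: an interval is NA (fields nan, ``na=True`` with a
reason) when the MCC itself is undefined (a zero margin), when a
transform is evaluated at its boundary (|MCC-hat| = 1 for the Fisher
scale), or when the estimated variance is zero or non-finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from . import _kernels
from .confusion import ConfusionCounts
from .errors import InputError

__all__ = [
    "ConfidenceInterval",
    "simple_ci",
    "fisher_ci",
    "naive_fisher_ci",
    "z_quantile",
]


@dataclass(frozen=True)
class ConfidenceInterval:
    """A two-sided confidence interval with its point estimate.

    ``na=True`` marks an interval that could not be constructed;
    ``na_reason`` says why and the numeric fields are nan.
    """

    lower: float
    upper: float
    level: float
    method: str
    estimate: float
    na: bool = False
    na_reason: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.level < 1:
            raise InputError(f"level must be in (0, 1), got {self.level}")
        if not self.na and not (self.lower <= self.estimate <= self.upper):
            raise InputError(
                f"malformed interval: lower={self.lower}, estimate={self.estimate}, upper={self.upper}"
            )

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, value: float) -> bool:
        return (not self.na) and self.lower <= value <= self.upper


def z_quantile(level: float) -> float:
    """Upper alpha/2 standard-normal quantile for a two-sided level."""
    if not 0 < level < 1:
        raise InputError(f"level must be in (0, 1), got {level}")
    return float(norm.ppf(0.5 + level / 2.0))


def _na(method: str, level: float, reason: str, estimate: float = math.nan) -> ConfidenceInterval:
    return ConfidenceInterval(
        lower=math.nan,
        upper=math.nan,
        level=level,
        method=method,
        estimate=estimate,
        na=True,
        na_reason=reason,
    )


def _check_counts(counts: ConfusionCounts, min_n: int, method: str) -> None:
    if not isinstance(counts, ConfusionCounts):
        raise InputError(f"expected ConfusionCounts, got {type(counts).__name__}")
    if counts.n < min_n:
        raise InputError(f"{method} interval requires n >= {min_n}, got n = {counts.n}")


# ---------------------------------------------------------------------------
# Vectorized internals shared with the Monte-Carlo engine.  All take cell
# probability arrays of shape (..., 4) and a scalar n, and return unit-free
# bounds plus definedness masks; nan marks undefined entries.
# ---------------------------------------------------------------------------


def _phi_and_var(phat: np.ndarray):
    """phi and its unit-n delta variance at plug-in probabilities.

    Returns (r, var, defined) where defined marks rows with all margins
    positive; r and var are nan elsewhere.
    """
    phat = np.asarray(phat, dtype=float)
    defined = np.all(_kernels.margins4(phat) > 0, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = _kernels.snap_unit_phi(_kernels.phi(phat), phat)
        var = _kernels.mult_quad(_kernels.grad_phi(phat), phat)
    var = np.clip(var, 0.0, None)
    r = np.where(defined, r, np.nan)
    var = np.where(defined, var, np.nan)
    return r, var, defined


def _unit_phi(phat: np.ndarray) -> np.ndarray:
    """Exact mask for |phi| = 1: both off-diagonal or both diagonal cells
    zero.  Detected from the cells rather than the computed phi, which
    can land one ulp below 1."""
    phat = np.asarray(phat, dtype=float)
    off = (phat[..., 1] == 0) & (phat[..., 2] == 0)
    diag = (phat[..., 0] == 0) & (phat[..., 3] == 0)
    return off | diag


def _simple_bounds(phat: np.ndarray, n: int, z: float):
    """Vectorized Simple-method bounds; nan outside the defined set."""
    r, var, defined = _phi_and_var(phat)
    half = z * np.sqrt(var / n)
    return r - half, r + half, r, defined


def _fisher_bounds(phat: np.ndarray, n: int, z: float):
    """Vectorized Fisher's z bounds; defined requires |phi| < 1."""
    r, var, defined = _phi_and_var(phat)
    with np.errstate(divide="ignore", invalid="ignore"):
        defined = defined & ~_unit_phi(phat)
        se_z = np.where(defined, np.sqrt(var / n) / (1.0 - r * r), np.nan)
        center = np.arctanh(np.where(defined, r, 0.0))
        center = np.where(defined, center, np.nan)
    return np.tanh(center - z * se_z), np.tanh(center + z * se_z), r, defined


def _naive_bounds(phat: np.ndarray, n: int, z: float):
    """Vectorized 1/(n-3)-variance bounds; defined requires |phi| < 1."""
    r, _, defined = _phi_and_var(phat)
    defined = defined & ~_unit_phi(phat)
    half = z * math.sqrt(1.0 / (n - 3))
    with np.errstate(invalid="ignore"):
        center = np.where(defined, np.arctanh(np.where(defined, r, 0.0)), np.nan)
    return np.tanh(center - half), np.tanh(center + half), r, defined


# ---------------------------------------------------------------------------
# Scalar API
# ---------------------------------------------------------------------------


def simple_ci(counts: ConfusionCounts, level: float = 0.95) -> ConfidenceInterval:
    """Delta-method normal interval on the MCC scale (Simple method)."""
    _check_counts(counts, 2, "simple")
    z = z_quantile(level)
    phat = counts.as_array() / counts.n
    if np.any(_kernels.margins4(phat) == 0):
        return _na("simple", level, "zero margin: MCC undefined")
    r, var, _ = _phi_and_var(phat)
    r = float(r)
    var = float(var)
    if not math.isfinite(var) or var <= 0:
        return _na("simple", level, "zero or non-finite variance estimate", estimate=r)
    half = z * math.sqrt(var / counts.n)
    return ConfidenceInterval(r - half, r + half, level, "simple", r)


def fisher_ci(counts: ConfusionCounts, level: float = 0.95) -> ConfidenceInterval:
    """Fisher's z interval: delta variance on the artanh scale, tanh back."""
    _check_counts(counts, 2, "fisher")
    z = z_quantile(level)
    phat = counts.as_array() / counts.n
    if np.any(_kernels.margins4(phat) == 0):
        return _na("fisher", level, "zero margin: MCC undefined")
    r, var, _ = _phi_and_var(phat)
    r = float(r)
    var = float(var)
    if _unit_phi(phat):
        r = math.copysign(1.0, r)
        return _na("fisher", level, f"MCC equals {r:g}: Fisher transform undefined", estimate=r)
    if not math.isfinite(var) or var <= 0:
        return _na("fisher", level, "zero or non-finite variance estimate", estimate=r)
    se_z = math.sqrt(var / counts.n) / (1.0 - r * r)
    center = math.atanh(r)
    return ConfidenceInterval(
        math.tanh(center - z * se_z), math.tanh(center + z * se_z), level, "fisher", r
    )


def naive_fisher_ci(counts: ConfusionCounts, level: float = 0.95) -> ConfidenceInterval:
    """Fisher's transform with the normal-theory variance 1/(n-3)."""
    _check_counts(counts, 4, "naive")
    z = z_quantile(level)
    phat = counts.as_array() / counts.n
    if np.any(_kernels.margins4(phat) == 0):
        return _na("naive", level, "zero margin: MCC undefined")
    r = float(_kernels.phi(phat))
    if _unit_phi(phat):
        r = math.copysign(1.0, r)
        return _na("naive", level, f"MCC equals {r:g}: Fisher transform undefined", estimate=r)
    half = z * math.sqrt(1.0 / (counts.n - 3))
    center = math.atanh(r)
    return ConfidenceInterval(
        math.tanh(center - half), math.tanh(center + half), level, "naive", r
    )
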