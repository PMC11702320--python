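"""Joint-probability reconstruction for partially identified paired tables.

Published classifier comparisons often report only each classifier's
sensitivity and specificity on a common benchmark (here: n_pos positive
and n_neg negative samples).  Those marginals do not identify the 8-cell
joint distribution p[i][j][k]: two degrees of freedom remain, chosen as

* p001 — probability the truth is positive but both classifiers predict
  negative (both miss);
* p110 — probability the truth is negative but both classifiers predict
  positive (both false-alarm).

Given (p001, p110) inside their feasibility box, the joint is fully
determined by the cell algebra (with pi = n_pos / (n_pos + n_neg)):

    p111 = pi (s1 + s2 - 1) + p001     p000 = (1-pi)(t1 + t2 - 1) + p110
    p101 = pi (1 - s2) - p001          p010 = (1-pi)(1 - t2) - p110
    p011 = pi (1 - s1) - p001          p100 = (1-pi)(1 - t1) - p110

Nonnegativity of all cells gives the box

    p001 in [max(0, pi (1 - s1 - s2)),      pi  * min(1 - s1, 1 - s2)]
    p110 in [max(0, (1-pi)(1 - t1 - t2)), (1-pi) * min(1 - t1, 1 - t2)]

Sweeping a grid over the box and computing the Modified-Transformation
interval for the MCC difference at each point shows how the inference
depends on the unidentified agreement structure: the point difference is
fixed by the marginals, while the interval width varies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .ci_paired import mt_ci_from_probs
from .confusion import PairedCellProbs
from .errors import InfeasibleError, InputError

__all__ = [
    "MarginalSummary",
    "FeasibleBox",
    "feasible_box",
    "reconstruct_joint",
    "mt_grid",
]


@dataclass(frozen=True)
class MarginalSummary:
    """Benchmark composition and per-classifier marginal accuracies."""

    n_pos: int
    n_neg: int
    sens1: float
    spec1: float
    sens2: float
    spec2: float

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise InputError("n_pos and n_neg must be >= 1")
        for name in ("sens1", "spec1", "sens2", "spec2"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InputError(f"{name} must be in [0, 1], got {v}")

    @property
    def n(self) -> int:
        return self.n_pos + self.n_neg

    @property
    def prevalence(self) -> float:
        return self.n_pos / self.n


@dataclass(frozen=True)
class FeasibleBox:
    """Attainable (p001, p110) rectangle implied by the marginals."""

    p001_min: float
    p001_max: float
    p110_min: float
    p110_max: float


def feasible_box(marg: MarginalSummary) -> FeasibleBox:
    """Nonnegativity box for the free parameters (p001, p110)."""
    pi = marg.prevalence
    p001_min = max(0.0, pi * (1.0 - marg.sens1 - marg.sens2))
    p001_max = pi * min(1.0 - marg.sens1, 1.0 - marg.sens2)
    p110_min = max(0.0, (1.0 - pi) * (1.0 - marg.spec1 - marg.spec2))
    p110_max = (1.0 - pi) * min(1.0 - marg.spec1, 1.0 - marg.spec2)
    if p001_min > p001_max + 1e-15 or p110_min > p110_max + 1e-15:
        raise InfeasibleError("marginals admit no joint distribution")
    return FeasibleBox(p001_min, max(p001_min, p001_max), p110_min, max(p110_min, p110_max))


def reconstruct_joint(marg: MarginalSummary, p001: float, p110: float) -> PairedCellProbs:
    """The unique joint with the given marginals and free cells.

    Raises :class:`InfeasibleError` naming the first negative cell when
    (p001, p110) falls outside the feasibility box.
    """
    pi = marg.prevalence
    s1, s2, t1, t2 = marg.sens1, marg.sens2, marg.spec1, marg.spec2
    cells = {
        "p111": pi * (s1 + s2 - 1.0) + p001,
        "p101": pi * (1.0 - s2) - p001,
        "p011": pi * (1.0 - s1) - p001,
        "p001": p001,
        "p000": (1.0 - pi) * (t1 + t2 - 1.0) + p110,
        "p010": (1.0 - pi) * (1.0 - t2) - p110,
        "p100": (1.0 - pi) * (1.0 - t1) - p110,
        "p110": p110,
    }
    for name, v in cells.items():
        if v < -1e-12:
            raise InfeasibleError(
                f"(p001={p001}, p110={p110}) is outside the feasible box: cell {name} = {v} < 0"
            )
    p = np.zeros((2, 2, 2))
    for name, v in cells.items():
        i, j, k = (int(c) for c in name[1:])
        p[i, j, k] = max(v, 0.0)
    return PairedCellProbs.from_array(p)


def _grid(lo: float, hi: float, step: float) -> np.ndarray:
    """Closed grid from lo to hi in the given step, endpoints included."""
    if step <= 0:
        raise InputError(f"step must be > 0, got {step}")
    k = int(math.floor((hi - lo) / step + 1e-9))
    pts = lo + step * np.arange(k + 1)
    if hi - pts[-1] > 1e-12:
        pts = np.append(pts, hi)
    return pts


def mt_grid(
    marg: MarginalSummary,
    p001_step: float = 0.025,
    p110_step: float = 0.001,
    level: float = 0.95,
) -> pd.DataFrame:
    """MT intervals for the MCC difference over the feasibility grid.

    One row per in-box grid point with columns p001, p110, diff, lower,
    upper and excludes_zero.  The effective sample size for the
    delta-method variance is the benchmark size n_pos + n_neg, with the
    reconstructed cells treated as exact plug-in probabilities.
    """
    box = feasible_box(marg)
    rows = []
    for p001 in _grid(box.p001_min, box.p001_max, p001_step):
        for p110 in _grid(box.p110_min, box.p110_max, p110_step):
            joint = reconstruct_joint(marg, float(p001), float(p110))
            ci = mt_ci_from_probs(joint, marg.n, level)
            rows.append(
                {
                    "p001": float(p001),
                    "p110": float(p110),
                    "diff": ci.estimate,
                    "lower": ci.lower,
                    "upper": ci.upper,
                    "na": ci.na,
                    "excludes_zero": (not ci.na) and (ci.lower > 0.0 or ci.upper < 0.0),
                }
            )
    return pd.DataFrame(rows)
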