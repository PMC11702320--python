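"""Confusion-table types, the MCC and companion metrics, and the variance
stabilizing transforms.

The Matthews correlation coefficient (MCC, also called the phi
coefficient) of a 2x2 confusion table

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

is the Pearson correlation between the binary actual and predicted label
vectors.  It is undefined (NA, represented as ``nan``) whenever one of
the four margins is zero, since the denominator then vanishes.

Two strictly increasing transforms are provided:

* ``fisher_z``: f(x) = artanh(x), mapping a correlation in (-1, 1) to the
  real line (Fisher's z transformation);
* ``mt_transform``: g(x) = (1/2) log((2+x)/(2-x)) = artanh(x/2), the same
  idea stretched to (-2, 2) so it applies to a *difference* of two MCCs.

Paired tables index cells as (i, j, k) = (prediction of classifier 1,
prediction of classifier 2, actual label), all binary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Union

import numpy as np

from . import _kernels
from .errors import DomainError, InputError

__all__ = [
    "ConfusionCounts",
    "CellProbs",
    "PairedCounts",
    "PairedCellProbs",
    "MetricSet",
    "counts_from_labels",
    "mcc",
    "metric_set",
    "fisher_z",
    "fisher_z_inv",
    "mt_transform",
    "mt_transform_inv",
    "marginalize",
]

_PROB_TOL = 1e-12


@dataclass(frozen=True)
class ConfusionCounts:
    """Observed 2x2 confusion table (nonnegative integers, total >= 1)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and not isinstance(v, bool)):
                raise InputError(f"{name} must be an integer, got {v!r}")
            if v < 0:
                raise InputError(f"{name} must be >= 0, got {v}")
        if self.n < 1:
            raise InputError("total count must be >= 1")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_array(self) -> np.ndarray:
        """Cell vector in the canonical order (p11, p10, p01, p00)."""
        return np.array([self.tp, self.fp, self.fn, self.tn], dtype=float)

    def to_probs(self) -> "CellProbs":
        """Plug-in cell probabilities p-hat = counts / n."""
        return CellProbs.from_array(self.as_array() / self.n)

    def scaled(self, k: int) -> "ConfusionCounts":
        """The same table with every count multiplied by integer k."""
        return ConfusionCounts(self.tp * k, self.fp * k, self.fn * k, self.tn * k)


@dataclass(frozen=True)
class CellProbs:
    """Cell probabilities (p11, p10, p01, p00) of a 2x2 table; sum to 1."""

    p11: float
    p10: float
    p01: float
    p00: float

    def __post_init__(self) -> None:
        a = self.as_array()
        if np.any(a < -_PROB_TOL) or np.any(a > 1 + _PROB_TOL):
            raise InputError(f"cell probabilities must lie in [0, 1], got {a}")
        if abs(a.sum() - 1.0) > _PROB_TOL:
            raise InputError(f"cell probabilities must sum to 1, got {a.sum()!r}")

    @classmethod
    def from_array(cls, a: Iterable[float]) -> "CellProbs":
        a = np.asarray(a, dtype=float)
        if a.shape != (4,):
            raise InputError(f"expected 4 cell probabilities, got shape {a.shape}")
        return cls(*map(float, a))

    def as_array(self) -> np.ndarray:
        return np.array([self.p11, self.p10, self.p01, self.p00], dtype=float)


@dataclass(frozen=True)
class PairedCounts:
    """Counts c[i][j][k] of a paired design, shape (2, 2, 2)."""

    cells: tuple

    def __post_init__(self) -> None:
        a = np.asarray(self.cells)
        if a.shape != (2, 2, 2):
            raise InputError(f"paired counts must have shape (2,2,2), got {a.shape}")
        if not np.issubdtype(a.dtype, np.integer):
            if not np.all(a == np.floor(a)):
                raise InputError("paired counts must be integers")
        if np.any(a < 0):
            raise InputError("paired counts must be >= 0")
        if a.sum() < 1:
            raise InputError("total paired count must be >= 1")
        object.__setattr__(
            self, "cells", tuple(tuple(tuple(int(x) for x in row) for row in plane) for plane in a)
        )

    @classmethod
    def from_array(cls, a) -> "PairedCounts":
        return cls(cells=np.asarray(a))

    @property
    def n(self) -> int:
        return int(np.asarray(self.cells).sum())

    def count(self, i: int, j: int, k: int) -> int:
        return self.cells[i][j][k]

    def as_array(self) -> np.ndarray:
        """Flat length-8 float vector, C-order over (i, j, k)."""
        return np.asarray(self.cells, dtype=float).ravel()

    def to_probs(self) -> "PairedCellProbs":
        return PairedCellProbs.from_array(self.as_array() / self.n)


@dataclass(frozen=True)
class PairedCellProbs:
    """Joint probabilities p[i][j][k] of a paired design; sum to 1."""

    cells: tuple

    def __post_init__(self) -> None:
        a = np.asarray(self.cells, dtype=float)
        if a.shape != (2, 2, 2):
            raise InputError(f"paired probabilities must have shape (2,2,2), got {a.shape}")
        if np.any(a < -_PROB_TOL) or np.any(a > 1 + _PROB_TOL):
            raise InputError("paired cell probabilities must lie in [0, 1]")
        if abs(a.sum() - 1.0) > _PROB_TOL:
            raise InputError(f"paired cell probabilities must sum to 1, got {a.sum()!r}")
        object.__setattr__(
            self, "cells", tuple(tuple(tuple(float(x) for x in row) for row in plane) for plane in a)
        )

    @classmethod
    def from_array(cls, a) -> "PairedCellProbs":
        a = np.asarray(a, dtype=float)
        if a.shape == (8,):
            a = a.reshape(2, 2, 2)
        return cls(cells=a)

    def prob(self, i: int, j: int, k: int) -> float:
        return self.cells[i][j][k]

    def as_array(self) -> np.ndarray:
        """Flat length-8 float vector, C-order over (i, j, k)."""
        return np.asarray(self.cells, dtype=float).ravel()


@dataclass(frozen=True)
class MetricSet:
    """Companion performance metrics of one confusion table.

    Each metric is ``nan`` exactly when its own denominator is zero.
    """

    mcc: float
    accuracy: float
    balanced_accuracy: float
    f1: float
    tpr: float
    tnr: float
    precision: float


TableLike = Union[ConfusionCounts, CellProbs, PairedCounts, PairedCellProbs]


def _cell_vector(table: Union[ConfusionCounts, CellProbs]) -> np.ndarray:
    if isinstance(table, (ConfusionCounts, CellProbs)):
        return table.as_array()
    raise InputError(f"expected ConfusionCounts or CellProbs, got {type(table).__name__}")


def counts_from_labels(actual, predicted) -> ConfusionCounts:
    """Tally a 2x2 confusion table from binary label vectors.

    The positive class is coded 1.  Raises :class:`InputError` naming the
    first offending index on a non-binary entry or a length mismatch.
    """
    a = np.asarray(actual)
    p = np.asarray(predicted)
    if a.ndim != 1 or p.ndim != 1:
        raise InputError("label vectors must be one-dimensional")
    if a.shape[0] != p.shape[0]:
        raise InputError(f"length mismatch: actual has {a.shape[0]}, predicted has {p.shape[0]}")
    if a.shape[0] < 1:
        raise InputError("label vectors must have length >= 1")
    for name, v in (("actual", a), ("predicted", p)):
        bad = ~np.isin(v, (0, 1))
        if bad.any():
            idx = int(np.flatnonzero(bad)[0])
            raise InputError(f"non-binary value {v[idx]!r} in {name} at index {idx}")
    a = a.astype(int)
    p = p.astype(int)
    return ConfusionCounts(
        tp=int(np.sum((p == 1) & (a == 1))),
        fp=int(np.sum((p == 1) & (a == 0))),
        fn=int(np.sum((p == 0) & (a == 1))),
        tn=int(np.sum((p == 0) & (a == 0))),
    )


def mcc(table: Union[ConfusionCounts, CellProbs]) -> float:
    """MCC of a table; ``nan`` when any margin is zero.

    Scale invariant: counts and the corresponding plug-in probabilities
    give the identical value.
    """
    v = _cell_vector(table)
    if np.any(_kernels.margins4(v) == 0):
        return math.nan
    return float(_kernels.snap_unit_phi(_kernels.phi(v), v))


def metric_set(table: ConfusionCounts) -> MetricSet:
    """Accuracy, balanced accuracy, F1, TPR, TNR, precision and MCC."""
    if not isinstance(table, ConfusionCounts):
        raise InputError(f"expected ConfusionCounts, got {type(table).__name__}")
    tp, fp, fn, tn = table.tp, table.fp, table.fn, table.tn

    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else math.nan

    tpr = ratio(tp, tp + fn)
    tnr = ratio(tn, tn + fp)
    return MetricSet(
        mcc=mcc(table),
        accuracy=(tp + tn) / table.n,
        balanced_accuracy=(tpr + tnr) / 2.0,
        f1=ratio(2 * tp, 2 * tp + fp + fn),
        tpr=tpr,
        tnr=tnr,
        precision=ratio(tp, tp + fp),
    )


def fisher_z(x: float) -> float:
    """Fisher's z transformation f(x) = artanh(x), domain (-1, 1)."""
    if not abs(x) < 1:
        raise DomainError(f"fisher_z requires |x| < 1, got {x}")
    return float(np.arctanh(x))


def fisher_z_inv(y: float) -> float:
    """Inverse of Fisher's z: tanh."""
    return float(np.tanh(y))


def mt_transform(x: float) -> float:
    """g(x) = (1/2) log((2+x)/(2-x)) = artanh(x/2), domain (-2, 2).

    Applied to an MCC difference, whose natural range is [-2, 2].
    """
    if not abs(x) < 2:
        raise DomainError(f"mt_transform requires |x| < 2, got {x}")
    return float(np.arctanh(x / 2.0))


def mt_transform_inv(y: float) -> float:
    """Inverse of the modified transformation: 2 tanh(y)."""
    return float(2.0 * np.tanh(y))


def marginalize(paired: Union[PairedCounts, PairedCellProbs], which: int):
    """Collapse a paired table to the 2x2 table of classifier 1 or 2.

    For classifier 1 the cells are (p111+p101, p110+p100, p011+p001,
    p010+p000); classifier 2 sums over the first prediction index
    instead.  Mass is conserved.
    """
    if which not in (1, 2):
        raise InputError(f"which must be 1 or 2, got {which!r}")
    J = _kernels.J1 if which == 1 else _kernels.J2
    v = J @ paired.as_array()
    if isinstance(paired, PairedCounts):
        return ConfusionCounts(tp=int(v[0]), fp=int(v[1]), fn=int(v[2]), tn=int(v[3]))
    if isinstance(paired, PairedCellProbs):
        return CellProbs.from_array(v)
    raise InputError(f"expected PairedCounts or PairedCellProbs, got {type(paired).__name__}")
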