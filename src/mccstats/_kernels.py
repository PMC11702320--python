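"""Vectorized numerical kernels shared across the package.

Everything here operates on plain ndarrays whose last axis indexes
multinomial cells: length 4 in the order (p11, p10, p01, p00) =
(TP, FP, FN, TN) for a single classifier, length 8 in C-order over
(i, j, k) = (pred1, pred2, actual) for a paired design.  Leading axes
broadcast, so the Monte-Carlo engine can push a million replicates
through these in one call.

The quadratic forms exploit the multinomial covariance structure
Sigma(p) = diag(p) - p p^T, so g^T Sigma g is computed without ever
materializing a matrix:

    g^T Sigma(p) g = sum_a p_a g_a^2 - (sum_a p_a g_a)^2
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "J1",
    "J2",
    "margins4",
    "phi",
    "grad_phi",
    "mult_quad",
    "mult_cross",
    "psi",
    "grad_psi",
]

# Marginalization maps (4x8, entries 0/1): J_l @ p8 gives the 2x2 cell
# vector (p11, p10, p01, p00) of classifier l.  Flat index of cell
# (i, j, k) is 4i + 2j + k.
J1 = np.zeros((4, 8))
J1[0, [7, 5]] = 1.0  # TP1 = p111 + p101
J1[1, [6, 4]] = 1.0  # FP1 = p110 + p100
J1[2, [3, 1]] = 1.0  # FN1 = p011 + p001
J1[3, [2, 0]] = 1.0  # TN1 = p010 + p000

J2 = np.zeros((4, 8))
J2[0, [7, 3]] = 1.0  # TP2 = p111 + p011
J2[1, [6, 2]] = 1.0  # FP2 = p110 + p010
J2[2, [5, 1]] = 1.0  # FN2 = p101 + p001
J2[3, [4, 0]] = 1.0  # TN2 = p100 + p000

J1.setflags(write=False)
J2.setflags(write=False)


def margins4(p: np.ndarray) -> np.ndarray:
    """The four margins (TP+FP, TP+FN, TN+FP, TN+FN) of a 2x2 table.

    Any zero margin makes the phi denominator vanish, so these decide
    whether the MCC is defined.
    """
    p11, p10, p01, p00 = np.moveaxis(np.asarray(p, dtype=float), -1, 0)
    return np.stack([p11 + p10, p11 + p01, p00 + p10, p00 + p01], axis=-1)


def phi(p: np.ndarray) -> np.ndarray:
    """phi coefficient (MCC) of cell vectors; scale invariant.

    Returns nan where a margin is zero (0/0).
    """
    p11, p10, p01, p00 = np.moveaxis(np.asarray(p, dtype=float), -1, 0)
    num = p11 * p00 - p10 * p01
    with np.errstate(divide="ignore", invalid="ignore"):
        den = np.sqrt((p11 + p10) * (p11 + p01) * (p00 + p10) * (p00 + p01))
        return num / den


def grad_phi(p: np.ndarray) -> np.ndarray:
    """Gradient of phi with respect to the four cell probabilities.

    phi = N / sqrt(M1 M2 M3 M4) with N = p11 p00 - p10 p01 and margins
    M1 = p11+p10, M2 = p11+p01, M3 = p00+p10, M4 = p00+p01; the quotient
    rule gives, e.g.,

        d phi / d p11 = p00 / D - (phi/2) (1/M1 + 1/M2)

    with D the denominator.  The gradient is taken of the unconstrained
    formula on an open box around the simplex, as the delta method
    requires; the multinomial covariance absorbs the sum-to-one
    degeneracy.
    """
    p11, p10, p01, p00 = np.moveaxis(np.asarray(p, dtype=float), -1, 0)
    m1 = p11 + p10
    m2 = p11 + p01
    m3 = p00 + p10
    m4 = p00 + p01
    den = np.sqrt(m1 * m2 * m3 * m4)
    f = (p11 * p00 - p10 * p01) / den
    g11 = p00 / den - 0.5 * f * (1.0 / m1 + 1.0 / m2)
    g10 = -p01 / den - 0.5 * f * (1.0 / m1 + 1.0 / m3)
    g01 = -p10 / den - 0.5 * f * (1.0 / m2 + 1.0 / m4)
    g00 = p11 / den - 0.5 * f * (1.0 / m3 + 1.0 / m4)
    return np.stack([g11, g10, g01, g00], axis=-1)


def snap_unit_phi(r: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Replace r by exactly +/-1 where the cells dictate |phi| = 1.

    phi = 1 iff both off-diagonal cells are zero, -1 iff both diagonal
    cells are zero; the floating evaluation can land one ulp short, so
    the boundary is detected from the cells themselves.
    """
    p = np.asarray(p, dtype=float)
    pos = (p[..., 1] == 0) & (p[..., 2] == 0)
    neg = (p[..., 0] == 0) & (p[..., 3] == 0)
    return np.where(neg, -1.0, np.where(pos, 1.0, r))


def mult_quad(g: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Quadratic form g^T Sigma(p) g for multinomial Sigma, vectorized."""
    g = np.asarray(g, dtype=float)
    p = np.asarray(p, dtype=float)
    return (p * g * g).sum(axis=-1) - (p * g).sum(axis=-1) ** 2


def mult_cross(g1: np.ndarray, g2: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Bilinear form g1^T Sigma(p) g2 for multinomial Sigma, vectorized."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    p = np.asarray(p, dtype=float)
    return (p * g1 * g2).sum(axis=-1) - (p * g1).sum(axis=-1) * (p * g2).sum(axis=-1)


def psi(p8: np.ndarray) -> np.ndarray:
    """MCC difference psi(p) = phi(J1 p) - phi(J2 p) of a paired table."""
    p8 = np.asarray(p8, dtype=float)
    return phi(p8 @ J1.T) - phi(p8 @ J2.T)


def grad_psi(p8: np.ndarray) -> np.ndarray:
    """Gradient of psi: J1^T grad phi(m1) - J2^T grad phi(m2)."""
    p8 = np.asarray(p8, dtype=float)
    return grad_phi(p8 @ J1.T) @ J1 - grad_phi(p8 @ J2.T) @ J2
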