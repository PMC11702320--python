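"""Delta-method machinery: multinomial covariance, analytic gradients,
quadratic-form variances, and a finite-difference oracle.

For counts n*p-hat following a multinomial(n, p) distribution, the CLT
gives sqrt(n) (p-hat - p) -> N(0, Sigma(p)) with Sigma(p) = diag(p) -
p p^T.  Any smooth scalar statistic h(p-hat) then satisfies

    sqrt(n) (h(p-hat) - h(p)) -> N(0, grad h(p)^T Sigma(p) grad h(p)).

This module supplies the gradients needed for the MCC statistics:

* ``grad_phi`` — the MCC itself, phi(p) on a 4-cell table;
* ``grad_fisher_phi`` — f o phi with f = artanh (chain rule factor
  1 / (1 - phi^2));
* ``grad_psi`` — the paired MCC difference psi(p) = phi(J1 p) - phi(J2 p)
  on an 8-cell table;
* ``grad_psi_tilde`` — the 8x2 Jacobian of the pair (MCC1, MCC2);
* ``grad_g_psi`` — g o psi with g = artanh(./2) (chain rule factor
  2 / (4 - psi^2)).

Gradients are taken of the unconstrained formulas on an open box around
the simplex; Sigma(p) itself annihilates the constant direction, so no
tangent-space projection is needed (or wanted) for the quadratic form.
"""

from __future__ import annotations

from typing import Callable, Union

import numpy as np

from . import _kernels
from .confusion import CellProbs, PairedCellProbs
from .errors import DomainError, InputError

__all__ = [
    "multinomial_cov",
    "grad_phi",
    "grad_fisher_phi",
    "grad_psi",
    "grad_psi_tilde",
    "grad_g_psi",
    "delta_variance",
    "fd_gradient",
]

_VAR_CLIP = 1e-12


def _as_vector(p, d: int) -> np.ndarray:
    if isinstance(p, CellProbs) or isinstance(p, PairedCellProbs):
        v = p.as_array()
    else:
        v = np.asarray(p, dtype=float).ravel()
    if v.shape != (d,):
        raise InputError(f"expected a length-{d} probability vector, got shape {v.shape}")
    return v


def _any_vector(p) -> np.ndarray:
    if isinstance(p, (CellProbs, PairedCellProbs)):
        return p.as_array()
    v = np.asarray(p, dtype=float).ravel()
    if v.shape not in ((4,), (8,)):
        raise InputError(f"expected a length-4 or length-8 vector, got shape {v.shape}")
    return v


def multinomial_cov(p) -> np.ndarray:
    """Sigma(p) = diag(p) - p p^T, the multinomial covariance of p-hat.

    Symmetric, positive semidefinite, rows summing to zero.
    """
    v = _any_vector(p)
    return np.diag(v) - np.outer(v, v)


def _require_margins(v4: np.ndarray, what: str = "table") -> None:
    if np.any(_kernels.margins4(v4) <= 0):
        raise DomainError(f"{what} has a zero margin; phi gradient undefined")


def grad_phi(p) -> np.ndarray:
    """Analytic gradient of phi at a 4-cell probability vector."""
    v = _as_vector(p, 4)
    _require_margins(v)
    return _kernels.grad_phi(v)


def grad_fisher_phi(p) -> np.ndarray:
    """Gradient of f o phi, i.e. grad phi / (1 - phi^2)."""
    v = _as_vector(p, 4)
    _require_margins(v)
    r = float(_kernels.phi(v))
    if abs(r) >= 1:
        raise DomainError(f"|phi| = {abs(r)} >= 1; Fisher transform gradient undefined")
    return _kernels.grad_phi(v) / (1.0 - r * r)


def _require_paired_margins(v8: np.ndarray) -> None:
    if np.any(_kernels.margins4(v8 @ _kernels.J1.T) <= 0):
        raise DomainError("marginal table of classifier 1 has a zero margin")
    if np.any(_kernels.margins4(v8 @ _kernels.J2.T) <= 0):
        raise DomainError("marginal table of classifier 2 has a zero margin")


def grad_psi(p) -> np.ndarray:
    """Gradient of the MCC difference psi on an 8-cell vector."""
    v = _as_vector(p, 8)
    _require_paired_margins(v)
    return _kernels.grad_psi(v)


def grad_psi_tilde(p) -> np.ndarray:
    """8x2 Jacobian of psi-tilde(p) = (MCC1(p), MCC2(p)).

    Column l is J_l^T grad phi(marginal l); grad psi is column 1 minus
    column 2.
    """
    v = _as_vector(p, 8)
    _require_paired_margins(v)
    c1 = _kernels.grad_phi(v @ _kernels.J1.T) @ _kernels.J1
    c2 = _kernels.grad_phi(v @ _kernels.J2.T) @ _kernels.J2
    return np.stack([c1, c2], axis=-1)


def grad_g_psi(p) -> np.ndarray:
    """Gradient of g o psi, i.e. grad psi * 2 / (4 - psi^2)."""
    v = _as_vector(p, 8)
    _require_paired_margins(v)
    d = float(_kernels.psi(v))
    if abs(d) >= 2:
        raise DomainError(f"|psi| = {abs(d)} >= 2; modified transform gradient undefined")
    return _kernels.grad_psi(v) * (2.0 / (4.0 - d * d))


def delta_variance(grad: np.ndarray, cov: np.ndarray):
    """Quadratic form grad^T Sigma grad.

    A vector gradient yields a scalar (tiny negative floating-point
    excursions, above -1e-12, are clipped to zero); an 8x2 Jacobian
    yields the symmetrized 2x2 covariance matrix of (MCC1, MCC2).
    """
    g = np.asarray(grad, dtype=float)
    s = np.asarray(cov, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise InputError(f"covariance must be square, got shape {s.shape}")
    if g.ndim == 1:
        if g.shape[0] != s.shape[0]:
            raise InputError(f"shape mismatch: gradient {g.shape} vs covariance {s.shape}")
        v = float(g @ s @ g)
        if v < -_VAR_CLIP:
            raise DomainError(f"variance quadratic form is negative: {v}")
        return max(v, 0.0)
    if g.ndim == 2:
        if g.shape[0] != s.shape[0]:
            raise InputError(f"shape mismatch: jacobian {g.shape} vs covariance {s.shape}")
        m = g.T @ s @ g
        return (m + m.T) / 2.0
    raise InputError(f"gradient must be 1- or 2-dimensional, got shape {g.shape}")


def fd_gradient(func: Callable[[np.ndarray], float], p, h: float = 1e-6) -> np.ndarray:
    """Central finite differences of a scalar field, coordinate by
    coordinate, with no simplex renormalization.

    Serves as the independent oracle for the analytic gradients: the
    delta method differentiates the unconstrained formulas, so the probe
    points deliberately leave the simplex.
    """
    v = np.asarray(p, dtype=float).ravel()
    out = np.empty_like(v)
    for a in range(v.size):
        e = np.zeros_like(v)
        e[a] = h
        out[a] = (func(v + e) - func(v - e)) / (2.0 * h)
    return out
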