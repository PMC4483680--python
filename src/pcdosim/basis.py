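"""Orthonormal Legendre tensor-product basis over standardized field-orientation angles.

The magnetic-flux-density orientation is described by the spherical angles
``theta`` (polar, degrees, open support (0, 180)) and ``phi`` (azimuth,
degrees, open support (-180, 180)), both uniformly distributed.  The matching
orthogonal family is the Legendre one on (-1, 1); this module provides the
*orthonormal* variant ``sqrt(2n+1) * P_n`` so that the mean and variance of a
chaos expansion can be read directly off its coefficients.

Axis convention shared by the whole package: ``z`` is the vertical
(head-to-toe) axis of the standing body, ``x`` points front-to-back and ``y``
right-to-left.  The unit field direction is
``u(theta, phi) = (sin th cos ph, sin th sin ph, cos th)``, so ``theta = 0``
is a top-down field, ``(theta=90, phi=0)`` a front-to-back field and
``(theta=90, phi=+-90)`` a lateral field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np

THETA_SUPPORT = (0.0, 180.0)
PHI_SUPPORT = (-180.0, 180.0)

_EPS = np.finfo(float).eps


def _clamp_open(values: np.ndarray, lo: float, hi: float, name: str) -> np.ndarray:
    """Clamp endpoint values one epsilon into the open interval; reject outsiders."""
    v = np.asarray(values, dtype=float)
    if np.any(~np.isfinite(v)) or np.any(v < lo) or np.any(v > hi):
        raise ValueError(f"{name} must lie within [{lo}, {hi}]")
    span = hi - lo
    return np.clip(v, lo + span * _EPS, hi - span * _EPS)


def clamp_angles(theta_deg, phi_deg) -> tuple[np.ndarray, np.ndarray]:
    """Validate orientation angles and nudge exact endpoints into the open supports."""
    theta = _clamp_open(theta_deg, *THETA_SUPPORT, name="theta_deg")
    phi = _clamp_open(phi_deg, *PHI_SUPPORT, name="phi_deg")
    return theta, phi


def standardize(theta_deg, phi_deg) -> np.ndarray:
    """Map angles (degrees) onto the Legendre domain: xi1 = theta/90 - 1, xi2 = phi/180.

    Returns an array of shape ``(..., 2)`` with both coordinates in (-1, 1).
    """
    theta, phi = clamp_angles(theta_deg, phi_deg)
    return np.stack([theta / 90.0 - 1.0, phi / 180.0], axis=-1)


def destandardize(xi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`standardize`; returns ``(theta_deg, phi_deg)``."""
    xi = np.asarray(xi, dtype=float)
    theta = (xi[..., 0] + 1.0) * 90.0
    phi = xi[..., 1] * 180.0
    return theta, phi


def total_degree_indices(K: int, p: int) -> tuple[tuple[int, ...], ...]:
    """All K-dimensional multi-indices with total degree <= p, graded lexicographic.

    The constant index ``(0, ..., 0)`` comes first; within each total degree the
    ordering is lexicographic with the leading dimension decreasing, e.g. for
    K=2, degree 1: ``(1, 0)`` before ``(0, 1)``.  The length of the result is
    ``binomial(p + K, K)``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if p < 0:
        raise ValueError("p must be >= 0")

    def compositions(total: int, parts: int):
        if parts == 1:
            yield (total,)
            return
        for first in range(total, -1, -1):
            for rest in compositions(total - first, parts - 1):
                yield (first,) + rest

    out: list[tuple[int, ...]] = []
    for d in range(p + 1):
        out.extend(compositions(d, K))
    assert len(out) == comb(p + K, K)
    return tuple(out)


def _orthonormal_table(xi: np.ndarray, nmax: int) -> np.ndarray:
    """Table of sqrt(2n+1) * P_n(xi) for n = 0..nmax via the three-term recurrence."""
    xi = np.asarray(xi, dtype=float)
    T = np.empty(xi.shape + (nmax + 1,))
    T[..., 0] = 1.0
    if nmax >= 1:
        T[..., 1] = xi
    for n in range(1, nmax):
        # (n+1) P_{n+1} = (2n+1) x P_n - n P_{n-1}, on the raw P_n columns
        T[..., n + 1] = ((2 * n + 1) * xi * T[..., n] - n * T[..., n - 1]) / (n + 1)
    T *= np.sqrt(2 * np.arange(nmax + 1) + 1.0)
    return T


def legendre_orthonormal(n: int, xi) -> np.ndarray | float:
    """Evaluate the orthonormal Legendre polynomial sqrt(2n+1) * P_n at xi in [-1, 1].

    Orthonormal with respect to the uniform density 1/2 on (-1, 1).
    """
    if n < 0:
        raise ValueError("degree n must be >= 0")
    arr = np.asarray(xi, dtype=float)
    if np.any(np.abs(arr) > 1.0):
        raise ValueError("xi must lie in [-1, 1]")
    value = _orthonormal_table(arr, n)[..., n]
    return float(value) if np.isscalar(xi) or arr.ndim == 0 else value


@dataclass(frozen=True)
class BasisSpec:
    """Total-degree-truncated tensor basis: K inputs, maximum total degree p.

    ``indices`` is the graded-lexicographic multi-index sequence and
    ``P = binomial(p + K, K)`` its length.
    """

    K: int
    p: int
    indices: tuple[tuple[int, ...], ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.indices is None:
            object.__setattr__(self, "indices", total_degree_indices(self.K, self.p))
        if self.indices[0] != (0,) * self.K:
            raise ValueError("constant multi-index must come first")
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("multi-indices must be unique")

    @property
    def P(self) -> int:
        return len(self.indices)


def evaluate_multiindices(points: np.ndarray, indices, K: int | None = None) -> np.ndarray:
    """Evaluate tensor-product orthonormal Legendre polynomials at standardized points.

    ``points`` has shape ``(M, K)``; returns the matrix of shape ``(M, len(indices))``
    with entry ``(i, j) = prod_k sqrt(2 a_jk + 1) P_{a_jk}(xi_ik)``.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("point set must be non-empty")
    indices = tuple(tuple(a) for a in indices)
    K = pts.shape[1] if K is None else K
    if pts.shape[1] != K or any(len(a) != K for a in indices):
        raise ValueError("dimension mismatch between points and multi-indices")
    nmax = max((max(a) for a in indices), default=0)
    tables = [_orthonormal_table(pts[:, k], nmax) for k in range(K)]
    out = np.ones((pts.shape[0], len(indices)))
    for j, alpha in enumerate(indices):
        for k, a in enumerate(alpha):
            if a:
                out[:, j] *= tables[k][:, a]
    return out


def evaluate_basis(points: np.ndarray, spec: BasisSpec) -> np.ndarray:
    """Full design matrix Psi of shape ``(M, spec.P)``; column 0 is all ones."""
    return evaluate_multiindices(points, spec.indices, K=spec.K)
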