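"""Closed-form quasi-static eddy-current solver in a homogeneous ellipsoid.

This is the synthetic-data stage of the pipeline: a stand-in deterministic
solver producing per-tissue 99th-percentile induced-field observations
``E_99th(theta, phi)`` with the statistical structure the surrogate analysis
assumes — smooth, strictly positive, genuinely orientation-dependent through
quasi-static induction physics, of millivolt-per-metre magnitude at the
200 uT / 50 Hz reference exposure, with optional multiplicative numerical
noise of at most 5 % CV.

Physics.  For a homogeneous conducting triaxial ellipsoid with semi-axes
(a, b, c) in a uniform sinusoidal flux density B, the interior induced
electric field is the superposition of the three principal-axis solutions;
for the z-component,

    E^(z) = omega * B_z / (a^2 + b^2) * (-a^2 y, b^2 x, 0),

and cyclically for B_x (currents in the y-z cross-section) and B_y (x-z
cross-section), with omega = 2 pi f.  The solution satisfies curl E = -dB/dt
and J.n = 0 on the boundary exactly.  All components share one time phase, so
RMS amplitudes superpose linearly.

Heterogeneous conductivity, tissue-interface corrections and small-cube vector
averaging are deliberately out of scope: the field inside each tissue region
is read off this single-body solution, which keeps the orientation dependence
exact and the response analytic in the angles.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import Design

REFERENCE_B_RMS_T = 200e-6   # ICNIRP 2010 general-public reference level at 50 Hz
REFERENCE_FREQUENCY_HZ = 50.0
MAX_NOISE_CV = 0.05          # stated numerical-uncertainty bound of the observations


@dataclass(frozen=True)
class BodyEllipsoid:
    """Homogeneous conducting body: semi-axes along x (front-back), y (lateral),
    z (vertical), in metres."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("semi-axes must be strictly positive")

    @property
    def semi_axes(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])

    def contains(self, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        p = np.atleast_2d(points)
        return np.sum((p / self.semi_axes) ** 2, axis=1) <= 1.0 + tol


@dataclass(frozen=True)
class SolverConfig:
    """Exposure scenario: RMS flux density, frequency, multiplicative noise."""

    b_rms: float = REFERENCE_B_RMS_T
    frequency: float = REFERENCE_FREQUENCY_HZ
    noise_cv: float = 0.0
    noise_seed: int = 0

    def __post_init__(self) -> None:
        if self.b_rms <= 0 or self.frequency <= 0:
            raise ValueError("b_rms and frequency must be strictly positive")
        if not 0.0 <= self.noise_cv <= MAX_NOISE_CV:
            raise ValueError(f"noise_cv must lie in [0, {MAX_NOISE_CV}]")

    @property
    def omega(self) -> float:
        return 2.0 * np.pi * self.frequency


@dataclass(frozen=True)
class TissueRegion:
    """Axis-aligned ellipsoidal sub-region standing in for a segmented tissue.

    ``center`` is the offset from the body centre (metres); ``grid_step`` the
    spacing of the regular point cloud on which the field percentile is taken.
    """

    name: str
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    is_cns_head: bool = False
    grid_step: float = 2e-3

    def __post_init__(self) -> None:
        if min(self.semi_axes) <= 0 or self.grid_step <= 0:
            raise ValueError("semi-axes and grid_step must be strictly positive")

    def point_cloud(self) -> np.ndarray:
        """Regular grid of spacing ``grid_step`` clipped to the region ellipsoid."""
        g = self.grid_step
        axes = []
        for s in self.semi_axes:
            k = int(np.floor(s / g))
            axes.append(g * np.arange(-k, k + 1))
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        mask = np.sum((pts / np.asarray(self.semi_axes)) ** 2, axis=1) <= 1.0
        pts = pts[mask] + np.asarray(self.center)
        if pts.shape[0] == 0:
            raise ValueError(f"empty point cloud for region '{self.name}'")
        return pts

    def bounding_corners(self) -> np.ndarray:
        c = np.asarray(self.center)
        s = np.asarray(self.semi_axes)
        signs = np.array([[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)])
        return c + signs * s


@dataclass(frozen=True)
class GAModel:
    """A synthetic pregnant-body fixture: the conducting body, the fetus
    whole-body region and the per-tissue sub-regions."""

    label: str
    body: BodyEllipsoid
    fetus_whole_body: TissueRegion
    tissues: tuple[TissueRegion, ...]

    def __post_init__(self) -> None:
        expected = {"3mo": 15, "7mo": 17, "9mo": 26}
        if self.label in expected and len(self.tissues) != expected[self.label]:
            raise ValueError(
                f"fixture '{self.label}' must carry {expected[self.label]} tissues")
        for region in (self.fetus_whole_body, *self.tissues):
            corners = region.bounding_corners()
            if not np.all(self.body.contains(corners)):
                raise ValueError(f"region '{region.name}' extends outside the body")

    @property
    def all_regions(self) -> tuple[TissueRegion, ...]:
        return (self.fetus_whole_body, *self.tissues)

    def region(self, name: str) -> TissueRegion:
        for r in self.all_regions:
            if r.name == name:
                return r
        raise KeyError(name)


def _unit_field_shapes(points: np.ndarray, body: BodyEllipsoid) -> np.ndarray:
    """Geometric field shapes F_k(p), shape (3, M, 3): E = omega*B * sum_k u_k F_k.

    Axis k drives circulating currents in the orthogonal cross-section (i, j)
    taken in cyclic order (i, j, k): F_k = (-s_i^2 p_j e_i + s_j^2 p_i e_j) /
    (s_i^2 + s_j^2).
    """
    p = np.atleast_2d(points)
    s2 = body.semi_axes ** 2
    F = np.zeros((3, p.shape[0], 3))
    for k in range(3):
        i, j = (k + 1) % 3, (k + 2) % 3
        denom = s2[i] + s2[j]
        F[k, :, i] = -s2[i] * p[:, j] / denom
        F[k, :, j] = s2[j] * p[:, i] / denom
    return F


def eddy_field(points: np.ndarray, b_direction: np.ndarray,
               body: BodyEllipsoid, config: SolverConfig) -> np.ndarray:
    """RMS induced electric field vectors (V/m) at interior points.

    ``b_direction`` is the unit direction of the flux density of RMS amplitude
    ``config.b_rms``.  Points outside the body raise.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.all(body.contains(p)):
        raise ValueError("point outside the body ellipsoid")
    u = np.asarray(b_direction, dtype=float)
    F = _unit_field_shapes(p, body)
    E = config.omega * config.b_rms * np.tensordot(u, F, axes=(0, 0))
    return E if np.asarray(points).ndim > 1 else E[0]


def _percentile99(magnitudes: np.ndarray) -> float:
    # linear-interpolation order-statistic definition
    return float(np.percentile(magnitudes, 99.0))


class VirtualSolver:
    """Observation source: evaluates per-tissue E_99th over orientation designs.

    Caches the three per-axis field-shape matrices per tissue so that each
    orientation costs one small linear combination plus a percentile.
    """

    def __init__(self, ga: GAModel, config: SolverConfig | None = None):
        self.ga = ga
        self.config = config or SolverConfig()
        self._shapes: dict[str, np.ndarray] = {}

    def _tissue_shapes(self, name: str) -> np.ndarray:
        if name not in self._shapes:
            region = self.ga.region(name)
            pts = region.point_cloud()
            if pts.shape[0] < 500:
                raise ValueError(
                    f"point cloud of '{name}' has {pts.shape[0]} points (< 500); "
                    "decrease grid_step")
            self._shapes[name] = _unit_field_shapes(pts, self.ga.body)
        return self._shapes[name]

    def e99th_from_unit_vectors(self, name: str, directions: np.ndarray) -> np.ndarray:
        """Noise-free E_99th (V/m) per unit field direction, shape (n, 3).

        Exactly even in the direction: negating a row negates every field
        component bitwise, leaving the magnitudes and the percentile unchanged.
        """
        F = self._tissue_shapes(name)
        scale = self.config.omega * self.config.b_rms
        U = np.atleast_2d(np.asarray(directions, dtype=float))
        out = np.empty(U.shape[0])
        for i, u in enumerate(U):
            E = u[0] * F[0] + u[1] * F[1] + u[2] * F[2]
            mags = scale * np.sqrt(np.einsum("ij,ij->i", E, E))
            out[i] = _percentile99(mags)
        return out

    def e99th_values(self, name: str, design: Design) -> np.ndarray:
        """Noise-free E_99th (V/m) per design orientation."""
        return self.e99th_from_unit_vectors(name, design.unit_vectors())

    def _noise_factors(self, name: str, design: Design) -> np.ndarray:
        cv = self.config.noise_cv
        if cv == 0.0:
            return np.ones(len(design))
        # one independent multiplicative draw per (tissue, orientation),
        # reproducible for a given design and noise seed
        crc = zlib.crc32(repr(design.cache_key()).encode())
        crc = zlib.crc32(name.encode(), crc)
        rng = np.random.default_rng(np.random.SeedSequence(
            [int(self.config.noise_seed), crc]))
        return np.exp(rng.normal(0.0, cv, size=len(design)))

    def observe(self, design: Design, tissues=None) -> pd.DataFrame:
        """E_99th table for the requested tissues (default: all, fetus first)."""
        names = [r.name for r in self.ga.all_regions] if tissues is None else list(tissues)
        data = {}
        for name in names:
            data[name] = self.e99th_values(name, design) * self._noise_factors(name, design)
        return pd.DataFrame(data)


def e99th(region: TissueRegion, theta_deg, phi_deg, ga: GAModel,
          config: SolverConfig | None = None) -> np.ndarray | float:
    """Convenience wrapper: E_99th of one region at the given orientation(s)."""
    solver = VirtualSolver(ga, config)
    design = Design(kind="direct", theta_deg=np.atleast_1d(theta_deg),
                    phi_deg=np.atleast_1d(phi_deg), seed_or_skip=0)
    values = (solver.e99th_values(region.name, design)
              * solver._noise_factors(region.name, design))
    return float(values[0]) if np.isscalar(theta_deg) else values
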