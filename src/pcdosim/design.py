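"""Experimental designs over field orientations.

Two kinds of designs are used: a deterministic 2-D Sobol low-discrepancy
sequence for the build set (quasi-Monte-Carlo observation design) and seeded
pseudo-random designs, uniform *in the angles* theta and phi (which is the
stated input distribution, not uniform on the sphere), for validation and for
the orientation sweep.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
from scipy.stats import qmc

from .basis import PHI_SUPPORT, THETA_SUPPORT, clamp_angles, standardize


@dataclass(frozen=True)
class Design:
    """A set of orientation angles plus the integer that reproduces it.

    ``seed_or_skip`` is the Sobol skip count for ``kind="sobol"`` and the RNG
    seed for ``kind="uniform_random"``.
    """

    kind: str
    theta_deg: np.ndarray
    phi_deg: np.ndarray
    seed_or_skip: int

    def __post_init__(self) -> None:
        theta, phi = clamp_angles(self.theta_deg, self.phi_deg)
        object.__setattr__(self, "theta_deg", np.atleast_1d(theta))
        object.__setattr__(self, "phi_deg", np.atleast_1d(phi))
        if self.theta_deg.shape != self.phi_deg.shape:
            raise ValueError("theta_deg and phi_deg must have equal length")

    def __len__(self) -> int:
        return self.theta_deg.shape[0]

    def standardized(self) -> np.ndarray:
        """Points mapped to the Legendre domain, shape (n, 2)."""
        return standardize(self.theta_deg, self.phi_deg)

    def unit_vectors(self) -> np.ndarray:
        """Unit field directions under the package axis convention, shape (n, 3)."""
        return orientation_to_unit_vector(self.theta_deg, self.phi_deg)

    def cache_key(self) -> tuple:
        """Cheap deterministic identity used for memoising solver output."""
        crc = zlib.crc32(np.round(self.theta_deg, 10).tobytes())
        crc = zlib.crc32(np.round(self.phi_deg, 10).tobytes(), crc)
        return (self.kind, len(self), int(self.seed_or_skip), crc)


def _from_unit_square(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    theta = THETA_SUPPORT[0] + u[:, 0] * (THETA_SUPPORT[1] - THETA_SUPPORT[0])
    phi = PHI_SUPPORT[0] + u[:, 1] * (PHI_SUPPORT[1] - PHI_SUPPORT[0])
    return theta, phi


def sobol_design(n: int, skip: int = 1) -> Design:
    """First ``n`` points of the unscrambled 2-D Sobol sequence, mapped to angles.

    ``skip`` initial points are dropped (default 1, discarding the origin of the
    unit square).  Deterministic: identical arguments give bit-identical designs,
    and designs of increasing ``n`` are nested.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sampler = qmc.Sobol(d=2, scramble=False)
    if skip:
        sampler.fast_forward(skip)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # non power-of-two draw
        u = sampler.random(n)
    theta, phi = _from_unit_square(u)
    if np.unique(np.column_stack([theta, phi]), axis=0).shape[0] != n:
        raise ValueError("Sobol design contains duplicate points")
    return Design(kind="sobol", theta_deg=theta, phi_deg=phi, seed_or_skip=skip)


def uniform_random_design(n: int, seed: int) -> Design:
    """``n`` i.i.d. orientations, theta ~ U(0, 180) and phi ~ U(-180, 180).

    Uniform in the angles (the input probability model), not uniform on the
    sphere.  Reproducible given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.random((n, 2))
    theta, phi = _from_unit_square(u)
    return Design(kind="uniform_random", theta_deg=theta, phi_deg=phi, seed_or_skip=seed)


def orientation_to_unit_vector(theta_deg, phi_deg) -> np.ndarray:
    """u = (sin th cos ph, sin th sin ph, cos th) for angles in degrees."""
    theta = np.deg2rad(np.asarray(theta_deg, dtype=float))
    phi = np.deg2rad(np.asarray(phi_deg, dtype=float))
    return np.stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)],
        axis=-1,
    )
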