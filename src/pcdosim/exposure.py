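"""Exposure statistics from fitted chaos surrogates.

Because the basis is orthonormal with respect to the input distribution, the
first two moments of the surrogate come straight from the coefficients:
``mean = a_0`` and ``variance = sum_{j>=1} a_j^2``.  The worst case over field
orientations (mE_99th) is estimated by sweeping the surrogate over a large
random orientation sample — uniform *in the angles*, matching the input
probability model — and compared against the ICNIRP 2010 basic restrictions
(0.02 V/m for CNS tissues of the head, 0.4 V/m elsewhere) as the percentage
ratio WS%.  High-exposure orientation regions (>= 70 % of the maximum, i.e.
within 3 dB) are classified into 70-79 / 80-89 / >=90 % bands and their solid
angles estimated by sin(theta) importance weighting of the angle-uniform
sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import Design, uniform_random_design
from .sparse import PCModel

BAND_LABELS = ("below70", "b70_79", "b80_89", "ge90")
FULL_SPHERE_SR = 4.0 * np.pi


@dataclass(frozen=True)
class RegulatoryLimits:
    """ICNIRP 2010 basic restrictions for the general public at 50 Hz."""

    cns_head_limit: float = 0.02       # V/m
    other_limit: float = 0.4           # V/m
    reference_level_b: float = 200e-6  # T RMS
    frequency: float = 50.0            # Hz

    def limit_for(self, is_cns_head: bool) -> float:
        return self.cns_head_limit if is_cns_head else self.other_limit


@dataclass
class TissueExposureSummary:
    tissue: str
    is_cns_head: bool
    mean: float          # V/m
    std: float           # V/m
    cv_percent: float
    mE99th: float        # V/m
    e_lim: float         # V/m
    ws_percent: float


@dataclass
class OrientationBandMap:
    """Sweep orientations with band labels and per-band solid angles."""

    sweep: Design
    values: np.ndarray
    mE99th: float
    bands: np.ndarray                      # one of BAND_LABELS per orientation
    solid_angles_sr: dict[str, float]
    solid_angle_se_sr: dict[str, float]


def moments_from_coefficients(model: PCModel) -> tuple[float, float]:
    """Analytic (mean, variance) of the surrogate under the input distribution."""
    if model.active_indices[0] != (0,) * model.spec.K:
        raise ValueError("model lacks the constant term")
    mean = float(model.coefficients[0])
    variance = float(np.sum(model.coefficients[1:] ** 2))
    return mean, variance


def coefficient_of_variation(mean: float, variance: float) -> float:
    """100 * std / mean, for a strictly positive mean."""
    if mean <= 0:
        raise ValueError("coefficient of variation requires a positive mean")
    return 100.0 * float(np.sqrt(variance)) / mean


def orientation_sweep(model: PCModel, M: int = 10000, seed: int = 0):
    """Evaluate the surrogate on M random orientations.

    Returns ``(design, values, mE99th)`` where mE99th is the sweep maximum.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    design = uniform_random_design(M, seed=seed)
    values = model.predict(design)
    return design, values, float(values.max())


def grid_max(model: PCModel, step_deg: float = 1.0) -> tuple[float, float, float]:
    """Deterministic cross-check of the sweep maximum on a dense angle grid.

    Returns ``(max value, theta_deg, phi_deg)`` of the surrogate over a regular
    grid of the stated step; cheap because the surrogate is a polynomial.
    """
    theta = np.arange(step_deg / 2.0, 180.0, step_deg)
    phi = np.arange(-180.0 + step_deg / 2.0, 180.0, step_deg)
    T, Ph = np.meshgrid(theta, phi, indexing="ij")
    design = Design(kind="grid", theta_deg=T.ravel(), phi_deg=Ph.ravel(), seed_or_skip=0)
    values = model.predict(design)
    k = int(np.argmax(values))
    return float(values[k]), float(T.ravel()[k]), float(Ph.ravel()[k])


def ws_percent(mE99th: float, is_cns_head: bool,
               limits: RegulatoryLimits | None = None) -> float:
    """Worst-case-scenario ratio 100 * mE_99th / E_lim."""
    if mE99th < 0:
        raise ValueError("mE99th must be >= 0")
    limits = limits or RegulatoryLimits()
    return 100.0 * mE99th / limits.limit_for(is_cns_head)


def band_classify(values: np.ndarray, mE99th: float,
                  thresholds: tuple[float, float, float] = (0.7, 0.8, 0.9)) -> np.ndarray:
    """Label each orientation by its fraction of the maximum.

    ``ge90`` for v >= t3*max, ``b80_89`` for t2*max <= v < t3*max, ``b70_79``
    for t1*max <= v < t2*max, else ``below70``.
    """
    if mE99th <= 0:
        raise ValueError("mE99th must be > 0")
    t1, t2, t3 = thresholds
    if not 0.0 < t1 < t2 < t3 < 1.0:
        raise ValueError("thresholds must be strictly increasing within (0, 1)")
    v = np.asarray(values, dtype=float)
    labels = np.full(v.shape, "below70", dtype=object)
    labels[v >= t1 * mE99th] = "b70_79"
    labels[v >= t2 * mE99th] = "b80_89"
    labels[v >= t3 * mE99th] = "ge90"
    return labels.astype(str)


def solid_angle(sweep: Design, member: np.ndarray) -> tuple[float, float]:
    """Monte-Carlo solid angle (sr) of an orientation set, with a standard error.

    The sweep is drawn uniform in the angles with density 1/(2 pi^2) per unit
    d(theta) d(phi); the spherical area element is sin(theta) d(theta) d(phi),
    so Omega = (2 pi^2 / M) * sum_{member} sin(theta_i).
    """
    member = np.asarray(member, dtype=bool)
    M = len(sweep)
    if M < 100:
        raise ValueError("need at least 100 sweep orientations")
    if member.shape[0] != M:
        raise ValueError("membership indicator misaligned with the sweep")
    w = 2.0 * np.pi ** 2 * np.sin(np.deg2rad(sweep.theta_deg)) * member
    omega = float(w.mean())
    se = float(w.std(ddof=1) / np.sqrt(M))
    return omega, se


def summarize_tissue(model: PCModel, is_cns_head: bool,
                     limits: RegulatoryLimits | None = None,
                     M: int = 10000, seed: int = 0) -> TissueExposureSummary:
    """Full per-tissue exposure summary: moments, CV, sweep maximum, WS%."""
    limits = limits or RegulatoryLimits()
    mean, variance = moments_from_coefficients(model)
    _, _, mE = orientation_sweep(model, M=M, seed=seed)
    return TissueExposureSummary(
        tissue=model.tissue,
        is_cns_head=is_cns_head,
        mean=mean,
        std=float(np.sqrt(variance)),
        cv_percent=coefficient_of_variation(mean, variance),
        mE99th=mE,
        e_lim=limits.limit_for(is_cns_head),
        ws_percent=ws_percent(mE, is_cns_head, limits),
    )


def band_map(model: PCModel, M: int = 10000, seed: int = 0,
             thresholds: tuple[float, float, float] = (0.7, 0.8, 0.9)) -> OrientationBandMap:
    """Sweep, classify into exposure bands and estimate per-band solid angles."""
    sweep, values, mE = orientation_sweep(model, M=M, seed=seed)
    bands = band_classify(values, mE, thresholds=thresholds)
    omegas, ses = {}, {}
    for label in BAND_LABELS:
        omegas[label], ses[label] = solid_angle(sweep, bands == label)
    return OrientationBandMap(sweep=sweep, values=values, mE99th=mE, bands=bands,
                              solid_angles_sr=omegas, solid_angle_se_sr=ses)
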