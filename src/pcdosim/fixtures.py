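"""Synthetic gestational-age fixtures for the virtual solver.

Three pregnant-body fixtures ("3mo", "7mo", "9mo") emulate the study
conditions: a homogeneous maternal ellipsoid, a fetus whole-body ellipsoid
whose volume tracks the fetal masses of roughly 15 g, 1.7 kg and 2.7 kg, and
15 / 17 / 26 tissue sub-regions named after commonly segmented fetal tissues.
Tissue lists beyond the commonly named organs are synthetic padding.  The
geometry is chosen so that the whole-body worst-case orientation is
front-to-back at 3 and 9 months (lateral fetal extent dominates) and lateral
at 7 months (front-back extent dominates), reflecting how fetal position and
size flip the dominant induction cross-section.

A rotationally invariant ``sphere_fixture`` (concentric spheres) is provided
for symmetry checks: every orientation then induces the same field pattern up
to rotation, so per-tissue E_99th is orientation-independent.
"""

from __future__ import annotations

import numpy as np

from .solver import BodyEllipsoid, GAModel, TissueRegion

#: maternal body half-thickness (front-back), half-width (lateral), half-height, metres
MATERNAL_BODY = BodyEllipsoid(a=0.13, b=0.20, c=0.85)

# fetus whole-body ellipsoids: semi-axes (m) and offset from the body centre;
# volumes correspond to ~15 g, ~1.7 kg and ~2.7 kg at unit tissue density
_FETUS = {
    "3mo": {"semi_axes": (0.0145, 0.0155, 0.0159), "center": (0.0, 0.010, -0.18)},
    "7mo": {"semi_axes": (0.082, 0.060, 0.0825), "center": (0.025, 0.0, -0.22)},
    "9mo": {"semi_axes": (0.070, 0.095, 0.0970), "center": (0.0, 0.0, -0.25)},
}

# tissue layout as fractions of the fetus ellipsoid: (center fraction, size fraction)
_LAYOUT: dict[str, tuple[tuple[float, float, float], tuple[float, float, float]]] = {
    "skin":        ((0.00, 0.00, 0.00), (0.97, 0.97, 0.97)),
    "fat":         ((0.00, 0.00, 0.00), (0.90, 0.90, 0.90)),
    "muscle":      ((0.00, 0.00, 0.00), (0.80, 0.80, 0.80)),
    "bone":        ((0.00, 0.00, 0.00), (0.25, 0.25, 0.72)),
    "brain":       ((0.00, 0.00, 0.62), (0.30, 0.30, 0.28)),
    "csf":         ((0.00, 0.00, 0.60), (0.34, 0.34, 0.32)),
    "eye_lens":    ((0.35, 0.15, 0.84), (0.07, 0.06, 0.05)),
    "spinal_cord": ((-0.20, 0.00, -0.05), (0.07, 0.07, 0.60)),
    "liver":       ((0.25, 0.20, 0.10), (0.30, 0.35, 0.20)),
    "kidney":      ((-0.25, 0.30, -0.15), (0.12, 0.12, 0.18)),
    "stomach":     ((0.30, -0.25, 0.15), (0.18, 0.20, 0.15)),
    "intestine":   ((0.10, 0.00, -0.35), (0.35, 0.40, 0.30)),
    "heart":       ((0.15, 0.10, 0.35), (0.15, 0.15, 0.17)),
    "lung":        ((0.00, 0.25, 0.40), (0.20, 0.25, 0.22)),
    "bladder":     ((0.05, 0.00, -0.62), (0.12, 0.13, 0.12)),
    "spleen":      ((-0.30, -0.30, 0.05), (0.12, 0.14, 0.13)),
    "gallbladder": ((0.30, 0.12, 0.00), (0.07, 0.07, 0.09)),
    "sat":         ((0.00, 0.00, 0.00), (0.94, 0.94, 0.94)),
    "adrenal":     ((-0.22, 0.28, 0.02), (0.06, 0.07, 0.07)),
    "esophagus":   ((-0.05, 0.00, 0.50), (0.05, 0.05, 0.20)),
    "thyroid":     ((0.05, 0.00, 0.68), (0.08, 0.10, 0.06)),
    "ovary":       ((0.00, 0.20, -0.50), (0.07, 0.07, 0.07)),
    "pancreas":    ((0.00, -0.20, 0.05), (0.20, 0.12, 0.08)),
    "thymus":      ((0.12, 0.00, 0.50), (0.10, 0.10, 0.08)),
    "trachea":     ((0.08, 0.00, 0.58), (0.05, 0.05, 0.18)),
    "tongue":      ((0.15, 0.00, 0.74), (0.10, 0.12, 0.07)),
}

_TISSUES_3MO = [
    "skin", "fat", "liver", "spinal_cord", "kidney", "eye_lens", "brain", "bone",
    "muscle", "bladder", "spleen", "intestine", "heart", "lung", "stomach",
]
_TISSUES_7MO = _TISSUES_3MO + ["gallbladder", "sat"]
_TISSUES_9MO = _TISSUES_7MO + [
    "adrenal", "csf", "esophagus", "thyroid", "ovary", "pancreas", "thymus",
    "trachea", "tongue",
]
TISSUE_LISTS = {"3mo": _TISSUES_3MO, "7mo": _TISSUES_7MO, "9mo": _TISSUES_9MO}

CNS_HEAD_TISSUES = {"brain", "csf"}

_TARGET_POINTS = 2000   # point-cloud size aimed for by the automatic grid step
_MIN_POINTS = 600       # floor keeping every cloud comfortably above 500 points
_DEFAULT_STEP = 2e-3    # metres; granularity comparable to small averaging cubes


def _auto_step(semi_axes, resolution_scale: float = 1.0) -> float:
    volume = 4.0 / 3.0 * np.pi * float(np.prod(np.asarray(semi_axes)))
    step = min(_DEFAULT_STEP, (volume / _TARGET_POINTS) ** (1.0 / 3.0))
    step *= resolution_scale
    return float(min(step, (volume / _MIN_POINTS) ** (1.0 / 3.0)))


def ga_fixture(label: str, resolution_scale: float = 1.0) -> GAModel:
    """Packaged gestational-age fixture ("3mo", "7mo" or "9mo").

    ``resolution_scale`` > 1 coarsens every point cloud proportionally (capped
    so that each cloud keeps well over 500 points); the default resolution
    targets ~2000 points per tissue and a 2 mm grid for the fetus whole body.
    """
    if label not in _FETUS:
        raise KeyError(f"unknown fixture label '{label}' (choose 3mo, 7mo or 9mo)")
    fp = _FETUS[label]
    f_center = np.asarray(fp["center"])
    f_semi = np.asarray(fp["semi_axes"])
    fetus = TissueRegion(
        name="whole_body",
        center=tuple(f_center),
        semi_axes=tuple(f_semi),
        is_cns_head=False,
        grid_step=_auto_step(f_semi, resolution_scale),
    )
    tissues = []
    for name in TISSUE_LISTS[label]:
        cfrac, sfrac = _LAYOUT[name]
        center = f_center + np.asarray(cfrac) * f_semi
        semi = np.asarray(sfrac) * f_semi
        tissues.append(TissueRegion(
            name=name,
            center=tuple(center),
            semi_axes=tuple(semi),
            is_cns_head=name in CNS_HEAD_TISSUES,
            grid_step=_auto_step(semi, resolution_scale),
        ))
    return GAModel(label=label, body=MATERNAL_BODY,
                   fetus_whole_body=fetus, tissues=tuple(tissues))


def sphere_fixture(resolution_scale: float = 1.0) -> GAModel:
    """Spherical body with concentric spherical regions: rotationally invariant.

    Used to check that the whole chain is orientation-blind when the physics
    is, i.e. E_99th is constant across orientations up to grid discretisation.
    """
    body = BodyEllipsoid(a=0.3, b=0.3, c=0.3)

    def region(name: str, r: float) -> TissueRegion:
        return TissueRegion(name=name, center=(0.0, 0.0, 0.0),
                            semi_axes=(r, r, r),
                            grid_step=_auto_step((r, r, r), resolution_scale))

    fetus = region("whole_body", 0.10)
    tissues = (region("inner", 0.04), region("mid", 0.06), region("outer", 0.085))
    return GAModel(label="sphere", body=body, fetus_whole_body=fetus, tissues=tissues)
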