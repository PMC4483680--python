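"""On-disk formats: design / observation CSV, model JSON, results tables.

CSV dialect: comma-separated, UTF-8, ``.`` decimal, one header line.  Angles
are degrees, responses V/m.  Round trips are bit-exact thanks to ``repr``-level
float formatting.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .basis import BasisSpec
from .design import Design
from .sparse import ObservationSet, PCModel

AXIS_CONVENTION_NOTE = (
    "z vertical (head-to-toe), x front-to-back, y right-to-left; "
    "u(theta,phi) = (sin th cos ph, sin th sin ph, cos th)"
)

_FLOAT_FMT = "%.17g"


def write_design(path, design: Design) -> None:
    df = pd.DataFrame({"theta_deg": design.theta_deg, "phi_deg": design.phi_deg})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_design(path, kind: str = "file", seed_or_skip: int = 0) -> Design:
    df = pd.read_csv(path)
    for col in ("theta_deg", "phi_deg"):
        if col not in df.columns:
            raise ValueError(f"design file {path}: missing column '{col}'")
    return Design(kind=kind, theta_deg=df["theta_deg"].to_numpy(dtype=float),
                  phi_deg=df["phi_deg"].to_numpy(dtype=float), seed_or_skip=seed_or_skip)


def write_observations(path, obs: ObservationSet) -> None:
    df = pd.DataFrame({"theta_deg": obs.design.theta_deg,
                       "phi_deg": obs.design.phi_deg})
    for tissue in obs.tissues:
        df[tissue] = obs.responses[tissue].to_numpy()
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_observations(path, kind: str = "file", seed_or_skip: int = 0) -> ObservationSet:
    """Strictly parse an observations CSV: header, numeric cells, positivity."""
    df = pd.read_csv(path)
    for col in ("theta_deg", "phi_deg"):
        if col not in df.columns:
            raise ValueError(f"observations file {path}: missing column '{col}'")
    tissue_cols = [c for c in df.columns if c not in ("theta_deg", "phi_deg")]
    if not tissue_cols:
        raise ValueError(f"observations file {path}: no tissue columns")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | ~np.isfinite(numeric)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"observations file {path}: non-numeric value at row {row + 2}, "
                f"column '{col}'")
        df[col] = numeric
    for col in tissue_cols:
        nonpos = df[col].to_numpy() <= 0
        if nonpos.any():
            row = int(np.flatnonzero(nonpos)[0])
            raise ValueError(
                f"observations file {path}: non-positive response at row {row + 2}, "
                f"column '{col}'")
    design = Design(kind=kind, theta_deg=df["theta_deg"].to_numpy(dtype=float),
                    phi_deg=df["phi_deg"].to_numpy(dtype=float),
                    seed_or_skip=seed_or_skip)
    return ObservationSet(design=design, responses=df[tissue_cols])


def model_to_dict(model: PCModel) -> dict:
    return {
        "tissue": model.tissue,
        "K": model.spec.K,
        "p": model.spec.p,
        "convention_note": AXIS_CONVENTION_NOTE,
        "active_indices": [list(a) for a in model.active_indices],
        "coefficients": [float(c) for c in model.coefficients],
        "Q": model.Q,
        "loo_error": float(model.loo_error),
        "n_build": int(model.n_build),
        "seeds": model.seeds,
        "pmse_percent": None if model.pmse_percent is None else float(model.pmse_percent),
    }


def write_model(path, model: PCModel) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1) + "\n")


def read_model(path) -> PCModel:
    d = json.loads(Path(path).read_text())
    spec = BasisSpec(K=int(d["K"]), p=int(d["p"]))
    return PCModel(
        tissue=d["tissue"],
        spec=spec,
        active_indices=tuple(tuple(a) for a in d["active_indices"]),
        coefficients=np.asarray(d["coefficients"], dtype=float),
        loo_error=float(d["loo_error"]),
        n_build=int(d["n_build"]),
        pmse_percent=d.get("pmse_percent"),
        seeds=d.get("seeds"),
    )
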