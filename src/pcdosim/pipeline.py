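"""Full analysis pipeline: design -> observe -> fit -> validate -> analyze.

One run fits a sparse chaos surrogate of E_99th per tissue (adaptive over the
(N, p) ladder), derives moments / CV / worst-case statistics for every tissue
and the orientation-band map plus solid angles for the fetus whole body, and
writes every artifact (designs, observations, model JSONs, results CSVs,
summary JSON, log) into the output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .design import uniform_random_design
from .exposure import (RegulatoryLimits, band_map, grid_max, summarize_tissue)
from .fixtures import ga_fixture, sphere_fixture
from .solver import GAModel, SolverConfig, VirtualSolver
from .sparse import ObservationSet, adaptive_fit, fit_pc, pmse

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Flat, JSON-compatible configuration of one pipeline run."""

    ga_label: str = "9mo"
    n_grid: tuple[int, ...] = (75, 150, 300)
    p_grid: tuple[int, ...] = (5, 10, 15)
    tau_percent: float = 0.5
    sweep_size: int = 10000
    band_thresholds: tuple[float, float, float] = (0.7, 0.8, 0.9)
    b_rms: float = 200e-6
    frequency: float = 50.0
    noise_cv: float = 0.0
    seed_validation: int = 101
    seed_sweep: int = 202
    seed_noise: int = 303
    resolution_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.tau_percent <= 0:
            raise ValueError("tau_percent must be > 0")
        t1, t2, t3 = self.band_thresholds
        if not 0.0 < t1 < t2 < t3 < 1.0:
            raise ValueError("band thresholds must be strictly increasing in (0, 1)")
        for grid in (self.n_grid, self.p_grid):
            if list(grid) != sorted(grid):
                raise ValueError("grids must be ascending")

    def solver_config(self) -> SolverConfig:
        return SolverConfig(b_rms=self.b_rms, frequency=self.frequency,
                            noise_cv=self.noise_cv, noise_seed=self.seed_noise)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        for key in ("n_grid", "p_grid", "band_thresholds"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    summaries: pd.DataFrame
    models: dict
    reports: dict
    whole_body_bands: object
    solid_angles: dict
    converged_all: bool
    out_dir: Path | None = None
    extras: dict = field(default_factory=dict)


def _build_fixture(config: PipelineConfig) -> GAModel:
    if config.ga_label == "sphere":
        return sphere_fixture(resolution_scale=config.resolution_scale)
    return ga_fixture(config.ga_label, resolution_scale=config.resolution_scale)


class _FileSolver:
    """Observation source backed by user-supplied CSVs instead of the virtual solver.

    Build observations come from ``obs``; validation observations from ``val_obs``
    when given, otherwise from the held-out tail of ``obs`` (last third of rows,
    so that build N = 2/3 of rows and S = N/2).
    """

    def __init__(self, obs: ObservationSet, val_obs: ObservationSet | None = None):
        if val_obs is None:
            n = len(obs.design)
            n_build = int(np.ceil(2 * n / 3))
            if n - n_build < 1:
                raise ValueError("too few rows to hold out a validation set")
            self.build = _slice_obs(obs, slice(0, n_build))
            self.val = _slice_obs(obs, slice(n_build, n))
        else:
            self.build = obs
            self.val = val_obs

    def observe(self, design, tissues=None):
        for source in (self.build, self.val):
            if len(source.design) == len(design) and np.allclose(
                    source.design.theta_deg, design.theta_deg):
                table = source.responses
                return table if tissues is None else table[list(tissues)]
        raise KeyError("design not backed by the supplied observation files")


def _slice_obs(obs: ObservationSet, sl: slice) -> ObservationSet:
    from .design import Design
    d = obs.design
    design = Design(kind=d.kind, theta_deg=d.theta_deg[sl], phi_deg=d.phi_deg[sl],
                    seed_or_skip=d.seed_or_skip)
    return ObservationSet(design=design, responses=obs.responses.iloc[sl].reset_index(drop=True))


def fit_from_observations(obs: ObservationSet, p_grid, tau_percent: float = 0.5,
                          val_obs: ObservationSet | None = None):
    """Fit per-tissue surrogates from user-supplied observation tables.

    Returns ``{tissue: (PCModel, FitReport-like dict)}``; the build design size
    is fixed by the file, so only the degree ladder is explored.
    """
    source = _FileSolver(obs, val_obs)
    results = {}
    for tissue in obs.tissues:
        y = source.build.responses[tissue].to_numpy()
        y_val = source.val.responses[tissue].to_numpy()
        best = None
        for p in sorted(p_grid):
            model = fit_pc(source.build.design, y, p=p, tissue=tissue)
            pm = pmse(y_val, model.predict(source.val.design))
            model.pmse_percent = pm
            if best is None or pm < best[0]:
                best = (pm, model)
            if pm < tau_percent:
                break
        pm, model = best
        results[tissue] = (model, {"pmse_percent": pm, "converged": pm < tau_percent})
    return results


def run_pipeline(config: PipelineConfig, out_dir=None,
                 ga: GAModel | None = None) -> PipelineResult:
    """Execute the full analysis for one fixture; optionally persist artifacts."""
    t0 = time.time()
    ga = ga or _build_fixture(config)
    solver = VirtualSolver(ga, config.solver_config())
    limits = RegulatoryLimits(reference_level_b=config.b_rms,
                              frequency=config.frequency)
    seeds = {"validation": config.seed_validation,
             "sweep": config.seed_sweep, "noise": config.seed_noise}
    chash = config.config_hash()
    log_lines = [f"config_hash={chash} seeds={seeds} ga={ga.label}"]

    models, reports, rows = {}, {}, []
    for region in ga.all_regions:
        t_start = time.time()
        model, report = adaptive_fit(solver, region.name, config.n_grid,
                                     config.p_grid, tau_percent=config.tau_percent,
                                     seeds=seeds)
        summary = summarize_tissue(model, region.is_cns_head, limits,
                                   M=config.sweep_size, seed=config.seed_sweep)
        gmax, gth, gph = grid_max(model, step_deg=1.0)
        models[region.name] = model
        reports[region.name] = report
        rows.append({
            "tissue": region.name,
            "is_cns_head": region.is_cns_head,
            "mean_V_per_m": summary.mean,
            "std_V_per_m": summary.std,
            "cv_percent": summary.cv_percent,
            "mE99th_V_per_m": summary.mE99th,
            "e_lim_V_per_m": summary.e_lim,
            "ws_percent": summary.ws_percent,
            "grid_max_V_per_m": gmax,
            "pmse_percent": model.pmse_percent,
            "converged": report.converged,
        })
        log_lines.append(
            f"tissue={region.name} N={model.n_build} p={model.spec.p} Q={model.Q} "
            f"pMSE={model.pmse_percent:.4f}% converged={report.converged} "
            f"elapsed={time.time() - t_start:.1f}s")

    summaries = pd.DataFrame(rows)
    converged_all = bool(summaries["converged"].all())

    wb_model = models["whole_body"]
    bands = band_map(wb_model, M=config.sweep_size, seed=config.seed_sweep,
                     thresholds=config.band_thresholds)
    gmax, gth, gph = grid_max(wb_model, step_deg=1.0)
    solid_angles = {
        label: {"solid_angle_sr": bands.solid_angles_sr[label],
                "standard_error_sr": bands.solid_angle_se_sr[label]}
        for label in bands.solid_angles_sr
    }
    extras = {"whole_body_grid_max_V_per_m": gmax,
              "whole_body_argmax_theta_deg": gth,
              "whole_body_argmax_phi_deg": gph}

    result = PipelineResult(config=config, summaries=summaries, models=models,
                            reports=reports, whole_body_bands=bands,
                            solid_angles=solid_angles, converged_all=converged_all,
                            extras=extras)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summaries.to_csv(out / f"results_{ga.label}.csv", index=False,
                         float_format="%.17g")
        pd.DataFrame({
            "theta_deg": bands.sweep.theta_deg,
            "phi_deg": bands.sweep.phi_deg,
            "value_V_per_m": bands.values,
            "band": bands.bands,
        }).to_csv(out / f"bands_{ga.label}.csv", index=False, float_format="%.17g")
        for name, model in models.items():
            pio.write_model(out / f"model_{ga.label}_{name}.json", model)
        summary_json = {
            "config_hash": chash,
            "config": config.to_dict(),
            "ga": ga.label,
            "converged_all": converged_all,
            "mE99th_whole_body_V_per_m": bands.mE99th,
            **extras,
            "solid_angles": solid_angles,
        }
        (out / f"summary_{ga.label}.json").write_text(
            json.dumps(summary_json, indent=1) + "\n")
        log_lines.append(f"total_elapsed={time.time() - t0:.1f}s "
                         f"converged_all={converged_all}")
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        result.out_dir = out

    for line in log_lines:
        logger.info(line)
    return result
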