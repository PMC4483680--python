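"""Sparse chaos-expansion fitting: LARS selection, hybrid OLS, LOO model choice.

The fitting scheme follows the sparse-regression chaos framework: the least
angle regression (LARS) path over the candidate basis supplies a nested family
of active sets; on every active set the coefficients are re-estimated by
ordinary least squares on the *unscaled* basis matrix ("hybrid" LARS); the
expansion kept is the one minimising the closed-form leave-one-out (LOO)
cross-validation error.  Validation against an independent design uses the
percentage mean square error

    pMSE = 100 / S * sum_i ((y_val_i - y_pred_i) / y_val_i)^2

and the build is refined over a ladder of design sizes N and maximum degrees p
until pMSE drops below a threshold tau (0.5 % by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla

from .basis import BasisSpec, evaluate_basis, evaluate_multiindices
from .design import Design, sobol_design, uniform_random_design

logger = logging.getLogger(__name__)

DEFAULT_TAU_PERCENT = 0.5


@dataclass
class ObservationSet:
    """Paired orientation design and per-tissue response table (V/m).

    ``responses`` columns are tissue names; every value must be finite and
    strictly positive, with one row per design point.
    """

    design: Design
    responses: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.responses) != len(self.design):
            raise ValueError("response length must equal design length")
        values = self.responses.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("responses must be finite")
        if np.any(values <= 0):
            raise ValueError("responses must be strictly positive")

    @property
    def tissues(self) -> list[str]:
        return list(self.responses.columns)


@dataclass
class PCModel:
    """A fitted sparse chaos expansion for one tissue.

    ``active_indices`` always starts with the constant multi-index; the
    coefficients are aligned with it and carry the units of the response (V/m).
    """

    tissue: str
    spec: BasisSpec
    active_indices: tuple[tuple[int, ...], ...]
    coefficients: np.ndarray
    loo_error: float
    n_build: int
    pmse_percent: float | None = None
    seeds: dict | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.active_indices = tuple(tuple(a) for a in self.active_indices)
        if self.active_indices[0] != (0,) * self.spec.K:
            raise ValueError("constant term must be the first active index")
        if len(self.coefficients) != len(self.active_indices):
            raise ValueError("coefficients misaligned with active indices")

    @property
    def Q(self) -> int:
        return len(self.coefficients)

    def predict_xi(self, xi: np.ndarray) -> np.ndarray:
        """Evaluate the surrogate at standardized points of shape (M, K)."""
        Psi = evaluate_multiindices(xi, self.active_indices, K=self.spec.K)
        return Psi @ self.coefficients

    def predict(self, design: Design) -> np.ndarray:
        return self.predict_xi(design.standardized())


@dataclass
class FitReport:
    """Diagnostics of one adaptive fit: the path tried and where it stopped."""

    m: int
    loo_errors: list[float]
    selected_step: int
    pmse_percent: float
    tau_percent: float
    n_grid: list[int]
    p_grid: list[int]
    tried: list[dict] = field(default_factory=list)
    converged: bool = False


def lars_path(design_matrix: np.ndarray, y: np.ndarray, max_active: int | None = None):
    """Least-angle-regression inclusion order over the non-constant columns.

    ``design_matrix`` is the N x P basis matrix whose column 0 is the constant;
    the non-constant columns are centered and scaled to unit norm for the
    correlation computations only.  Returns the ordered list of active sets as
    tuples of column indices into ``design_matrix`` (excluding column 0, which
    is implicitly always in the model); the k-th entry has k members.  The path
    stops early if the active Gram matrix becomes numerically singular.
    """
    Psi = np.asarray(design_matrix, dtype=float)
    y = np.asarray(y, dtype=float)
    N, P = Psi.shape
    if N < 2:
        raise ValueError("need at least two observations")
    if np.ptp(Psi[:, 0]) > 1e-12 * max(1.0, abs(Psi[0, 0])):
        raise ValueError("column 0 of the design matrix must be constant")

    limit = min(P - 1, N - 2)
    if max_active is not None:
        limit = min(limit, max_active)
    if limit <= 0:
        return []

    X = Psi[:, 1:] - Psi[:, 1:].mean(axis=0)
    norms = np.linalg.norm(X, axis=0)
    valid = norms > 1e-13 * max(norms.max(initial=0.0), 1.0)
    Xs = np.zeros_like(X)
    Xs[:, valid] = X[:, valid] / norms[valid]

    yc = y - y.mean()
    yscale = max(np.linalg.norm(yc), 1.0)
    mu = np.zeros(N)
    active: list[int] = []
    inactive = set(np.flatnonzero(valid))
    sets: list[tuple[int, ...]] = []

    if not inactive:
        return []

    c = Xs.T @ yc
    j0 = max(inactive, key=lambda j: abs(c[j]))
    if abs(c[j0]) <= 1e-13 * yscale:  # response carries no signal
        return []
    active.append(j0)
    inactive.discard(j0)

    while True:
        sets.append(tuple(j + 1 for j in active))
        if len(active) >= limit or not inactive:
            break
        c = Xs.T @ (yc - mu)
        C = float(np.max(np.abs(c[active])))
        if C <= 1e-13 * yscale:  # residual exhausted
            break
        s = np.sign(c[active])
        s[s == 0] = 1.0
        XA = Xs[:, active] * s
        G = XA.T @ XA
        try:
            cho = sla.cho_factor(G)
            w = sla.cho_solve(cho, np.ones(len(active)))
        except sla.LinAlgError:
            logger.warning("LARS path stopped early: singular active Gram matrix "
                           "at %d active columns", len(active))
            break
        wsum = float(w.sum())
        if wsum <= 0:
            logger.warning("LARS path stopped early: non-positive equiangular norm")
            break
        AA = 1.0 / np.sqrt(wsum)
        u = XA @ (AA * w)
        a = Xs.T @ u

        gamma_best, j_best = None, None
        for j in inactive:
            for num, den in ((C - c[j], AA - a[j]), (C + c[j], AA + a[j])):
                if den > 1e-14:
                    g = num / den
                    if g > 1e-12 and (gamma_best is None or g < gamma_best):
                        gamma_best, j_best = g, j
        if j_best is None:
            break
        mu = mu + gamma_best * u
        active.append(j_best)
        inactive.discard(j_best)

    return sets


def hybrid_ols(active_set, design_matrix: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS coefficients on the selected columns of the original basis matrix.

    The constant column 0 is always part of the model (prepended if absent from
    ``active_set``).  Raises if the selected columns are numerically rank
    deficient, naming them.
    """
    cols = list(active_set)
    if 0 not in cols:
        cols = [0] + cols
    A = np.asarray(design_matrix, dtype=float)[:, cols]
    coef, _, rank, _ = np.linalg.lstsq(A, np.asarray(y, dtype=float), rcond=None)
    if rank < len(cols):
        raise np.linalg.LinAlgError(
            f"singular normal system for basis columns {cols} (rank {rank})"
        )
    return coef


def loo_error(active_matrix: np.ndarray, y: np.ndarray, coefficients: np.ndarray) -> float:
    """Relative leave-one-out error via the hat-matrix diagonal, no refits.

        err = sum_i ((y_i - yhat_i) / (1 - h_i))^2 / sum_i (y_i - ybar)^2

    with ``h_i`` the i-th diagonal entry of A (A^T A)^{-1} A^T.
    """
    A = np.asarray(active_matrix, dtype=float)
    y = np.asarray(y, dtype=float)
    if A.shape[0] <= A.shape[1]:
        raise ValueError("need more observations than columns for LOO")
    Qm, _ = np.linalg.qr(A)
    h = np.einsum("ij,ij->i", Qm, Qm)
    if np.any(h >= 1.0 - 1e-10):
        raise ValueError("leverage ~1 encountered; LOO error undefined")
    denom = float(np.sum((y - y.mean()) ** 2))
    if denom == 0.0:
        raise ValueError("constant response; relative LOO error undefined")
    resid = y - A @ np.asarray(coefficients, dtype=float)
    return float(np.sum((resid / (1.0 - h)) ** 2) / denom)


def _select_with_diagnostics(path, design_matrix, y, spec: BasisSpec,
                             tissue: str = "", n_build: int | None = None):
    """Hybrid-OLS + LOO over all path steps; minimum LOO wins, ties to smaller."""
    Psi = np.asarray(design_matrix, dtype=float)
    y = np.asarray(y, dtype=float)
    N = Psi.shape[0]
    n_build = N if n_build is None else n_build

    degenerate = float(np.sum((y - y.mean()) ** 2)) <= 1e-28 * max(1.0, float(y.mean()) ** 2)
    candidates = [()] + [tuple(s) for s in path]
    loo_errors: list[float] = []
    best = None  # (err, step, cols, coef)
    for step, active in enumerate(candidates):
        cols = [0] + list(active)
        try:
            coef = hybrid_ols(active, Psi, y)
            if degenerate:
                err = 0.0 if step == 0 else np.inf
            else:
                err = loo_error(Psi[:, cols], y, coef)
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.debug("skipping path step %d (%s): %s", step, tissue, exc)
            loo_errors.append(np.nan)
            continue
        loo_errors.append(err)
        if best is None or err < best[0]:
            best = (err, step, cols, coef)
    if best is None:
        raise RuntimeError(f"no admissible model along the LARS path for '{tissue}'")
    err, step, cols, coef = best
    model = PCModel(
        tissue=tissue,
        spec=spec,
        active_indices=tuple(spec.indices[j] for j in cols),
        coefficients=coef,
        loo_error=err,
        n_build=n_build,
    )
    return model, loo_errors, step


def select_model(path, design_matrix, y, spec: BasisSpec,
                 tissue: str = "", n_build: int | None = None) -> PCModel:
    """Return the path step with minimal LOO error as a fitted :class:`PCModel`."""
    model, _, _ = _select_with_diagnostics(path, design_matrix, y, spec,
                                           tissue=tissue, n_build=n_build)
    return model


def pmse(y_val: np.ndarray, y_pred: np.ndarray) -> float:
    """Percentage mean square error of predictions on a validation set."""
    y_val = np.asarray(y_val, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_val.shape != y_pred.shape:
        raise ValueError("validation and prediction vectors must align")
    if np.any(y_val == 0):
        raise ValueError("zero validation value; relative error undefined")
    return float(np.mean(((y_val - y_pred) / y_val) ** 2) * 100.0)


class FunctionSolver:
    """Adapter exposing plain callables ``f(theta_deg, phi_deg) -> value`` as an
    observation source with the same ``observe`` surface as the virtual solver."""

    def __init__(self, functions: dict):
        self.functions = dict(functions)

    def observe(self, design: Design, tissues=None) -> pd.DataFrame:
        names = list(self.functions) if tissues is None else list(tissues)
        data = {name: np.asarray(self.functions[name](design.theta_deg, design.phi_deg),
                                 dtype=float)
                for name in names}
        return pd.DataFrame(data)


def fit_pc(design: Design, y: np.ndarray, p: int, tissue: str = "") -> PCModel:
    """One-shot hybrid-LARS fit at fixed maximum degree ``p``."""
    spec = BasisSpec(K=2, p=p)
    Psi = evaluate_basis(design.standardized(), spec)
    path = lars_path(Psi, y)
    return select_model(path, Psi, y, spec, tissue=tissue, n_build=len(design))


def adaptive_fit(solver, tissue: str, n_grid, p_grid,
                 tau_percent: float = DEFAULT_TAU_PERCENT,
                 seeds: dict | None = None):
    """Refine the expansion over the (N, p) ladder until pMSE < tau.

    For every N in ``n_grid`` a Sobol build design is observed and, for every p
    in ``p_grid``, a surrogate is fitted and validated on a fresh
    uniform-random design of size S = N // 2 (seeded by ``seeds['validation']``).
    The first (N, p) whose pMSE beats the threshold wins; otherwise the best
    model seen is returned with ``converged=False``.

    ``solver`` must expose ``observe(design, tissues=[name]) -> DataFrame``.
    """
    n_grid = list(n_grid)
    p_grid = list(p_grid)
    if not n_grid or not p_grid:
        raise ValueError("n_grid and p_grid must be non-empty")
    if n_grid != sorted(n_grid) or p_grid != sorted(p_grid):
        raise ValueError("n_grid and p_grid must be ascending")
    seeds = dict(seeds or {})
    val_seed = int(seeds.get("validation", 0))

    best = None  # (pmse, model, report_fields)
    tried: list[dict] = []
    for N in n_grid:
        build = sobol_design(N)
        y = solver.observe(build, tissues=[tissue])[tissue].to_numpy()
        S = max(1, N // 2)
        val = uniform_random_design(S, seed=val_seed)
        y_val = solver.observe(val, tissues=[tissue])[tissue].to_numpy()
        xi = build.standardized()
        for p in p_grid:
            spec = BasisSpec(K=2, p=p)
            Psi = evaluate_basis(xi, spec)
            path = lars_path(Psi, y)
            try:
                model, loos, step = _select_with_diagnostics(
                    path, Psi, y, spec, tissue=tissue, n_build=N)
            except RuntimeError as exc:
                raise RuntimeError(f"fit failed for {tissue} at N={N}, p={p}") from exc
            pm = pmse(y_val, model.predict(val))
            model.pmse_percent = pm
            model.seeds = {"validation": val_seed, **{k: v for k, v in seeds.items()
                                                      if k != "validation"}}
            tried.append({"N": N, "p": p, "loo_error": model.loo_error,
                          "pmse_percent": pm, "Q": model.Q})
            logger.info("fit %-16s N=%-4d p=%-3d Q=%-4d loo=%.3e pMSE=%.4f%%",
                        tissue, N, p, model.Q, model.loo_error, pm)
            entry = (pm, model, loos, step, N)
            if best is None or pm < best[0]:
                best = entry
            if pm < tau_percent:
                report = FitReport(m=min(spec.P, N - 1), loo_errors=loos,
                                   selected_step=step, pmse_percent=pm,
                                   tau_percent=tau_percent, n_grid=n_grid,
                                   p_grid=p_grid, tried=tried, converged=True)
                return model, report
    pm, model, loos, step, N = best
    report = FitReport(m=min(model.spec.P, N - 1), loo_errors=loos,
                       selected_step=step, pmse_percent=pm,
                       tau_percent=tau_percent, n_grid=n_grid, p_grid=p_grid,
                       tried=tried, converged=False)
    return model, report
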