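"""Sparse chaos fitting: LARS path, hybrid OLS, LOO selection, pMSE, refinement."""

import numpy as np
import pytest

import pcdosim as pc
from pcdosim.sparse import _select_with_diagnostics


def make_instance(rng, N=40, p=3, signal_cols=(), coefs=(), noise=1.0):
    spec = pc.BasisSpec(K=2, p=p)
    xi = rng.uniform(-1, 1, (N, 2))
    Psi = pc.evaluate_basis(xi, spec)
    y = noise * rng.normal(size=N)
    for j, a in zip(signal_cols, coefs):
        y = y + a * Psi[:, j]
    return spec, Psi, y


class TestLarsPath:
    def test_first_column_is_max_correlation(self, rng):
        for _ in range(5):
            spec, Psi, y = make_instance(rng)
            path = pc.lars_path(Psi, y)
            X = Psi[:, 1:] - Psi[:, 1:].mean(0)
            X = X / np.linalg.norm(X, axis=0)
            yc = y - y.mean()
            assert path[0][0] == np.argmax(np.abs(X.T @ yc)) + 1

    def test_perfect_correlation_selected_first(self, rng):
        spec, Psi, _ = make_instance(rng)
        y = Psi[:, 4].copy()
        path = pc.lars_path(Psi, y)
        assert path[0] == (4,)
        coef = pc.hybrid_ols(path[0], Psi, y)
        resid = y - Psi[:, [0, 4]] @ coef
        assert np.linalg.norm(resid) < 1e-10

    def test_residual_norms_non_increasing(self, rng):
        # explicit least-squares oracle at each path step
        spec, Psi, y = make_instance(rng, N=30, p=2)  # 5 non-constant columns
        path = pc.lars_path(Psi, y)
        norms = []
        for active in path:
            coef = pc.hybrid_ols(active, Psi, y)
            norms.append(np.linalg.norm(y - Psi[:, [0] + list(active)] @ coef))
        assert all(a >= b - 1e-10 for a, b in zip(norms, norms[1:]))

    def test_matches_reference_lars_order(self, rng):
        sklearn = pytest.importorskip("sklearn.linear_model")
        for _ in range(10):
            spec, Psi, y = make_instance(rng, N=40, p=3,
                                         signal_cols=(3,), coefs=(2.0,))
            mine = [s[-1] for s in pc.lars_path(Psi, y)]
            X = Psi[:, 1:] - Psi[:, 1:].mean(0)
            X = X / np.linalg.norm(X, axis=0)
            _, active, _ = sklearn.lars_path(X, y - y.mean(), method="lar")
            theirs = [a + 1 for a in active]
            k = min(len(mine), len(theirs))
            assert mine[:k] == theirs[:k]

    def test_active_set_sizes(self, rng):
        spec, Psi, y = make_instance(rng, N=12, p=5)  # limit = N - 2 = 10
        path = pc.lars_path(Psi, y)
        assert [len(s) for s in path] == list(range(1, len(path) + 1))
        assert len(path) <= min(Psi.shape[1] - 1, 10)


class TestHybridOls:
    def test_intercept_only_is_mean(self, rng):
        y = rng.normal(size=20)
        Psi = pc.evaluate_basis(rng.uniform(-1, 1, (20, 2)), pc.BasisSpec(K=2, p=2))
        coef = pc.hybrid_ols((), Psi, y)
        assert coef[0] == pytest.approx(y.mean(), abs=1e-12)

    def test_exact_interpolation_of_basis_combination(self, rng):
        spec, Psi, _ = make_instance(rng, N=25, p=2)
        y = 2.0 + 0.5 * Psi[:, 1]  # column 1 is the (1, 0) polynomial
        coef = pc.hybrid_ols((1,), Psi, y)
        np.testing.assert_allclose(coef, [2.0, 0.5], atol=1e-10)

    def test_residual_orthogonality(self, rng):
        # normal-equations oracle: residuals orthogonal to active columns
        Psi = rng.normal(size=(20, 4))
        Psi[:, 0] = 1.0
        y = rng.normal(size=20)
        coef = pc.hybrid_ols((1, 2, 3), Psi, y)
        resid = y - Psi @ coef
        assert np.max(np.abs(Psi.T @ resid)) < 1e-10

    def test_singular_columns_rejected(self, rng):
        Psi = np.ones((10, 3))
        Psi[:, 1] = rng.normal(size=10)
        Psi[:, 2] = 2 * Psi[:, 1]
        with pytest.raises(np.linalg.LinAlgError):
            pc.hybrid_ols((1, 2), Psi, rng.normal(size=10))


class TestLooError:
    def brute_force_loo(self, A, y):
        N = len(y)
        errs = []
        for i in range(N):
            mask = np.arange(N) != i
            c, *_ = np.linalg.lstsq(A[mask], y[mask], rcond=None)
            errs.append((y[i] - A[i] @ c) ** 2)
        return np.sum(errs) / np.sum((y - y.mean()) ** 2)

    def test_matches_explicit_refits(self, rng):
        A = rng.normal(size=(12, 3))
        A[:, 0] = 1.0
        y = rng.normal(size=12)
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        assert pc.loo_error(A, y, coef) == pytest.approx(
            self.brute_force_loo(A, y), abs=1e-10)

    def test_intercept_only_closed_form(self):
        # h_i = 1/N; for N = 2 the relative LOO error is exactly 4
        y = np.array([1.0, 3.0])
        A = np.ones((2, 1))
        assert pc.loo_error(A, y, np.array([y.mean()])) == pytest.approx(4.0)

    def test_noiseless_span_gives_zero(self, rng):
        A = rng.normal(size=(15, 3))
        A[:, 0] = 1.0
        coef_true = np.array([1.0, -2.0, 0.5])
        y = A @ coef_true
        assert pc.loo_error(A, y, coef_true) < 1e-20

    def test_constant_response_rejected(self):
        A = np.ones((5, 1))
        with pytest.raises(ValueError):
            pc.loo_error(A, np.full(5, 2.0), np.array([2.0]))


class TestSelectModel:
    def test_recovers_planted_sparse_response(self, rng):
        spec = pc.BasisSpec(K=2, p=5)
        xi = rng.uniform(-1, 1, (50, 2))
        Psi = pc.evaluate_basis(xi, spec)
        true_cols, true_coefs = [0, 4, 9], [3.0, 1.2, -0.7]
        y = Psi[:, true_cols] @ np.array(true_coefs)
        model = pc.select_model(pc.lars_path(Psi, y), Psi, y, spec, tissue="toy")
        fitted = dict(zip(model.active_indices, model.coefficients))
        for j, a in zip(true_cols, true_coefs):
            assert fitted[spec.indices[j]] == pytest.approx(a, abs=1e-8)
        extras = [v for k, v in fitted.items()
                  if k not in {spec.indices[j] for j in true_cols}]
        assert all(abs(v) < 1e-8 for v in extras)

    def test_pure_noise_selects_near_intercept(self):
        # with no signal the LOO minimum sits near the intercept-only end of
        # the path, far from the saturated basis (P = 15 here)
        qs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            spec, Psi, y = make_instance(rng, N=60, p=4)
            model = pc.select_model(pc.lars_path(Psi, y), Psi, y, spec)
            qs.append(model.Q)
        assert np.median(qs) <= 4
        assert max(qs) < spec.P
        assert sum(q <= 5 for q in qs) >= 15

    def test_q_bounded_by_path_length(self, rng):
        spec, Psi, y = make_instance(rng, N=10, p=5)
        model = pc.select_model(pc.lars_path(Psi, y), Psi, y, spec)
        assert model.Q <= min(spec.P, 10 - 1)

    def test_degenerate_constant_response(self, rng):
        spec, Psi, _ = make_instance(rng, N=20, p=3)
        y = np.full(20, 1.4e-3)
        model = pc.select_model(pc.lars_path(Psi, y), Psi, y, spec)
        assert model.Q == 1
        assert model.coefficients[0] == pytest.approx(1.4e-3)


class TestPmse:
    def test_examples(self):
        assert pc.pmse(np.array([1.0, 2.0]), np.array([1.0, 2.0])) == 0.0
        assert pc.pmse(np.array([1.0]), np.array([0.9])) == pytest.approx(1.0, rel=1e-9)
        assert pc.pmse(np.array([1.0, 2.0]), np.array([0.9, 2.0])) == pytest.approx(0.5)

    def test_zero_validation_value_rejected(self):
        with pytest.raises(ValueError):
            pc.pmse(np.array([0.0, 1.0]), np.array([1.0, 1.0]))


class TestAdaptiveFit:
    @staticmethod
    def quadratic_solver():
        def f(theta, phi):
            xi = pc.standardize(theta, phi)
            return 2.0 + 1.5 * xi[:, 0] ** 2 + 0.8 * xi[:, 0] * xi[:, 1]
        return pc.FunctionSolver({"toy": f})

    def test_polynomial_oracle_converges_at_first_sufficient_degree(self):
        model, report = pc.adaptive_fit(self.quadratic_solver(), "toy",
                                        n_grid=[40], p_grid=[1, 2, 5],
                                        tau_percent=0.5, seeds={"validation": 3})
        assert report.converged
        assert model.spec.p == 2
        assert model.pmse_percent < 1e-10

    def test_vacuous_threshold_converges_immediately(self):
        model, report = pc.adaptive_fit(self.quadratic_solver(), "toy",
                                        n_grid=[40, 80], p_grid=[1, 2],
                                        tau_percent=np.inf, seeds={"validation": 3})
        assert report.converged
        assert model.n_build == 40 and model.spec.p == 1

    def test_unreachable_threshold_reports_best(self):
        def noisy(theta, phi):
            rng = np.random.default_rng(np.int64(theta[0] * 1e6) % 2**31)
            return 1.0 + 0.1 * np.abs(rng.normal(size=len(theta)))
        solver = pc.FunctionSolver({"toy": noisy})
        model, report = pc.adaptive_fit(solver, "toy", n_grid=[30], p_grid=[1],
                                        tau_percent=1e-12, seeds={"validation": 3})
        assert not report.converged
        assert report.pmse_percent >= 1e-12

    def test_loo_closed_form_equals_refits_on_many_instances(self):
        # 100 seeded small instances, closed form vs explicit refits
        worst = 0.0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            ncol = rng.integers(1, 6)
            N = int(rng.integers(ncol + 2, 16))
            A = rng.normal(size=(N, ncol))
            A[:, 0] = 1.0
            y = rng.normal(size=N)
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            closed = pc.loo_error(A, y, coef)
            brute = TestLooError().brute_force_loo(A, y)
            worst = max(worst, abs(closed - brute))
        assert worst < 1e-8
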