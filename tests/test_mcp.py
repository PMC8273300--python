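"""MCP-penalized Cox selection: penalty closed forms, path anatomy, and the
unpenalized / null-model limits of the coordinate-descent solver."""

import warnings

import numpy as np
import pytest

from himasurv import CoxDesign, McpPenalty, fit_cox, fit_mcp_cox, lambda_path, mcp_value_deriv
from himasurv._fast import mcp_cox_solve
from himasurv.mcp import _standardize


@pytest.fixture(scope="module")
def design():
    rng = np.random.default_rng(51)
    n, q = 200, 5
    X = rng.standard_normal((n, q))
    X[:, 0] = (rng.random(n) < 0.5).astype(float)  # binary "exposure"
    lp = X @ np.array([0.4, 0.0, 0.6, 0.0, -0.5])
    time = rng.exponential(np.exp(-lp))
    event = (rng.random(n) < 0.85).astype(int)
    return CoxDesign(X, time, event)


class TestPenaltyClosedForm:
    def test_zero(self):
        val, der = mcp_value_deriv(0.0, McpPenalty(1.0, 3.0))
        assert val == 0.0 and der == 0.0

    def test_interior_point(self):
        val, der = mcp_value_deriv(1.5, McpPenalty(1.0, 3.0))
        assert val == pytest.approx(1.125)
        assert abs(der) == pytest.approx(0.5)

    def test_knot_continuity(self):
        pen = McpPenalty(0.8, 2.5)
        t = pen.a * pen.lam
        val, der = mcp_value_deriv(t, pen)
        assert der == 0.0
        assert val == pytest.approx(pen.a * pen.lam**2 / 2)
        val_out, _ = mcp_value_deriv(t + 1e-9, pen)
        assert val_out == pytest.approx(val)

    def test_invalid_shape(self):
        with pytest.raises(ValueError):
            McpPenalty(1.0, a=1.0)


class TestPenaltyProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(t=st.floats(-50, 50), lam=st.floats(0, 5), a=st.floats(1.01, 100))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_value_bounds_and_derivative_consistency(self, t, lam, a):
        pen = McpPenalty(lam, a)
        val, der = mcp_value_deriv(t, pen)
        assert 0.0 <= val <= a * lam**2 / 2 + 1e-12
        # numerical derivative away from the non-differentiable origin
        if abs(t) > 1e-3:
            h = 1e-6 * max(1.0, abs(t))
            v1, _ = mcp_value_deriv(t + h, pen)
            v0, _ = mcp_value_deriv(t - h, pen)
            assert der == pytest.approx((v1 - v0) / (2 * h), abs=1e-4)

    @given(lam=st.floats(0.01, 5), a=st.floats(1.01, 100),
           t1=st.floats(0, 40), t2=st.floats(0, 40))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_in_magnitude(self, lam, a, t1, t2):
        pen = McpPenalty(lam, a)
        lo, hi = sorted([t1, t2])
        assert mcp_value_deriv(lo, pen)[0] <= mcp_value_deriv(hi, pen)[0] + 1e-12


class TestLambdaPath:
    def test_grid_shape_and_zero_head(self, design):
        lams = lambda_path(design, n_unpen=2, n_lambda=30, ratio=0.05)
        assert len(lams) == 30
        assert np.all(np.diff(lams) < 0)
        fit = fit_mcp_cox(design, 2, lambdas=lams[:1])
        assert fit.df_path[0] == 0

    def test_lambda_max_matches_bisection(self, design):
        lams = lambda_path(design, n_unpen=2, n_lambda=40, ratio=0.02)
        lam_max = lams[0]

        def nnz_at(lam):
            f = fit_mcp_cox(design, 2, lambdas=np.array([lam]))
            return f.df_path[0]

        lo, hi = 0.0, lam_max
        for _ in range(25):
            mid = 0.5 * (lo + hi)
            if nnz_at(mid) == 0:
                hi = mid
            else:
                lo = mid
        step = lams[0] - lams[1]
        assert nnz_at(lam_max) == 0
        assert lam_max - hi <= step + 1e-8  # formula within one grid step of bisection

    def test_invalid_args(self, design):
        with pytest.raises(ValueError):
            lambda_path(design, 2, n_lambda=1)
        with pytest.raises(ValueError):
            lambda_path(design, 2, ratio=1.5)


class TestSolver:
    def test_lambda_zero_equals_newton_mle(self, design):
        Xs, scale = _standardize(design, 2)
        b = np.zeros(5)
        mcp_cox_solve(np.ascontiguousarray(Xs), design.event.astype(np.float64),
                      design.first, design.event_idx, b, 2, 0.0, 3.0, 5000, 1e-9)
        ref = fit_cox(CoxDesign(Xs, design.time, design.event.astype(int)))
        assert np.max(np.abs(b - ref.coef)) < 1e-5

    def test_above_lambda_max_selects_nothing(self, design):
        lams = lambda_path(design, 2, n_lambda=10)
        fit = fit_mcp_cox(design, 2, lambdas=np.array([lams[0] * 2.0]))
        assert len(fit.selected) == 0
        # unpenalized coefficients still fitted
        assert np.any(fit.coef[:2] != 0)

    def test_penalized_objective_improves(self, design):
        """The solver's endpoint must beat the warm start on the penalized
        objective (partial likelihood minus MCP penalty)."""
        from himasurv.cox import log_partial_likelihood
        Xs, _ = _standardize(design, 2)
        lam = 0.05
        d2 = CoxDesign(Xs, design.time, design.event.astype(int))

        def objective(b):
            pen = sum(mcp_value_deriv(t, McpPenalty(lam, 3.0))[0] for t in b[2:])
            return log_partial_likelihood(d2, b) / design.n - pen

        b = np.zeros(5)
        start = objective(b)
        mcp_cox_solve(np.ascontiguousarray(Xs), design.event.astype(np.float64),
                      design.first, design.event_idx, b, 2, lam, 3.0, 1000, 1e-7)
        assert objective(b) >= start

    def test_large_a_approaches_soft_thresholding(self, design):
        """With a huge concavity parameter the MCP update degenerates to the
        lasso (soft-threshold) update; selected supports should then nest."""
        lams = lambda_path(design, 2, n_lambda=12, ratio=0.1)
        fit_mcp = fit_mcp_cox(design, 2, a=3.0, lambdas=lams)
        fit_big = fit_mcp_cox(design, 2, a=1e6, lambdas=lams)
        # lasso shrinks; MCP debiases - at matched lambda the MCP nonzero
        # coefficients are at least as large in magnitude
        mid = len(lams) // 2
        mcp_c = np.abs(fit_mcp.coef_path[2:, mid])
        las_c = np.abs(fit_big.coef_path[2:, mid])
        active = (mcp_c > 0) & (las_c > 0)
        if active.any():
            assert np.all(mcp_c[active] >= las_c[active] - 1e-6)


class TestSelection:
    def test_single_lambda_is_chosen(self, design):
        lams = lambda_path(design, 2, n_lambda=10)
        fit = fit_mcp_cox(design, 2, lambdas=lams[4:5])
        assert fit.lambda_opt == pytest.approx(lams[4])

    def test_bic_null_model_value(self, design):
        lams = lambda_path(design, 2, n_lambda=5)
        fit = fit_mcp_cox(design, 2, lambdas=lams[:1])
        assert fit.df_path[0] == 0
        assert fit.criterion_path[0] == pytest.approx(-2.0 * fit.loglik_path[0])

    def test_pure_noise_selects_sparsely(self, c0_15):
        from himasurv import SimConfig, generate_dataset
        from himasurv.propensity import fit_propensity
        wins = 0
        for seed in range(20):
            cfg = SimConfig(n_subjects=250, n_mediators=30, c0=c0_15,
                            seed=200 + seed, alpha_true=np.zeros(30),
                            beta_true=np.zeros(30))
            data = generate_dataset(cfg)
            fit = fit_propensity(data.exposure, data.confounders)
            X = np.column_stack([data.exposure.astype(float), fit.scores,
                                 data.mediators])
            d = CoxDesign(X, data.time, data.event)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = fit_mcp_cox(d, 2)
            if len(res.selected) <= 2:
                wins += 1
        assert wins >= 17

    def test_cv_criterion_runs(self, design):
        fit = fit_mcp_cox(design, 2, n_lambda=8, criterion="cv", cv_folds=3)
        assert fit.lambda_opt in fit.lambdas
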