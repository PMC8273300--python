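"""Distributional checks on the synthetic-data generator."""

import numpy as np
import pytest

from himasurv import (SimConfig, calibrate_censoring, generate_confounders,
                      generate_dataset, generate_exposure, generate_mediators,
                      generate_survival)
from himasurv.synthetic import MediationDataset


@pytest.fixture(scope="module")
def cfg():
    return SimConfig(n_subjects=100, n_mediators=50, seed=0)


class TestConfounders:
    def test_bernoulli_and_correlation_moments(self, cfg):
        rng = np.random.default_rng(1)
        Z = generate_confounders(100_000, cfg, rng)
        assert Z.shape == (100_000, 10)
        # binary block: success probability 0.3
        assert np.abs(Z[:, :5].mean(axis=0) - 0.3).max() < 0.01
        # normal block: unit variance, pairwise correlation 0.3
        assert np.abs(Z[:, 5:].std(axis=0) - 1.0).max() < 0.02
        corr = np.corrcoef(Z[:, 5], Z[:, 6])[0, 1]
        assert abs(corr - 0.3) < 0.02

    def test_single_subject(self, cfg):
        Z = generate_confounders(1, cfg, np.random.default_rng(0))
        assert Z.shape == (1, 10)

    def test_invalid_correlation_rejected(self):
        bad = SimConfig(n_subjects=10, n_mediators=5, normal_corr=-0.5)
        with pytest.raises(ValueError):
            generate_confounders(10, bad, np.random.default_rng(0))


class TestExposure:
    def test_logistic_probability_formula(self, cfg):
        rng = np.random.default_rng(2)
        Z = generate_confounders(1000, cfg, rng)
        # the Bernoulli probability is exactly expit(theta'Z), no intercept
        from scipy.special import expit
        p = expit(Z @ cfg.theta)
        assert np.all((0 < p) & (p < 1))
        row0 = np.zeros((1, 10))
        assert expit(row0 @ cfg.theta)[0] == 0.5

    def test_null_theta_gives_half(self, cfg):
        rng = np.random.default_rng(3)
        Z = generate_confounders(100_000, cfg, rng)
        x = generate_exposure(Z, np.zeros(10), rng)
        assert abs(x.mean() - 0.5) < 0.01

    def test_dimension_mismatch(self, cfg):
        Z = generate_confounders(10, cfg, np.random.default_rng(0))
        with pytest.raises(ValueError):
            generate_exposure(Z, np.zeros(3), np.random.default_rng(0))


class TestMediators:
    def test_noise_only_variance(self):
        cfg = SimConfig(n_subjects=4000, n_mediators=6, seed=1,
                        alpha_true=np.zeros(6),
                        phi_mediator=np.zeros(10))
        rng = np.random.default_rng(4)
        Z = generate_confounders(4000, cfg, rng)
        x = generate_exposure(Z, cfg.theta, rng)
        M = generate_mediators(x, Z, cfg, rng)
        assert np.abs(M.var(axis=0, ddof=1) - 1.0).max() < 0.1

    def test_null_mediator_correlation_band(self):
        # shared confounder loading induces ~0.52 pairwise correlation
        cfg = SimConfig(n_subjects=4000, n_mediators=40, seed=2)
        data = generate_dataset(cfg.replace(target_censoring=0.0))
        nulls = data.mediators[:, 8:]
        corr = np.corrcoef(nulls.T)
        off = corr[np.triu_indices_from(corr, k=1)]
        assert 0.45 <= np.median(off) <= 0.65

    def test_ols_recovers_alpha(self):
        cfg = SimConfig(n_subjects=40_000, n_mediators=8, seed=3)
        rng = np.random.default_rng(5)
        Z = generate_confounders(cfg.n_subjects, cfg, rng)
        x = generate_exposure(Z, cfg.theta, rng)
        M = generate_mediators(x, Z, cfg, rng)
        A = np.column_stack([np.ones(cfg.n_subjects), x, Z])
        coef, *_ = np.linalg.lstsq(A, M[:, 0], rcond=None)
        assert abs(coef[1] - 0.5) < 0.03


class TestSurvival:
    def test_exponential_mean_at_null_predictor(self):
        cfg = SimConfig(n_subjects=100_000, n_mediators=4, seed=4,
                        alpha_true=np.zeros(4), beta_true=np.zeros(4),
                        gamma=0.0, phi_outcome=np.zeros(10),
                        phi_mediator=np.zeros(10))
        rng = np.random.default_rng(6)
        Z = generate_confounders(cfg.n_subjects, cfg, rng)
        x = generate_exposure(Z, cfg.theta, rng)
        M = generate_mediators(x, Z, cfg, rng)
        time, event = generate_survival(x, M, Z, cfg, rng, c0=None)
        assert event.all()
        assert abs(time.mean() - 2.0) < 0.05  # Exp(0.5) mean

    def test_event_indicator_definition(self, cfg):
        rng = np.random.default_rng(7)
        Z = generate_confounders(500, cfg, rng)
        x = generate_exposure(Z, cfg.theta, rng)
        M = generate_mediators(x, Z, cfg, rng)
        time, event = generate_survival(x, M, Z, cfg, rng, c0=2.0)
        # censored observations are exactly the uniform censoring draws < D
        assert np.isin(event, (0, 1)).all()
        assert np.all(time[event == 0] <= 2.0)

    def test_bad_c0(self, cfg):
        rng = np.random.default_rng(8)
        Z = generate_confounders(20, cfg, rng)
        x = generate_exposure(Z, cfg.theta, rng)
        M = generate_mediators(x, Z, cfg, rng)
        with pytest.raises(ValueError):
            generate_survival(x, M, Z, cfg, rng, c0=-1.0)


class TestCensoringCalibration:
    @pytest.mark.parametrize("target", [0.15, 0.30])
    def test_calibration_hits_target_on_fresh_sample(self, target):
        cfg = SimConfig(n_subjects=5000, n_mediators=10, seed=11)
        c0 = calibrate_censoring(cfg, target, np.random.default_rng(12))
        data = generate_dataset(cfg.replace(target_censoring=target, c0=c0, seed=99))
        assert abs(data.censoring_rate - target) < 0.02

    def test_monotone_in_target(self):
        cfg = SimConfig(n_subjects=100, n_mediators=10, seed=13)
        c15 = calibrate_censoring(cfg, 0.15, np.random.default_rng(14))
        c30 = calibrate_censoring(cfg, 0.30, np.random.default_rng(14))
        assert c30 < c15  # heavier censoring needs a smaller bound

    def test_invalid_target(self):
        cfg = SimConfig(n_subjects=100, n_mediators=10)
        with pytest.raises(ValueError):
            calibrate_censoring(cfg, 1.5, np.random.default_rng(0))


class TestGenerateDataset:
    def test_truth_manifest(self):
        cfg = SimConfig(n_subjects=50, n_mediators=30, target_censoring=0.0, seed=21)
        data = generate_dataset(cfg)
        assert list(data.true_indices) == [1, 2, 3, 4]
        np.testing.assert_allclose(data.true_products, [0.30, 0.36, 0.25, 0.30])

    def test_determinism(self):
        cfg = SimConfig(n_subjects=80, n_mediators=25, target_censoring=0.15, seed=22)
        a = generate_dataset(cfg)
        b = generate_dataset(cfg)
        np.testing.assert_array_equal(a.mediators, b.mediators)
        np.testing.assert_array_equal(a.time, b.time)
        np.testing.assert_array_equal(a.event, b.event)

    def test_shapes(self, c0_15):
        cfg = SimConfig(n_subjects=60, n_mediators=200, c0=c0_15, seed=23)
        data = generate_dataset(cfg)
        assert data.mediators.shape == (60, 200)
        assert data.confounders.shape == (60, 10)
        assert data.n_subjects == 60

    def test_dataset_validation(self):
        with pytest.raises(ValueError):
            MediationDataset(exposure=np.array([0, 1]),
                             mediators=np.zeros((2, 3)),
                             confounders=np.zeros((2, 2)),
                             time=np.array([-1.0, 2.0]),
                             event=np.array([1, 0]))
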