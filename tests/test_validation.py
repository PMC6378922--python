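import numpy as np
import pytest

import hystnet as hn
from hystnet.validation import (
    _correlation_vector,
    acf_whiteness,
    li_mcleod_portmanteau,
    percent_consistency,
    residuals,
    stability_index,
    validate_model,
)


class TestResiduals:
    def test_ols_residuals_orthogonal_to_regressors(self):
        gen = hn.MVARModel(np.array([[[0.5, 0.0], [0.3, 0.5]]]), np.eye(2), 128.0)
        x = hn.simulate_mvar(gen, 5000, seed=0)
        model = hn.fit_window(x, 1, "ols")
        res = residuals(model, x)
        xd = x - x.mean(axis=(1, 2), keepdims=True)
        Z = xd[:, :-1, 0]
        corr = res[:, :, 0] @ Z.T / res.shape[1]
        assert np.max(np.abs(corr)) < 1e-6

    def test_zero_model_returns_shifted_input(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2, 200))
        model = hn.MVARModel(np.zeros((1, 2, 2)), np.eye(2), 128.0)
        res = residuals(model, x)
        xd = x - x.mean(axis=1, keepdims=True)
        assert np.allclose(res[:, :, 0], xd[:, 1:])

    def test_generator_round_trip_recovers_noise_covariance(self):
        sigma = np.diag([1.0, 2.0])
        gen = hn.MVARModel(np.array([[[0.5, 0.0], [0.3, 0.4]]]), sigma, 128.0)
        x = hn.simulate_mvar(gen, 10_000, seed=2)
        res = residuals(gen, x)
        cov = res[:, :, 0] @ res[:, :, 0].T / res.shape[1]
        assert np.allclose(cov, sigma, rtol=0.05, atol=0.05)

    def test_dimension_mismatch_rejected(self):
        model = hn.MVARModel(np.zeros((1, 2, 2)), np.eye(2), 128.0)
        with pytest.raises(ValueError, match="channels"):
            residuals(model, np.zeros((3, 100)))


class TestAcfWhiteness:
    def test_white_noise_passes_most_of_the_time(self):
        hits = 0
        for seed in range(100):
            e = np.random.default_rng(seed).standard_normal((3, 1000))
            white, _ = acf_whiteness(e, n_lags=20)
            hits += white
        assert hits >= 90

    def test_autocorrelated_residuals_fail(self):
        gen = hn.MVARModel(np.array([[[0.8]]]), np.eye(1), 128.0)
        x = hn.simulate_mvar(gen, 2000, seed=3)
        white, max_r = acf_whiteness(x, n_lags=20)
        assert not white
        assert max_r > 0.5

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            acf_whiteness(np.ones((1, 500)), n_lags=10)

    def test_lag_budget_guard(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError):
            acf_whiteness(rng.standard_normal((1, 40)), n_lags=20)


class TestLiMcleod:
    def test_type_one_error_calibrated(self):
        # 500 Monte-Carlo runs of white residuals at alpha = 0.05
        rng = np.random.default_rng(42)
        rejections = 0
        for _ in range(500):
            e = rng.standard_normal((2, 200))
            _, p = li_mcleod_portmanteau(e, h=10, p=0)
            rejections += p < 0.05
        assert 0.03 <= rejections / 500 <= 0.07

    def test_power_against_underfit_model(self):
        gen = hn.random_stable_mvar(2, 4, seed=5, coupling=0.4)
        hits = 0
        for seed in range(20):
            x = hn.simulate_mvar(gen, 1000, seed=seed)
            under = hn.fit_window(x, 1)
            res = residuals(under, x)
            _, p = li_mcleod_portmanteau(res, h=10, p=1)
            hits += p < 0.05
        assert hits >= 18

    def test_h_equal_to_order_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError, match="exceed"):
            li_mcleod_portmanteau(rng.standard_normal((2, 500)), h=3, p=3)


class TestStabilityIndex:
    @pytest.mark.parametrize(
        "a,expected",
        [(0.5, np.log(0.5)), (1.0, 0.0), (1.2, np.log(1.2))],
    )
    def test_scalar_ar1_closed_form(self, a, expected):
        model = hn.MVARModel(np.array([[[a]]]), np.eye(1), 128.0)
        assert stability_index(model) == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_brute_force_divergence_oracle(self):
        rng = np.random.default_rng(7)
        for trial in range(20):
            k = int(rng.integers(1, 4))
            A = rng.normal(0.0, 0.45, size=(1, k, k))
            model = hn.MVARModel(A, np.eye(k), 128.0)
            idx = stability_index(model)
            # noiseless iteration from a random start diverges iff index > 0
            x = np.ones(k)
            for _ in range(2000):
                x = A[0] @ x
            diverged = not np.all(np.isfinite(x)) or np.linalg.norm(x) > 1e6
            decayed = np.linalg.norm(x) < 1e-3
            if idx > 0.01:
                assert diverged
            elif idx < -0.01:
                assert decayed


class TestPercentConsistency:
    def test_round_trip_model_exceeds_95(self):
        # long data (4 trials x 20k samples) so correlation-estimate
        # noise does not dominate the consistency norm
        gen = hn.network_to_mvar(hn.make_ground_truth_network("L1"))
        x = hn.simulate_mvar(gen, 20_000, n_trials=4, seed=8)
        model = hn.fit_window(x, 8)
        assert percent_consistency(x, model, seed=9) > 95.0

    def test_zero_model_on_structured_data_scores_low(self):
        gen = hn.MVARModel(np.array([[[0.95]]]), np.eye(1), 128.0)
        x = hn.simulate_mvar(gen, 4000, seed=10)
        zero = hn.MVARModel(np.zeros((1, 1, 1)), np.eye(1), 128.0)
        assert percent_consistency(x, zero, seed=11) < 50.0

    def test_identical_correlation_vectors_give_100(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal((2, 500))
        r = _correlation_vector(x, 20)
        pc = 100.0 * (1.0 - np.linalg.norm(r - r) / np.linalg.norm(r))
        assert pc == 100.0

    def test_unstable_model_rejected(self):
        bad = hn.MVARModel(np.array([[[1.1]]]), np.eye(1), 128.0)
        with pytest.raises(ValueError, match="stable"):
            percent_consistency(np.zeros((1, 100)) + np.arange(100), bad, seed=0)

    def test_deterministic_under_seed(self):
        gen = hn.MVARModel(np.array([[[0.6]]]), np.eye(1), 128.0)
        x = hn.simulate_mvar(gen, 2000, seed=13)
        model = hn.fit_window(x, 1)
        assert percent_consistency(x, model, seed=7) == percent_consistency(
            x, model, seed=7
        )


class TestFullBattery:
    def test_well_specified_session_passes_published_criteria(self, short_session):
        # stability < 0 and percent consistency > 85 on every condition
        for cond in ["L1", "H2", "L3"]:
            seg = hn.ensemble_normalize(short_session.segment(cond))
            model = hn.fit_window(seg, p=16)
            rep = validate_model(model, seg.data, seed=14)
            assert rep.stability_index < 0.0
            assert rep.percent_consistency > 85.0
            assert rep.acf_white
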