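"""Expected response, robust GLM, t-critical values and ROI selection."""

import numpy as np
import pytest
import statsmodels.api as sm

from fnirsvmd import (
    GroundTruth,
    NoiseModel,
    RobustGLM,
    build_expected_response,
    epoch,
    fit_condition,
    robust_fit,
    select_roi,
    simulate_session,
    t_critical,
)
from fnirsvmd.activation import ActivationMap, ChannelActivation, hrf_double_gamma


class TestExpectedResponse:
    def test_peak_normalized_to_one(self, xr):
        assert xr.xr.max() == pytest.approx(1.0)

    def test_zero_before_onset_and_nonnegative_rise(self, xr):
        assert xr.xr[0] == pytest.approx(0.0, abs=1e-9)
        # the early response (well before the undershoot) is non-negative
        assert np.all(xr.xr[: int(10 * 1.81)] >= -1e-12)

    def test_zero_duration_stimulus_all_zero(self):
        out = build_expected_response(0.0, 1.81)
        assert np.all(out.xr == 0.0)

    def test_peak_latency_against_convolution_oracle(self, design):
        """Brute-force discrete convolution of HRF and boxcar places the peak
        between the HRF peak delay and the stimulus end."""
        fs = design.sampling_hz
        dt = 1.0 / fs
        t = np.arange(0, 35, dt)
        box = (t < 15.0).astype(float)
        oracle = np.convolve(box, hrf_double_gamma(t))[: len(t)] * dt
        t_peak_oracle = t[np.argmax(oracle)]
        xr = build_expected_response(15.0, fs)
        t_peak = np.argmax(xr.xr) / fs
        assert t_peak == pytest.approx(t_peak_oracle, abs=dt)
        assert 6.0 < t_peak < 15.0

    def test_window_too_short_rejected(self):
        with pytest.raises(ValueError):
            build_expected_response(15.0, 1.81, window=(0.0, 0.0))

    def test_restrict_truncates(self, xr):
        short = xr.restrict(20.0)
        assert len(short) == 37
        assert np.allclose(short.xr, xr.xr[:37])


class TestRobustFit:
    def test_noiseless_exact_fit(self, xr):
        res = robust_fit(xr, 2.0 * xr.xr + 1.0)
        assert res.beta_hat == pytest.approx(2.0, abs=1e-8)
        assert res.alpha_hat == pytest.approx(1.0, abs=1e-8)
        assert res.converged

    def test_unit_weights_equal_ols(self, xr, rng):
        """Weights forced to 1 reproduce ordinary least squares to 1e-10."""
        x = xr.xr
        D = np.column_stack([x, np.ones_like(x)])
        for _ in range(20):
            y = rng.normal(0, 1, x.size) + rng.uniform(-2, 2) * x
            ols = np.linalg.lstsq(D, y, rcond=None)[0]
            g = RobustGLM(irls=False).fit(x, y)
            assert abs(g.coef_ - ols[0]) < 1e-10
            assert abs(g.intercept_ - ols[1]) < 1e-10

    def test_gaussian_noise_close_to_ols(self, xr, rng):
        """Without outliers the robust estimate tracks OLS closely."""
        x = xr.xr
        D = np.column_stack([x, np.ones_like(x)])
        diffs = []
        for _ in range(100):
            y = 1.0 * x + rng.normal(0, 0.1, x.size)
            ols = np.linalg.lstsq(D, y, rcond=None)[0][0]
            rob = RobustGLM().fit(x, y).coef_
            diffs.append(abs(rob - ols))
        assert np.mean(diffs) < 1e-2

    def test_outlier_resistance(self, xr, rng):
        """With 10% gross spikes the robust estimate beats OLS nearly always."""
        x = xr.xr
        D = np.column_stack([x, np.ones_like(x)])
        wins = 0
        n_rep = 100
        for _ in range(n_rep):
            y = x + rng.normal(0, 0.3, x.size)
            idx = rng.choice(x.size, size=max(1, x.size // 10), replace=False)
            y[idx] += 50.0
            ols = np.linalg.lstsq(D, y, rcond=None)[0][0]
            rob = RobustGLM().fit(x, y).coef_
            wins += abs(rob - 1.0) < abs(ols - 1.0)
        assert wins >= 95

    def test_matches_statsmodels_rlm(self, xr, rng):
        """Independent IRLS implementation (statsmodels RLM, bisquare) agrees
        on coefficients and standard errors.  statsmodels normalizes the MAD
        by Φ⁻¹(3/4) ≈ 0.67449 where this package uses the conventional
        0.6745, which bounds agreement near 1e-5."""
        x = xr.xr
        for _ in range(10):
            y = rng.uniform(-1, 2) * x + rng.normal(0, 0.5, x.size)
            mine = RobustGLM().fit(x, y)
            ref = sm.RLM(y, sm.add_constant(x),
                         M=sm.robust.norms.TukeyBiweight(4.685)).fit(
                conv="coefs", tol=1e-10, maxiter=200)
            assert mine.coef_ == pytest.approx(ref.params[1], abs=2e-5)
            assert mine.intercept_ == pytest.approx(ref.params[0], abs=2e-5)
            assert mine.se_ == pytest.approx(ref.bse[1], rel=1e-3)

    def test_t_identity_and_dof(self, xr, rng):
        y = xr.xr + rng.normal(0, 0.5, len(xr))
        res = robust_fit(xr, y)
        assert res.t == res.beta_hat / res.se  # bit-exact identity
        assert res.dof == 63
        assert RobustGLM(dof="n_minus_2").fit(xr.xr, y).dof_ == 62

    def test_constant_regressor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            robust_fit(np.ones(64), np.random.default_rng(0).normal(size=64))

    def test_too_short_input_rejected(self, xr):
        with pytest.raises(ValueError):
            robust_fit(xr.xr[:2], np.zeros(2))


class TestTCritical:
    def test_reference_threshold(self):
        assert round(t_critical(63, 0.05), 2) == 1.67

    def test_normal_limit(self):
        assert t_critical(10**7, 0.05) == pytest.approx(1.645, abs=1e-3)

    def test_strictly_decreasing_in_dof(self):
        vals = [t_critical(d, 0.05) for d in (1, 5, 20, 63, 500)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_invalid_dof_rejected(self):
        with pytest.raises(ValueError):
            t_critical(0, 0.05)


class TestFitCondition:
    def test_single_epoch_modes_identical(self, design, xr):
        d = design.__class__(trials_per_valence=1)
        truth = GroundTruth.constant(1.0)
        series, _ = simulate_session(d, truth, NoiseModel.white_only(0.3), seed=0)
        ep = epoch(series)
        a = fit_condition(ep, "positive", xr, mode="per-trial")
        b = fit_condition(ep, "positive", xr, mode="averaged")
        assert np.allclose(a.t_values, b.t_values, atol=1e-12)

    def test_null_mean_t_near_zero(self, design, xr):
        series, _ = simulate_session(design, GroundTruth.constant(0.0),
                                     NoiseModel.white_only(0.5), seed=1)
        ep = epoch(series)
        amap = fit_condition(ep, "positive", xr, mode="per-trial")
        # mean over 16 channels x 5 trials of a ~t(63) variate
        assert abs(amap.t_values.mean()) < 3.0 / np.sqrt(16 * 5)

    def test_high_snr_flags_all_active(self, design, xr):
        series, _ = simulate_session(design, GroundTruth.constant(3.0),
                                     NoiseModel.white_only(0.05), seed=2)
        ep = epoch(series)
        amap = fit_condition(ep, "positive", xr, mode="averaged")
        assert amap.active == list(range(1, 17))

    def test_missing_valence_rejected(self, design, xr):
        series, _ = simulate_session(design, GroundTruth.constant(1.0),
                                     NoiseModel.white_only(0.3), seed=3)
        ep = epoch(series)
        with pytest.raises(ValueError):
            fit_condition(ep, "neutral", xr)


class TestSelectRoi:
    def _map(self, ts, t_crt=1.67):
        entries = tuple(
            ChannelActivation(channel=i + 1, beta=t, se=1.0, t=t, p=0.5, n_trials=5)
            for i, t in enumerate(ts)
        )
        return ActivationMap(entries=entries, mode="averaged", valence="positive",
                             t_crt=t_crt, dof=63)

    def test_strict_threshold(self):
        roi = select_roi(self._map([2.0, 1.0, 1.7]))
        assert roi == [1, 3]

    def test_boundary_excluded(self):
        roi = select_roi(self._map([1.67, 2.0]), t_crt=1.67)
        assert roi == [2]

    def test_empty_roi_warns(self):
        with pytest.warns(UserWarning, match="no channel"):
            roi = select_roi(self._map([0.1, 0.5]))
        assert roi == []
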