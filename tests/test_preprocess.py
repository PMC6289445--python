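"""Filtering, detrending, baseline correction, epoching."""

import numpy as np
import pytest

from fnirsvmd import (
    ConcentrationSeries,
    FilterSpec,
    GroundTruth,
    NoiseModel,
    SessionDesign,
    baseline_correct,
    build_schedule,
    detrend,
    epoch,
    lowpass,
    preprocess_session,
    simulate_session,
)
from fnirsvmd.preprocess import ButterworthLowPass


def _series(data, fs=1.81, schedule=None):
    data = np.atleast_2d(data)
    return ConcentrationSeries(hbo=data, hbr=np.zeros_like(data), sampling_hz=fs,
                               schedule=schedule)


class TestLowpass:
    def test_dc_gain_unity(self):
        s = _series(np.full(400, 3.7))
        out = lowpass(s)
        assert np.allclose(out.hbo, 3.7, atol=1e-9)

    def test_cutoff_attenuation_is_half(self):
        """Forward-backward Butterworth: |H|² = 0.5 at the cutoff."""
        fs, fc = 1.81, 0.15
        t = np.arange(0, 1200, 1 / fs)
        s = _series(np.sin(2 * np.pi * fc * t))
        out = lowpass(s, FilterSpec(order=4, cutoff_hz=fc))
        core = out.hbo[0, 300:-300]
        assert abs(np.max(np.abs(core)) - 0.5) < 0.01

    def test_stopband_attenuation_matches_analytic(self):
        """0.5 Hz tone is suppressed below the analytic |H(f)|² bound (<1%)."""
        fs, fc, f0 = 1.81, 0.15, 0.5
        t = np.arange(0, 1200, 1 / fs)
        s = _series(np.sin(2 * np.pi * f0 * t))
        out = lowpass(s)
        analytic = 1.0 / (1.0 + (f0 / fc) ** 8)  # |H|^2 for 4th order, two passes
        amp = np.max(np.abs(out.hbo[0, 300:-300]))
        assert amp < 0.01
        assert amp < 2 * analytic

    def test_cutoff_above_nyquist_rejected(self):
        s = _series(np.zeros(100))
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass(s, FilterSpec(cutoff_hz=1.0))

    def test_too_short_series_rejected(self):
        s = _series(np.zeros(10))
        with pytest.raises(ValueError, match="short"):
            lowpass(s)

    def test_shape_and_labels_preserved(self, rng):
        s = ConcentrationSeries(hbo=rng.normal(size=(16, 300)),
                                hbr=rng.normal(size=(16, 300)),
                                sampling_hz=1.81)
        out = lowpass(s)
        assert out.hbo.shape == s.hbo.shape
        assert out.channel_labels == s.channel_labels


class TestDetrend:
    def test_removes_exact_line(self):
        t = np.arange(200) / 1.81
        s = _series(4.2 - 0.03 * t)
        assert np.allclose(detrend(s).hbo, 0.0, atol=1e-10)

    def test_white_noise_nearly_unchanged(self, rng):
        n = 2000
        x = rng.normal(0, 1, n)
        out = detrend(_series(x)).hbo[0]
        # fitted slope is within 3 SE of zero, so the correction is tiny
        t = np.arange(n)
        removed = x - out
        slope = np.polyfit(t, removed, 1)[0]
        se = np.sqrt(12) / (n ** 1.5)  # SE of OLS slope for unit-variance noise
        assert abs(slope) < 3 * se

    def test_idempotent(self, rng):
        s = _series(rng.normal(0, 1, 500) + np.linspace(0, 5, 500))
        once = detrend(s)
        twice = detrend(once)
        assert np.allclose(twice.hbo, once.hbo, atol=1e-10)

    def test_dct_basis_removes_slow_drift(self):
        fs = 1.81
        t = np.arange(0, 600, 1 / fs)
        drift = np.cos(2 * np.pi * t / 600)  # period inside the DCT basis span
        out = detrend(_series(drift, fs), basis="dct", dct_cutoff_s=128)
        assert np.max(np.abs(out.hbo)) < 0.05 * np.max(np.abs(drift))


class TestBaselineCorrect:
    def test_baseline_mean_removed(self, rng):
        x = rng.normal(5.0, 0.1, 400)
        out = baseline_correct(_series(x), baseline_s=60.0)
        n0 = int(60 * 1.81)
        assert abs(out.hbo[0, :n0].mean()) < 1e-12

    def test_zero_series_unchanged(self):
        out = baseline_correct(_series(np.zeros(300)), baseline_s=60.0)
        assert np.all(out.hbo == 0.0)

    def test_commutes_with_epoch_offset(self, design, rng):
        """Correcting then epoching equals epoching then shifting every epoch
        by the same baseline mean."""
        truth = GroundTruth.constant(1.0)
        series, _ = simulate_session(design, truth, NoiseModel.white_only(0.3), seed=5)
        corrected = baseline_correct(series, design.baseline_s)
        ep_after = epoch(corrected)
        ep_before = epoch(series)
        n0 = int(design.baseline_s * design.sampling_hz)
        offsets = series.hbo[:, :n0].mean(axis=1)
        assert np.allclose(
            ep_after.epochs, ep_before.epochs - offsets[None, :, None], atol=1e-12
        )

    def test_empty_baseline_rejected(self):
        with pytest.raises(ValueError):
            baseline_correct(_series(np.ones(100)), baseline_s=0.1)


class TestEpoch:
    def test_reference_epoching(self, design):
        series, _ = simulate_session(design, GroundTruth.constant(0.0),
                                     NoiseModel.white_only(0.1), seed=0)
        ep = epoch(series)
        assert ep.epochs.shape == (10, 16, 64)
        assert sorted(set(ep.labels)) == ["negative", "positive"]

    def test_empty_schedule_empty_epochs(self):
        d = SessionDesign(trials_per_valence=0)
        series, _ = simulate_session(d, GroundTruth.constant(0.0),
                                     NoiseModel.white_only(0.1), seed=0)
        ep = epoch(series)
        assert ep.n_trials == 0

    def test_start_index_convention(self, design):
        sched = build_schedule(design, seed=0)
        n = design.n_samples
        data = np.zeros((1, n))
        data[0, 108] = 1.0  # floor(60 * 1.81)
        series = ConcentrationSeries(hbo=data, hbr=np.zeros_like(data),
                                     sampling_hz=1.81, schedule=sched,
                                     channel_labels=(1,))
        ep = epoch(series)
        assert ep.epochs[0, 0, 0] == 1.0

    def test_window_exceeding_series_rejected(self, design):
        series, _ = simulate_session(design, GroundTruth.constant(0.0),
                                     NoiseModel.white_only(0.1), seed=0)
        with pytest.raises(ValueError, match="trials"):
            epoch(series, window=(0.0, 80.0))


def test_detrend_baseline_composite_idempotent(design):
    """detrend → baseline-correct is a projection: applying it to its own
    output changes nothing (within 1e-9)."""
    series, _ = simulate_session(design, GroundTruth.constant(1.0), NoiseModel(), seed=8)
    filtered = lowpass(series)

    def chain(s):
        return baseline_correct(detrend(s), design.baseline_s)

    once = chain(filtered)
    twice = chain(once)
    scale = np.max(np.abs(once.hbo))
    assert np.max(np.abs(twice.hbo - once.hbo)) < 1e-9 * max(scale, 1.0)


def test_refiltering_only_touches_transition_band(design):
    """A second low-pass pass only perturbs transition-band content (near
    the 0.15 Hz cutoff, where |H|² < 1): away from the edges the output
    moves by a few percent of the signal scale at most, and the difference
    carries no low-frequency power (exact idempotence is impossible for an
    IIR magnitude response)."""
    from scipy.signal import periodogram

    series, _ = simulate_session(design, GroundTruth.constant(1.0), NoiseModel(), seed=8)
    once = lowpass(series)
    twice = lowpass(once)
    scale = np.max(np.abs(once.hbo))
    diff = (twice.hbo - once.hbo)[:, 50:-50]
    assert np.max(np.abs(diff)) < 0.05 * scale
    freqs, power = periodogram(diff[0], fs=design.sampling_hz)
    low = power[freqs < 0.05].sum()
    assert low < 0.05 * power.sum()


def test_preprocess_session_end_to_end(design):
    series, _ = simulate_session(design, GroundTruth.constant(1.0), NoiseModel(), seed=8)
    ep = preprocess_session(series)
    assert ep.epochs.shape == (10, 16, 64)


def test_transformer_rejects_short_input():
    with pytest.raises(ValueError):
        ButterworthLowPass(order=4, cutoff_hz=0.15, sampling_hz=1.81).transform(
            np.zeros((8, 2))
        )
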