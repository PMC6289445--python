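"""Filtering, detrending, baseline correction and epoching of concentration
series.

The reference chain is: 4th-order Butterworth low-pass at 0.15 Hz (removing
cardiac/respiratory oscillations), linear detrend over the session, mean
subtraction over the initial baseline period, then slicing one epoch per
stimulus event.  Filtering is zero-phase (forward-backward), so the
effective magnitude response is |H|² — exactly −6 dB at the nominal cutoff.

The array-level steps are exposed both as sklearn transformers operating on
``(n_times, n_channels)`` matrices (composable in a ``Pipeline``) and as
functions on :class:`~fnirsvmd.containers.ConcentrationSeries`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import ConcentrationSeries, EpochSet
from .paradigm import StimulusSchedule, onset_to_index, samples_per_epoch

__all__ = [
    "FilterSpec",
    "ButterworthLowPass",
    "LinearDetrend",
    "BaselineCorrect",
    "lowpass",
    "detrend",
    "baseline_correct",
    "epoch",
    "preprocess_session",
]


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass filter parameters (default: 4th order Butterworth, 0.15 Hz)."""

    order: int = 4
    cutoff_hz: float = 0.15
    kind: str = "lowpass"

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff_hz must be > 0")
        if self.kind != "lowpass":
            raise ValueError("only low-pass filtering is supported")


class ButterworthLowPass(BaseEstimator, TransformerMixin):
    """Zero-phase Butterworth low-pass over the time axis of (n_times, n_ch)."""

    def __init__(self, order: int = 4, cutoff_hz: float = 0.15, sampling_hz: float = 1.81):
        self.order = order
        self.cutoff_hz = cutoff_hz
        self.sampling_hz = sampling_hz

    def _sos(self):
        nyq = self.sampling_hz / 2.0
        if self.cutoff_hz >= nyq:
            raise ValueError(
                f"cutoff {self.cutoff_hz} Hz must lie below the Nyquist frequency {nyq} Hz"
            )
        FilterSpec(order=self.order, cutoff_hz=self.cutoff_hz)
        return signal.butter(self.order, self.cutoff_hz, btype="low", fs=self.sampling_hz, output="sos")

    def fit(self, X, y=None):
        self._sos()
        self.n_features_in_ = np.asarray(X).shape[1] if np.asarray(X).ndim == 2 else 1
        return self

    def transform(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] <= 3 * self.order:
            raise ValueError(
                f"series of {X.shape[0]} samples is too short for order {self.order} "
                "zero-phase filtering (need > 3x the filter order)"
            )
        return signal.sosfiltfilt(self._sos(), X, axis=0)


class LinearDetrend(BaseEstimator, TransformerMixin):
    """Remove the per-column least-squares straight line over the session.

    ``basis="dct"`` instead regresses out a discrete-cosine low-frequency
    set (periods longer than ``dct_cutoff_s``), the style of SPM-like
    high-pass drift removal.
    """

    def __init__(self, basis: Literal["linear", "dct"] = "linear",
                 dct_cutoff_s: float = 128.0, sampling_hz: float = 1.81):
        self.basis = basis
        self.dct_cutoff_s = dct_cutoff_s
        self.sampling_hz = sampling_hz

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X).shape[1] if np.asarray(X).ndim == 2 else 1
        return self

    def transform(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n = X.shape[0]
        if n < 2:
            raise ValueError("need at least 2 samples to detrend")
        if self.basis == "linear":
            return signal.detrend(X, axis=0, type="linear")
        if self.basis != "dct":
            raise ValueError(f"unknown basis {self.basis!r}")
        # DCT-II regressors with period > dct_cutoff_s, plus the constant.
        duration = n / self.sampling_hz
        k_max = int(np.floor(2.0 * duration / self.dct_cutoff_s))
        t = np.arange(n)
        cols = [np.ones(n)]
        for k in range(1, max(k_max, 0) + 1):
            cols.append(np.cos(np.pi * k * (2 * t + 1) / (2 * n)))
        B = np.column_stack(cols)
        coef, *_ = np.linalg.lstsq(B, X, rcond=None)
        return X - B @ coef


class BaselineCorrect(BaseEstimator, TransformerMixin):
    """Subtract the per-column mean of the first ``baseline_s`` seconds."""

    def __init__(self, baseline_s: float = 60.0, sampling_hz: float = 1.81):
        self.baseline_s = baseline_s
        self.sampling_hz = sampling_hz

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X).shape[1] if np.asarray(X).ndim == 2 else 1
        return self

    def transform(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n0 = onset_to_index(self.baseline_s, self.sampling_hz)
        if n0 < 1:
            raise ValueError("baseline window contains no samples")
        if n0 > X.shape[0]:
            raise ValueError("baseline_s exceeds the series length")
        return X - X[:n0].mean(axis=0, keepdims=True)


# ---------------------------------------------------------------------------
# ConcentrationSeries-level wrappers
# ---------------------------------------------------------------------------

def _apply(series: ConcentrationSeries, tr) -> ConcentrationSeries:
    # transformers work on (n_times, n_channels); series stores (n_ch, n_t)
    return series.with_data(
        tr.transform(series.hbo.T).T, tr.transform(series.hbr.T).T
    )


def lowpass(series: ConcentrationSeries, spec: FilterSpec = FilterSpec()) -> ConcentrationSeries:
    """Zero-phase Butterworth low-pass of both chromophores."""
    return _apply(
        series,
        ButterworthLowPass(spec.order, spec.cutoff_hz, series.sampling_hz),
    )


def detrend(series: ConcentrationSeries, basis: str = "linear",
            dct_cutoff_s: float = 128.0) -> ConcentrationSeries:
    """Remove per-channel linear (or DCT low-frequency) drift."""
    return _apply(series, LinearDetrend(basis, dct_cutoff_s, series.sampling_hz))


def baseline_correct(series: ConcentrationSeries, baseline_s: float = 60.0) -> ConcentrationSeries:
    """Subtract the per-channel mean of the initial baseline period."""
    return _apply(series, BaselineCorrect(baseline_s, series.sampling_hz))


def epoch(
    series: ConcentrationSeries,
    schedule: StimulusSchedule | None = None,
    window: tuple[float, float] = (0.0, 35.0),
) -> EpochSet:
    """Slice one epoch per stimulus event.

    Epochs span ``[onset + window[0], ...)`` for
    ``samples_per_epoch(window span)`` samples — 64 samples for the default
    35 s window at 1.81 Hz.  Onsets map to indices by the floor convention.
    """
    if schedule is None:
        schedule = series.schedule
    if schedule is None:
        raise ValueError("no schedule attached to the series or given")
    if not schedule.events:
        return EpochSet(
            np.empty((0, series.n_channels, 0)), (), window, series.sampling_hz,
            series.channel_labels,
        )
    n = samples_per_epoch(window[1] - window[0], series.sampling_hz)
    slices, labels, bad = [], [], []
    for ev in schedule.events:
        i0 = onset_to_index(ev.onset_s + window[0], series.sampling_hz)
        if i0 + n > series.n_times:
            bad.append(ev.trial_index)
            continue
        slices.append(series.hbo[:, i0:i0 + n])
        labels.append(ev.valence)
    if bad:
        raise ValueError(f"epoch window exceeds the series end for trials {bad}")
    return EpochSet(
        np.stack(slices), tuple(labels), window, series.sampling_hz, series.channel_labels
    )


def preprocess_session(
    series: ConcentrationSeries,
    spec: FilterSpec = FilterSpec(),
    baseline_s: float | None = None,
    window: tuple[float, float] = (0.0, 35.0),
    detrend_basis: str = "linear",
) -> EpochSet:
    """Full chain: filter → detrend → baseline-correct → epoch."""
    if baseline_s is None:
        baseline_s = series.schedule.design.baseline_s if series.schedule else 60.0
    out = lowpass(series, spec)
    out = detrend(out, basis=detrend_basis)
    out = baseline_correct(out, baseline_s)
    return epoch(out, window=window)
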