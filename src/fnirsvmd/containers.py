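"""In-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .paradigm import SessionDesign, StimulusSchedule, samples_per_epoch

__all__ = ["ConcentrationSeries", "EpochSet"]


@dataclass(frozen=True)
class ConcentrationSeries:
    """Channel × time ΔHbO/ΔHbR concentration changes (µM) of one session."""

    hbo: np.ndarray
    hbr: np.ndarray
    sampling_hz: float
    schedule: StimulusSchedule | None = None
    channel_labels: tuple = ()

    def __post_init__(self) -> None:
        hbo = np.atleast_2d(np.asarray(self.hbo, dtype=float))
        hbr = np.atleast_2d(np.asarray(self.hbr, dtype=float))
        if hbo.shape != hbr.shape:
            raise ValueError("HbO and HbR matrices must share shape")
        object.__setattr__(self, "hbo", hbo)
        object.__setattr__(self, "hbr", hbr)
        if self.sampling_hz <= 0:
            raise ValueError("sampling_hz must be > 0")
        labels = tuple(self.channel_labels) if len(self.channel_labels) else tuple(
            range(1, hbo.shape[0] + 1)
        )
        if len(labels) != hbo.shape[0]:
            raise ValueError("channel_labels length must match the channel axis")
        object.__setattr__(self, "channel_labels", labels)
        if self.schedule is not None:
            expected = samples_per_epoch(self.schedule.session_total_s, self.sampling_hz)
            if hbo.shape[1] != expected:
                raise ValueError(
                    f"time axis has {hbo.shape[1]} samples; schedule implies {expected}"
                )

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[0]

    @property
    def n_times(self) -> int:
        return self.hbo.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_times) / self.sampling_hz

    def with_data(self, hbo: np.ndarray, hbr: np.ndarray) -> "ConcentrationSeries":
        return replace(self, hbo=hbo, hbr=hbr)


@dataclass(frozen=True)
class EpochSet:
    """Trial × channel × time array of epoched responses plus labels.

    ``window`` is (start_s, end_s) relative to stimulus onset; the time axis
    has ``samples_per_epoch(end_s − start_s, sampling_hz)`` samples.
    """

    epochs: np.ndarray
    labels: tuple
    window: tuple[float, float]
    sampling_hz: float
    channel_labels: tuple = ()

    def __post_init__(self) -> None:
        ep = np.asarray(self.epochs, dtype=float)
        if ep.size and ep.ndim != 3:
            raise ValueError("epochs must be (n_trials, n_channels, n_times)")
        if ep.size == 0:
            ep = ep.reshape(0, len(self.channel_labels), 0)
        object.__setattr__(self, "epochs", ep)
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.labels) != ep.shape[0]:
            raise ValueError("labels must align with trials")
        labels = tuple(self.channel_labels) if len(self.channel_labels) else tuple(
            range(1, ep.shape[1] + 1)
        )
        object.__setattr__(self, "channel_labels", labels)
        if ep.size:
            n_expected = samples_per_epoch(self.window[1] - self.window[0], self.sampling_hz)
            if ep.shape[2] != n_expected:
                raise ValueError(
                    f"epoch length {ep.shape[2]} != samples_per_epoch "
                    f"({n_expected}) for window {self.window}"
                )

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_times(self) -> int:
        return self.epochs.shape[2]

    def select(self, valence: str | None) -> "EpochSet":
        """Subset of trials with the given valence label (None → all)."""
        if valence is None:
            return self
        idx = [i for i, v in enumerate(self.labels) if v == valence]
        return EpochSet(
            self.epochs[idx],
            tuple(self.labels[i] for i in idx),
            self.window,
            self.sampling_hz,
            self.channel_labels,
        )

    def channel_subset(self, channels: Sequence) -> "EpochSet":
        pos = [self.channel_labels.index(c) for c in channels]
        return EpochSet(
            self.epochs[:, pos, :], self.labels, self.window, self.sampling_hz,
            tuple(self.channel_labels[p] for p in pos),
        )

    def roi_average(self, channels: Sequence | None = None) -> np.ndarray:
        """Average over (ROI) channels → (n_trials, n_times)."""
        sub = self if channels is None else self.channel_subset(channels)
        return sub.epochs.mean(axis=1)
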