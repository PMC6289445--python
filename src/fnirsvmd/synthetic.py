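"""Ground-truth-labelled synthetic fNIRS recordings.

Forward model per channel: the ΔHbO trace is the sum of (i) the expected
hemodynamic response of every stimulus event scaled by that channel's
activation strength β (µM) for the event's valence, (ii) sinusoidal
physiological oscillations (cardiac, respiratory, Mayer waves) with random
per-channel phases, (iii) a linear drift, and (iv) white Gaussian noise.
ΔHbR is an anti-correlated scaled copy of the HbO activation component plus
its own (scaled) noise, which is all the downstream analysis needs, since
classification uses HbO only.

Default noise amplitudes are calibrated so that β = 1 µM gives single-trial
t-values straddling the activation threshold, making ROI selection
non-trivial by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .activation import session_regressor
from .containers import ConcentrationSeries
from .optics import ExtinctionTable, PathSpec, forward_optical_density
from .paradigm import SessionDesign, StimulusSchedule, build_schedule

__all__ = [
    "GroundTruth",
    "NoiseModel",
    "BetaSampler",
    "SubjectRecording",
    "simulate_session",
    "forward_session_od",
    "make_cohort",
]

DEFAULT_CHANNELS = tuple(range(1, 17))


@dataclass(frozen=True)
class GroundTruth:
    """Activation strength β (µM) per (channel, valence)."""

    beta: dict
    channels: tuple = DEFAULT_CHANNELS

    def __post_init__(self) -> None:
        object.__setattr__(self, "channels", tuple(self.channels))
        valences = {v for (_, v) in self.beta}
        for ch in self.channels:
            for v in valences:
                if (ch, v) not in self.beta:
                    raise ValueError(f"missing beta for channel {ch}, valence {v!r}")

    @classmethod
    def constant(
        cls,
        value: float,
        channels: Sequence = DEFAULT_CHANNELS,
        valences: Sequence[str] = ("positive", "negative"),
    ) -> "GroundTruth":
        return cls(
            beta={(ch, v): float(value) for ch in channels for v in valences},
            channels=tuple(channels),
        )

    @classmethod
    def from_arrays(
        cls,
        values: dict,
        channels: Sequence = DEFAULT_CHANNELS,
    ) -> "GroundTruth":
        """Build from ``{valence: per-channel array}``."""
        beta = {}
        for v, arr in values.items():
            arr = np.asarray(arr, dtype=float)
            if len(arr) != len(channels):
                raise ValueError("per-valence beta array must match channel count")
            for ch, b in zip(channels, arr):
                beta[(ch, v)] = float(b)
        return cls(beta=beta, channels=tuple(channels))

    def array(self, valence: str) -> np.ndarray:
        return np.array([self.beta[(ch, valence)] for ch in self.channels])

    def to_dict(self) -> dict:
        return {
            "channels": list(self.channels),
            "beta": {f"{ch}|{v}": b for (ch, v), b in self.beta.items()},
        }


@dataclass(frozen=True)
class NoiseModel:
    """Physiological + instrumental noise: (frequency Hz, amplitude µM) terms.

    Defaults: cardiac 1.1 Hz / 0.4 µM, respiratory 0.25 Hz / 0.6 µM, Mayer
    waves 0.1 Hz / 0.8 µM, drift 0.005 µM/s, white noise SD 0.8 µM.
    """

    cardiac: tuple[float, float] = (1.1, 0.4)
    respiratory: tuple[float, float] = (0.25, 0.6)
    mayer: tuple[float, float] = (0.1, 0.8)
    drift_slope: float = 0.005
    white_sd: float = 0.8

    def __post_init__(self) -> None:
        for name in ("cardiac", "respiratory", "mayer"):
            f, a = getattr(self, name)
            if f <= 0:
                raise ValueError(f"{name} frequency must be > 0")
            if a < 0:
                raise ValueError(f"{name} amplitude must be >= 0")
        if self.white_sd < 0:
            raise ValueError("white_sd must be >= 0")

    @classmethod
    def silent(cls) -> "NoiseModel":
        """All noise terms zero (deterministic forward model)."""
        return cls(cardiac=(1.1, 0.0), respiratory=(0.25, 0.0), mayer=(0.1, 0.0),
                   drift_slope=0.0, white_sd=0.0)

    @classmethod
    def white_only(cls, sd: float = 0.8) -> "NoiseModel":
        """I.i.d. Gaussian noise only (the calibration null)."""
        return cls(cardiac=(1.1, 0.0), respiratory=(0.25, 0.0), mayer=(0.1, 0.0),
                   drift_slope=0.0, white_sd=sd)

    def sinusoids(self) -> tuple[tuple[float, float], ...]:
        return (self.cardiac, self.respiratory, self.mayer)


def _noise_matrix(noise: NoiseModel, n_ch: int, times: np.ndarray,
                  rng: np.random.Generator, scale: float = 1.0) -> np.ndarray:
    out = np.zeros((n_ch, len(times)))
    for f, a in noise.sinusoids():
        if a == 0:
            continue
        phases = rng.uniform(0.0, 2.0 * np.pi, size=n_ch)
        out += scale * a * np.sin(2.0 * np.pi * f * times[None, :] + phases[:, None])
    out += scale * noise.drift_slope * times[None, :]
    if noise.white_sd > 0:
        out += rng.normal(0.0, scale * noise.white_sd, size=out.shape)
    return out


def simulate_session(
    design: SessionDesign,
    truth: GroundTruth,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    hbr_ratio: float = 0.3,
    schedule: StimulusSchedule | None = None,
) -> tuple[ConcentrationSeries, GroundTruth]:
    """Simulate one session's ΔHbO/ΔHbR recording with known activation.

    The valence order is drawn from ``seed`` (unless an explicit
    ``schedule`` is supplied), as are noise phases and white noise, so the
    output is a deterministic function of its arguments.
    """
    truth_valences = {v for (_, v) in truth.beta}
    if not set(design.valences) <= truth_valences:
        raise ValueError(
            f"ground truth lacks valences {set(design.valences) - truth_valences}"
        )
    rng = np.random.default_rng(seed)
    if schedule is None:
        schedule = build_schedule(design, seed=int(rng.integers(2**31)))
    n_ch = len(truth.channels)
    times = np.arange(design.n_samples) / design.sampling_hz

    act = np.zeros((n_ch, design.n_samples))
    for v in design.valences:
        reg = session_regressor(schedule, valence=v)
        act += truth.array(v)[:, None] * reg[None, :]

    hbo = act + _noise_matrix(noise, n_ch, times, rng)
    hbr = -hbr_ratio * act + _noise_matrix(noise, n_ch, times, rng, scale=hbr_ratio)
    series = ConcentrationSeries(
        hbo=hbo, hbr=hbr, sampling_hz=design.sampling_hz,
        schedule=schedule, channel_labels=truth.channels,
    )
    return series, truth


def forward_session_od(
    series: ConcentrationSeries,
    extinction: ExtinctionTable | None = None,
    path: PathSpec | None = None,
) -> np.ndarray:
    """Two-wavelength ΔA series of a simulated session, (n_ch, n_t, 2)."""
    conc = np.stack([series.hbo, series.hbr], axis=-1)
    return forward_optical_density(conc, extinction, path)


@dataclass(frozen=True)
class BetaSampler:
    """Per-subject β distribution: independent normals per (channel, valence).

    ``mean``/``sd`` map valence → µM.  ``active_channels`` restricts nonzero
    β to a subset (others get β = 0, i.e. inactive).
    """

    mean: dict = field(default_factory=lambda: {"positive": 1.0, "negative": 1.0})
    sd: dict = field(default_factory=lambda: {"positive": 0.2, "negative": 0.2})
    active_channels: tuple | None = None

    def sample(self, rng: np.random.Generator, channels: Sequence) -> GroundTruth:
        beta = {}
        active = set(self.active_channels) if self.active_channels is not None else set(channels)
        for ch in channels:
            for v, m in self.mean.items():
                b = rng.normal(m, self.sd.get(v, 0.0)) if ch in active else 0.0
                beta[(ch, v)] = float(b)
        return GroundTruth(beta=beta, channels=tuple(channels))

    @classmethod
    def point_mass(cls, values: dict) -> "BetaSampler":
        return cls(mean=dict(values), sd={v: 0.0 for v in values})


@dataclass(frozen=True)
class SubjectRecording:
    """All sessions of one simulated subject."""

    subject: int
    sessions: tuple  # of (SessionDesign, ConcentrationSeries, GroundTruth)

    def session(self, category: str):
        for d, s, t in self.sessions:
            if d.category == category:
                return d, s, t
        raise KeyError(category)


def make_cohort(
    n_subjects: int,
    designs: Sequence[SessionDesign],
    truth_sampler: BetaSampler | Callable[[np.random.Generator, Sequence], GroundTruth],
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    channels: Sequence = DEFAULT_CHANNELS,
    hbr_ratio: float = 0.3,
) -> list[SubjectRecording]:
    """Simulate a cohort: per subject, one session per design.

    β is redrawn from the sampler per subject per session; session seeds are
    derived from the master seed, so two cohorts with the same arguments are
    identical.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if len(designs) == 0:
        raise ValueError("need at least one session design")
    master = np.random.default_rng(seed)
    sample = truth_sampler.sample if isinstance(truth_sampler, BetaSampler) else truth_sampler
    cohort = []
    for subj in range(1, n_subjects + 1):
        sessions = []
        for design in designs:
            truth = sample(master, channels)
            sess_seed = int(master.integers(2**31))
            series, truth = simulate_session(
                design, truth, noise, seed=sess_seed, hbr_ratio=hbr_ratio
            )
            sessions.append((design, series, truth))
        cohort.append(SubjectRecording(subject=subj, sessions=tuple(sessions)))
    return cohort
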