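"""Block-design experimental paradigm: session timing, stimulus schedules.

A session is a baseline period followed by back-to-back trials, each a
stimulus picture followed by rest.  Four sessions (one per store category)
make up one recording.  All downstream epoching derives its sample counts
from the conventions fixed here: durations are discretized with a ceiling,
onsets with a floor, and epoch windows are half-open ``[start, start + N)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SessionDesign",
    "StimulusEvent",
    "StimulusSchedule",
    "build_schedule",
    "total_experiment_duration",
    "samples_per_epoch",
    "onset_to_index",
    "DEFAULT_CATEGORIES",
]

#: The four store categories of the reference block design.
DEFAULT_CATEGORIES = ("menswear", "womenswear", "underwear", "sportswear")

# Guard against float fuzz when discretizing durations/onsets (1 ns at 1 Hz).
_EPS = 1e-9


@dataclass(frozen=True)
class SessionDesign:
    """Timing and composition of one category's session.

    Defaults encode the reference design: 60 s baseline, then 10 trials of
    15 s stimulus + 30 s rest (5 positive + 5 negative pictures in random
    order), sampled at 1.81 Hz — 510 s per session, 2040 s over 4 sessions.
    """

    category: str = "menswear"
    baseline_s: float = 60.0
    stimulus_s: float = 15.0
    rest_s: float = 30.0
    trials_per_valence: int = 5
    valences: tuple[str, ...] = ("positive", "negative")
    sampling_hz: float = 1.81

    def __post_init__(self) -> None:
        for name in ("baseline_s", "stimulus_s", "rest_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.trials_per_valence < 0:
            raise ValueError("trials_per_valence must be >= 0")
        if self.sampling_hz <= 0:
            raise ValueError("sampling_hz must be > 0")
        if len(set(self.valences)) != len(self.valences):
            raise ValueError("valences must be distinct labels")
        object.__setattr__(self, "valences", tuple(self.valences))

    @property
    def n_trials(self) -> int:
        return self.trials_per_valence * len(self.valences)

    @property
    def trial_s(self) -> float:
        return self.stimulus_s + self.rest_s

    @property
    def task_s(self) -> float:
        return self.n_trials * self.trial_s

    @property
    def session_total_s(self) -> float:
        return self.baseline_s + self.task_s

    @property
    def n_samples(self) -> int:
        """Number of samples in one recorded session (ceiling convention)."""
        return samples_per_epoch(self.session_total_s, self.sampling_hz)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SessionDesign":
        d = dict(d)
        if "valences" in d:
            d["valences"] = tuple(d["valences"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        d = self.to_dict()
        d["valences"] = list(d["valences"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SessionDesign":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class StimulusEvent:
    onset_s: float
    duration_s: float
    valence: str
    trial_index: int


@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered, non-overlapping stimulus events of one session."""

    events: tuple[StimulusEvent, ...]
    session_total_s: float
    seed: int
    design: SessionDesign = field(compare=False)

    def __post_init__(self) -> None:
        onsets = [e.onset_s for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def valence_labels(self) -> list[str]:
        return [e.valence for e in self.events]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.onset_s, e.duration_s, e.valence, e.trial_index) for e in self.events],
            columns=["onset_s", "duration_s", "valence", "trial_index"],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self) -> str:
        return json.dumps(
            {
                "session_total_s": self.session_total_s,
                "seed": self.seed,
                "events": [asdict(e) for e in self.events],
            }
        )


def build_schedule(design: SessionDesign, seed: int) -> StimulusSchedule:
    """Lay out one session: baseline, then trials in seeded random valence order.

    Each valence appears exactly ``design.trials_per_valence`` times; the
    order is a uniform random permutation of that multiset (the reference
    design states only "random order", so runs of equal valence are allowed).
    """
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.asarray(design.valences, dtype=object), design.trials_per_valence)
    order = rng.permutation(len(labels))
    events = tuple(
        StimulusEvent(
            onset_s=design.baseline_s + i * design.trial_s,
            duration_s=design.stimulus_s,
            valence=str(labels[order[i]]),
            trial_index=i,
        )
        for i in range(design.n_trials)
    )
    return StimulusSchedule(
        events=events, session_total_s=design.session_total_s, seed=int(seed), design=design
    )


def total_experiment_duration(designs: Sequence[SessionDesign]) -> float:
    """Total duration in seconds of a multi-session experiment."""
    if len(designs) == 0:
        raise ValueError("need at least one session design")
    return float(sum(d.session_total_s for d in designs))


def samples_per_epoch(duration_s: float, sampling_hz: float) -> int:
    """Number of samples covering ``duration_s`` at ``sampling_hz`` (ceiling).

    The ceiling convention reproduces the reference epoch length: a 35 s
    epoch (15 s stimulus + 20 s of the rest period) at 1.81 Hz spans
    63.35 sample intervals and is stored as N = 64 samples.
    """
    if duration_s <= 0 or sampling_hz <= 0:
        raise ValueError("duration_s and sampling_hz must be > 0")
    return int(math.ceil(duration_s * sampling_hz - _EPS))


def onset_to_index(onset_s: float, sampling_hz: float) -> int:
    """0-based sample index of an onset: ``floor(onset × fs)``."""
    if onset_s < 0 or sampling_hz <= 0:
        raise ValueError("onset_s must be >= 0 and sampling_hz > 0")
    return int(math.floor(onset_s * sampling_hz + _EPS))
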