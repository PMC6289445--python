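"""End-to-end cohort analysis: preprocessing → t-maps → features → LDA.

Glues the pipeline stages together the way the reference analysis runs
them, per subject and store category:

1. filter / detrend / baseline-correct the session and epoch it (35 s);
2. fit the robust GLM per channel and valence, threshold at t_crt to get
   the ROI (falling back to the single highest-t channel when no channel
   passes, so feature extraction stays defined);
3. average HbO over the ROI, compute the seven 20-s features per trial and
   min-max rescale them within the classification problem;
4. cross-validate LDA over all 21 feature pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .activation import (
    ActivationMap,
    build_expected_response,
    fit_condition,
    select_roi,
)
from .classify import AccuracyGrid, cohort_pair_search
from .containers import EpochSet
from .features import FeatureTable, extract_feature_table
from .preprocess import FilterSpec, preprocess_session
from .synthetic import SubjectRecording

__all__ = [
    "SessionAnalysis",
    "analyze_session",
    "two_class_tables",
    "four_class_tables",
    "run_two_class",
    "run_four_class",
]


@dataclass(frozen=True)
class SessionAnalysis:
    """Per-session intermediate products of the pipeline."""

    category: str
    epochs: EpochSet
    maps: dict            # valence -> ActivationMap
    rois: dict            # valence -> tuple of channels (after fallback)


def _roi_with_fallback(amap: ActivationMap) -> tuple:
    roi = select_roi(amap)
    if not roi:
        # no channel passed threshold: use the single best channel so the
        # ROI-averaged signal (and hence features) remains defined
        roi = [amap.channels[int(np.argmax(amap.t_values))]]
    return tuple(roi)


def analyze_session(
    design,
    series,
    window: tuple[float, float] = (0.0, 35.0),
    mode: Literal["per-trial", "averaged"] = "per-trial",
    spec: FilterSpec = FilterSpec(),
) -> SessionAnalysis:
    """Preprocess one session and map activation per valence."""
    epochs = preprocess_session(series, spec=spec, window=window)
    xr = build_expected_response(design.stimulus_s, design.sampling_hz, window)
    maps, rois = {}, {}
    for valence in design.valences:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            # occasional per-trial IRLS non-convergence on pure-noise epochs
            warnings.simplefilter("ignore", RuntimeWarning)
            amap = fit_condition(epochs, valence, xr, mode=mode)
            maps[valence] = amap
            rois[valence] = _roi_with_fallback(amap)
    return SessionAnalysis(category=design.category, epochs=epochs, maps=maps, rois=rois)


def _session_xr(design, window=(0.0, 35.0)):
    return build_expected_response(design.stimulus_s, design.sampling_hz, window)


def two_class_tables(
    cohort: Sequence[SubjectRecording],
    category: str,
    window_s: float = 20.0,
    mode: Literal["per-trial", "averaged"] = "per-trial",
) -> list[FeatureTable]:
    """Per-subject rescaled feature tables for positive-vs-negative of one store.

    The ROI is the union of the positive and negative ROIs of that subject's
    session; labels are the trial valences.
    """
    tables = []
    for rec in cohort:
        design, series, _ = rec.session(category)
        ana = analyze_session(design, series)
        roi = tuple(sorted(set().union(*ana.rois.values()), key=str))
        xr = _session_xr(design)
        table = extract_feature_table(ana.epochs, roi, xr, window_s=window_s)
        tables.append(table.rescale())
    return tables


def four_class_tables(
    cohort: Sequence[SubjectRecording],
    valence: str,
    window_s: float = 20.0,
    mode: Literal["per-trial", "averaged"] = "per-trial",
) -> list[FeatureTable]:
    """Per-subject rescaled tables for the four-store problem at one valence.

    Rows are the ``trials_per_valence`` trials of the given valence from each
    of the subject's sessions, labelled by store category; each session
    contributes its own (per-category) ROI.
    """
    tables = []
    for rec in cohort:
        per_session = []
        for design, series, _ in rec.sessions:
            ana = analyze_session(design, series)
            roi = ana.rois[valence]
            xr = _session_xr(design)
            sub = ana.epochs.select(valence)
            per_session.append(
                extract_feature_table(
                    sub, roi, xr, window_s=window_s,
                    labels=[design.category] * sub.n_trials,
                )
            )
        merged = per_session[0]
        for t in per_session[1:]:
            merged = merged.concat(t)
        tables.append(merged.rescale())
    return tables


def run_two_class(
    cohort: Sequence[SubjectRecording],
    category: str,
    scheme="loo",
) -> AccuracyGrid:
    """Cohort two-class accuracy grid (all 21 feature pairs) for one store."""
    return cohort_pair_search(two_class_tables(cohort, category), "two-class", scheme)


def run_four_class(
    cohort: Sequence[SubjectRecording],
    valence: str,
    scheme="loo",
) -> AccuracyGrid:
    """Cohort four-class accuracy grid for one display valence."""
    return cohort_pair_search(four_class_tables(cohort, valence), "four-class", scheme)
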