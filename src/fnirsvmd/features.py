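"""Windowed statistical features of the ROI-averaged HbO response.

Seven features are computed on the first 20 s of each epoch (37 samples at
1.81 Hz), starting at stimulus onset: mean, peak (max), unbiased variance,
skewness (third standardized moment), kurtosis (fourth standardized moment,
Pearson convention — normal → 3), the robust-GLM t-value of the expected
response restricted to the window, and the least-squares slope versus time
in seconds.  Before classification each feature column is min-max rescaled
onto [0, 1] across all samples of one classification problem:
z' = (z − min z) / (max z − min z).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .activation import ExpectedResponse, robust_fit
from .containers import EpochSet
from .paradigm import samples_per_epoch

__all__ = [
    "FEATURE_NAMES",
    "FeatureTable",
    "compute_features",
    "WindowFeatureExtractor",
    "minmax_rescale",
    "enumerate_feature_pairs",
    "extract_feature_table",
]

FEATURE_NAMES = ("mean", "peak", "variance", "skewness", "kurtosis", "t_value", "slope")


def compute_features(
    signal: np.ndarray,
    sampling_hz: float,
    xr: ExpectedResponse,
    window_s: float = 20.0,
    kurtosis_convention: str = "pearson",
) -> np.ndarray:
    """Seven-feature vector of one (ROI-averaged) epoch signal.

    ``signal`` starts at stimulus onset; only the first ``window_s`` seconds
    enter the computation.  Constant input yields zero variance, skewness
    and kurtosis by convention, but the t-value is inestimable there and the
    underlying division-by-zero error is propagated (a constant epoch
    indicates an upstream fault).
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    n = samples_per_epoch(window_s, sampling_hz)
    if n > len(signal):
        raise ValueError(
            f"window of {window_s} s ({n} samples) exceeds the epoch ({len(signal)} samples)"
        )
    if n < 3:
        raise ValueError("window must contain at least 3 samples")
    y = signal[:n]
    t = np.arange(n) / sampling_hz

    mean = float(y.mean())
    peak = float(y.max())
    variance = float(y.var(ddof=1))
    if np.ptp(y) == 0:
        # a constant epoch indicates an upstream fault: the t-value feature
        # is inestimable (zero residual scale), so the error propagates
        raise ValueError("constant epoch signal: t-value feature is inestimable")
    if variance == 0.0:
        skew = 0.0
        kurt = 0.0
    else:
        skew = float(stats.skew(y, bias=True))
        kurt = float(stats.kurtosis(y, fisher=(kurtosis_convention == "excess"), bias=True))
    res = robust_fit(xr.restrict(window_s), y)
    slope = float(np.polyfit(t, y, 1)[0])
    return np.array([mean, peak, variance, skew, kurt, res.t, slope])


class WindowFeatureExtractor(BaseEstimator, TransformerMixin):
    """Transformer: (n_trials, n_times) epoch matrix → (n_trials, 7) features."""

    def __init__(self, xr: ExpectedResponse = None, sampling_hz: float = 1.81,
                 window_s: float = 20.0, kurtosis_convention: str = "pearson"):
        self.xr = xr
        self.sampling_hz = sampling_hz
        self.window_s = window_s
        self.kurtosis_convention = kurtosis_convention

    def fit(self, X, y=None):
        if self.xr is None:
            raise ValueError("an ExpectedResponse (xr) is required")
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.vstack([
            compute_features(row, self.sampling_hz, self.xr, self.window_s,
                             self.kurtosis_convention)
            for row in X
        ])

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)


def minmax_rescale(column: np.ndarray) -> np.ndarray:
    """Affine map of one feature column onto [0, 1].

    A constant column has no spread to normalize; it is mapped to all zeros
    with a warning.
    """
    column = np.asarray(column, dtype=float)
    if column.size < 1:
        raise ValueError("need at least one value")
    lo, hi = column.min(), column.max()
    if hi == lo:
        warnings.warn("constant feature column rescaled to zeros", UserWarning)
        return np.zeros_like(column)
    return (column - lo) / (hi - lo)


def enumerate_feature_pairs(k: int = 7) -> list[tuple[int, int]]:
    """All unordered index pairs in lexicographic order — 21 for 7 features."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return list(itertools.combinations(range(k), 2))


@dataclass(frozen=True)
class FeatureTable:
    """Trial × feature matrix with class labels for one classification problem."""

    data: pd.DataFrame  # columns: FEATURE_NAMES
    labels: tuple
    window: tuple[float, float] = (0.0, 20.0)
    rescaled: bool = False
    roi_channels: tuple = ()

    def __post_init__(self) -> None:
        if tuple(self.data.columns) != FEATURE_NAMES:
            raise ValueError(f"feature columns must be {FEATURE_NAMES}")
        if len(self.labels) != len(self.data):
            raise ValueError("labels must align with rows")
        object.__setattr__(self, "labels", tuple(self.labels))
        if self.rescaled:
            vals = self.data.to_numpy()
            if vals.size and (vals.min() < -1e-12 or vals.max() > 1 + 1e-12):
                raise ValueError("rescaled table has values outside [0, 1]")

    @property
    def X(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def y(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=object)

    def rescale(self) -> "FeatureTable":
        """Min-max rescale every feature column across the table's rows."""
        if self.rescaled:
            return self
        out = self.data.copy()
        for col in out.columns:
            out[col] = minmax_rescale(out[col].to_numpy())
        return replace(self, data=out, rescaled=True)

    def pair(self, i: int, j: int) -> np.ndarray:
        return self.data.iloc[:, [i, j]].to_numpy()

    def concat(self, other: "FeatureTable") -> "FeatureTable":
        if self.rescaled != other.rescaled:
            raise ValueError("cannot concatenate rescaled with raw tables")
        return FeatureTable(
            data=pd.concat([self.data, other.data], ignore_index=True),
            labels=self.labels + other.labels,
            window=self.window,
            rescaled=self.rescaled,
            roi_channels=tuple(set(self.roi_channels) | set(other.roi_channels)),
        )

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "label", list(self.labels))
        out.to_csv(path, index=False)


def extract_feature_table(
    epochs: EpochSet,
    roi_channels,
    xr: ExpectedResponse,
    window_s: float = 20.0,
    labels=None,
) -> FeatureTable:
    """Feature table of the ROI-averaged HbO signal, one row per trial.

    ``labels`` defaults to the epoch valence labels (two-class problems);
    pass category labels for the four-class problem.
    """
    roi_channels = tuple(roi_channels)
    if not roi_channels:
        raise ValueError("ROI is empty; pass at least one channel")
    avg = epochs.roi_average(roi_channels)
    ext = WindowFeatureExtractor(xr=xr, sampling_hz=epochs.sampling_hz, window_s=window_s)
    mat = ext.fit(avg).transform(avg)
    return FeatureTable(
        data=pd.DataFrame(mat, columns=list(FEATURE_NAMES)),
        labels=tuple(labels) if labels is not None else epochs.labels,
        window=(0.0, window_s),
        rescaled=False,
        roi_channels=roi_channels,
    )
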