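"""Linear discriminant classification of feature pairs.

Two problems are supported: two-class (positive vs negative displays of one
store category) and four-class (the four store categories at one valence).
For each of the 21 unordered feature pairs, accuracy is estimated by
cross-validation (leave-one-out by default, stratified k-fold optionally)
and aggregated over subjects as mean ± SD; the best pair attains the
highest aggregate mean.

The discriminant is the classical pooled-covariance LDA: class k scores
``δ_k(x) = xᵀΣ⁻¹μ_k − ½μ_kᵀΣ⁻¹μ_k + log π_k`` with Σ the pooled
within-class covariance.  A trace-scaled ridge is added when Σ is singular,
and prediction ties break deterministically toward the first label in sort
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .features import FEATURE_NAMES, FeatureTable, enumerate_feature_pairs

__all__ = [
    "DiscriminantModel",
    "LinearDiscriminant",
    "lda_fit",
    "lda_predict",
    "cross_validate",
    "AccuracyGrid",
    "pair_search",
    "cohort_pair_search",
]

_RIDGE = 1e-6


@dataclass(frozen=True)
class DiscriminantModel:
    """Fitted LDA parameters: class means, pooled covariance, priors."""

    classes: tuple
    means: np.ndarray          # (k, p)
    covariance: np.ndarray     # (p, p) pooled within-class
    priors: np.ndarray         # (k,)
    coef: np.ndarray = field(repr=False)       # (k, p) Σ⁻¹ μ_k
    intercept: np.ndarray = field(repr=False)  # (k,)

    def __post_init__(self) -> None:
        if not np.allclose(self.covariance, self.covariance.T):
            raise ValueError("pooled covariance must be symmetric")
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("priors must sum to 1")


class LinearDiscriminant(BaseEstimator, ClassifierMixin):
    """Pooled-covariance linear discriminant classifier.

    Parameters
    ----------
    priors : "empirical" (class frequencies), "uniform", or an explicit
        mapping/sequence.  Balanced designs make empirical and uniform
        coincide; under leave-one-out splitting they differ (see the
        methods note).
    """

    def __init__(self, priors: str | Sequence | dict = "empirical"):
        self.priors = priors

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be (n_samples, n_features)")
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("need at least 2 classes")
        if counts.min() < 2:
            small = classes[counts < 2]
            raise ValueError(f"every class needs >= 2 samples; too few in {list(small)}")
        if np.ptp(X, axis=0).max() == 0:
            raise ValueError("all samples are identical; nothing to discriminate")
        n, p = X.shape
        k = len(classes)

        means = np.vstack([X[y == c].mean(axis=0) for c in classes])
        pooled = np.zeros((p, p))
        for c, mu in zip(classes, means):
            d = X[y == c] - mu
            pooled += d.T @ d
        pooled /= n - k

        if self.priors == "empirical":
            priors = counts / n
        elif self.priors == "uniform":
            priors = np.full(k, 1.0 / k)
        elif isinstance(self.priors, dict):
            priors = np.array([self.priors[c] for c in classes], dtype=float)
        else:
            priors = np.asarray(self.priors, dtype=float)
        priors = priors / priors.sum()

        cov = pooled
        if np.linalg.matrix_rank(cov) < p or np.linalg.cond(cov) > 1e12:
            cov = cov + _RIDGE * (np.trace(cov) / p if np.trace(cov) > 0 else 1.0) * np.eye(p)
        coef = np.linalg.solve(cov, means.T).T          # (k, p)
        intercept = -0.5 * np.einsum("kp,kp->k", means, coef) + np.log(priors)

        self.model_ = DiscriminantModel(
            classes=tuple(classes), means=means, covariance=cov,
            priors=priors, coef=coef, intercept=intercept,
        )
        self.classes_ = classes
        self.n_features_in_ = p
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X must have {self.n_features_in_} features, got shape {X.shape}"
            )
        return X @ self.model_.coef.T + self.model_.intercept

    def predict(self, X) -> np.ndarray:
        # np.argmax takes the first maximum: ties resolve to the first
        # label in sort order (classes_ is sorted by np.unique).
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]


def lda_fit(X, y, priors: str | Sequence | dict = "empirical") -> DiscriminantModel:
    """Fit pooled-covariance LDA and return the parameter bundle."""
    return LinearDiscriminant(priors=priors).fit(X, y).model_


def lda_predict(model: DiscriminantModel, X) -> np.ndarray:
    """Predict labels from a fitted :class:`DiscriminantModel`."""
    clf = LinearDiscriminant()
    clf.model_ = model
    clf.classes_ = np.asarray(model.classes)
    clf.n_features_in_ = model.means.shape[1]
    return clf.predict(np.asarray(X, dtype=float))


def cross_validate(
    X,
    y,
    scheme: str | tuple = "loo",
    priors: str | Sequence | dict = "uniform",
) -> float:
    """Cross-validated accuracy in percent.

    ``scheme`` is ``"loo"`` (leave-one-out) or ``("kfold", k, seed)`` for
    seeded stratified k-fold.  Priors default to "uniform": the block
    design is balanced, and re-estimating priors inside leave-one-out folds
    would bias accuracy through fold-induced class imbalance.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if scheme == "loo":
        splitter = LeaveOneOut()
    elif isinstance(scheme, tuple) and scheme[0] == "kfold":
        k = int(scheme[1])
        seed = int(scheme[2]) if len(scheme) > 2 else 0
        _, counts = np.unique(y, return_counts=True)
        if k > counts.min():
            raise ValueError(
                f"stratified {k}-fold needs >= {k} samples per class (smallest class "
                f"has {counts.min()}); lower k or use scheme='loo'"
            )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    correct = total = 0
    for train, test in splitter.split(X, y):
        clf = LinearDiscriminant(priors=priors).fit(X[train], y[train])
        correct += int((clf.predict(X[test]) == y[test]).sum())
        total += len(test)
    return 100.0 * correct / total


@dataclass(frozen=True)
class AccuracyGrid:
    """Accuracy per feature pair (and per subject), plus aggregates."""

    grid: pd.DataFrame          # index: pair name, columns: subjects or problem
    mean: pd.Series             # aggregate mean per pair (%)
    sd: pd.Series               # aggregate SD per pair (%)
    best_pair: tuple[str, str]
    best_accuracy: float
    problem: str
    scheme: str | tuple

    def __post_init__(self) -> None:
        vals = self.grid.to_numpy(dtype=float)
        if vals.size and (vals.min() < 0 or vals.max() > 100):
            raise ValueError("accuracies must lie in [0, 100]%")

    def best_row(self) -> pd.Series:
        return self.grid.loc["-".join(self.best_pair)]

    def to_frame(self) -> pd.DataFrame:
        out = self.grid.copy()
        out["mean"] = self.mean
        out["sd"] = self.sd
        return out


def _pair_name(i: int, j: int) -> str:
    return f"{FEATURE_NAMES[i]}-{FEATURE_NAMES[j]}"


def pair_search(
    table: FeatureTable,
    problem: Literal["two-class", "four-class"] = "two-class",
    scheme: str | tuple = "loo",
    priors: str | Sequence | dict = "uniform",
) -> AccuracyGrid:
    """Evaluate all 21 feature pairs on one subject's feature table."""
    if not table.rescaled:
        raise ValueError("pair_search expects a rescaled FeatureTable")
    pairs = enumerate_feature_pairs(len(FEATURE_NAMES))
    accs = {
        _pair_name(i, j): cross_validate(table.pair(i, j), table.y, scheme, priors)
        for i, j in pairs
    }
    grid = pd.DataFrame({"accuracy": accs})
    mean = grid["accuracy"]
    best_idx = int(np.argmax(mean.to_numpy()))
    i, j = pairs[best_idx]
    return AccuracyGrid(
        grid=grid, mean=mean, sd=pd.Series(0.0, index=grid.index),
        best_pair=(FEATURE_NAMES[i], FEATURE_NAMES[j]),
        best_accuracy=float(mean.iloc[best_idx]),
        problem=problem, scheme=scheme,
    )


def cohort_pair_search(
    tables: Sequence[FeatureTable],
    problem: Literal["two-class", "four-class"] = "two-class",
    scheme: str | tuple = "loo",
    priors: str | Sequence | dict = "uniform",
) -> AccuracyGrid:
    """Subject-wise grid over all pairs, aggregated as mean ± SD per pair.

    One :class:`FeatureTable` per subject (already rescaled within subject).
    The best pair maximizes the across-subject mean accuracy.
    """
    if len(tables) == 0:
        raise ValueError("need at least one subject table")
    pairs = enumerate_feature_pairs(len(FEATURE_NAMES))
    cols = {}
    for s, table in enumerate(tables, start=1):
        if not table.rescaled:
            raise ValueError("cohort_pair_search expects rescaled FeatureTables")
        cols[f"sub{s:02d}"] = [
            cross_validate(table.pair(i, j), table.y, scheme, priors) for i, j in pairs
        ]
    grid = pd.DataFrame(cols, index=[_pair_name(i, j) for i, j in pairs])
    mean = grid.mean(axis=1)
    sd = grid.std(axis=1, ddof=1) if grid.shape[1] > 1 else pd.Series(0.0, index=grid.index)
    best_idx = int(np.argmax(mean.to_numpy()))
    i, j = pairs[best_idx]
    return AccuracyGrid(
        grid=grid, mean=mean, sd=sd,
        best_pair=(FEATURE_NAMES[i], FEATURE_NAMES[j]),
        best_accuracy=float(mean.iloc[best_idx]),
        problem=problem, scheme=scheme,
    )
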