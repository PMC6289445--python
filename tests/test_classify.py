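"""LDA classifier, cross-validation and feature-pair search."""

import numpy as np
import pandas as pd
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from fnirsvmd import (
    FEATURE_NAMES,
    FeatureTable,
    LinearDiscriminant,
    cohort_pair_search,
    cross_validate,
    lda_fit,
    lda_predict,
    pair_search,
)


def _blobs(rng, centers, n=20, spread=0.3):
    X, y = [], []
    for label, c in centers.items():
        X.append(rng.normal(0, spread, (n, len(c))) + np.asarray(c))
        y += [label] * n
    return np.vstack(X), np.array(y)


class TestLinearDiscriminant:
    def test_separable_two_class(self, rng):
        X, y = _blobs(rng, {"a": (0, 0), "b": (10, 10)})
        clf = LinearDiscriminant().fit(X, y)
        assert (clf.predict(X) == y).all()
        # decision boundary crosses near the midpoint (5, 5)
        lo = clf.predict(np.array([[4.0, 4.0]]))[0]
        hi = clf.predict(np.array([[6.0, 6.0]]))[0]
        assert (lo, hi) == ("a", "b")

    def test_chance_on_identical_distributions(self, rng):
        Xtr = rng.normal(0, 1, (100, 2))
        ytr = np.array(["a", "b"] * 50)
        clf = LinearDiscriminant(priors="uniform").fit(Xtr, ytr)
        Xte = rng.normal(0, 1, (1000, 2))
        yte = np.array(["a", "b"] * 500)
        acc = (clf.predict(Xte) == yte).mean()
        assert abs(acc - 0.5) < 1.96 * np.sqrt(0.25 / 1000) + 0.02

    def test_four_separated_corners(self, rng):
        X, y = _blobs(rng, {"a": (0, 0), "b": (0, 20), "c": (20, 0), "d": (20, 20)})
        clf = LinearDiscriminant().fit(X, y)
        assert (clf.predict(X) == y).mean() == 1.0

    def test_tie_breaks_to_first_sorted_label(self):
        X = np.array([[-1.0, 0.0], [-1.1, 0.1], [1.0, 0.0], [1.1, -0.1]])
        y = np.array(["b", "b", "a", "a"])
        clf = LinearDiscriminant(priors="uniform").fit(X, y)
        # the origin is equidistant from both class means with equal priors
        assert clf.predict(np.array([[0.0, 0.0]]))[0] == "a"

    def test_small_class_rejected(self, rng):
        X = rng.normal(0, 1, (3, 2))
        with pytest.raises(ValueError, match=">= 2 samples"):
            LinearDiscriminant().fit(X, np.array(["a", "a", "b"]))

    def test_identical_samples_rejected(self):
        X = np.ones((6, 2))
        with pytest.raises(ValueError, match="identical"):
            LinearDiscriminant().fit(X, np.array(["a"] * 3 + ["b"] * 3))

    def test_singular_covariance_regularized(self):
        # second feature is a copy of the first: pooled covariance singular
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 20)
        X = np.column_stack([x, x])
        y = np.array(["a"] * 10 + ["b"] * 10)
        X[10:] += 3.0
        clf = LinearDiscriminant().fit(X, y)  # must not raise
        assert (clf.predict(X) == y).mean() > 0.9

    def test_matches_sklearn_predictions(self, rng):
        X, y = _blobs(rng, {"a": (0, 0), "b": (1.5, 1.0)}, n=40, spread=1.0)
        mine = LinearDiscriminant(priors="empirical").fit(X, y).predict(X)
        ref = LinearDiscriminantAnalysis().fit(X, y).predict(X)
        assert (mine == ref).all()

    def test_dimension_mismatch_rejected(self, rng):
        X, y = _blobs(rng, {"a": (0, 0), "b": (5, 5)})
        clf = LinearDiscriminant().fit(X, y)
        with pytest.raises(ValueError):
            clf.predict(np.zeros((3, 5)))

    def test_model_bundle_round_trip(self, rng):
        X, y = _blobs(rng, {"a": (0, 0), "b": (4, 4)})
        model = lda_fit(X, y)
        assert np.isclose(model.priors.sum(), 1.0)
        assert (lda_predict(model, X) == LinearDiscriminant().fit(X, y).predict(X)).all()

    def test_affine_feature_rescaling_invariance(self, rng):
        """Accuracy is unchanged by any affine map of a feature column."""
        X, y = _blobs(rng, {"a": (0, 0), "b": (1.0, 0.5)}, n=30, spread=1.0)
        Xs = X.copy()
        Xs[:, 0] = 10.0 * Xs[:, 0] - 7.0
        p1 = LinearDiscriminant().fit(X, y).predict(X)
        p2 = LinearDiscriminant().fit(Xs, y).predict(Xs)
        assert (p1 == p2).all()


class TestCrossValidate:
    def test_loo_separable_is_perfect(self, rng):
        X, y = _blobs(rng, {"a": (0, 0), "b": (10, 10)}, n=5)
        assert cross_validate(X, y, "loo") == 100.0

    def test_deterministic_given_seed(self, rng):
        X, y = _blobs(rng, {"a": (0, 0), "b": (1, 1)}, n=10, spread=1.0)
        a = cross_validate(X, y, ("kfold", 5, 3))
        b = cross_validate(X, y, ("kfold", 5, 3))
        assert a == b

    def test_permutation_null_near_chance(self, rng):
        """Across 200 seeded label permutations the mean leave-one-out
        accuracy sits near 50% (uniform priors remove the fold-imbalance
        bias)."""
        X = rng.normal(0, 1, (10, 2))
        accs = []
        for _ in range(200):
            y = rng.permutation(["a"] * 5 + ["b"] * 5)
            accs.append(cross_validate(X, y, "loo", priors="uniform"))
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(np.mean(accs) - 50.0) < 3 * se + 1.0

    def test_excessive_folds_rejected(self, rng):
        X, y = _blobs(rng, {"a": (0, 0), "b": (1, 1)}, n=3)
        with pytest.raises(ValueError, match="lower k"):
            cross_validate(X, y, ("kfold", 5, 0))


def _feature_table(rng, signal_col=0, delta=2.0, n_per=5):
    """Synthetic table where only one column separates the classes."""
    data = rng.normal(0, 1, (2 * n_per, 7))
    data[n_per:, signal_col] += delta
    labels = ("negative",) * n_per + ("positive",) * n_per
    df = pd.DataFrame(data, columns=list(FEATURE_NAMES))
    return FeatureTable(data=df, labels=labels).rescale()


class TestPairSearch:
    def test_grid_has_21_rows(self, rng):
        grid = pair_search(_feature_table(rng), "two-class")
        assert len(grid.grid) == 21

    def test_best_pair_attains_max(self, rng):
        grid = pair_search(_feature_table(rng), "two-class")
        assert grid.best_accuracy == pytest.approx(grid.mean.max())

    def test_requires_rescaled_table(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (10, 7)), columns=list(FEATURE_NAMES))
        raw = FeatureTable(data=df, labels=("a",) * 5 + ("b",) * 5)
        with pytest.raises(ValueError, match="rescaled"):
            pair_search(raw)

    def test_signal_feature_recovered(self, rng):
        """When only 'mean' carries class signal, the best pair contains it
        in nearly all replicates."""
        hits = 0
        n_rep = 50
        for _ in range(n_rep):
            grid = pair_search(_feature_table(rng, signal_col=0, delta=3.0))
            hits += "mean" in grid.best_pair
        assert hits >= 45  # >= 90%

    def test_cohort_aggregation(self, rng):
        tables = [_feature_table(rng) for _ in range(4)]
        grid = cohort_pair_search(tables, "two-class")
        assert grid.grid.shape == (21, 4)
        assert grid.mean.loc[grid.grid.index[0]] == pytest.approx(
            grid.grid.iloc[0].mean()
        )
        assert grid.best_accuracy >= grid.mean.max() - 1e-12
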