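"""SMOTE balancing, ROC AUC, importance-frequency ranking, epoch design."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from phytonox.data_io import ACTIVE, NOT_ACTIVE
from phytonox.descriptors import DescriptorMatrix
from phytonox.design import (
    CART,
    CLASSIFIER_NAMES,
    GRADIENT_BOOSTING,
    DesignConfig,
    design_ml_system,
    fit_epoch,
    rank_descriptor_importance,
    roc_auc,
)
from phytonox.errors import ConfigurationError, DegenerateDataError
from phytonox.smote import smote_balance
from phytonox.synthetic import CompoundSimDesign, simulate_compound_dataset


class TestSmote:
    def test_equalizes_75_50(self, rng):
        X = rng.normal(size=(125, 4))
        y = np.array([ACTIVE] * 75 + [NOT_ACTIVE] * 50)
        Xb, yb = smote_balance(X, y, rng=rng)
        counts = dict(zip(*np.unique(yb, return_counts=True)))
        assert counts == {ACTIVE: 75, NOT_ACTIVE: 75}

    def test_originals_preserved(self, rng):
        X = rng.normal(size=(30, 3))
        y = np.array([ACTIVE] * 20 + [NOT_ACTIVE] * 10)
        Xb, yb = smote_balance(X, y, rng=rng)
        assert np.array_equal(Xb[:30], X)
        assert np.array_equal(yb[:30], y)

    def test_synthetic_points_interpolate(self, rng):
        """Synthetic minority samples stay inside the class bounding box."""
        X = rng.normal(size=(40, 3))
        y = np.array([ACTIVE] * 30 + [NOT_ACTIVE] * 10)
        Xb, yb = smote_balance(X, y, rng=rng)
        synthetic = Xb[40:]
        pool = X[y == NOT_ACTIVE]
        assert np.all(synthetic >= pool.min(axis=0) - 1e-12)
        assert np.all(synthetic <= pool.max(axis=0) + 1e-12)

    def test_deterministic_given_seed(self):
        X = np.random.default_rng(3).normal(size=(20, 2))
        y = np.array([ACTIVE] * 14 + [NOT_ACTIVE] * 6)
        Xa, _ = smote_balance(X, y, rng=np.random.default_rng(5))
        Xb, _ = smote_balance(X, y, rng=np.random.default_rng(5))
        assert np.array_equal(Xa, Xb)

    def test_neighbor_reduction_logged(self, rng, caplog):
        X = rng.normal(size=(13, 2))
        y = np.array([ACTIVE] * 10 + [NOT_ACTIVE] * 3)
        with caplog.at_level("WARNING"):
            smote_balance(X, y, k_neighbors=5, rng=rng)
        assert "reducing SMOTE neighbours" in caplog.text

    def test_singleton_class_rejected(self, rng):
        X = rng.normal(size=(5, 2))
        y = np.array([ACTIVE] * 4 + [NOT_ACTIVE])
        with pytest.raises(DegenerateDataError):
            smote_balance(X, y, rng=rng)


class TestRocAuc:
    def test_perfect_ordering(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_symmetry_identity(self, rng):
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, 50)
        labels[0], labels[1] = 0, 1  # both classes present
        assert roc_auc(scores, labels) + roc_auc(-scores, labels) == pytest.approx(1.0)

    def test_ties_count_half(self):
        assert roc_auc([0.5, 0.5], [0, 1]) == 0.5

    def test_matches_sklearn(self, rng):
        for _ in range(10):
            scores = rng.normal(size=40)
            labels = rng.integers(0, 2, 40)
            if labels.min() == labels.max():
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores)
            )

    def test_null_centers_on_half(self, rng):
        aucs = [
            roc_auc(rng.normal(size=60), np.array([0, 1] * 30)) for _ in range(200)
        ]
        mc_sd = np.std(aucs, ddof=1) / np.sqrt(len(aucs))
        assert abs(np.mean(aucs) - 0.5) < 3 * mc_sd

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateDataError):
            roc_auc([0.1, 0.2], [1, 1])


class TestRanking:
    def test_frequency_bounds_and_conservation(self):
        X, y, _ = simulate_compound_dataset(
            CompoundSimDesign(n_active=40, n_inactive=30, n_informative=2, effect=2.0, seed=0)
        )
        ranking = rank_descriptor_importance(X, y, n_reps=3, top_positions=8, seed=1)
        freqs = ranking.frequencies()
        n_cycles = 3 * len(CLASSIFIER_NAMES)
        assert ranking.n_cycles == n_cycles
        assert (freqs <= n_cycles).all()
        assert freqs.sum() == 8 * n_cycles  # top_positions per cycle, none skipped

    def test_informative_descriptor_ranks_first(self):
        X, y, informative = simulate_compound_dataset(
            CompoundSimDesign(n_informative=1, effect=3.0, seed=2)
        )
        ranking = rank_descriptor_importance(X, y, n_reps=10, seed=5)
        assert ranking.table.iloc[0]["descriptor"] == informative[0]
        assert ranking.table.iloc[0]["frequency"] >= int(0.975 * ranking.n_cycles)

    def test_ranks_are_permutation_and_topk_selected(self):
        X, y, _ = simulate_compound_dataset(CompoundSimDesign(seed=3))
        ranking = rank_descriptor_importance(X, y, n_reps=2, top_k=5, seed=0)
        assert sorted(ranking.table["rank"]) == list(range(1, 17))
        assert ranking.table["selected"].sum() == 5
        assert len(ranking.selected_names) == 5

    def test_missing_values_rejected(self):
        frame = pd.DataFrame({"a": [1.0, np.nan], "b": [1.0, 2.0]}, index=["x", "y"])
        with pytest.raises(DegenerateDataError):
            rank_descriptor_importance(DescriptorMatrix(frame), [ACTIVE, NOT_ACTIVE], 1)


@pytest.fixture(scope="module")
def ranked_data():
    X, y, _ = simulate_compound_dataset(
        CompoundSimDesign(n_informative=4, effect=3.0, seed=4)
    )
    ranking = rank_descriptor_importance(X, y, n_reps=2, seed=6)
    return X.select(ranking.selected_names).frame, y


class TestEpochDesign:
    def test_no_test_set_leakage(self, ranked_data):
        """Perturbing test rows changes neither normalization nor balancing."""
        frame, y = ranked_data
        idx = np.random.default_rng(0).permutation(len(frame))
        train_idx, test_idx = idx[:120], idx[120:]
        config = DesignConfig(classifiers=(CART,), subset_max=4, kfold_repeats=1)
        base = fit_epoch(frame, y, train_idx, test_idx, CART, config, seed=9)
        tampered = frame.copy()
        tampered.iloc[test_idx] += 100.0
        altered = fit_epoch(tampered, y, train_idx, test_idx, CART, config, seed=9)
        pd.testing.assert_series_equal(base.stats.mean, altered.stats.mean)
        pd.testing.assert_series_equal(base.stats.sd, altered.stats.sd)
        assert base.balanced_counts == altered.balanced_counts
        assert base.best_m == altered.best_m

    def test_balanced_counts_equal(self, ranked_data):
        frame, y = ranked_data
        idx = np.random.default_rng(1).permutation(len(frame))
        config = DesignConfig(classifiers=(CART,), subset_max=3, kfold_repeats=1)
        result = fit_epoch(frame, y, idx[:120], idx[120:], CART, config, seed=1)
        counts = set(result.balanced_counts.values())
        assert len(counts) == 1

    def test_design_is_deterministic(self, ranked_data):
        frame, y = ranked_data
        X = DescriptorMatrix(frame)
        ranking = rank_descriptor_importance(X, y, n_reps=1, seed=0)
        config = DesignConfig(classifiers=(CART,), n_epochs=2, subset_max=4, kfold_repeats=1)
        r1 = design_ml_system(X, y, ranking, CART, config, seed=3)
        r2 = design_ml_system(X, y, ranking, CART, config, seed=3)
        assert r1.metrics_frame().equals(r2.metrics_frame())
        assert r1.best_m == r2.best_m

    def test_tie_breaks_prefer_smaller_m(self, ranked_data):
        frame, y = ranked_data
        idx = np.random.default_rng(2).permutation(len(frame))
        config = DesignConfig(classifiers=(GRADIENT_BOOSTING,), subset_max=6, kfold_repeats=1)
        result = fit_epoch(frame, y, idx[:120], idx[120:], GRADIENT_BOOSTING, config, seed=2)
        best = result.best_m
        top = result.cv_accuracy[best]
        assert all(result.cv_accuracy[m] < top for m in result.cv_accuracy if m < best)

    def test_invalid_config(self):
        with pytest.raises(ConfigurationError):
            DesignConfig(train_fraction=1.5)
        with pytest.raises(ConfigurationError):
            DesignConfig(classifiers=("svm",))
        with pytest.raises(ConfigurationError):
            DesignConfig(subset_min=0)
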