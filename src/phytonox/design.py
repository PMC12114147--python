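"""Consensus ML-system design for activity classification.

The design procedure works in two stages:

1. **Importance-frequency descriptor ranking** — four tree-based
   classifier families (random forest, a single CART tree, extremely
   randomized trees, and extreme gradient boosting) are each refit
   ``n_reps`` times with fresh seeds on the full dataset; after every
   fit, the descriptors occupying the top ``top_positions`` ranks of the
   impurity-based feature importances are recorded.  A descriptor's
   *frequency* is the number of cycles (classifier x repetition) in
   which it appeared among those top positions; the ``top_k`` most
   frequent descriptors are selected, ties broken by mean importance
   rank and then name.

2. **Incremental model design** — per evaluation epoch: a stratified
   70/30 split; z-score normalization fitted on the training side only;
   SMOTE equalization of the normalized training classes; for a growing
   prefix of the ranked descriptors (m = 2..k), repeated stratified
   K-fold accuracy on the balanced training set selects the best m
   (ties to the smaller m); the winning model is refit on the full
   balanced training set and scored on the untouched 30% test set
   (overall accuracy, active-class sensitivity, not-active specificity,
   rank-based ROC AUC).  Five such epochs are run per classifier and the
   best (classifier, m) pair maximizes mean test accuracy.

Everything is a pure function of (data, config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold, cross_val_score, train_test_split
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .data_io import ACTIVE, NOT_ACTIVE
from .descriptors import DescriptorMatrix, NormalizationStats, fit_normalization, normalize
from .errors import ConfigurationError, DegenerateDataError
from .smote import smote_balance
from .utils import MAX_SEED

logger = logging.getLogger(__name__)

RANDOM_FOREST = "random_forest"
CART = "cart"
EXTRA_TREES = "extra_trees"
GRADIENT_BOOSTING = "gradient_boosting"
CLASSIFIER_NAMES = (RANDOM_FOREST, CART, EXTRA_TREES, GRADIENT_BOOSTING)


def make_classifier(name: str, seed: int):
    """Instantiate a classifier with library-default hyperparameters."""
    if name == RANDOM_FOREST:
        return RandomForestClassifier(random_state=seed)
    if name == CART:
        return DecisionTreeClassifier(random_state=seed)
    if name == EXTRA_TREES:
        return ExtraTreesClassifier(random_state=seed)
    if name == GRADIENT_BOOSTING:
        return XGBClassifier(random_state=seed, n_jobs=1, verbosity=0)
    raise ConfigurationError(f"unknown classifier {name!r}")


def encode_labels(y) -> np.ndarray:
    """Map {active, not_active} to {1, 0}."""
    labels = np.asarray(y)
    unknown = set(labels.tolist()) - {ACTIVE, NOT_ACTIVE}
    if unknown:
        raise ConfigurationError(f"unsupported label(s): {sorted(unknown)}")
    return (labels == ACTIVE).astype(int)


# ---------------------------------------------------------------------------
# descriptor ranking
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RankingResult:
    table: pd.DataFrame                 # rank, descriptor, frequency, mean rank, selected
    selected_names: tuple[str, ...]     # top_k descriptors in rank order
    n_cycles: int
    top_positions: int

    def frequencies(self) -> pd.Series:
        return self.table.set_index("descriptor")["frequency"]


def rank_descriptor_importance(
    X: DescriptorMatrix,
    y,
    n_reps: int = 100,
    top_positions: int = 16,
    top_k: int = 16,
    seed: int = 0,
) -> RankingResult:
    """Importance-frequency ranking over classifier x repetition cycles.

    With the default four classifier families and 100 repetitions this
    performs 400 importance-evaluation cycles.
    """
    y_enc = encode_labels(y)
    if X.frame.isna().any().any():
        raise DegenerateDataError("ranking requires complete descriptor values")
    names = np.array(X.names)
    top_positions = min(top_positions, len(names))
    if top_k > len(names):
        raise ConfigurationError("top_k exceeds the number of descriptors")
    values = X.values
    rng = np.random.default_rng(seed)
    frequency = np.zeros(len(names), dtype=int)
    rank_sum = np.zeros(len(names), dtype=float)
    n_cycles = 0
    skipped = 0
    total = len(CLASSIFIER_NAMES) * n_reps
    for rep in range(n_reps):
        for clf_name in CLASSIFIER_NAMES:
            clf_seed = int(rng.integers(0, MAX_SEED))
            try:
                clf = make_classifier(clf_name, clf_seed)
                clf.fit(values, y_enc)
                importances = np.asarray(clf.feature_importances_, dtype=float)
            except Exception as exc:  # pragma: no cover - defensive
                skipped += 1
                logger.warning("cycle skipped (%s rep %d): %s", clf_name, rep, exc)
                continue
            # importance rank 0 = most important; random tie-break for exact ties
            order = np.argsort(-(importances + 1e-12 * rng.random(len(names))))
            ranks = np.empty(len(names), dtype=int)
            ranks[order] = np.arange(len(names))
            frequency[ranks < top_positions] += 1
            rank_sum += ranks
            n_cycles += 1
    if skipped > 0.05 * total:
        raise DegenerateDataError(f"{skipped}/{total} ranking cycles failed")
    mean_rank = rank_sum / max(n_cycles, 1)
    order = sorted(
        range(len(names)), key=lambda j: (-frequency[j], mean_rank[j], names[j])
    )
    table = pd.DataFrame(
        {
            "rank": np.arange(1, len(names) + 1),
            "descriptor": names[order],
            "frequency": frequency[order],
            "mean_importance_rank": mean_rank[order],
            "selected": np.arange(len(names)) < top_k,
        }
    )
    return RankingResult(
        table=table,
        selected_names=tuple(str(n) for n in names[order][:top_k]),
        n_cycles=n_cycles,
        top_positions=top_positions,
    )


# ---------------------------------------------------------------------------
# design configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DesignConfig:
    """Knobs of the incremental design procedure (defaults = study setup)."""

    classifiers: tuple[str, ...] = CLASSIFIER_NAMES
    train_fraction: float = 0.7
    n_epochs: int = 5
    subset_min: int = 2
    subset_max: int = 16
    kfold_splits: int = 5
    kfold_repeats: int = 3
    smote_neighbors: int = 5
    balance_before_cv: bool = True
    force_m: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ConfigurationError("train_fraction must lie in (0, 1)")
        unknown = set(self.classifiers) - set(CLASSIFIER_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown classifier(s): {sorted(unknown)}")
        if self.subset_min < 1 or self.subset_min > self.subset_max:
            raise ConfigurationError("need 1 <= subset_min <= subset_max")
        if self.n_epochs < 1 or self.kfold_splits < 2 or self.kfold_repeats < 1:
            raise ConfigurationError("invalid epoch / K-fold configuration")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def roc_auc(scores, labels) -> float:
    """Rank-based ROC AUC (Mann-Whitney identity); ties count one half."""
    scores = np.asarray(scores, dtype=float)
    y = encode_labels(labels) if not np.issubdtype(np.asarray(labels).dtype, np.number) else np.asarray(labels)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DegenerateDataError("ROC AUC needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass(frozen=True)
class EpochResult:
    epoch: int
    best_m: int
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    cv_accuracy: dict[int, float]       # m -> repeated K-fold mean accuracy
    stats: NormalizationStats
    balanced_counts: dict[str, int]


@dataclass(frozen=True)
class DesignResult:
    classifier: str
    epochs: tuple[EpochResult, ...]
    best_m: int                         # argmax of mean CV accuracy over epochs

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([e.accuracy for e in self.epochs]))

    @property
    def mean_auc(self) -> float:
        return float(np.mean([e.auc for e in self.epochs]))

    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "classifier": self.classifier,
                    "epoch": e.epoch,
                    "best_m": e.best_m,
                    "accuracy": e.accuracy,
                    "sensitivity": e.sensitivity,
                    "specificity": e.specificity,
                    "auc": e.auc,
                }
                for e in self.epochs
            ]
        )


# ---------------------------------------------------------------------------
# epoch-level design
# ---------------------------------------------------------------------------


def fit_epoch(
    frame: pd.DataFrame,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    classifier: str,
    config: DesignConfig,
    seed: int,
    epoch: int = 0,
) -> EpochResult:
    """One design epoch on an explicit train/test split.

    ``frame`` holds the ranked descriptors in rank order.  All training-
    side statistics (normalization, SMOTE) are computed from the training
    rows only, so altering test rows cannot change them.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    train_frame = frame.iloc[train_idx]
    stats = fit_normalization(DescriptorMatrix(train_frame))
    train_norm = normalize(DescriptorMatrix(train_frame), stats).values
    y_train = y[train_idx]
    if config.balance_before_cv:
        X_bal, y_bal = smote_balance(train_norm, y_train, config.smote_neighbors, rng)
    else:
        X_bal, y_bal = train_norm, y_train
    y_bal_enc = encode_labels(y_bal)
    subset_max = min(config.subset_max, frame.shape[1])
    ms = range(config.subset_min, subset_max + 1)
    if config.force_m is not None:
        ms = [min(config.force_m, subset_max)]
    cv_scores: dict[int, float] = {}
    for m in ms:
        cv = RepeatedStratifiedKFold(
            n_splits=config.kfold_splits,
            n_repeats=config.kfold_repeats,
            random_state=int(rng.integers(0, MAX_SEED)),
        )
        clf = make_classifier(classifier, int(rng.integers(0, MAX_SEED)))
        scores = cross_val_score(clf, X_bal[:, :m], y_bal_enc, cv=cv, scoring="accuracy")
        cv_scores[m] = float(scores.mean())
    best_m = max(cv_scores, key=lambda m: (cv_scores[m], -m))
    final = make_classifier(classifier, int(rng.integers(0, MAX_SEED)))
    final.fit(X_bal[:, :best_m], y_bal_enc)
    test_norm = normalize(DescriptorMatrix(frame.iloc[test_idx]), stats).values
    y_test = encode_labels(y[test_idx])
    pred = final.predict(test_norm[:, :best_m])
    proba = final.predict_proba(test_norm[:, :best_m])[:, 1]
    accuracy = float((pred == y_test).mean())
    sensitivity = float((pred[y_test == 1] == 1).mean())
    specificity = float((pred[y_test == 0] == 0).mean())
    auc = roc_auc(proba, y_test)
    counts = dict(zip(*np.unique(y_bal, return_counts=True)))
    return EpochResult(
        epoch=epoch,
        best_m=best_m,
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        auc=auc,
        cv_accuracy=cv_scores,
        stats=stats,
        balanced_counts={str(k): int(v) for k, v in counts.items()},
    )


def design_ml_system(
    X: DescriptorMatrix,
    y,
    ranking: RankingResult,
    classifier: str,
    config: DesignConfig = DesignConfig(),
    seed: int = 0,
) -> DesignResult:
    """Run the full multi-epoch design for one classifier."""
    if len(ranking.selected_names) < min(config.subset_max, len(ranking.selected_names)):
        raise ConfigurationError("ranking selects fewer descriptors than subset_max")
    frame = X.select(ranking.selected_names).frame
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    epochs = []
    for epoch in range(config.n_epochs):
        split_seed = int(rng.integers(0, MAX_SEED))
        train_idx, test_idx = train_test_split(
            np.arange(len(frame)),
            test_size=1.0 - config.train_fraction,
            stratify=y,
            random_state=split_seed,
        )
        epoch_seed = int(rng.integers(0, MAX_SEED))
        epochs.append(
            fit_epoch(frame, y, train_idx, test_idx, classifier, config, epoch_seed, epoch)
        )
    # classifier-level m: argmax of the CV-accuracy curve averaged over epochs
    curves = pd.DataFrame([e.cv_accuracy for e in epochs]).mean(axis=0)
    best_m = int(max(curves.index, key=lambda m: (curves[m], -m)))
    return DesignResult(classifier=classifier, epochs=tuple(epochs), best_m=best_m)


@dataclass(frozen=True)
class EvaluationReport:
    results: dict[str, DesignResult]
    best_classifier: str
    best_m: int
    config: DesignConfig

    def metrics_frame(self) -> pd.DataFrame:
        return pd.concat(
            [r.metrics_frame() for r in self.results.values()], ignore_index=True
        )

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for name, r in self.results.items():
            frame = r.metrics_frame()
            rows.append(
                {
                    "classifier": name,
                    "best_m": r.best_m,
                    "mean_accuracy": frame["accuracy"].mean(),
                    "mean_sensitivity": frame["sensitivity"].mean(),
                    "mean_specificity": frame["specificity"].mean(),
                    "mean_auc": frame["auc"].mean(),
                }
            )
        return pd.DataFrame(rows)

    def manifest(self) -> dict:
        return {
            "best_classifier": self.best_classifier,
            "best_m": self.best_m,
            "config": asdict(self.config),
            "summary": self.summary_frame().to_dict(orient="records"),
        }


def evaluate_all(
    X: DescriptorMatrix,
    y,
    ranking: RankingResult,
    config: DesignConfig = DesignConfig(),
    seed: int = 0,
) -> EvaluationReport:
    """Design all configured classifiers; pick the best (classifier, m) pair."""
    results: dict[str, DesignResult] = {}
    for i, name in enumerate(config.classifiers):
        results[name] = design_ml_system(X, y, ranking, name, config, seed + i)
    best = max(results, key=lambda n: results[n].mean_accuracy)
    return EvaluationReport(
        results=results,
        best_classifier=best,
        best_m=results[best].best_m,
        config=config,
    )
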