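"""Deployment: full-data refits, persistent model bundles, consensus calls.

After the design stage has fixed each classifier's best descriptor count
m, every classifier is *redesigned on the full labeled dataset*: fresh
normalization statistics over all compounds, SMOTE equalization, and a
refit on the first m ranked descriptors.  Each fitted system is saved as
a bundle directory — a JSON manifest (format version, seed, config
snapshot, class counts, hyperparameters, decision threshold), the
normalization statistics, the serialized model, and a small probe set
whose stored outputs are re-checked on load — so deployment never
recomputes training-side statistics.

Query compounds are classified by every bundle; a prediction is
*accepted* only when all bundles agree (unanimity rule), otherwise it is
reported unresolved.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd

from .data_io import ACTIVE, NOT_ACTIVE, CompoundRecord
from .descriptors import (
    DescriptorMatrix,
    NormalizationStats,
    compute_descriptors,
    fit_normalization,
    normalize,
)
from .design import DesignConfig, EvaluationReport, encode_labels, make_classifier
from .errors import ConfigurationError, FormatError
from .smote import smote_balance
from .utils import MAX_SEED

logger = logging.getLogger(__name__)

FORMAT_VERSION = "1"
UNRESOLVED = "unresolved"
FAILED = "failed"

_MANIFEST = "manifest.json"
_STATS = "normalization.json"
_MODEL = "model.joblib"
_PROBE = "probe.json"


@dataclass
class ModelBundle:
    """A deployable classifier with its feature list and train statistics."""

    classifier: str
    feature_names: tuple[str, ...]
    stats: NormalizationStats
    model: object
    manifest: dict

    def predict_calls(self, matrix: DescriptorMatrix) -> np.ndarray:
        """Hard active/not-active calls for pre-computed descriptors."""
        sub = normalize(matrix.select(self.feature_names), self.stats)
        proba = self.model.predict_proba(sub.values)[:, 1]
        threshold = float(self.manifest.get("threshold", 0.5))
        return np.where(proba >= threshold, ACTIVE, NOT_ACTIVE)

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / _MANIFEST).write_text(json.dumps(self.manifest, indent=2))
        self.stats.to_json(directory / _STATS)
        joblib.dump(self.model, directory / _MODEL)
        probe = np.zeros((3, len(self.feature_names)))
        probe[1] = 1.0
        probe[2] = -1.0
        probe_frame = DescriptorMatrix(
            pd.DataFrame(probe, index=["p0", "p1", "p2"], columns=self.feature_names)
        )
        outputs = self.predict_calls(probe_frame).tolist()
        (directory / _PROBE).write_text(
            json.dumps({"vectors": probe.tolist(), "calls": outputs})
        )
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "ModelBundle":
        directory = Path(directory)
        manifest = json.loads((directory / _MANIFEST).read_text())
        version = str(manifest.get("format_version"))
        if version != FORMAT_VERSION:
            raise FormatError(
                f"bundle format version {version!r} incompatible with {FORMAT_VERSION!r}"
            )
        stats = NormalizationStats.from_json(directory / _STATS)
        model = joblib.load(directory / _MODEL)
        bundle = cls(
            classifier=manifest["classifier"],
            feature_names=tuple(manifest["feature_names"]),
            stats=stats,
            model=model,
            manifest=manifest,
        )
        probe = json.loads((directory / _PROBE).read_text())
        probe_frame = DescriptorMatrix(
            pd.DataFrame(
                np.asarray(probe["vectors"], dtype=float),
                index=[f"p{i}" for i in range(len(probe["vectors"]))],
                columns=bundle.feature_names,
            )
        )
        recomputed = bundle.predict_calls(probe_frame).tolist()
        if recomputed != probe["calls"]:
            raise FormatError("bundle probe outputs do not reproduce stored calls")
        return bundle


def build_final_system(
    X_full: DescriptorMatrix,
    y_full,
    report: EvaluationReport,
    config: DesignConfig | None = None,
    seed: int = 0,
    use_smote: bool = True,
    out_dir: str | Path | None = None,
) -> list[ModelBundle]:
    """Refit every configured classifier on the full dataset; one bundle each.

    Each classifier keeps its own best feature count m from the design
    report unless ``config.force_m`` pins all of them to one value.
    """
    config = config or report.config
    best_m = {}
    feature_order = None
    for name in config.classifiers:
        if name not in report.results:
            raise ConfigurationError(f"design report lacks a best m for {name!r}")
        best_m[name] = config.force_m or report.results[name].best_m
        # ranked descriptor order as seen by the design epochs
        feature_order = tuple(report.results[name].epochs[0].stats.mean.index)
    return build_system(
        X_full, y_full, feature_order, best_m, config, seed, use_smote, out_dir
    )


def build_system(
    X_full: DescriptorMatrix,
    y_full,
    feature_order: Sequence[str],
    best_m: dict[str, int],
    config: DesignConfig,
    seed: int = 0,
    use_smote: bool = True,
    out_dir: str | Path | None = None,
) -> list[ModelBundle]:
    """Lower-level builder taking an explicit ranked feature order and m map."""
    y_full = np.asarray(y_full)
    rng = np.random.default_rng(seed)
    bundles = []
    for name in config.classifiers:
        m = best_m[name]
        features = tuple(feature_order[:m])
        sub = X_full.select(features)
        stats = fit_normalization(sub)
        X_norm = normalize(sub, stats).values
        if use_smote:
            X_bal, y_bal = smote_balance(
                X_norm, y_full, config.smote_neighbors, rng
            )
        else:
            X_bal, y_bal = X_norm, y_full
        clf_seed = int(rng.integers(0, MAX_SEED))
        model = make_classifier(name, clf_seed)
        model.fit(X_bal, encode_labels(y_bal))
        counts = {
            str(k): int(v) for k, v in zip(*np.unique(y_full, return_counts=True))
        }
        manifest = {
            "format_version": FORMAT_VERSION,
            "classifier": name,
            "feature_names": list(features),
            "n_features": m,
            "seed": seed,
            "classifier_seed": clf_seed,
            "threshold": 0.5,
            "smote": bool(use_smote),
            "training_class_counts": counts,
            "hyperparameters": {
                k: v for k, v in model.get_params().items()
                if isinstance(v, (int, float, str, bool, type(None)))
            },
            "created": datetime.now(timezone.utc).isoformat(),
        }
        bundle = ModelBundle(name, features, stats, model, manifest)
        if out_dir is not None:
            bundle.save(Path(out_dir) / name)
        bundles.append(bundle)
    return bundles


def load_system(directory: str | Path) -> list[ModelBundle]:
    """Load every bundle subdirectory under ``directory``."""
    directory = Path(directory)
    bundles = [
        ModelBundle.load(sub)
        for sub in sorted(directory.iterdir())
        if (sub / _MANIFEST).exists()
    ]
    if not bundles:
        raise FormatError(f"no model bundles found under {directory}")
    return bundles


@dataclass(frozen=True)
class ConsensusPrediction:
    compound_id: str
    calls: dict[str, str]              # classifier -> active / not_active
    consensus: str                     # active / not_active / unresolved / failed
    accepted: bool


def predict_consensus(
    bundles: Sequence[ModelBundle], queries: Sequence[CompoundRecord]
) -> list[ConsensusPrediction]:
    """Classify each query with every bundle and apply the unanimity rule.

    Descriptors are computed once over the union of bundle features; a
    query whose descriptors are undefined for any required feature is
    marked failed without affecting the others.  Output order preserves
    input order, and the consensus is invariant to bundle order.
    """
    if not bundles:
        raise ConfigurationError("at least one model bundle is required")
    all_features: list[str] = []
    for bundle in bundles:
        for f in bundle.feature_names:
            if f not in all_features:
                all_features.append(f)
    matrix = compute_descriptors(queries, all_features)
    predictions = []
    complete = matrix.frame.notna().all(axis=1)
    ok_matrix = DescriptorMatrix(matrix.frame.loc[complete])
    calls_by_bundle = {
        b.classifier: dict(zip(ok_matrix.ids, b.predict_calls(ok_matrix)))
        for b in bundles
    }
    for record in queries:
        if not complete.loc[record.id]:
            predictions.append(
                ConsensusPrediction(record.id, {}, FAILED, accepted=False)
            )
            continue
        calls = {name: str(calls_by_bundle[name][record.id]) for name in calls_by_bundle}
        unique = set(calls.values())
        if len(unique) == 1:
            consensus, accepted = unique.pop(), True
        else:
            consensus, accepted = UNRESOLVED, False
        predictions.append(ConsensusPrediction(record.id, calls, consensus, accepted))
    return predictions


def summarize_predictions(predictions: Sequence[ConsensusPrediction]) -> dict[str, int]:
    """Counts partitioning the query set by consensus outcome."""
    summary = {"accepted_active": 0, "accepted_not_active": 0, "unresolved": 0, "failed": 0}
    for p in predictions:
        if p.consensus == ACTIVE:
            summary["accepted_active"] += 1
        elif p.consensus == NOT_ACTIVE:
            summary["accepted_not_active"] += 1
        elif p.consensus == FAILED:
            summary["failed"] += 1
        else:
            summary["unresolved"] += 1
    return summary


def predictions_table(predictions: Sequence[ConsensusPrediction]) -> pd.DataFrame:
    classifiers = sorted({name for p in predictions for name in p.calls})
    rows = []
    for p in predictions:
        row = {"compound": p.compound_id}
        for name in classifiers:
            row[f"call_{name}"] = p.calls.get(name, "")
        row["consensus"] = p.consensus
        row["accepted"] = p.accepted
        rows.append(row)
    return pd.DataFrame(rows)
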