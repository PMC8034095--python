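"""False-positive reduction: a boosted-tree classifier over cluster metadata.

Clusters born from real nodules tend to have high member confidences, many
inferences, and members from both the axial and the coronal MIP stack;
vessel-induced confounders are typically sparse and single-axis.  A gradient
boosted tree trained on the six cluster features separates the two and its
probability becomes the candidate's final nodule confidence score.
"""

from __future__ import annotations

import base64
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import xgboost as xgb

from .clustering import FEATURE_NAMES, ClusterFeatures, NoduleCandidate, with_score
from .io import NoduleAnnotation


@dataclass(frozen=True)
class ReducerConfig:
    """Boosted-tree hyperparameters (the pipeline's fixed operating values).

    ``scale_pos_weight`` compensates the class imbalance between true-nodule
    and confounder clusters.
    """

    learning_rate: float = 0.05
    max_depth: int = 6
    n_estimators: int = 200
    scale_pos_weight: float = 2.7
    colsample: float = 0.6
    subsample: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("learning_rate", "colsample", "subsample"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        for name in ("max_depth", "n_estimators"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not self.scale_pos_weight > 0:
            raise ValueError("scale_pos_weight must be > 0")


def features_matrix(items: Sequence[ClusterFeatures | NoduleCandidate]) -> np.ndarray:
    """Stack cluster features into an (n, 6) float matrix in the canonical
    ``FEATURE_NAMES`` order."""
    rows = []
    for item in items:
        f = item.features if isinstance(item, NoduleCandidate) else item
        rows.append([f.max_conf, f.mean_conf, float(f.n_inferences),
                     float(f.has_both_axes), f.dist_top_mm, f.dist_bottom_mm])
    return np.asarray(rows, dtype=np.float32).reshape(-1, len(FEATURE_NAMES))


def label_candidates(
    candidates: Sequence[NoduleCandidate],
    annotations: Sequence[NoduleAnnotation],
    match_dist_mm: float = 10.0,
) -> tuple[np.ndarray, list[str | None]]:
    """Distance-based surrogate labelling of candidates against ground truth.

    A candidate is positive iff its centroid lies within ``match_dist_mm``
    (Euclidean) of some same-scan annotation centre; it is matched to the
    nearest such annotation, ties broken by smaller nodule id.  Returns a
    boolean label array and the matched nodule id (or None) per candidate.
    """
    by_scan: dict[str, list[NoduleAnnotation]] = {}
    for ann in annotations:
        by_scan.setdefault(ann.scan_id, []).append(ann)

    labels = np.zeros(len(candidates), dtype=bool)
    matched: list[str | None] = [None] * len(candidates)
    for i, cand in enumerate(candidates):
        best: tuple[float, str] | None = None
        for ann in by_scan.get(cand.scan_id, ()):
            dist = float(np.linalg.norm(
                np.subtract(cand.centroid_mm, ann.center_mm)))
            if dist <= match_dist_mm:
                key = (dist, ann.nodule_id)
                if best is None or key < best:
                    best = key
        if best is not None:
            labels[i] = True
            matched[i] = best[1]
    return labels, matched


class ReducerModel:
    """A trained boosted-tree ensemble over the six cluster features."""

    def __init__(self, booster: xgb.XGBClassifier, config: ReducerConfig):
        self._clf = booster
        self.config = config

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        """Probability of being a true nodule, one value in [0, 1] per row."""
        features = np.asarray(features, dtype=np.float32)
        if features.ndim != 2 or features.shape[1] != len(FEATURE_NAMES):
            raise ValueError(
                f"expected an (n, {len(FEATURE_NAMES)}) feature matrix, "
                f"got shape {features.shape}"
            )
        if len(features) == 0:
            return np.zeros(0)
        return self._clf.predict_proba(features)[:, 1]

    @property
    def feature_importances(self) -> dict[str, float]:
        """Gain-based importances, normalized to sum to 1."""
        raw = np.asarray(self._clf.feature_importances_, dtype=float)
        total = raw.sum()
        if total > 0:
            raw = raw / total
        return dict(zip(FEATURE_NAMES, raw))

    def save(self, path: str | Path) -> None:
        """Serialize model, config and importances to a single JSON file."""
        booster_raw = self._clf.get_booster().save_raw("json")
        payload = {
            "format": "nodulecad-reducer",
            "config": self.config.__dict__,
            "feature_names": list(FEATURE_NAMES),
            "feature_importances": self.feature_importances,
            "booster_b64": base64.b64encode(bytes(booster_raw)).decode("ascii"),
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "ReducerModel":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        if payload.get("format") != "nodulecad-reducer":
            raise ValueError(f"{path}: not a reducer model file")
        config = ReducerConfig(**payload["config"])
        clf = _make_classifier(config)
        clf.load_model(bytearray(base64.b64decode(payload["booster_b64"])))
        return cls(clf, config)


def _make_classifier(config: ReducerConfig) -> xgb.XGBClassifier:
    return xgb.XGBClassifier(
        learning_rate=config.learning_rate,
        max_depth=config.max_depth,
        n_estimators=config.n_estimators,
        scale_pos_weight=config.scale_pos_weight,
        colsample_bytree=config.colsample,
        subsample=config.subsample,
        random_state=config.seed,
        n_jobs=1,
        tree_method="hist",
        objective="binary:logistic",
        eval_metric="logloss",
    )


def train_reducer(
    features: np.ndarray | Sequence[ClusterFeatures],
    labels: Sequence[bool | int],
    config: ReducerConfig | None = None,
) -> ReducerModel:
    """Train the boosted-tree reducer; deterministic given ``config.seed``."""
    config = config or ReducerConfig()
    X = (np.asarray(features, dtype=np.float32)
         if isinstance(features, np.ndarray) else features_matrix(list(features)))
    y = np.asarray(labels, dtype=int)
    if len(X) != len(y):
        raise ValueError(f"feature/label length mismatch: {len(X)} vs {len(y)}")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("training needs at least 2 examples of each class")
    clf = _make_classifier(config)
    clf.fit(X, y)
    return ReducerModel(clf, config)


def score_candidates(model: ReducerModel,
                     candidates: Sequence[NoduleCandidate]) -> list[NoduleCandidate]:
    """Attach the reducer probability to each candidate as its final score;
    order is preserved."""
    if not candidates:
        return []
    probs = model.predict_proba(features_matrix(list(candidates)))
    return [with_score(c, p) for c, p in zip(candidates, probs)]


def feature_importance_report(model: ReducerModel) -> list[tuple[str, float]]:
    """Features sorted by normalized importance, descending; ties broken by
    feature name."""
    imp = model.feature_importances
    return sorted(imp.items(), key=lambda kv: (-kv[1], kv[0]))
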