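"""Matching predictions to ground truth; precision/recall/FP-per-scan; FROC.

Each slice query yields at most one prediction.  A prediction can hit the
nodule the report intended (``tp_intended``), hit a different real nodule
(``tp_unintended``), hit nothing (``fp``), or be absent (``fn``).  Standard
metrics count any real-nodule hit as a true positive; the *adjusted* variants
re-count unintended hits as false positives, giving a stricter reading of
how often the pipeline returns the nodule the report was about.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .clustering import NoduleCandidate
from .io import NoduleAnnotation
from .selection import SliceQuery, select_candidate

OUTCOMES = ("tp_intended", "tp_unintended", "fp", "fn")


@dataclass(frozen=True)
class EvaluationResult:
    n_queries: int
    n_scans: int
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    fp_per_scan: float
    adjusted_tp: int
    adjusted_fp: int
    adjusted_precision: float
    adjusted_recall: float
    adjusted_fp_per_scan: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class FrocPoint:
    """One point of a free-response ROC curve: the recall and FP-per-scan
    obtained when selection uses ``score_threshold`` as its confidence floor."""

    score_threshold: float
    recall: float
    fp_per_scan: float


def _hit(prediction: NoduleCandidate, annotation: NoduleAnnotation,
         hit_dist_mm: float) -> bool:
    dist = float(np.linalg.norm(np.subtract(prediction.centroid_mm,
                                            annotation.center_mm)))
    return dist <= max(annotation.diameter_mm, hit_dist_mm)


def match_prediction(
    prediction: NoduleCandidate | None,
    query: SliceQuery,
    annotations: Sequence[NoduleAnnotation],
    hit_dist_mm: float = 10.0,
) -> str:
    """Classify one query's prediction as tp_intended/tp_unintended/fp/fn.

    The hit criterion is Euclidean distance from the predicted centroid to
    the annotation centre of at most ``max(annotation diameter,
    hit_dist_mm)`` — tolerant of the slight centroid offsets the MIP and
    cluster-mean steps introduce.
    """
    if prediction is None:
        return "fn"
    same_scan = [a for a in annotations if a.scan_id == query.scan_id]
    intended = [a for a in same_scan if a.nodule_id == query.intended_nodule_id]
    if query.intended_nodule_id is not None and not intended:
        raise ValueError(
            f"intended nodule {query.intended_nodule_id!r} absent from annotations"
        )
    if intended and _hit(prediction, intended[0], hit_dist_mm):
        return "tp_intended"
    for ann in same_scan:
        if intended and ann.nodule_id == intended[0].nodule_id:
            continue
        if _hit(prediction, ann, hit_dist_mm):
            return "tp_unintended"
    return "fp"


def evaluate_predictions(
    predictions: Sequence[NoduleCandidate | None],
    queries: Sequence[SliceQuery],
    annotations: Sequence[NoduleAnnotation],
    hit_dist_mm: float = 10.0,
) -> list[str]:
    """Match every query's prediction, preventing double-counted nodules.

    Queries are processed in order; once a query claims an annotation as its
    intended true positive, a later ``tp_intended`` on the same annotation is
    demoted to ``tp_unintended`` (greedy in query order).
    """
    if len(predictions) != len(queries):
        raise ValueError("one prediction per query required")
    outcomes: list[str] = []
    claimed: set[tuple[str, str]] = set()
    for pred, query in zip(predictions, queries):
        outcome = match_prediction(pred, query, annotations, hit_dist_mm)
        if outcome == "tp_intended":
            key = (query.scan_id, str(query.intended_nodule_id))
            if key in claimed:
                outcome = "tp_unintended"
            else:
                claimed.add(key)
        outcomes.append(outcome)
    return outcomes


def compute_metrics(outcomes: Iterable[str], n_scans: int) -> EvaluationResult:
    """Aggregate outcomes into precision, recall, FP/scan and adjusted
    variants.

    A query whose prediction is a false positive also misses its intended
    nodule, so ``fn = n_queries − tp``.  Precision with zero predictions is
    defined as 1 (vacuous truth).  Adjusted metrics count only intended hits
    as true positives and demote unintended hits to false positives.
    """
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    counts = {o: 0 for o in OUTCOMES}
    for o in outcomes:
        if o not in counts:
            raise ValueError(f"unknown outcome {o!r}")
        counts[o] += 1
    n_queries = sum(counts.values())

    def _prf(tp: int, fp: int) -> tuple[float, float, float]:
        precision = tp / (tp + fp) if (tp + fp) > 0 else 1.0
        recall = tp / n_queries if n_queries > 0 else 0.0
        return precision, recall, fp / n_scans

    tp = counts["tp_intended"] + counts["tp_unintended"]
    fp = counts["fp"]
    precision, recall, fp_per_scan = _prf(tp, fp)
    adj_tp = counts["tp_intended"]
    adj_fp = fp + counts["tp_unintended"]
    adj_precision, adj_recall, adj_fp_per_scan = _prf(adj_tp, adj_fp)
    return EvaluationResult(
        n_queries=n_queries, n_scans=n_scans,
        tp=tp, fp=fp, fn=n_queries - tp,
        precision=precision, recall=recall, fp_per_scan=fp_per_scan,
        adjusted_tp=adj_tp, adjusted_fp=adj_fp,
        adjusted_precision=adj_precision, adjusted_recall=adj_recall,
        adjusted_fp_per_scan=adj_fp_per_scan,
    )


def evaluate_queries(
    candidates_by_scan: dict[str, Sequence[NoduleCandidate]],
    queries: Sequence[SliceQuery],
    annotations: Sequence[NoduleAnnotation],
    hit_dist_mm: float = 10.0,
    min_score: float | None = None,
    window_mm: float | None = None,
    use_3d_distance: bool = False,
) -> tuple[EvaluationResult, list[str], list[NoduleCandidate | None]]:
    """Run selection for every query and evaluate the outcomes.

    ``min_score``/``window_mm`` override the per-query settings when given
    (used by the FROC sweep).  Returns (metrics, outcomes, predictions).
    """
    from dataclasses import replace

    predictions: list[NoduleCandidate | None] = []
    for query in queries:
        q = query
        if min_score is not None:
            q = replace(q, min_score=min_score)
        if window_mm is not None:
            q = replace(q, window_mm=window_mm)
        cands = candidates_by_scan.get(query.scan_id, ())
        predictions.append(select_candidate(cands, q, use_3d_distance))
    outcomes = evaluate_predictions(predictions, queries, annotations, hit_dist_mm)
    n_scans = max(1, len({q.scan_id for q in queries}))
    return compute_metrics(outcomes, n_scans), outcomes, predictions


def froc_curve(
    candidates_by_scan: dict[str, Sequence[NoduleCandidate]],
    queries: Sequence[SliceQuery],
    annotations: Sequence[NoduleAnnotation],
    window_mm: float = 10.0,
    thresholds: Sequence[float] | None = None,
    hit_dist_mm: float = 10.0,
) -> list[FrocPoint]:
    """Sweep the final-score threshold and record (recall, FP/scan) per point.

    The default grid spans [0.20, 1.0] — 0.20 is the pipeline's confidence
    floor — in steps of 0.05.  Points are returned sorted by threshold
    descending (strictest first, lowest FP rate first).
    """
    if thresholds is None:
        thresholds = np.round(np.arange(0.20, 1.0 + 1e-9, 0.05), 10)
    thresholds = sorted(set(float(t) for t in thresholds), reverse=True)
    if not thresholds:
        raise ValueError("threshold grid must be nonempty")
    if any(not 0.0 <= t <= 1.0 for t in thresholds):
        raise ValueError("thresholds must lie in [0, 1]")
    points = []
    for t in thresholds:
        metrics, _, _ = evaluate_queries(
            candidates_by_scan, queries, annotations, hit_dist_mm,
            min_score=t, window_mm=window_mm,
        )
        points.append(FrocPoint(score_threshold=t, recall=metrics.recall,
                                fp_per_scan=metrics.fp_per_scan))
    return points


def plot_froc(points: Sequence[FrocPoint], path: str, title: str = "FROC") -> None:
    """Render a FROC curve (recall vs FP/scan) to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = [p.fp_per_scan for p in points]
    ys = [p.recall for p in points]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(xs, ys, marker="o")
    ax.set_xlabel("false positives per scan")
    ax.set_ylabel("recall")
    ax.set_title(title)
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
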