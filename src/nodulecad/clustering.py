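"""Aggregate per-slice 2D detections into 3D nodule candidates.

Raw inferences live on individual MIP slices; a real nodule produces a dense
swarm of them — across many overlapping slices and, usually, on both the
axial and the coronal stack.  Lifting each inference to its world (x, y, z)
position and density-clustering with DBSCAN turns that swarm into a single
candidate, while isolated spurious inferences fall out as noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from sklearn.cluster import DBSCAN

from .io import Detection2D, ScanGeometry


@dataclass(frozen=True)
class ClusteringConfig:
    """Confidence pre-filter and DBSCAN parameters.

    Defaults follow the pipeline's operating point: inferences with
    confidence below 0.1 are discarded as background noise, two inferences
    are neighbours within ``eps_mm`` = 10 mm, and a cluster needs at least
    ``min_samples`` = 4 inferences.
    """

    min_confidence: float = 0.1
    eps_mm: float = 10.0
    min_samples: int = 4

    def __post_init__(self) -> None:
        if not self.eps_mm > 0:
            raise ValueError("eps_mm must be > 0")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")
        if not 0.0 <= self.min_confidence <= 1.0:
            raise ValueError("min_confidence must lie in [0, 1]")


@dataclass(frozen=True)
class Detection3D:
    """A 2D detection back-projected to its world position.

    Axial slices constrain (x, y) in-plane and z via the slice position;
    coronal slices constrain (x, z) in-plane and y via the slice position.
    ``diameter_mm`` is the larger box side.
    """

    source: Detection2D
    center_mm: tuple[float, float, float]
    diameter_mm: float
    confidence: float
    axis: str


@dataclass(frozen=True)
class ClusterFeatures:
    """Cluster metadata used for false-positive reduction: max/mean member
    confidence, inference count, dual-axis presence, and distance from the
    cluster centroid to the top and bottom of the scan in mm."""

    max_conf: float
    mean_conf: float
    n_inferences: int
    has_both_axes: bool
    dist_top_mm: float
    dist_bottom_mm: float

    def __post_init__(self) -> None:
        if self.max_conf < self.mean_conf - 1e-12:
            raise ValueError("max_conf must be >= mean_conf")


FEATURE_NAMES = ("max_conf", "mean_conf", "n_inferences", "has_both_axes",
                 "dist_top_mm", "dist_bottom_mm")


@dataclass(frozen=True)
class NoduleCandidate:
    """A DBSCAN cluster summarized into one nodule candidate.

    The centroid (coordinate-wise mean of member centres) is the predicted
    nodule position; the bounding diameter is the largest member box diameter
    — deliberately an envelope, not a size estimate, and in practice roughly
    twice the true nodule diameter.  ``score`` is the false-positive reducer's
    probability and stays ``None`` until scoring runs.
    """

    candidate_id: int
    scan_id: str
    members: tuple[Detection3D, ...]
    centroid_mm: tuple[float, float, float]
    bounding_diameter_mm: float
    features: ClusterFeatures
    score: float | None = None


def lift_to_3d(detections: Sequence[Detection2D]) -> list[Detection3D]:
    """Embed 2D detections into world (x, y, z) mm, preserving order."""
    lifted: list[Detection3D] = []
    for d in detections:
        if d.axis == "axial":
            center = (d.center_u_mm, d.center_v_mm, d.slice_pos_mm)
        else:
            center = (d.center_u_mm, d.slice_pos_mm, d.center_v_mm)
        lifted.append(Detection3D(
            source=d, center_mm=center,
            diameter_mm=max(d.width_mm, d.height_mm),
            confidence=d.confidence, axis=d.axis,
        ))
    return lifted


def filter_low_confidence(detections: Sequence[Detection3D],
                          config: ClusteringConfig | None = None) -> list[Detection3D]:
    """Drop detections with confidence strictly below the threshold
    (a confidence of exactly ``min_confidence`` is kept)."""
    config = config or ClusteringConfig()
    return [d for d in detections if d.confidence >= config.min_confidence]


def cluster_detections(
    detections: Sequence[Detection3D],
    config: ClusteringConfig | None = None,
) -> tuple[list[list[Detection3D]], list[Detection3D]]:
    """DBSCAN in world mm: returns ``(clusters, noise)``.

    Standard DBSCAN semantics on Euclidean distance between detection
    centres: a core point has at least ``min_samples`` neighbours within
    ``eps_mm`` (itself included); clusters are maximal density-connected
    sets; everything else is noise.  Border points reachable from several
    clusters go to the cluster discovered first in input order (the classic
    single-pass policy), which makes the output deterministic.  Cluster order
    follows discovery order; member order follows input order.
    """
    config = config or ClusteringConfig()
    if not detections:
        return [], []
    scan_ids = {d.source.scan_id for d in detections}
    if len(scan_ids) > 1:
        raise ValueError(f"detections span multiple scans: {sorted(scan_ids)}")
    centers = np.asarray([d.center_mm for d in detections], dtype=float)
    labels = DBSCAN(eps=config.eps_mm, min_samples=config.min_samples,
                    metric="euclidean").fit_predict(centers)
    n_clusters = labels.max() + 1 if labels.size else 0
    clusters: list[list[Detection3D]] = [[] for _ in range(n_clusters)]
    noise: list[Detection3D] = []
    for det, label in zip(detections, labels):
        if label == -1:
            noise.append(det)
        else:
            clusters[label].append(det)
    return clusters, noise


def summarize_cluster(cluster: Sequence[Detection3D], geometry: ScanGeometry,
                      candidate_id: int = 0) -> NoduleCandidate:
    """Summarize a cluster: centroid = mean of member centres, bounding
    diameter = max member diameter, plus the metadata features."""
    if not cluster:
        raise ValueError("cannot summarize an empty cluster")
    centers = np.asarray([d.center_mm for d in cluster], dtype=float)
    confs = np.asarray([d.confidence for d in cluster], dtype=float)
    centroid = tuple(float(v) for v in centers.mean(axis=0))
    axes_present = {d.axis for d in cluster}
    features = ClusterFeatures(
        max_conf=float(confs.max()),
        mean_conf=float(confs.mean()),
        n_inferences=len(cluster),
        has_both_axes=axes_present == {"axial", "coronal"},
        dist_top_mm=float(geometry.z_max_mm - centroid[2]),
        dist_bottom_mm=float(centroid[2] - geometry.z_min_mm),
    )
    return NoduleCandidate(
        candidate_id=candidate_id,
        scan_id=cluster[0].source.scan_id,
        members=tuple(cluster),
        centroid_mm=centroid,
        bounding_diameter_mm=float(max(d.diameter_mm for d in cluster)),
        features=features,
        score=None,
    )


def candidates_from_detections(
    detections: Sequence[Detection2D],
    geometry: ScanGeometry,
    config: ClusteringConfig | None = None,
    first_candidate_id: int = 0,
) -> list[NoduleCandidate]:
    """Full aggregation for one scan: lift -> confidence filter -> DBSCAN ->
    summarize.  Noise detections are discarded, not emitted as candidates."""
    config = config or ClusteringConfig()
    lifted = filter_low_confidence(lift_to_3d(detections), config)
    clusters, _ = cluster_detections(lifted, config)
    return [
        summarize_cluster(cluster, geometry, candidate_id=first_candidate_id + i)
        for i, cluster in enumerate(clusters)
    ]


def with_score(candidate: NoduleCandidate, score: float) -> NoduleCandidate:
    return replace(candidate, score=float(score))
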