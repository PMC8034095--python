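"""Axial-slice-assisted selection of the final nodule prediction.

Radiology reports record the axial slice on which a nodule was seen.  Given
that position, selection drops low-confidence candidates (final score below
0.20 by default) and returns the remaining candidate closest in z within a
fixed window (10 mm by default, 20 mm as the sensitive alternative) — or
nothing, which downstream evaluation counts as a miss.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .clustering import NoduleCandidate


@dataclass(frozen=True)
class SliceQuery:
    """One report-derived lookup: scan, target axial position, and the
    selection parameters.

    ``intended_nodule_id`` identifies which ground-truth nodule the report
    refers to (synthetic/evaluation use only).  ``target_xy_mm`` optionally
    carries an in-plane position so that selection can use full 3D distance;
    reports normally constrain only the axial slice, so it defaults to None.
    """

    scan_id: str
    target_z_mm: float
    intended_nodule_id: str | None = None
    window_mm: float = 10.0
    min_score: float = 0.20
    target_xy_mm: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.window_mm > 0:
            raise ValueError("window_mm must be > 0")
        if not 0.0 <= self.min_score <= 1.0:
            raise ValueError("min_score must lie in [0, 1]")


def _query_distance(cand: NoduleCandidate, query: SliceQuery, use_3d: bool) -> float:
    dz = cand.centroid_mm[2] - query.target_z_mm
    if use_3d:
        if query.target_xy_mm is None:
            raise ValueError("3D distance requires query.target_xy_mm")
        dx = cand.centroid_mm[0] - query.target_xy_mm[0]
        dy = cand.centroid_mm[1] - query.target_xy_mm[1]
        return float(np.sqrt(dx * dx + dy * dy + dz * dz))
    return abs(dz)


def select_candidate(
    candidates: Sequence[NoduleCandidate],
    query: SliceQuery,
    use_3d_distance: bool = False,
) -> NoduleCandidate | None:
    """Select the closest sufficiently confident candidate near the target z.

    Candidates scoring below ``query.min_score`` are dropped as low-confidence
    false positives.  Among the rest, the one minimizing |centroid_z −
    target_z| is returned, provided that distance is within
    ``query.window_mm``; otherwise ``None``.  Distance is measured along z
    only by default (the report constrains only the slice position);
    ``use_3d_distance`` switches to Euclidean distance against
    ``query.target_xy_mm`` + ``target_z_mm`` for sensitivity analysis.

    Ties in distance are broken by higher score, then lower candidate id, so
    the result is deterministic.
    """
    best: tuple[float, float, int] | None = None
    best_cand: NoduleCandidate | None = None
    for cand in candidates:
        if cand.scan_id != query.scan_id:
            raise ValueError(
                f"candidate scan {cand.scan_id!r} does not match query {query.scan_id!r}"
            )
        if cand.score is None:
            raise ValueError("candidates must be scored before selection")
        if cand.score < query.min_score:
            continue
        dist = _query_distance(cand, query, use_3d_distance)
        if dist > query.window_mm:
            continue
        key = (dist, -cand.score, cand.candidate_id)
        if best is None or key < best:
            best, best_cand = key, cand
    return best_cand


def slice_number_to_z(
    slice_index: int,
    slice_thickness_mm: float,
    origin_z_mm: float,
    ordering: str = "inferior_first",
    extent_mm: float | None = None,
) -> float:
    """Convert a report's axial slice index to a world z position in mm.

    ``inferior_first`` scans count slices from the lowest z upward
    (z = origin + index * thickness); ``superior_first`` count down from the
    top of the scan (z = origin + extent − index * thickness, requiring
    ``extent_mm``).  Raises if the result falls outside the scan.
    """
    if slice_index < 0:
        raise ValueError("slice_index must be >= 0")
    if ordering == "inferior_first":
        z = origin_z_mm + slice_index * slice_thickness_mm
    elif ordering == "superior_first":
        if extent_mm is None:
            raise ValueError("superior_first ordering requires extent_mm")
        z = origin_z_mm + extent_mm - slice_index * slice_thickness_mm
    else:
        raise ValueError(f"unknown ordering {ordering!r}")
    if extent_mm is not None and not (origin_z_mm - 1e-9 <= z <= origin_z_mm + extent_mm + 1e-9):
        raise ValueError(
            f"slice {slice_index} maps to z={z} mm, outside "
            f"[{origin_z_mm}, {origin_z_mm + extent_mm}]"
        )
    return float(z)
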