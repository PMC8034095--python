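"""The 2D detector contract and a non-learned baseline blob detector.

The clustering/reduction/selection stages consume plain ``Detection2D``
records, so any detector that can emit the detections CSV plugs into the
pipeline — a neural object detector run elsewhere, the baseline blob detector
below, or the seeded simulator in :mod:`nodulecad.phantom`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from skimage import measure

from .io import Detection2D, read_detections
from .preprocess import MipStack

#: HU span over which the baseline detector's confidence ramps from 0 to 1.
CONFIDENCE_HU_SCALE = 500.0


def detect_blobs(stack: MipStack, hu_threshold: float = -300.0,
                 min_diameter_mm: float = 3.0,
                 max_diameter_mm: float = 30.0) -> list[Detection2D]:
    """Detect bright blobs on each MIP slice by threshold + connected components.

    Per slice: binarize at ``hu_threshold``, label 8-connected components, and
    keep those whose equivalent diameter lies in
    ``[min_diameter_mm, max_diameter_mm]``.  The detection box is the
    component's bounding box in world mm; confidence is the component's mean
    HU above threshold scaled by ``CONFIDENCE_HU_SCALE`` and clipped to [0, 1].
    Fully deterministic.

    This is a geometric stand-in for a learned detector, intended for
    end-to-end desk-scale runs; its confidence mapping exists only to exercise
    the downstream confidence logic.
    """
    if min_diameter_mm >= max_diameter_mm:
        raise ValueError("min_diameter_mm must be < max_diameter_mm")
    su, sv = stack.in_plane_spacing_mm
    ou, ov = stack.in_plane_origin_mm
    detections: list[Detection2D] = []
    for pos, image in zip(stack.slice_pos_mm, stack.slices):
        mask = image > hu_threshold
        if not mask.any():
            continue
        labels = measure.label(mask, connectivity=2)
        for region in measure.regionprops(labels, intensity_image=image):
            eq_diam = region.equivalent_diameter_area * su
            if not (min_diameter_mm <= eq_diam <= max_diameter_mm):
                continue
            rmin, cmin, rmax, cmax = region.bbox   # rows = v, cols = u
            width = (cmax - cmin) * su
            height = (rmax - rmin) * sv
            center_u = ou + (cmin + cmax - 1) / 2.0 * su
            center_v = ov + (rmin + rmax - 1) / 2.0 * sv
            conf = (region.intensity_mean - hu_threshold) / CONFIDENCE_HU_SCALE
            detections.append(Detection2D(
                scan_id=stack.scan_id, axis=stack.axis, slice_pos_mm=float(pos),
                center_u_mm=float(center_u), center_v_mm=float(center_v),
                width_mm=float(width), height_mm=float(height),
                confidence=float(np.clip(conf, 0.0, 1.0)),
            ))
    return detections


def adapt_external(path: str | Path) -> tuple[list[Detection2D], list[tuple[int, str]]]:
    """Ingest an externally produced detections CSV, tolerating bad rows.

    Returns ``(detections, rejected)`` where ``rejected`` lists
    ``(row_number, reason)`` for rows violating the detection invariants.
    A file whose header does not match the schema raises.
    """
    import csv

    from .io import DETECTION_COLUMNS

    path = Path(path)
    detections: list[Detection2D] = []
    rejected: list[tuple[int, str]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(DETECTION_COLUMNS).issubset(reader.fieldnames):
            raise ValueError(
                f"{path.name}: expected columns {DETECTION_COLUMNS}, got {reader.fieldnames}"
            )
        for i, row in enumerate(reader, start=2):
            try:
                detections.append(Detection2D(
                    scan_id=row["scan_id"], axis=row["axis"],
                    slice_pos_mm=float(row["slice_pos_mm"]),
                    center_u_mm=float(row["center_u_mm"]),
                    center_v_mm=float(row["center_v_mm"]),
                    width_mm=float(row["width_mm"]),
                    height_mm=float(row["height_mm"]),
                    confidence=float(row["confidence"]),
                ))
            except ValueError as exc:
                rejected.append((i, str(exc)))
    return detections, rejected
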