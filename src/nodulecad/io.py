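"""Volume, annotation, detection and candidate I/O, plus world<->voxel geometry.

Conventions used throughout the package
---------------------------------------
* Voxel arrays are indexed ``(z, y, x)`` (the order SimpleITK/NumPy hand back).
* ``origin_mm`` and ``spacing_mm`` are ``(x, y, z)`` tuples in the LPS world
  frame, as in LUNA MetaImage headers.
* World coordinates are continuous millimetres; voxel indices are 0-based,
  with index ``(0, 0, 0)``'s centre at ``origin_mm``.
* Only axis-aligned volumes are accepted: direction matrices other than the
  identity are rejected rather than silently resampled.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import SimpleITK as sitk

ATTENUATION_CLASSES = ("soft_tissue", "ground_glass", "mixed", "calcified", "unknown")
AXES = ("axial", "coronal")

DETECTION_COLUMNS = [
    "scan_id",
    "axis",
    "slice_pos_mm",
    "center_u_mm",
    "center_v_mm",
    "width_mm",
    "height_mm",
    "confidence",
]

CANDIDATE_COLUMNS = [
    "candidate_id",
    "scan_id",
    "x_mm",
    "y_mm",
    "z_mm",
    "bounding_diameter_mm",
    "max_conf",
    "mean_conf",
    "n_inferences",
    "has_both_axes",
    "dist_top_mm",
    "dist_bottom_mm",
    "score",
]


@dataclass(frozen=True)
class CtVolume:
    """A 3D CT grid in Hounsfield units with its world geometry.

    ``voxels`` is indexed ``(z, y, x)``; ``origin_mm``/``spacing_mm`` are
    ``(x, y, z)``.
    """

    voxels: np.ndarray
    origin_mm: tuple[float, float, float]
    spacing_mm: tuple[float, float, float]
    scan_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3 or min(v.shape) < 1:
            raise ValueError("voxels must be a non-empty 3D array")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        if not np.all(np.isfinite(v)):
            raise ValueError("HU values must be finite")

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return tuple(self.voxels.shape)  # type: ignore[return-value]

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical extent (x, y, z): number of voxels times spacing."""
        nz, ny, nx = self.voxels.shape
        sx, sy, sz = self.spacing_mm
        return (nx * sx, ny * sy, nz * sz)

    @property
    def geometry(self) -> "ScanGeometry":
        return ScanGeometry(origin_mm=self.origin_mm, extent_mm=self.extent_mm,
                            scan_id=self.scan_id)


@dataclass(frozen=True)
class ScanGeometry:
    """World-space bounding box of a scan, without the voxel payload.

    Sufficient for cluster metadata (distance to scan top/bottom) and for
    detection simulation; ``CtVolume.geometry`` derives one from a volume.
    """

    origin_mm: tuple[float, float, float]
    extent_mm: tuple[float, float, float]
    scan_id: str = ""

    @property
    def z_min_mm(self) -> float:
        return self.origin_mm[2]

    @property
    def z_max_mm(self) -> float:
        return self.origin_mm[2] + self.extent_mm[2]


@dataclass(frozen=True)
class NoduleAnnotation:
    """Ground-truth nodule: world centre, diameter and attenuation class."""

    nodule_id: str
    scan_id: str
    center_mm: tuple[float, float, float]
    diameter_mm: float
    attenuation: str = "unknown"

    def __post_init__(self) -> None:
        if not self.diameter_mm > 0:
            raise ValueError(f"diameter must be > 0, got {self.diameter_mm}")
        if self.attenuation not in ATTENUATION_CLASSES:
            raise ValueError(f"unknown attenuation class {self.attenuation!r}")
        if not all(np.isfinite(self.center_mm)):
            raise ValueError("nodule centre must be finite")


@dataclass(frozen=True)
class Detection2D:
    """One raw detector inference on a single MIP slice.

    ``slice_pos_mm`` is the world position of the slice's projection-window
    centre along the projection axis.  In-plane coordinates: axial slices use
    ``(u, v) = (x, y)``; coronal slices use ``(u, v) = (x, z)``.
    """

    scan_id: str
    axis: str
    slice_pos_mm: float
    center_u_mm: float
    center_v_mm: float
    width_mm: float
    height_mm: float
    confidence: float

    def __post_init__(self) -> None:
        if self.axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}, got {self.axis!r}")
        if not (self.width_mm > 0 and self.height_mm > 0):
            raise ValueError("detection box must have positive width and height")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must lie in [0, 1], got {self.confidence}")
        for v in (self.slice_pos_mm, self.center_u_mm, self.center_v_mm):
            if not np.isfinite(v):
                raise ValueError("detection coordinates must be finite")


def _check_axis_aligned(image: sitk.Image) -> None:
    direction = np.asarray(image.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise ValueError(
            "only axis-aligned volumes are supported; "
            f"direction matrix is {direction.tolist()}"
        )


def read_volume(path: str | Path, scan_id: str | None = None) -> CtVolume:
    """Read a MetaImage (.mhd/.raw) or NIfTI (.nii/.nii.gz) volume.

    The returned array is indexed ``(z, y, x)``; origin and spacing come from
    the header as ``(x, y, z)``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() not in {".mhd", ".mha", ".nii"} and not path.name.endswith(".nii.gz"):
        raise ValueError(f"unsupported volume format: {path.name}")
    image = sitk.ReadImage(str(path))
    _check_axis_aligned(image)
    voxels = sitk.GetArrayFromImage(image).astype(np.float32)
    return CtVolume(
        voxels=voxels,
        origin_mm=tuple(image.GetOrigin()),
        spacing_mm=tuple(image.GetSpacing()),
        scan_id=scan_id if scan_id is not None else path.name.split(".")[0],
    )


def write_volume(volume: CtVolume, path: str | Path) -> None:
    """Write a volume as MetaImage or NIfTI, chosen by file extension."""
    image = sitk.GetImageFromArray(np.asarray(volume.voxels, dtype=np.float32))
    image.SetOrigin(tuple(float(v) for v in volume.origin_mm))
    image.SetSpacing(tuple(float(v) for v in volume.spacing_mm))
    sitk.WriteImage(image, str(path))


def world_to_voxel(volume: CtVolume | ScanGeometry, point_mm: Sequence[float],
                   spacing_mm: Sequence[float] | None = None) -> tuple[float, float, float]:
    """Map a world point (x, y, z) mm to a continuous voxel index (z, y, x).

    Exact inverse of :func:`voxel_to_world`.  Points outside the grid are
    allowed and simply produce out-of-range indices.
    """
    origin = np.asarray(volume.origin_mm, dtype=float)
    spacing = np.asarray(
        spacing_mm if spacing_mm is not None else volume.spacing_mm, dtype=float
    )
    idx_xyz = (np.asarray(point_mm, dtype=float) - origin) / spacing
    return (idx_xyz[2], idx_xyz[1], idx_xyz[0])


def voxel_to_world(volume: CtVolume | ScanGeometry, index_zyx: Sequence[float],
                   spacing_mm: Sequence[float] | None = None) -> tuple[float, float, float]:
    """Map a continuous voxel index (z, y, x) to world (x, y, z) mm."""
    origin = np.asarray(volume.origin_mm, dtype=float)
    spacing = np.asarray(
        spacing_mm if spacing_mm is not None else volume.spacing_mm, dtype=float
    )
    idx_xyz = np.asarray(index_zyx, dtype=float)[::-1]
    world = origin + idx_xyz * spacing
    return (world[0], world[1], world[2])


def read_annotations(path: str | Path) -> list[NoduleAnnotation]:
    """Read a LUNA-dialect annotation CSV.

    Required columns: ``seriesuid, coordX, coordY, coordZ, diameter_mm``.
    Optional columns ``nodule_id`` and ``attenuation`` are preserved; missing
    nodule ids default to ``<seriesuid>-n<row>``.
    """
    path = Path(path)
    annotations: list[NoduleAnnotation] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"seriesuid", "coordX", "coordY", "coordZ", "diameter_mm"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(
                f"{path.name}: expected LUNA columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for i, row in enumerate(reader, start=2):  # header is line 1
            try:
                center = (float(row["coordX"]), float(row["coordY"]), float(row["coordZ"]))
                diameter = float(row["diameter_mm"])
                if not all(np.isfinite(center)) or not np.isfinite(diameter):
                    raise ValueError("non-finite coordinate")
                annotations.append(NoduleAnnotation(
                    nodule_id=row.get("nodule_id") or f"{row['seriesuid']}-n{i}",
                    scan_id=row["seriesuid"],
                    center_mm=center,
                    diameter_mm=diameter,
                    attenuation=row.get("attenuation") or "unknown",
                ))
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path.name}, row {i}: {exc}") from exc
    return annotations


def write_annotations(annotations: Iterable[NoduleAnnotation], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["seriesuid", "coordX", "coordY", "coordZ", "diameter_mm",
                         "nodule_id", "attenuation"])
        for a in annotations:
            writer.writerow([a.scan_id, repr(a.center_mm[0]), repr(a.center_mm[1]),
                             repr(a.center_mm[2]), repr(a.diameter_mm),
                             a.nodule_id, a.attenuation])


def read_detections(path: str | Path) -> list[Detection2D]:
    """Read a detections CSV; any invalid row raises with its row number."""
    path = Path(path)
    detections: list[Detection2D] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(DETECTION_COLUMNS).issubset(reader.fieldnames):
            raise ValueError(
                f"{path.name}: expected columns {DETECTION_COLUMNS}, got {reader.fieldnames}"
            )
        for i, row in enumerate(reader, start=2):
            try:
                detections.append(Detection2D(
                    scan_id=row["scan_id"],
                    axis=row["axis"],
                    slice_pos_mm=float(row["slice_pos_mm"]),
                    center_u_mm=float(row["center_u_mm"]),
                    center_v_mm=float(row["center_v_mm"]),
                    width_mm=float(row["width_mm"]),
                    height_mm=float(row["height_mm"]),
                    confidence=float(row["confidence"]),
                ))
            except ValueError as exc:
                raise ValueError(f"{path.name}, row {i}: {exc}") from exc
    return detections


def write_detections(detections: Iterable[Detection2D], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(DETECTION_COLUMNS)
        for d in detections:
            writer.writerow([d.scan_id, d.axis, repr(d.slice_pos_mm),
                             repr(d.center_u_mm), repr(d.center_v_mm),
                             repr(d.width_mm), repr(d.height_mm), repr(d.confidence)])


def write_candidates(candidates: Iterable["NoduleCandidate"], path: str | Path) -> None:
    """Write candidate clusters with their metadata features and final score."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CANDIDATE_COLUMNS)
        for c in candidates:
            f = c.features
            writer.writerow([
                c.candidate_id, c.scan_id,
                repr(c.centroid_mm[0]), repr(c.centroid_mm[1]), repr(c.centroid_mm[2]),
                repr(c.bounding_diameter_mm),
                repr(f.max_conf), repr(f.mean_conf), f.n_inferences,
                int(f.has_both_axes), repr(f.dist_top_mm), repr(f.dist_bottom_mm),
                "" if c.score is None else repr(c.score),
            ])


def read_candidates(path: str | Path) -> list["NoduleCandidate"]:
    """Read candidates written by :func:`write_candidates` (members are not
    round-tripped; the summary record is)."""
    from .clustering import ClusterFeatures, NoduleCandidate

    path = Path(path)
    out: list[NoduleCandidate] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(CANDIDATE_COLUMNS).issubset(reader.fieldnames):
            raise ValueError(f"{path.name}: expected columns {CANDIDATE_COLUMNS}")
        for i, row in enumerate(reader, start=2):
            try:
                features = ClusterFeatures(
                    max_conf=float(row["max_conf"]),
                    mean_conf=float(row["mean_conf"]),
                    n_inferences=int(row["n_inferences"]),
                    has_both_axes=bool(int(row["has_both_axes"])),
                    dist_top_mm=float(row["dist_top_mm"]),
                    dist_bottom_mm=float(row["dist_bottom_mm"]),
                )
                out.append(NoduleCandidate(
                    candidate_id=int(row["candidate_id"]),
                    scan_id=row["scan_id"],
                    members=(),
                    centroid_mm=(float(row["x_mm"]), float(row["y_mm"]), float(row["z_mm"])),
                    bounding_diameter_mm=float(row["bounding_diameter_mm"]),
                    features=features,
                    score=float(row["score"]) if row["score"] not in ("", None) else None,
                ))
            except ValueError as exc:
                raise ValueError(f"{path.name}, row {i}: {exc}") from exc
    return out
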