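"""Seeded synthetic chest-CT phantoms and a raw-detection simulator.

The phantom emulates the features of a screening CT that drive this
pipeline's behaviour: lung fields at low attenuation inside a soft-tissue
body, tubular vessels — including ones running along a projection axis,
which mimic nodules on that axis's MIP only — and spherical nodules of
several attenuation classes.

The detection simulator mimics the statistics of a 2D detector run on
overlapping MIP stacks, without rendering or detecting anything: a real
nodule is visible on every slice whose 25 mm window covers it, so it yields a
dense swarm of detections on both axes; a perpendicular-vessel confounder
yields a sparse single-axis chain; background scatter yields isolated
low-confidence hits.  Everything is driven by a single seed, so downstream
stages can be stress-tested deterministically and independently of detector
quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io import (ATTENUATION_CLASSES, CtVolume, Detection2D, NoduleAnnotation,
                 ScanGeometry)

#: HU painted for each nodule attenuation class.
ATTENUATION_HU = {
    "soft_tissue": 60.0,
    "ground_glass": -500.0,
    "mixed": -200.0,
    "calcified": 400.0,
    "unknown": 60.0,
}

VESSEL_ORIENTATIONS = ("axial_perpendicular", "coronal_perpendicular", "random_walk")


@dataclass(frozen=True)
class PhantomNodule:
    center_mm: tuple[float, float, float]
    diameter_mm: float
    attenuation: str = "soft_tissue"


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and content of one synthetic scan.

    Defaults render a 200 mm cube at 2 mm voxels (kept coarse so a phantom
    renders in well under a second): an ellipsoidal lung field at −850 HU
    inside a 40 HU body, with air at −1000 HU outside, plus vessels and
    nodules painted by HU and additive Gaussian noise on top.
    """

    shape_mm: tuple[float, float, float] = (200.0, 200.0, 200.0)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    lung_center_mm: tuple[float, float, float] = (100.0, 100.0, 100.0)
    lung_semiaxes_mm: tuple[float, float, float] = (80.0, 70.0, 85.0)
    lung_hu: float = -850.0
    body_hu: float = 40.0
    air_hu: float = -1000.0
    n_vessels: int = 6
    vessel_radius_range_mm: tuple[float, float] = (1.5, 4.0)
    vessel_hu: float = 50.0
    vessel_orientations: tuple[str, ...] = VESSEL_ORIENTATIONS
    nodules: tuple[PhantomNodule, ...] = ()
    noise_sigma_hu: float = 20.0
    seed: int = 0
    scan_id: str = "phantom"

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_mm) or any(e <= 0 for e in self.shape_mm):
            raise ValueError("shape and spacing must be positive")
        for o in self.vessel_orientations:
            if o not in VESSEL_ORIENTATIONS:
                raise ValueError(f"unknown vessel orientation {o!r}")
        for nod in self.nodules:
            if nod.diameter_mm <= 0:
                raise ValueError("nodule diameters must be > 0")
            if nod.attenuation not in ATTENUATION_CLASSES:
                raise ValueError(f"unknown attenuation {nod.attenuation!r}")

    @property
    def geometry(self) -> ScanGeometry:
        return ScanGeometry(origin_mm=self.origin_mm, extent_mm=self.shape_mm,
                            scan_id=self.scan_id)


def _inside_lung(spec: PhantomSpec, point_mm: Sequence[float],
                 margin_mm: float = 0.0) -> bool:
    rel = (np.asarray(point_mm) - np.asarray(spec.lung_center_mm)) / (
        np.asarray(spec.lung_semiaxes_mm) - margin_mm)
    return float(np.sum(rel ** 2)) <= 1.0


def _world_grids(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[int, int, int]]:
    sx, sy, sz = spec.spacing_mm
    ex, ey, ez = spec.shape_mm
    nx, ny, nz = (int(round(ex / sx)), int(round(ey / sy)), int(round(ez / sz)))
    ox, oy, oz = spec.origin_mm
    zs = oz + np.arange(nz) * sz
    ys = oy + np.arange(ny) * sy
    xs = ox + np.arange(nx) * sx
    return zs, ys, xs, (nz, ny, nx)


def _paint_sphere(voxels: np.ndarray, zs: np.ndarray, ys: np.ndarray,
                  xs: np.ndarray, center_mm: Sequence[float], radius_mm: float,
                  hu: float) -> None:
    cx, cy, cz = center_mm
    dz2 = (zs - cz)[:, None, None] ** 2
    dy2 = (ys - cy)[None, :, None] ** 2
    dx2 = (xs - cx)[None, None, :] ** 2
    voxels[dz2 + dy2 + dx2 <= radius_mm ** 2] = hu


def generate_phantom(spec: PhantomSpec) -> tuple[CtVolume, list[NoduleAnnotation]]:
    """Render a phantom volume and return it with its ground-truth annotations.

    Painting order: air background, body ellipsoid, lung ellipsoid, vessels,
    nodules, then additive Gaussian noise (``noise_sigma_hu``).  Nodules must
    lie inside the lung field and must not overlap each other.  Deterministic:
    the same spec (including seed) yields a bit-identical volume.
    """
    for nod in spec.nodules:
        if not _inside_lung(spec, nod.center_mm, margin_mm=nod.diameter_mm / 2.0):
            raise ValueError(f"nodule at {nod.center_mm} is not inside the lung field")
    for i, a in enumerate(spec.nodules):
        for b in spec.nodules[i + 1:]:
            gap = float(np.linalg.norm(np.subtract(a.center_mm, b.center_mm)))
            if gap < (a.diameter_mm + b.diameter_mm) / 2.0:
                raise ValueError(f"nodules at {a.center_mm} and {b.center_mm} overlap")

    rng = np.random.default_rng(spec.seed)
    zs, ys, xs, shape = _world_grids(spec)
    voxels = np.full(shape, spec.air_hu, dtype=np.float32)

    # Body: an ellipsoid 10% larger than the lung field in-plane, full z extent.
    body_semi = (spec.lung_semiaxes_mm[0] * 1.15, spec.lung_semiaxes_mm[1] * 1.15)
    bx = ((xs - spec.lung_center_mm[0]) / body_semi[0]) ** 2
    by = ((ys - spec.lung_center_mm[1]) / body_semi[1]) ** 2
    voxels[:, (by[:, None] + bx[None, :]) <= 1.0] = spec.body_hu

    lz = ((zs - spec.lung_center_mm[2]) / spec.lung_semiaxes_mm[2]) ** 2
    ly = ((ys - spec.lung_center_mm[1]) / spec.lung_semiaxes_mm[1]) ** 2
    lx = ((xs - spec.lung_center_mm[0]) / spec.lung_semiaxes_mm[0]) ** 2
    lung = (lz[:, None, None] + ly[None, :, None] + lx[None, None, :]) <= 1.0
    voxels[lung] = spec.lung_hu

    for _ in range(spec.n_vessels):
        orientation = spec.vessel_orientations[
            rng.integers(0, len(spec.vessel_orientations))]
        radius = rng.uniform(*spec.vessel_radius_range_mm)
        start = np.asarray(spec.lung_center_mm) + rng.uniform(-0.5, 0.5, 3) * (
            np.asarray(spec.lung_semiaxes_mm))
        if orientation == "axial_perpendicular":      # runs along z
            direction = np.array([0.0, 0.0, 1.0])
        elif orientation == "coronal_perpendicular":  # runs along y
            direction = np.array([0.0, 1.0, 0.0])
        else:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
        length = rng.uniform(40.0, 120.0)
        step = min(spec.spacing_mm) / 2.0
        point = start - direction * length / 2.0
        for _ in range(int(length / step)):
            if orientation == "random_walk":
                direction = direction + rng.normal(scale=0.08, size=3)
                direction /= np.linalg.norm(direction)
            point = point + direction * step
            if _inside_lung(spec, point, margin_mm=radius):
                _paint_sphere(voxels, zs, ys, xs, point, radius, spec.vessel_hu)

    annotations: list[NoduleAnnotation] = []
    for i, nod in enumerate(spec.nodules):
        _paint_sphere(voxels, zs, ys, xs, nod.center_mm, nod.diameter_mm / 2.0,
                      ATTENUATION_HU[nod.attenuation])
        annotations.append(NoduleAnnotation(
            nodule_id=f"{spec.scan_id}-n{i}", scan_id=spec.scan_id,
            center_mm=nod.center_mm, diameter_mm=nod.diameter_mm,
            attenuation=nod.attenuation,
        ))

    if spec.noise_sigma_hu > 0:
        voxels = voxels + rng.normal(
            scale=spec.noise_sigma_hu, size=voxels.shape).astype(np.float32)

    volume = CtVolume(voxels=voxels.astype(np.float32), origin_mm=spec.origin_mm,
                      spacing_mm=spec.spacing_mm, scan_id=spec.scan_id)
    return volume, annotations


@dataclass(frozen=True)
class DetectionNoiseModel:
    """Stochastic model of a 2D detector's raw inferences on MIP stacks.

    A true nodule of diameter d is MIP-visible over roughly d + window mm
    along each projection axis; the simulator draws a Poisson number of
    detections per axis at ``rate_per_mm`` over that extent, scatters their
    slice positions uniformly within it, jitters in-plane positions with
    Gaussian noise, and samples confidences from a clipped normal.  With
    probability ``1 − dual_axis_prob`` a nodule fires on a single axis only.

    Confounders: per scan, a Poisson number of single-axis vessel chains
    (each a short dense run of moderate-confidence detections — the
    perpendicular-vessel failure mode) and uniform low-confidence scatter.
    """

    rate_per_mm: float = 0.4
    dual_axis_prob: float = 0.9
    position_jitter_sigma_mm: float = 1.5
    conf_mean: float = 0.65
    conf_sigma: float = 0.15
    box_scale_range: tuple[float, float] = (1.0, 2.0)
    mip_window_mm: float = 25.0
    chain_rate_per_scan: float = 2.0
    chain_mean_extra_len: float = 4.0
    chain_min_len: int = 3
    chain_span_mm: float = 14.0
    chain_conf_mean: float = 0.5
    chain_conf_sigma: float = 0.2
    chain_box_range_mm: tuple[float, float] = (3.0, 8.0)
    scatter_rate_per_scan: float = 30.0
    scatter_conf_max: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rate_per_mm", "chain_rate_per_scan", "scatter_rate_per_scan",
                     "position_jitter_sigma_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.dual_axis_prob <= 1.0:
            raise ValueError("dual_axis_prob must lie in [0, 1]")


def _axis_coords(axis: str, point: Sequence[float]) -> tuple[float, float, float]:
    """(slice_pos, u, v) of a world point on the given stack axis."""
    x, y, z = point
    return (z, x, y) if axis == "axial" else (y, x, z)


def simulate_detections(
    annotations: Sequence[NoduleAnnotation],
    geometry: ScanGeometry,
    model: DetectionNoiseModel,
) -> tuple[list[Detection2D], list[str]]:
    """Simulate raw 2D detections for one scan.

    Returns ``(detections, fired_axes)`` where ``fired_axes[i]`` records
    whether annotation i fired on ``"both"`` axes, ``"axial"``, ``"coronal"``
    or ``"none"`` (useful for conditioning evaluation on dual-axis nodules).
    Deterministic given ``model.seed``.
    """
    rng = np.random.default_rng(model.seed)
    detections: list[Detection2D] = []
    fired: list[str] = []
    ox, oy, oz = geometry.origin_mm
    ex, ey, ez = geometry.extent_mm

    for ann in annotations:
        both = rng.random() < model.dual_axis_prob
        if both:
            axes = ["axial", "coronal"]
        else:
            axes = ["axial" if rng.random() < 0.5 else "coronal"]
        visible = ann.diameter_mm + model.mip_window_mm
        fired_axes: list[str] = []
        for axis in axes:
            n = rng.poisson(model.rate_per_mm * visible)
            if n == 0:
                continue
            fired_axes.append(axis)
            c_axis, cu, cv = _axis_coords(axis, ann.center_mm)
            for _ in range(n):
                pos = c_axis + rng.uniform(-visible / 2.0, visible / 2.0)
                u = cu + rng.normal(scale=model.position_jitter_sigma_mm)
                v = cv + rng.normal(scale=model.position_jitter_sigma_mm)
                conf = float(np.clip(rng.normal(model.conf_mean, model.conf_sigma),
                                     0.01, 1.0))
                size = ann.diameter_mm * rng.uniform(*model.box_scale_range)
                detections.append(Detection2D(
                    scan_id=geometry.scan_id, axis=axis, slice_pos_mm=float(pos),
                    center_u_mm=float(u), center_v_mm=float(v),
                    width_mm=float(size), height_mm=float(size * rng.uniform(0.8, 1.2)),
                    confidence=conf,
                ))
        if len(fired_axes) == 2:
            fired.append("both")
        elif fired_axes:
            fired.append(fired_axes[0])
        else:
            fired.append("none")

    # Vessel confounder chains: dense single-axis runs of moderate confidence.
    n_chains = rng.poisson(model.chain_rate_per_scan)
    for _ in range(n_chains):
        axis = "axial" if rng.random() < 0.5 else "coronal"
        center = (ox + rng.uniform(0.25, 0.75) * ex,
                  oy + rng.uniform(0.25, 0.75) * ey,
                  oz + rng.uniform(0.25, 0.75) * ez)
        c_axis, cu, cv = _axis_coords(axis, center)
        n = model.chain_min_len + rng.poisson(model.chain_mean_extra_len)
        for _ in range(n):
            pos = c_axis + rng.uniform(-model.chain_span_mm / 2.0,
                                       model.chain_span_mm / 2.0)
            size = rng.uniform(*model.chain_box_range_mm)
            detections.append(Detection2D(
                scan_id=geometry.scan_id, axis=axis, slice_pos_mm=float(pos),
                center_u_mm=float(cu + rng.normal(scale=1.0)),
                center_v_mm=float(cv + rng.normal(scale=1.0)),
                width_mm=float(size), height_mm=float(size),
                confidence=float(np.clip(
                    rng.normal(model.chain_conf_mean, model.chain_conf_sigma),
                    0.05, 1.0)),
            ))

    # Uniform low-confidence scatter over the whole scan.
    n_scatter = rng.poisson(model.scatter_rate_per_scan)
    for _ in range(n_scatter):
        axis = "axial" if rng.random() < 0.5 else "coronal"
        point = (ox + rng.uniform(0, ex), oy + rng.uniform(0, ey),
                 oz + rng.uniform(0, ez))
        pos, u, v = _axis_coords(axis, point)
        size = rng.uniform(2.0, 10.0)
        detections.append(Detection2D(
            scan_id=geometry.scan_id, axis=axis, slice_pos_mm=float(pos),
            center_u_mm=float(u), center_v_mm=float(v),
            width_mm=float(size), height_mm=float(size),
            confidence=float(rng.uniform(0.0, model.scatter_conf_max)),
        ))
    return detections, fired


def sample_nodules(
    rng: np.random.Generator,
    spec: PhantomSpec,
    n_nodules: int,
    min_separation_mm: float = 40.0,
    diameter_range_mm: tuple[float, float] = (4.0, 12.0),
) -> tuple[PhantomNodule, ...]:
    """Rejection-sample non-overlapping nodules well inside the lung field.

    Attenuation classes are drawn with screening-like frequencies (soft
    tissue dominant, occasional ground-glass/mixed/calcified).
    """
    classes = ("soft_tissue", "ground_glass", "mixed", "calcified")
    probs = (0.85, 0.05, 0.05, 0.05)
    nodules: list[PhantomNodule] = []
    attempts = 0
    while len(nodules) < n_nodules:
        attempts += 1
        if attempts > 2000:
            raise RuntimeError("could not place nodules with the requested separation")
        d = rng.uniform(*diameter_range_mm)
        offset = rng.uniform(-0.65, 0.65, 3) * np.asarray(spec.lung_semiaxes_mm)
        center = tuple(float(v) for v in np.asarray(spec.lung_center_mm) + offset)
        if not _inside_lung(spec, center, margin_mm=d / 2.0 + 2.0):
            continue
        if any(np.linalg.norm(np.subtract(center, n.center_mm)) < min_separation_mm
               for n in nodules):
            continue
        attenuation = classes[rng.choice(len(classes), p=probs)]
        nodules.append(PhantomNodule(center_mm=center, diameter_mm=float(d),
                                     attenuation=attenuation))
    return tuple(nodules)
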