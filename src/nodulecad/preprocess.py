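"""Isotropic resampling and overlapping maximum intensity projection (MIP).

A thick, overlapping MIP makes spherical nodules stand out against tubular
vessels: a sphere stays compact in projection, while a vessel smears into a
line unless it runs along the projection axis.  The pipeline therefore builds
MIP stacks along two axes (axial, projecting along z; coronal, projecting
along y) so that a vessel can mimic a nodule on at most one of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import AXES, CtVolume, Detection2D, NoduleAnnotation

_EPS = 1e-9


@dataclass(frozen=True)
class PreprocessConfig:
    """Resampling and projection parameters.

    voxel_mm
        Isotropic target spacing; 1 mm gives a consistent real-world scale
        regardless of the scanner's native slice thickness.
    mip_window_mm
        Thickness of each projection window (default 25 mm).
    stride_mm
        Spacing between consecutive window centres; defaults to ``voxel_mm``
        (maximally overlapping slabs — one output slice per voxel plane).
        Must be an integer multiple of ``voxel_mm``.
    """

    voxel_mm: float = 1.0
    mip_window_mm: float = 25.0
    stride_mm: float | None = None

    def __post_init__(self) -> None:
        if not self.voxel_mm > 0:
            raise ValueError("voxel_mm must be > 0")
        if self.stride_mm is None:
            object.__setattr__(self, "stride_mm", self.voxel_mm)
        if self.mip_window_mm < self.voxel_mm:
            raise ValueError("mip_window_mm must be >= voxel_mm")
        if self.stride_mm < self.voxel_mm:
            raise ValueError("stride_mm must be >= voxel_mm")
        ratio = self.stride_mm / self.voxel_mm
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("stride_mm must be an integer multiple of voxel_mm")


@dataclass(frozen=True)
class MipStack:
    """An ordered stack of MIP slices along one projection axis.

    ``slice_pos_mm[i]`` is the world position of slice ``i``'s window centre
    along the projection axis.  ``slices[i]`` is a 2D image indexed
    ``(v, u)``: axial slices are ``(y, x)``, coronal slices are ``(z, x)``.
    """

    scan_id: str
    axis: str
    slice_pos_mm: np.ndarray
    slices: np.ndarray  # (n_slices, nv, nu)
    in_plane_origin_mm: tuple[float, float]  # (u, v)
    in_plane_spacing_mm: tuple[float, float]
    window_mm: float

    def __post_init__(self) -> None:
        if self.axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}")
        pos = np.asarray(self.slice_pos_mm)
        if len(pos) != len(self.slices):
            raise ValueError("slice_pos_mm and slices length mismatch")
        if len(pos) > 1:
            steps = np.diff(pos)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
                raise ValueError("slice positions must increase by a constant stride")


def resample_isotropic(volume: CtVolume, config: PreprocessConfig | None = None) -> CtVolume:
    """Resample a volume to isotropic voxels by trilinear interpolation.

    The output grid has ``round(extent / voxel_mm)`` voxels per axis so the
    physical extent is preserved to within one voxel; the origin is unchanged.
    """
    config = config or PreprocessConfig()
    if min(volume.voxels.shape) < 2:
        raise ValueError("cannot resample a volume with a single slice along an axis")
    t = config.voxel_mm
    sx, sy, sz = volume.spacing_mm
    nz, ny, nx = volume.voxels.shape
    new_shape = (
        max(1, round(nz * sz / t)),
        max(1, round(ny * sy / t)),
        max(1, round(nx * sx / t)),
    )
    # New voxel j sits at world origin + j*t  ->  old continuous index j*t/s.
    grids = [
        np.arange(n_new) * t / s_old
        for n_new, s_old in zip(new_shape, (sz, sy, sx))
    ]
    coords = np.meshgrid(*grids, indexing="ij")
    resampled = ndimage.map_coordinates(
        volume.voxels.astype(np.float32), coords, order=1, mode="nearest"
    )
    return CtVolume(
        voxels=resampled.astype(np.float32),
        origin_mm=volume.origin_mm,
        spacing_mm=(t, t, t),
        scan_id=volume.scan_id,
    )


def _window_half_width_voxels(window_mm: float, voxel_mm: float) -> int:
    """Number of voxel planes on each side whose centres fall inside the
    closed window [-w/2, w/2]."""
    return int(np.floor(window_mm / (2.0 * voxel_mm) + _EPS))


def build_mip_stack(volume: CtVolume, axis: str,
                    config: PreprocessConfig | None = None) -> MipStack:
    """Build an overlapping MIP stack along ``axis`` from an isotropic volume.

    Each output slice at position ``p`` holds, per pixel, the maximum voxel
    value over the planes whose centres lie in ``[p - w/2, p + w/2]`` along
    the projection axis; windows are clipped at the volume boundary.
    """
    config = config or PreprocessConfig()
    if axis not in AXES:
        raise ValueError(f"axis must be one of {AXES}, got {axis!r}")
    if not np.allclose(volume.spacing_mm, config.voxel_mm):
        raise ValueError("build_mip_stack requires an isotropic volume at voxel_mm")

    t = config.voxel_mm
    half = _window_half_width_voxels(config.mip_window_mm, t)
    size = 2 * half + 1
    ox, oy, oz = volume.origin_mm

    if axis == "axial":
        proj_dim, axis_origin = 0, oz          # project along z -> (y, x) images
        in_plane_origin = (ox, oy)
    else:
        proj_dim, axis_origin = 1, oy          # project along y -> (z, x) images
        in_plane_origin = (ox, oz)

    # 'nearest' edge padding replicates boundary values, which for a running
    # maximum is exactly the clipped-window maximum.
    filtered = ndimage.maximum_filter1d(volume.voxels, size=size, axis=proj_dim,
                                        mode="nearest")
    step = round(config.stride_mm / t)
    n_axis = volume.voxels.shape[proj_dim]
    indices = np.arange(0, n_axis, step)
    slices = np.take(filtered, indices, axis=proj_dim)
    if axis == "coronal":
        slices = np.moveaxis(slices, 1, 0)     # -> (n_slices, z, x)
    positions = axis_origin + indices * t
    return MipStack(
        scan_id=volume.scan_id,
        axis=axis,
        slice_pos_mm=positions.astype(float),
        slices=np.ascontiguousarray(slices),
        in_plane_origin_mm=in_plane_origin,
        in_plane_spacing_mm=(t, t),
        window_mm=config.mip_window_mm,
    )


def project_annotations(annotations: list[NoduleAnnotation],
                        stack: MipStack) -> list[Detection2D]:
    """Project 3D nodule annotations onto a MIP stack as 2D ground-truth boxes.

    A nodule of diameter ``d`` centred at ``c`` appears (as a square box of
    side ``d`` at its in-plane coordinates, confidence 1) on every slice whose
    projection window intersects ``[c_axis - d/2, c_axis + d/2]``.
    """
    boxes: list[Detection2D] = []
    half_window = stack.window_mm / 2.0
    for ann in annotations:
        if ann.scan_id != stack.scan_id:
            raise ValueError(
                f"annotation scan {ann.scan_id!r} does not match stack {stack.scan_id!r}"
            )
        cx, cy, cz = ann.center_mm
        if stack.axis == "axial":
            c_axis, u, v = cz, cx, cy
        else:
            c_axis, u, v = cy, cx, cz
        reach = half_window + ann.diameter_mm / 2.0
        on = np.abs(stack.slice_pos_mm - c_axis) <= reach + _EPS
        for pos in stack.slice_pos_mm[on]:
            boxes.append(Detection2D(
                scan_id=stack.scan_id, axis=stack.axis, slice_pos_mm=float(pos),
                center_u_mm=u, center_v_mm=v,
                width_mm=ann.diameter_mm, height_mm=ann.diameter_mm,
                confidence=1.0,
            ))
    return boxes
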