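"""Lesion segmentation from per-slice planar contours.

Lesion boundaries are drawn as closed polygons on a subset of axial slices
(typically every second slice); the missing slices are filled in by
shape-based interpolation — averaging the signed distance transforms of the
two bounding contours and extracting the zero level set. The full stack is
then rasterized into a boolean voxel mask used for volumetry (voxel area x
slice thickness) and for masked mean-T1 extraction.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np
from matplotlib.path import Path as MplPath
from scipy import ndimage
from shapely.geometry import Polygon
from skimage import measure

from .relaxometry import T1Map

__all__ = [
    "ContourStack",
    "VolumeMask",
    "MaskedMean",
    "interpolate_contours",
    "rasterize",
    "mask_volume_cm3",
    "mean_in_mask",
    "save_contours",
    "load_contours",
]


@dataclass
class ContourStack:
    """Closed planar lesion contours on a (possibly sparse) set of slices.

    ``slices`` maps slice index to an (N, 2) array of in-plane vertex
    coordinates in mm; polygons are implicitly closed (last vertex connects
    to the first) and must be simple.
    """

    slices: dict[int, np.ndarray]
    slice_thickness_mm: float
    in_plane_spacing_mm: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.slices:
            raise ValueError("contour stack has no contours")
        if self.slice_thickness_mm <= 0 or any(s <= 0 for s in self.in_plane_spacing_mm):
            raise ValueError("spacing must be strictly positive")
        cleaned: dict[int, np.ndarray] = {}
        for k in sorted(self.slices):
            poly = np.asarray(self.slices[k], dtype=float)
            if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
                raise ValueError(f"slice {k}: a polygon needs >= 3 (x, y) vertices")
            if not Polygon(poly).is_valid:
                raise ValueError(f"slice {k}: polygon is not simple")
            cleaned[int(k)] = poly
        self.slices = cleaned

    @property
    def populated(self) -> list[int]:
        return sorted(self.slices)


@dataclass
class VolumeMask:
    """Boolean voxel grid with physical spacing (dx, dy, dz) in mm."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be 3D")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be strictly positive")


class MaskedMean(NamedTuple):
    mean: float
    n_used: int
    n_invalid_excluded: int


def _signed_distance(polygon: np.ndarray, origin: np.ndarray, step: float, shape: tuple[int, int]) -> np.ndarray:
    """Signed distance to the polygon boundary on a regular grid (negative
    inside), via complementary Euclidean distance transforms."""
    ys = origin[1] + (np.arange(shape[0]) + 0.5) * step
    xs = origin[0] + (np.arange(shape[1]) + 0.5) * step
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    inside = MplPath(polygon).contains_points(pts).reshape(shape)
    d_out = ndimage.distance_transform_edt(~inside, sampling=step)
    d_in = ndimage.distance_transform_edt(inside, sampling=step)
    return d_out - d_in


def interpolate_contours(stack: ContourStack, grid_step_mm: float | None = None) -> ContourStack:
    """Fill every missing slice between the first and last drawn contour.

    Shape-based interpolation: for a missing slice a fraction ``t`` of the
    way between its bounding drawn slices, the contour is the zero level set
    of ``(1-t)*sdf_lower + t*sdf_upper``, where each sdf is the signed
    distance transform of the bounding polygon on a common fine grid.
    Drawn slices pass through unchanged. ``grid_step_mm`` controls the
    resolution of the level-set grid (default: half the finer in-plane
    spacing, capped at 0.5 mm).
    """
    drawn = stack.populated
    if len(drawn) == 1:
        return replace(stack, slices=dict(stack.slices))
    if grid_step_mm is None:
        grid_step_mm = min(0.5, min(stack.in_plane_spacing_mm) / 2.0)

    all_pts = np.vstack(list(stack.slices.values()))
    margin = 4.0 * grid_step_mm + 2.0
    origin = all_pts.min(axis=0) - margin
    extent = all_pts.max(axis=0) + margin - origin
    shape = (int(np.ceil(extent[1] / grid_step_mm)), int(np.ceil(extent[0] / grid_step_mm)))

    sdf_cache = {
        k: _signed_distance(stack.slices[k], origin, grid_step_mm, shape) for k in drawn
    }
    out = dict(stack.slices)
    for lo, hi in zip(drawn[:-1], drawn[1:]):
        for k in range(lo + 1, hi):
            t = (k - lo) / (hi - lo)
            sdf = (1.0 - t) * sdf_cache[lo] + t * sdf_cache[hi]
            contours = measure.find_contours(sdf, 0.0)
            if not contours:
                raise ValueError(f"interpolated slice {k} produced no contour")
            # keep the longest zero-level contour; rows are (row=y, col=x)
            c = max(contours, key=len)
            verts = np.column_stack(
                [origin[0] + (c[:, 1] + 0.5) * grid_step_mm,
                 origin[1] + (c[:, 0] + 0.5) * grid_step_mm]
            )
            out[k] = verts
    return replace(stack, slices=out)


def rasterize(
    stack: ContourStack,
    grid_shape: tuple[int, int, int],
    spacing_mm: tuple[float, float, float] | None = None,
) -> VolumeMask:
    """Voxelize a contour stack: a voxel is set iff its center lies inside
    the slice's polygon (even-odd rule).

    Grid axes are (x, y, z); the voxel at index (i, j, k) has its center at
    ((i+0.5)*dx, (j+0.5)*dy) in-plane on slice k.
    """
    if spacing_mm is None:
        spacing_mm = (*stack.in_plane_spacing_mm, stack.slice_thickness_mm)
    dx, dy, dz = spacing_mm
    nx, ny, nz = grid_shape
    extent = np.array([nx * dx, ny * dy])
    for k, poly in stack.slices.items():
        if k < 0 or k >= nz:
            raise ValueError(f"contour slice {k} lies outside the grid (nz={nz})")
        if np.any(poly < 0) or np.any(poly > extent):
            raise ValueError(f"slice {k}: polygon extends outside the grid")
    xs = (np.arange(nx) + 0.5) * dx
    ys = (np.arange(ny) + 0.5) * dy
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    mask = np.zeros(grid_shape, dtype=bool)
    for k, poly in stack.slices.items():
        mask[:, :, k] = MplPath(poly).contains_points(centers).reshape(nx, ny)
    return VolumeMask(mask, spacing_mm)


def mask_volume_cm3(mask: VolumeMask) -> float:
    """Lesion volume: per-slice segmented area times slice thickness, in cm3."""
    n_true = int(mask.voxels.sum())
    if n_true == 0:
        raise ValueError("mask is empty")
    dx, dy, dz = mask.spacing_mm
    return n_true * dx * dy * dz / 1000.0


def mean_in_mask(t1map: T1Map, mask: VolumeMask) -> MaskedMean:
    """Arithmetic mean of valid map voxels under the mask.

    Invalid (NaN) map voxels are excluded and counted; raises if every
    masked voxel is invalid.
    """
    if t1map.voxels.shape != mask.voxels.shape:
        raise ValueError("map and mask grids are not congruent")
    vals = t1map.voxels[mask.voxels]
    if vals.size == 0:
        raise ValueError("mask is empty")
    valid = np.isfinite(vals)
    n_invalid = int(np.sum(~valid))
    if not np.any(valid):
        raise ValueError("all masked voxels are invalid")
    return MaskedMean(float(vals[valid].mean()), int(valid.sum()), n_invalid)


def save_contours(stack: ContourStack, path: str | Path) -> None:
    """Write a contour stack to the package's JSON layout."""
    doc = {
        "slice_thickness_mm": stack.slice_thickness_mm,
        "in_plane_spacing_mm": list(stack.in_plane_spacing_mm),
        "slices": {str(k): np.asarray(v).tolist() for k, v in stack.slices.items()},
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_contours(path: str | Path) -> ContourStack:
    doc = json.loads(Path(path).read_text())
    return ContourStack(
        slices={int(k): np.asarray(v, dtype=float) for k, v in doc["slices"].items()},
        slice_thickness_mm=float(doc["slice_thickness_mm"]),
        in_plane_spacing_mm=tuple(doc["in_plane_spacing_mm"]),
    )
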