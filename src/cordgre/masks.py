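"""Sub-voxel segmentations, binarization, ROI construction and areas.

Segmentations are exchanged as sub-voxel occupancy maps (fraction of each
voxel inside the contour).  Binarization uses inclusion thresholds of 100%
for the spinal cord and 50% for gray matter and CSF; the 100% threshold is
applied as occupancy >= 1 - 1e-6 to absorb floating-point rasterization
error.  The binary white-matter mask is the set difference SC minus GM.
The CSF reference ROI is an analytic ellipse of fixed area (7.5 mm^2 by
default) placed anterior to the cord.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .phantom import GridSpec, PhantomVolume

__all__ = [
    "SubVoxelMask",
    "BinaryMask",
    "PlacementError",
    "binarize",
    "subtract",
    "ellipse_roi",
    "place_csf_roi",
    "cross_sectional_area",
    "area_report",
    "binarize_phantom",
]

log = logging.getLogger(__name__)

_FULL_INCLUSION_EPS = 1e-6


class PlacementError(ValueError):
    """Raised when an ROI cannot be placed in the requested compartment."""


@dataclass
class SubVoxelMask:
    """Per-voxel occupancy fraction in [0, 1] for one tissue label."""

    occupancy: np.ndarray  # (nx, ny, nz)
    label: str
    voxel_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        if self.occupancy.ndim != 3:
            raise ValueError("occupancy must be a 3-D (x, y, slice) array")
        if not np.all(np.isfinite(self.occupancy)):
            raise ValueError("occupancy must be finite")
        if self.occupancy.min() < -1e-9 or self.occupancy.max() > 1 + 1e-9:
            raise ValueError("occupancy must lie in [0, 1]")

    @property
    def voxel_area_mm2(self) -> float:
        return self.voxel_mm[0] * self.voxel_mm[1]


@dataclass
class BinaryMask:
    """Binarized ROI membership for one tissue label."""

    data: np.ndarray  # (nx, ny, nz) bool
    label: str
    voxel_area_mm2: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be a 3-D (x, y, slice) array")

    def __and__(self, other: "BinaryMask") -> np.ndarray:
        return self.data & other.data

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def slice(self, index: int) -> np.ndarray:
        return self.data[:, :, index]


def binarize(mask: SubVoxelMask, threshold: float) -> BinaryMask:
    """Include voxels with occupancy >= threshold.

    ``threshold`` must lie in (0, 1]; a threshold of exactly 1 ("100%
    inclusion") is applied with a 1e-6 tolerance.  An empty result is legal
    but logged.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    eff = threshold - _FULL_INCLUSION_EPS if threshold >= 1.0 else threshold
    data = mask.occupancy >= eff
    if not data.any():
        log.warning("binarize(%s, %.3g) produced an empty mask", mask.label, threshold)
    return BinaryMask(data=data, label=mask.label, voxel_area_mm2=mask.voxel_area_mm2)


def subtract(sc: BinaryMask, gm: BinaryMask) -> BinaryMask:
    """White matter as the set difference SC AND NOT GM."""
    if sc.data.shape != gm.data.shape:
        raise ValueError("masks are on different grids")
    if sc.voxel_area_mm2 != gm.voxel_area_mm2:
        raise ValueError("masks have different voxel areas")
    return BinaryMask(data=sc.data & ~gm.data, label="wm", voxel_area_mm2=sc.voxel_area_mm2)


def ellipse_roi(
    center_mm: tuple[float, float],
    grid: GridSpec,
    area_mm2: float = 7.5,
    aspect: float = 2.0,
    slices: list[int] | None = None,
    supersampling: int = 16,
    label: str = "csf",
) -> SubVoxelMask:
    """Analytic elliptical ROI rasterised with sub-voxel occupancy.

    The ellipse has the requested analytic area (default 7.5 mm^2) and
    ``aspect`` = (left-right semi-axis) / (antero-posterior semi-axis);
    ``aspect = 1`` gives a circle of radius sqrt(area / pi).  Coordinates
    are mm relative to the grid centre, anterior = -y.  The ellipse is drawn
    on the given ``slices`` (default: all).
    """
    if area_mm2 <= 0:
        raise ValueError("area must be positive")
    if aspect <= 0:
        raise ValueError("aspect must be positive")
    b = math.sqrt(area_mm2 / (math.pi * aspect))
    a = aspect * b

    nx, ny = grid.shape
    ss = supersampling
    xs = (np.arange(nx * ss) + 0.5) * (grid.voxel_mm / ss) - nx * grid.voxel_mm / 2
    ys = (np.arange(ny * ss) + 0.5) * (grid.voxel_mm / ss) - ny * grid.voxel_mm / 2
    x, y = np.meshgrid(xs, ys, indexing="ij")
    cx, cy = center_mm
    inside = ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 <= 1.0
    plane = inside.reshape(nx, ss, ny, ss).mean(axis=(1, 3))

    occ = np.zeros((nx, ny, grid.n_slices))
    for s in slices if slices is not None else range(grid.n_slices):
        occ[:, :, s] = plane
    return SubVoxelMask(occupancy=occ, label=label, voxel_mm=grid.voxel_dims_mm)


def place_csf_roi(
    phantom: PhantomVolume,
    area_mm2: float = 7.5,
    aspect: float = 2.0,
    clearance_mm: float = 0.6,
    slices: list[int] | None = None,
    overlap_tol: float = 1e-3,
) -> SubVoxelMask:
    """CSF reference ellipse placed anterior to the cord, per slice.

    The centre sits ``clearance_mm`` plus one ellipse semi-axis anterior to
    the cord boundary of each slice.  Raises :class:`PlacementError` if the
    ellipse overlaps the cord ground truth or leaves the CSF compartment.
    """
    grid = phantom.grid
    b = math.sqrt(area_mm2 / (math.pi * aspect))
    use = slices if slices is not None else list(range(grid.n_slices))
    occ = np.zeros(phantom.cord.shape)
    for s in use:
        _, b_cord = phantom.cord_semi_axes(s)
        center = (0.0, -(b_cord + clearance_mm + b))
        plane = ellipse_roi(
            center, grid, area_mm2=area_mm2, aspect=aspect, slices=[s]
        ).occupancy[:, :, s]
        overlap = float((plane * phantom.cord[:, :, s]).sum())
        if overlap > overlap_tol:
            raise PlacementError(
                f"CSF ellipse overlaps the cord on slice {s} (overlap {overlap:.3g} voxels)"
            )
        inside_csf = float((plane * phantom.occupancy["csf"][:, :, s]).sum())
        if inside_csf < 0.98 * plane.sum():
            raise PlacementError(
                f"CSF ellipse leaves the CSF compartment on slice {s}"
            )
        occ[:, :, s] = plane
    return SubVoxelMask(occupancy=occ, label="csf", voxel_mm=grid.voxel_dims_mm)


def cross_sectional_area(mask: BinaryMask, slice_index: int) -> float:
    """Slice-wise area in mm^2 (voxel count times voxel area)."""
    if not 0 <= slice_index < mask.data.shape[2]:
        raise ValueError(f"slice {slice_index} out of range")
    return float(mask.data[:, :, slice_index].sum()) * mask.voxel_area_mm2


def area_report(masks: dict[str, BinaryMask]):
    """Per-slice area table (mm^2) for a set of binary masks."""
    import pandas as pd

    n_slices = next(iter(masks.values())).data.shape[2]
    rows = []
    for label, mask in masks.items():
        for s in range(n_slices):
            rows.append(
                {"label": label, "slice": s, "area_mm2": cross_sectional_area(mask, s)}
            )
    return pd.DataFrame(rows)


def binarize_phantom(
    phantom: PhantomVolume,
    sc_threshold: float = 1.0,
    gm_threshold: float = 0.5,
    csf_roi_kwargs: dict | None = None,
) -> dict[str, BinaryMask]:
    """Standard ROI set from phantom ground truth.

    SC is binarized at the 100% inclusion threshold, GM at 50%, WM is
    SC minus GM, and CSF is the anterior reference ellipse binarized at 50%.
    """
    grid = phantom.grid
    voxel = grid.voxel_dims_mm
    sc = binarize(
        SubVoxelMask(phantom.cord, "sc", voxel), sc_threshold
    )
    gm_sub = SubVoxelMask(phantom.occupancy["gm"], "gm", voxel)
    gm = binarize(gm_sub, gm_threshold)
    # GM voxels must lie inside the binary cord for the WM subtraction
    gm = BinaryMask(gm.data & sc.data, "gm", gm.voxel_area_mm2)
    wm = subtract(sc, gm)
    csf_sub = place_csf_roi(phantom, **(csf_roi_kwargs or {}))
    csf = binarize(csf_sub, 0.5)
    return {"sc": sc, "gm": gm, "wm": wm, "csf": csf}
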