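"""Slice-wise segmentability metrics and slice-stack aggregation.

Within-ROI definitions (tissue-uniformity convention, not air-noise based):

* ``SNR  = mean(I) / SD(I)`` within one ROI,
* ``CNR  = |mean_1 - mean_2| / sqrt(SD_1^2 + SD_2^2)`` between two ROIs,
* ``contrast = |mean_1 - mean_2| / (0.5 (mean_1 + mean_2))``,
* ``CNR / sqrt(t)`` with t the acquisition time (per-repetition time x NSA).

Standard deviations are sample SDs (n - 1 denominator).  All metrics are
invariant under global intensity scaling.  Metrics are computed per slice
and averaged over three-slice stacks centred on the LSE slice (greatest
cord cross-sectional area) and the CM slice (most caudal slice with
butterfly-shaped gray matter).

A ROI whose SD vanishes (e.g. a noiseless phantom) yields an ``inf``
sentinel and a degenerate flag rather than an exception, so grids over many
series complete.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .masks import BinaryMask, cross_sectional_area
from .series import SeriesImage

__all__ = [
    "RegionDefinition",
    "snr",
    "cnr",
    "contrast",
    "cnr_efficiency",
    "find_lse_slice",
    "find_cm_slice",
    "stack_slices",
    "aggregate",
    "slice_metrics",
    "metrics_table",
    "METRIC_NAMES",
]

log = logging.getLogger(__name__)

METRIC_NAMES = (
    "snr_gm",
    "snr_wm",
    "cnr_wm_csf",
    "cnr_gm_wm",
    "contrast_wm_csf",
    "contrast_gm_wm",
    "cnr_wm_csf_per_sqrt_t",
    "cnr_gm_wm_per_sqrt_t",
)


@dataclass(frozen=True)
class RegionDefinition:
    """Slice indices of the two evaluation stacks."""

    lse_slice: int
    cm_slice: int
    half_width: int = 1  # three-slice stack: key slice +/- 1

    def slices(self, region: str, n_slices: int) -> list[int]:
        center = {"lse": self.lse_slice, "cm": self.cm_slice}[region.lower()]
        return stack_slices(center, self.half_width, n_slices)


def _roi_values(image: SeriesImage | np.ndarray, roi: BinaryMask, slice_index: int | None):
    data = image.data if isinstance(image, SeriesImage) else np.asarray(image)
    if slice_index is None:
        return data[roi.data]
    return data[:, :, slice_index][roi.slice(slice_index)]


def snr(image, roi: BinaryMask, slice_index: int | None = None) -> float:
    """Within-ROI mean intensity over its sample SD; inf if the SD vanishes."""
    vals = _roi_values(image, roi, slice_index)
    if vals.size < 2:
        raise ValueError("SNR needs at least two ROI voxels")
    sd = vals.std(ddof=1)
    if sd == 0:
        log.warning("degenerate SNR: zero SD in ROI %s", roi.label)
        return float("inf")
    return float(vals.mean() / sd)


def cnr(image, roi1: BinaryMask, roi2: BinaryMask, slice_index: int | None = None) -> float:
    """|mean difference| over the root-sum-square of the two sample SDs."""
    v1 = _roi_values(image, roi1, slice_index)
    v2 = _roi_values(image, roi2, slice_index)
    if v1.size < 2 or v2.size < 2:
        raise ValueError("CNR needs at least two voxels in each ROI")
    denom = float(np.hypot(v1.std(ddof=1), v2.std(ddof=1)))
    if denom == 0:
        log.warning("degenerate CNR: both ROI SDs vanish (%s, %s)", roi1.label, roi2.label)
        return float("inf")
    return float(abs(v1.mean() - v2.mean()) / denom)


def contrast(image, roi1: BinaryMask, roi2: BinaryMask, slice_index: int | None = None) -> float:
    """|mean difference| normalised by the average of the two means."""
    v1 = _roi_values(image, roi1, slice_index)
    v2 = _roi_values(image, roi2, slice_index)
    if v1.size == 0 or v2.size == 0:
        raise ValueError("contrast needs non-empty ROIs")
    m1, m2 = float(v1.mean()), float(v2.mean())
    if m1 + m2 <= 0:
        log.warning("degenerate contrast: zero mean sum (%s, %s)", roi1.label, roi2.label)
        return float("inf")
    return abs(m1 - m2) / (0.5 * (m1 + m2))


def contrast_from_signals(s1: float, s2: float) -> float:
    """Contrast of two noiseless signal amplitudes (same formula)."""
    if s1 + s2 <= 0:
        raise ValueError("signals must have a positive sum")
    return abs(s1 - s2) / (0.5 * (s1 + s2))


def cnr_efficiency(cnr_value: float, acquisition_time_s: float) -> float:
    """CNR per square root of acquisition time (s^-1/2)."""
    if acquisition_time_s <= 0:
        raise ValueError("acquisition time must be positive")
    return cnr_value / np.sqrt(acquisition_time_s)


def find_lse_slice(sc_mask: BinaryMask) -> int:
    """Slice with the greatest cord cross-sectional area.

    Ties break toward the more rostral slice (higher index; slices are
    numbered caudal to rostral).
    """
    n = sc_mask.data.shape[2]
    areas = np.array([cross_sectional_area(sc_mask, s) for s in range(n)])
    if areas.max() == 0:
        raise ValueError("all slices are empty")
    return int(n - 1 - np.argmax(areas[::-1]))


def find_cm_slice(metadata: dict | None = None, user_index: int | None = None) -> int:
    """Most caudal slice with butterfly-shaped gray matter.

    Butterfly-shape detection is not inferred from images: the index comes
    from phantom ground truth (``metadata['cm_slice']``) or from the user.
    """
    if user_index is not None:
        return int(user_index)
    if metadata is not None and "cm_slice" in metadata:
        return int(metadata["cm_slice"])
    raise ValueError(
        "CM slice unknown: supply user_index or metadata with a 'cm_slice' entry"
    )


def stack_slices(center: int, half_width: int, n_slices: int) -> list[int]:
    """Slice stack ``center +/- half_width``, truncated at the volume edge."""
    lo, hi = center - half_width, center + half_width
    if lo < 0 or hi >= n_slices:
        warnings.warn(
            f"slice stack [{lo}, {hi}] truncated to the volume (0..{n_slices - 1})",
            stacklevel=2,
        )
    return [s for s in range(lo, hi + 1) if 0 <= s < n_slices]


def aggregate(slice_values: np.ndarray | list[float]) -> float:
    """Arithmetic mean over the slices of a stack."""
    vals = np.asarray(slice_values, dtype=float)
    if vals.size == 0:
        raise ValueError("nothing to aggregate")
    return float(vals.mean())


def slice_metrics(image: SeriesImage, rois: dict[str, BinaryMask], slice_index: int) -> dict[str, float]:
    """All base metrics of one series image on one slice."""
    gm, wm, csf = rois["gm"], rois["wm"], rois["csf"]
    return {
        "snr_gm": snr(image, gm, slice_index),
        "snr_wm": snr(image, wm, slice_index),
        "cnr_wm_csf": cnr(image, wm, csf, slice_index),
        "cnr_gm_wm": cnr(image, gm, wm, slice_index),
        "contrast_wm_csf": contrast(image, wm, csf, slice_index),
        "contrast_gm_wm": contrast(image, gm, wm, slice_index),
    }


def metrics_table(
    images: list[SeriesImage],
    rois: dict[str, BinaryMask],
    region_def: RegionDefinition,
    rep_time_s: float | None = None,
    regions: tuple[str, ...] = ("lse", "cm"),
) -> pd.DataFrame:
    """Long-format metric records for a series grid.

    One row per (series, NSA, region, metric); values are stack averages of
    the slice-wise metrics.  The ``/sqrt(t)`` forms are emitted when
    ``rep_time_s`` is given, with t = rep_time_s x NSA.
    """
    n_slices = next(iter(rois.values())).data.shape[2]
    rows = []
    for image in images:
        for region in regions:
            slices = region_def.slices(region, n_slices)
            per_slice = [slice_metrics(image, rois, s) for s in slices]
            agg = {
                name: aggregate([m[name] for m in per_slice])
                for name in per_slice[0]
            }
            if rep_time_s is not None:
                t = rep_time_s * image.nsa
                agg["cnr_wm_csf_per_sqrt_t"] = cnr_efficiency(agg["cnr_wm_csf"], t)
                agg["cnr_gm_wm_per_sqrt_t"] = cnr_efficiency(agg["cnr_gm_wm"], t)
            for name, value in agg.items():
                rows.append(
                    {
                        "series_id": image.series_id,
                        "n_echoes_used": image.n_echoes_used,
                        "last_echo": image.last_echo,
                        "nsa": image.nsa,
                        "region": region,
                        "metric": name,
                        "value": value,
                        "degenerate": not np.isfinite(value),
                        "slices": tuple(slices),
                    }
                )
    return pd.DataFrame(rows)
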