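"""Derived image series: RMS echo combination and repetition averaging.

From a raw acquisition with E echoes and R repetitions the study grid holds
one image per (series, NSA) pair, where the series axis runs over the E
single echoes plus the E-1 leading-echo combinations (echoes 1-2, ..., 1-E)
and NSA over 1..R — (2E - 1) * R images in total (72 for E=5, R=8).
Combination is applied within each repetition first, then successive
repetitions 1..n are averaged in acquisition order.

Root-mean-squares combination of the leading k echoes is voxel-wise
``sqrt(mean_i I_i^2)`` (mean, not sum, so intensity ranges stay comparable
across k; every downstream metric is scale-invariant either way).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .protocol import AcquisitionProtocol

__all__ = [
    "MultiEchoDataset",
    "SeriesImage",
    "series_ids",
    "parse_series_id",
    "series_volume",
    "rms_combine",
    "average_repetitions",
    "build_grid",
    "grid_manifest",
]


@dataclass
class MultiEchoDataset:
    """Magnitude intensities I(x, y, slice, echo, repetition) >= 0."""

    data: np.ndarray
    voxel_mm: tuple[float, float, float]
    protocol: AcquisitionProtocol | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 5:
            raise ValueError(
                f"expected 5 axes (x, y, slice, echo, repetition), got {self.data.ndim}"
            )
        if not np.all(np.isfinite(self.data)) or np.any(self.data < 0):
            raise ValueError("intensities must be finite and non-negative")
        if self.n_echoes < 1 or self.n_repetitions < 1:
            raise ValueError("need at least one echo and one repetition")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_echoes(self) -> int:
        return self.data.shape[3]

    @property
    def n_repetitions(self) -> int:
        return self.data.shape[4]

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]

    @property
    def n_images(self) -> int:
        """Number of raw echo-images (echoes x repetitions)."""
        return self.n_echoes * self.n_repetitions


@dataclass
class SeriesImage:
    """One derived volume of the series grid."""

    data: np.ndarray
    series_id: str
    nsa: int
    source_repetitions: tuple[int, ...]
    voxel_mm: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("SeriesImage holds a single (x, y, slice) volume")
        if self.nsa < 1 or len(self.source_repetitions) != self.nsa:
            raise ValueError("nsa must match the number of source repetitions")

    @property
    def n_echoes_used(self) -> int:
        kind, k = parse_series_id(self.series_id)
        return k if kind == "combo" else 1

    @property
    def last_echo(self) -> int:
        _, k = parse_series_id(self.series_id)
        return k


def series_ids(n_echoes: int) -> list[str]:
    """All (2E - 1) series identifiers: singles then leading combinations."""
    if n_echoes < 1:
        raise ValueError("n_echoes must be >= 1")
    singles = [f"echo{e}" for e in range(1, n_echoes + 1)]
    combos = [f"echo1-{k}" for k in range(2, n_echoes + 1)]
    return singles + combos


def parse_series_id(series_id: str) -> tuple[str, int]:
    """Return ('single', e) for 'echo{e}' or ('combo', k) for 'echo1-{k}'."""
    if not series_id.startswith("echo"):
        raise ValueError(f"malformed series id {series_id!r}")
    body = series_id[4:]
    if "-" in body:
        first, last = body.split("-", 1)
        if first != "1":
            raise ValueError(f"combinations start at echo 1, got {series_id!r}")
        return "combo", int(last)
    return "single", int(body)


def series_volume(dataset: MultiEchoDataset, series_id: str, repetition: int) -> np.ndarray:
    """Raw or RMS-combined volume of one repetition for the given series."""
    if not 0 <= repetition < dataset.n_repetitions:
        raise ValueError(f"repetition {repetition} out of range")
    kind, k = parse_series_id(series_id)
    if not 1 <= k <= dataset.n_echoes:
        raise ValueError(f"series {series_id!r} needs echo {k} of {dataset.n_echoes}")
    if kind == "single":
        return dataset.data[:, :, :, k - 1, repetition]
    return np.sqrt(np.mean(dataset.data[:, :, :, :k, repetition] ** 2, axis=3))


def rms_combine(dataset: MultiEchoDataset, k: int, repetition: int = 0) -> SeriesImage:
    """Root-mean-squares combination of the leading ``k`` echoes of one repetition.

    ``k = 1`` returns the first echo unchanged.
    """
    if not 1 <= k <= dataset.n_echoes:
        raise ValueError(f"k must be in 1..{dataset.n_echoes}, got {k}")
    sid = "echo1" if k == 1 else f"echo1-{k}"
    return SeriesImage(
        data=series_volume(dataset, sid, repetition),
        series_id=sid,
        nsa=1,
        source_repetitions=(repetition,),
        voxel_mm=dataset.voxel_mm,
    )


def average_repetitions(images: list[SeriesImage], n: int) -> SeriesImage:
    """Arithmetic mean of the first ``n`` repetitions (acquisition order)."""
    if not images:
        raise ValueError("no images to average")
    if not 1 <= n <= len(images):
        raise ValueError(f"n must be in 1..{len(images)}, got {n}")
    sid = images[0].series_id
    if any(im.series_id != sid for im in images):
        raise ValueError("cannot average across different series ids")
    stack = np.stack([im.data for im in images[:n]], axis=-1)
    sources = tuple(r for im in images[:n] for r in im.source_repetitions)
    return SeriesImage(
        data=stack.mean(axis=-1),
        series_id=sid,
        nsa=n,
        source_repetitions=sources,
        voxel_mm=images[0].voxel_mm,
    )


def build_grid(dataset: MultiEchoDataset) -> list[SeriesImage]:
    """Full series grid: one image per (series, NSA) pair.

    For E echoes and R repetitions this yields (2E - 1) * R images; the
    combination is applied per repetition first, then repetitions 1..n are
    averaged.
    """
    R = dataset.n_repetitions
    out: list[SeriesImage] = []
    for sid in series_ids(dataset.n_echoes):
        per_rep = np.stack(
            [series_volume(dataset, sid, r) for r in range(R)], axis=-1
        )
        cummean = np.cumsum(per_rep, axis=-1) / np.arange(1, R + 1)
        for n in range(1, R + 1):
            out.append(
                SeriesImage(
                    data=cummean[..., n - 1],
                    series_id=sid,
                    nsa=n,
                    source_repetitions=tuple(range(n)),
                    voxel_mm=dataset.voxel_mm,
                )
            )
    return out


def grid_manifest(images: list[SeriesImage]):
    """Manifest DataFrame (series id, NSA, echoes used) for a series grid."""
    import pandas as pd

    return pd.DataFrame(
        {
            "series_id": [im.series_id for im in images],
            "nsa": [im.nsa for im in images],
            "n_echoes_used": [im.n_echoes_used for im in images],
            "last_echo": [im.last_echo for im in images],
        }
    )
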