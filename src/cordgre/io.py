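"""NIfTI and sidecar I/O for datasets, series grids and masks.

Datasets are written one NIfTI per repetition (echoes on the 4th axis) plus
a 5-D convenience file; sub-voxel masks are float occupancy volumes and
binary masks uint8.  Protocol, geometry and provenance go into a YAML
sidecar.  Real acquisitions can be loaded from a 5-D magnitude NIfTI
(x, y, slice, echo, repetition).
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .masks import BinaryMask, SubVoxelMask
from .phantom import PhantomVolume
from .protocol import AcquisitionProtocol
from .series import MultiEchoDataset, SeriesImage, grid_manifest

__all__ = [
    "write_dataset",
    "load_dataset",
    "write_phantom_masks",
    "write_series_grid",
    "write_binary_mask",
    "load_subvoxel_mask",
]


def _affine(voxel_mm) -> np.ndarray:
    return np.diag([voxel_mm[0], voxel_mm[1], voxel_mm[2], 1.0])


def write_dataset(dataset: MultiEchoDataset, outdir: str | Path, stem: str = "megre") -> dict:
    """Write per-repetition 4-D NIfTIs, a 5-D file, and a YAML sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aff = _affine(dataset.voxel_mm)
    paths = {"repetitions": []}
    for r in range(dataset.n_repetitions):
        p = outdir / f"{stem}_rep{r + 1}.nii.gz"
        nib.save(nib.Nifti1Image(dataset.data[..., r], aff), p)
        paths["repetitions"].append(str(p))
    p5 = outdir / f"{stem}_5d.nii.gz"
    nib.save(nib.Nifti1Image(dataset.data, aff), p5)
    paths["five_d"] = str(p5)

    sidecar = {
        "voxel_mm": list(dataset.voxel_mm),
        "n_echoes": dataset.n_echoes,
        "n_repetitions": dataset.n_repetitions,
    }
    if dataset.protocol is not None:
        sidecar["protocol"] = _plain(asdict(dataset.protocol))
    for key in ("lse_slice", "cm_slice"):
        if key in dataset.meta:
            sidecar[key] = int(dataset.meta[key])
    if "noise" in dataset.meta:
        sidecar["noise"] = _plain(asdict(dataset.meta["noise"]))
    sidecar_path = outdir / f"{stem}.yaml"
    sidecar_path.write_text(yaml.safe_dump(sidecar, sort_keys=False))
    paths["sidecar"] = str(sidecar_path)
    return paths


def load_dataset(path: str | Path, protocol: AcquisitionProtocol | None = None) -> MultiEchoDataset:
    """Load a 5-D magnitude NIfTI (x, y, slice, echo, repetition)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 5:
        raise ValueError(f"expected a 5-D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    meta = {}
    sidecar = Path(path).with_suffix("").with_suffix(".yaml")
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
    return MultiEchoDataset(
        data=data, voxel_mm=tuple(float(z) for z in zooms), protocol=protocol, meta=meta
    )


def write_phantom_masks(phantom: PhantomVolume, outdir: str | Path, stem: str = "phantom") -> dict:
    """Ground-truth occupancy maps as float NIfTI plus a YAML sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aff = _affine(phantom.grid.voxel_dims_mm)
    paths = {}
    for label, occ in phantom.occupancy.items():
        p = outdir / f"{stem}_{label}_occupancy.nii.gz"
        nib.save(nib.Nifti1Image(occ.astype(np.float32), aff), p)
        paths[label] = str(p)
    sidecar = {
        "geometry": _plain(asdict(phantom.geometry)),
        "grid": _plain(asdict(phantom.grid)),
        "lse_slice": phantom.lse_slice,
        "cm_slice": phantom.cm_slice,
        "cord_area_mm2": [float(a) for a in phantom.cord_area_mm2],
    }
    p = outdir / f"{stem}.yaml"
    p.write_text(yaml.safe_dump(sidecar, sort_keys=False))
    paths["sidecar"] = str(p)
    return paths


def write_binary_mask(mask: BinaryMask, path: str | Path, voxel_mm) -> None:
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), _affine(voxel_mm)), str(path))


def load_subvoxel_mask(path: str | Path, label: str) -> SubVoxelMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    zooms = img.header.get_zooms()[:3]
    return SubVoxelMask(occupancy=data, label=label, voxel_mm=tuple(float(z) for z in zooms))


def write_series_grid(images: list[SeriesImage], outdir: str | Path) -> Path:
    """Write every grid image as NIfTI plus a CSV manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = grid_manifest(images)
    paths = []
    for im in images:
        name = f"{im.series_id.replace('echo', 'echo')}_nsa{im.nsa}.nii.gz"
        voxel = im.voxel_mm or (1.0, 1.0, 1.0)
        nib.save(nib.Nifti1Image(im.data, _affine(voxel)), outdir / name)
        paths.append(str(outdir / name))
    manifest["path"] = paths
    mpath = outdir / "manifest.csv"
    manifest.to_csv(mpath, index=False)
    return mpath


def _plain(obj):
    """Recursively convert tuples/numpy scalars for YAML serialisation."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_plain(v) for v in obj.tolist()]
    return obj
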