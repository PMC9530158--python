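"""Shared fixtures: a small desk-scale phantom and simulated acquisitions.

The small configuration (64 x 64 in-plane at 0.5 mm, 6 slices) keeps the
full anatomy — cord ellipse, GM butterfly, CSF annulus — at the study's
voxel size while staying fast; the acceptance suite additionally runs the
reduced study grid (128 x 128 x 12).
"""

import numpy as np
import pytest

import cordgre as cg


@pytest.fixture(scope="session")
def tissue() -> cg.TissueModel:
    return cg.TissueModel()


@pytest.fixture(scope="session")
def grid_small() -> cg.GridSpec:
    return cg.GridSpec(shape=(72, 72), voxel_mm=0.5, n_slices=10)


@pytest.fixture(scope="session")
def geometry_small(grid_small) -> cg.PhantomGeometry:
    return cg.PhantomGeometry.for_slices(grid_small.n_slices)


@pytest.fixture(scope="session")
def protocol_small(grid_small) -> cg.AcquisitionProtocol:
    return cg.AcquisitionProtocol(
        matrix=grid_small.shape,
        n_slices=grid_small.n_slices,
        in_plane_mm=grid_small.voxel_mm,
        slice_thickness_mm=grid_small.slice_thickness_mm,
    )


@pytest.fixture(scope="session")
def phantom_small(geometry_small, grid_small) -> cg.PhantomVolume:
    return cg.build_geometry(geometry_small, grid_small)


@pytest.fixture(scope="session")
def rois_small(phantom_small):
    return cg.binarize_phantom(phantom_small)


@pytest.fixture(scope="session")
def sigma_small(tissue, protocol_small) -> float:
    return cg.calibrate_sigma(tissue, protocol_small)


@pytest.fixture(scope="session")
def dataset_noiseless(phantom_small, tissue, protocol_small) -> cg.MultiEchoDataset:
    return cg.simulate_dataset(phantom_small, tissue, protocol_small, cg.NoiseSpec(sigma=0.0))


@pytest.fixture(scope="session")
def dataset_noisy(phantom_small, tissue, protocol_small, sigma_small) -> cg.MultiEchoDataset:
    return cg.simulate_dataset(
        phantom_small, tissue, protocol_small, cg.NoiseSpec(sigma=sigma_small, seed=7)
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
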