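"""Shared fixtures; expensive Monte Carlo artifacts are session-scoped."""

from __future__ import annotations

import numpy as np
import pytest

from hsfli.camera_phantoms import (
    BULK_LADDER,
    CameraModel,
    PhantomSpec,
    generate_hsf_dataset,
)
from hsfli.core_io import AcquisitionConfig, default_config
from hsfli.mcfluor import OpticalProperties, VoxelVolume


@pytest.fixture(scope="session")
def paper_config() -> AcquisitionConfig:
    return default_config()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_homogeneous_volume(
    mu_a: float = 0.002,
    mu_s_prime: float = 1.0,
    g: float = 0.9,
    n: float = 1.37,
    shape=(80, 80, 60),
    voxel_mm: float = 0.1,
    n_outside: float = 1.0,
) -> VoxelVolume:
    op = OpticalProperties(mu_a=mu_a, mu_s_prime=mu_s_prime, g=g, n=n)
    return VoxelVolume(
        voxel_size_mm=voxel_mm,
        tissue_label=np.zeros(shape, dtype=np.uint8),
        properties=[op],
        n_outside=n_outside,
    )


def make_transparent_volume(shape=(60, 60, 40), voxel_mm: float = 0.1) -> VoxelVolume:
    op = OpticalProperties(mu_a=0.0, mu_s_prime=0.0, g=0.0, n=1.0)
    return VoxelVolume(
        voxel_size_mm=voxel_mm,
        tissue_label=np.zeros(shape, dtype=np.uint8),
        properties=[op],
        n_outside=1.0,
    )


@pytest.fixture(scope="session")
def ladder_dataset():
    """Three shallowest depth-ladder tubes, fx in {0, 0.6}, Poisson noise.

    Shared by the acceptance lifetime/R^2 tests and the pipeline tests;
    photon budget reduced relative to the acceptance script for runtime.
    """
    spec = PhantomSpec(kind="depth_ladder", depths_mm=(0.4, 1.4, 2.4), bulk=BULK_LADDER)
    camera = CameraModel(noise="poisson")
    return generate_hsf_dataset(
        spec,
        [0.0, 0.6],
        camera,
        n_photons=400_000,
        seed=11,
        n_emission=600_000,
        auto_gain_peak=1100.0,
    )
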