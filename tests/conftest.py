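"""Shared fixtures: small synthetic lobules and geometric phantoms."""

from __future__ import annotations

import numpy as np
import pytest

from lobule3d.core import binary_map
from lobule3d.synthetic import LobuleParams, TubeNetworkParams, generate_lobule


def small_params(seed: int = 1, **overrides) -> LobuleParams:
    """A 64^3 lobule that generates in under a second."""
    defaults = dict(
        shape=(64, 64, 64),
        hepatocyte_count=12,
        hsc_count=3,
        kc_count=3,
        sinusoids=TubeNetworkParams(n_paths=4, n_branches=2),
        bc=TubeNetworkParams(n_paths=5, n_branches=2, mean_radius_um=0.62),
        seed=seed,
    )
    defaults.update(overrides)
    return LobuleParams(**defaults)


@pytest.fixture(scope="session")
def small_lobule():
    """Small noisy lobule shared across read-only tests."""
    return generate_lobule(small_params())


@pytest.fixture(scope="session")
def clean_small_lobule():
    """Noise-free, PSF-free small lobule (exact intensity bookkeeping)."""
    return generate_lobule(small_params(noise_sd=0.0, psf_sigma_um=0.0))


@pytest.fixture(scope="session")
def default_lobule():
    """The standard 128^3 desk-scale lobule (seed 1), generated once."""
    return generate_lobule(LobuleParams(seed=1))


@pytest.fixture(scope="session")
def clean_default_lobule():
    """Noise-free, PSF-free lobule at the standard 128^3 scale."""
    return generate_lobule(LobuleParams(seed=1, noise_sd=0.0, psf_sigma_um=0.0))


def digital_ball(radius_vox: float, pad: int = 3) -> np.ndarray:
    n = int(2 * (radius_vox + pad) + 1)
    c = n // 2
    zz, yy, xx = np.meshgrid(*(np.arange(n),) * 3, indexing="ij")
    return (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius_vox**2


def digital_ellipsoid(semi_axes_vox, pad: int = 3) -> np.ndarray:
    a = np.asarray(semi_axes_vox, float)
    n = (2 * (a + pad) + 1).astype(int)
    c = n // 2
    zz, yy, xx = np.meshgrid(*(np.arange(k) for k in n), indexing="ij")
    return ((zz - c[0]) / a[0]) ** 2 + ((yy - c[1]) / a[1]) ** 2 + (
        (xx - c[2]) / a[2]
    ) ** 2 <= 1.0


def digital_cylinder(radius_vox: float, length_vox: int, pad: int = 4):
    """Axis along x."""
    n = int(2 * radius_vox) + 2 * pad + 1
    c = n // 2
    shape = (n, n, length_vox + 2 * pad)
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    return (
        ((zz - c) ** 2 + (yy - c) ** 2 <= radius_vox**2)
        & (xx >= pad)
        & (xx < pad + length_vox)
    )


def as_mask(arr, voxel_size_um: float = 0.3):
    return binary_map(arr, voxel_size_um)
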