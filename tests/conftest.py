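import numpy as np
import pytest

from flfmip import OpticalConfig, simulate_psf_stack


@pytest.fixture(scope="session")
def tiny_cfg():
    """16 x 16 x 4 grid: small enough for brute-force oracles."""
    return OpticalConfig(fov_um=(4.8, 4.8), z_range_um=(-0.525, 0.525))


@pytest.fixture(scope="session")
def tiny_psf(tiny_cfg):
    return simulate_psf_stack(tiny_cfg)


@pytest.fixture(scope="session")
def small_cfg():
    """32 x 32 x 6 grid for pipeline-level tests."""
    return OpticalConfig(fov_um=(9.6, 9.6), z_range_um=(-0.875, 0.875))


@pytest.fixture(scope="session")
def small_psf(small_cfg):
    return simulate_psf_stack(small_cfg)


def direct_project(volume_data: np.ndarray, psf_data: np.ndarray) -> np.ndarray:
    """Brute-force forward projection: explicit sum of shifted kernels.

    Independent of the FFT path: every nonzero voxel deposits a scaled copy
    of its depth's PSF at its lateral offset on the zero-padded canvas.
    """
    nz, ny, nx = volume_data.shape
    _, V, U = psf_data.shape
    out = np.zeros((V + ny - 1, U + nx - 1))
    for iz in range(nz):
        h = psf_data[iz]
        for iy in range(ny):
            for ix in range(nx):
                w = volume_data[iz, iy, ix]
                if w != 0.0:
                    out[iy:iy + V, ix:ix + U] += w * h
    return out


def direct_tv3d(d: np.ndarray) -> float:
    """Nested-loop isotropic 3D TV with replicate boundary."""
    nz, ny, nx = d.shape
    total = 0.0
    for iz in range(nz):
        for iy in range(ny):
            for ix in range(nx):
                gz = d[min(iz + 1, nz - 1), iy, ix] - d[iz, iy, ix]
                gy = d[iz, min(iy + 1, ny - 1), ix] - d[iz, iy, ix]
                gx = d[iz, iy, min(ix + 1, nx - 1)] - d[iz, iy, ix]
                total += np.sqrt(gz * gz + gy * gy + gx * gx)
    return total
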