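import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import ndimage

from flfmip import (LightFieldFrame, ReconSettings, Volume, project,
                    reconstruct, tv3d)
from flfmip.optics import PSFStack
from conftest import direct_tv3d


def gaussian_kernel(n=5, sigma=0.6):
    r = np.arange(n) - n // 2
    k = np.exp(-(r[:, None] ** 2 + r[None, :] ** 2) / (2 * sigma**2))
    return k / k.sum()


def single_slice_psf(n=5, sigma=0.6):
    return PSFStack(data=gaussian_kernel(n, sigma)[None],
                    z_positions_um=np.array([0.0]), pixel_um=0.3)


class TestTV3D:
    def test_constant_volume_has_zero_tv(self):
        assert tv3d(np.full((4, 5, 6), 3.3)) == 0.0

    def test_single_step_counts_once(self):
        d = np.zeros((2, 1, 1))
        d[1] = 1.0
        assert tv3d(d) == pytest.approx(1.0)

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(0)
        d = rng.random((4, 4, 4))
        assert tv3d(d) == pytest.approx(direct_tv3d(d), abs=1e-12)

    def test_degenerate_axes_contribute_nothing(self):
        d = np.array([[[0.0, 1.0, 3.0]]])  # 1 x 1 x 3
        assert tv3d(d) == pytest.approx(3.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(hnp.arrays(np.float64, (3, 4, 5),
                      elements=st.floats(0.0, 10.0, allow_nan=False)))
    def test_tv_properties_hold_for_arbitrary_volumes(self, d):
        """TV is nonnegative, matches the nested-loop oracle, and is
        positively homogeneous."""
        ref = direct_tv3d(d)
        assert tv3d(d) == pytest.approx(ref, abs=1e-9)
        assert tv3d(2.5 * d) == pytest.approx(2.5 * ref, abs=1e-8)
        assert tv3d(d + 1.7) == pytest.approx(ref, abs=1e-8)


class TestReconstruct:
    def test_unregularized_single_slice_recovery(self):
        """lambda = 0, noiseless, well-posed: the solve inverts the blur to
        1e-4 relative."""
        rng = np.random.default_rng(1)
        psf = single_slice_psf()
        x_true = ndimage.gaussian_filter(rng.random((1, 16, 16)), 1.0)
        vol = Volume(data=x_true, voxel_size_um=(0.3, 0.3, 0.35),
                     z_positions_um=np.array([0.0]))
        frame = project(vol, psf)
        settings = ReconSettings(lambda_l1=0.0, lambda_tv=0.0, admm_rho=0.01,
                                 max_iters=400, rel_tol=1e-13, cg_iters=40,
                                 cg_tol=1e-16,
                                 depth_clip_axial_fwhm_multiplier=0.0)
        res = reconstruct(frame, psf, settings)
        err = np.linalg.norm(res.volume.data - x_true) / np.linalg.norm(x_true)
        assert err < 1e-4

    def test_five_point_sources_recovered(self, small_cfg):
        """Sparse prior: 5 point sources in a 64x64x8 volume land on the
        correct voxels with no spurious peak above 10% of the weakest."""
        from flfmip import OpticalConfig, simulate_psf_stack
        cfg = OpticalConfig(fov_um=(19.2, 19.2), z_range_um=(-1.225, 1.225))
        psf = simulate_psf_stack(cfg)
        ny, nx = cfg.lateral_shape()
        truth = [(1, 12, 20), (3, 40, 12), (4, 30, 45), (6, 52, 50), (2, 20, 55)]
        x = np.zeros((psf.n_z, ny, nx))
        for (iz, iy, ix) in truth:
            x[iz, iy, ix] = 1.0
        frame = project(Volume(data=x, voxel_size_um=cfg.voxel_size_um,
                               z_positions_um=cfg.z_grid_um()), psf)
        peak = frame.data.max()
        res = reconstruct(LightFieldFrame(data=frame.data / peak), psf,
                          ReconSettings(lambda_l1=0.01, max_iters=120,
                                        depth_clip_axial_fwhm_multiplier=0.0))
        d = res.volume.data
        found = []
        for (iz, iy, ix) in truth:
            sub = d[max(iz - 1, 0):iz + 2, iy - 1:iy + 2, ix - 1:ix + 2]
            found.append(sub.max())
            assert sub.max() > 0, f"source at {(iz, iy, ix)} lost"
            assert sub.max() == pytest.approx(
                d[max(iz - 1, 0):iz + 2, iy - 2:iy + 3, ix - 2:ix + 3].max())
        floor = 0.1 * min(found)
        mask = np.ones_like(d, dtype=bool)
        for (iz, iy, ix) in truth:
            mask[max(iz - 2, 0):iz + 3, max(iy - 2, 0):iy + 3,
                 max(ix - 2, 0):ix + 3] = False
        assert d[mask].max() < floor

    def test_objective_monotone_after_burn_in(self, tiny_cfg, tiny_psf):
        """Merged objective is non-increasing after the first 5 iterations
        (within 1e-9 of its initial value), across 10 random phantoms."""
        ny, nx = tiny_cfg.lateral_shape()
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = np.zeros((tiny_psf.n_z, ny, nx))
            pts = rng.integers(0, [tiny_psf.n_z, ny, nx], size=(4, 3))
            x[tuple(pts.T)] = rng.uniform(0.5, 1.5, size=4)
            frame = project(Volume(data=x, voxel_size_um=tiny_cfg.voxel_size_um,
                                   z_positions_um=tiny_cfg.z_grid_um()), tiny_psf)
            res = reconstruct(
                LightFieldFrame(data=frame.data / frame.data.max()), tiny_psf,
                ReconSettings(max_iters=30, depth_clip_axial_fwhm_multiplier=0.0))
            obj = res.objective_trace
            increases = np.diff(obj[5:])
            assert increases.max() <= 1e-9 * obj[0], f"seed {seed}"

    def test_data_fidelity_monotone_in_l1_weight(self):
        """Stronger l1 shrinkage can only worsen the data fit at convergence."""
        rng = np.random.default_rng(2)
        psf = single_slice_psf()
        x = np.zeros((1, 16, 16))
        x[0, [4, 8, 11], [5, 10, 3]] = 1.0
        vol = Volume(data=x, voxel_size_um=(0.3, 0.3, 0.35),
                     z_positions_um=np.array([0.0]))
        y = project(vol, psf)
        fids = []
        for lam in (0.0, 1e-3, 1e-2):
            res = reconstruct(y, psf,
                              ReconSettings(lambda_l1=lam, lambda_tv=0.0,
                                            max_iters=150, rel_tol=1e-10,
                                            cg_iters=20,
                                            depth_clip_axial_fwhm_multiplier=0.0))
            op_frame = project(res.volume, psf)
            fids.append(0.5 * float(((op_frame.data - y.data) ** 2).sum()))
        assert fids[0] <= fids[1] + 1e-10 <= fids[2] + 1e-10

    def test_scaling_equivariance(self, tiny_cfg, tiny_psf):
        """Scaling y and lambda by c (rho fixed) scales the solution by c."""
        rng = np.random.default_rng(4)
        ny, nx = tiny_cfg.lateral_shape()
        x = rng.random((tiny_psf.n_z, ny, nx)) * (rng.random((tiny_psf.n_z, ny, nx)) > 0.9)
        frame = project(Volume(data=x, voxel_size_um=tiny_cfg.voxel_size_um,
                               z_positions_um=tiny_cfg.z_grid_um()), tiny_psf)
        c = 3.7
        base = ReconSettings(lambda_l1=1e-3, lambda_tv=1e-4, admm_rho=1.0,
                             max_iters=25, depth_clip_axial_fwhm_multiplier=0.0)
        scaled = ReconSettings(lambda_l1=1e-3 * c, lambda_tv=1e-4 * c,
                               admm_rho=1.0, max_iters=25,
                               depth_clip_axial_fwhm_multiplier=0.0)
        r1 = reconstruct(frame, tiny_psf, base)
        r2 = reconstruct(LightFieldFrame(data=c * frame.data), tiny_psf, scaled)
        err = np.linalg.norm(r2.volume.data - c * r1.volume.data) \
            / max(np.linalg.norm(c * r1.volume.data), 1e-30)
        assert err < 1e-6

    def test_nan_measurement_rejected(self, tiny_psf):
        V, U = tiny_psf.canvas_shape
        bad = np.zeros((V + 15, U + 15))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            reconstruct(LightFieldFrame(data=bad), tiny_psf)

    def test_nonnegativity_enforced(self, tiny_cfg, tiny_psf):
        rng = np.random.default_rng(9)
        V, U = tiny_psf.canvas_shape
        y = rng.normal(size=(V + 15, U + 15))  # sign-indefinite measurement
        res = reconstruct(LightFieldFrame(data=y), tiny_psf,
                          ReconSettings(max_iters=10))
        assert res.volume.data.min() >= 0.0

    def test_depth_clip_zeroes_far_slices(self, small_cfg, small_psf):
        ny, nx = small_cfg.lateral_shape()
        x = np.zeros((small_psf.n_z, ny, nx))
        x[small_psf.n_z // 2, ny // 2, nx // 2] = 1.0
        frame = project(Volume(data=x, voxel_size_um=small_cfg.voxel_size_um,
                               z_positions_um=small_cfg.z_grid_um()), small_psf)
        res = reconstruct(
            LightFieldFrame(data=frame.data / frame.data.max()), small_psf,
            ReconSettings(max_iters=15, depth_clip_axial_fwhm_multiplier=0.25))
        from flfmip import psf_axial_fwhm
        fwhm = psf_axial_fwhm(small_psf)
        z = small_psf.z_positions_um
        zf = z[int(np.argmax(small_psf.data.max(axis=(1, 2))))]
        far = np.abs(z - zf) > 0.25 * fwhm
        assert not res.volume.data[far].any()
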