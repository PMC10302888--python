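"""Regularized 3D deconvolution of light-field frames by ADMM.

Solves

    min_x  1/2 ||H x - y||^2  +  lambda_l1 ||x||_1  +  lambda_tv TV3D(x)
           subject to x >= 0  (optional),

with H the depth-summed convolution operator and TV3D the isotropic 3D total
variation.  The splitting is a three-way consensus ADMM: the data quadratic is
solved by conjugate gradients on the normal equations in operator form, the
l1 term by soft-thresholding, the TV term by an isotropic TV proximal
(Chambolle) step, and nonnegativity by projection.  The penalty rho is fixed.

After solving, slices farther than ``depth_clip_axial_fwhm_multiplier`` times
the axial FWHM of the PSF from the nominal focal plane can be zeroed — the
reconstruction is only trustworthy within roughly twice the axial PSF extent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.restoration import denoise_tv_chambolle

from .forward import FLFOperator, LightFieldFrame, Volume
from .optics import PSFStack

__all__ = ["ReconSettings", "ReconResult", "tv3d", "reconstruct", "psf_axial_fwhm"]


@dataclass(frozen=True)
class ReconSettings:
    """Solver hyperparameters.

    Regularization weights are absolute: they multiply terms on the scale of
    the measurement handed in, so callers working in raw photon counts should
    scale them (or pre-normalize the frame) accordingly.  Defaults were chosen
    on the noiseless bead phantom.
    """

    lambda_l1: float = 1e-3
    lambda_tv: float = 1e-4
    admm_rho: float = 1.0
    max_iters: int = 60
    rel_tol: float = 1e-6
    nonnegativity: bool = True
    depth_clip_axial_fwhm_multiplier: float = 2.0
    cg_iters: int = 8
    cg_tol: float = 1e-12

    def __post_init__(self) -> None:
        if self.lambda_l1 < 0 or self.lambda_tv < 0:
            raise ValueError("regularization weights must be nonnegative")
        if self.admm_rho <= 0:
            raise ValueError("admm_rho must be positive")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be positive")
        if self.depth_clip_axial_fwhm_multiplier < 0:
            raise ValueError("depth clip multiplier must be nonnegative")


@dataclass
class ReconResult:
    volume: Volume
    objective_trace: np.ndarray
    primal_residuals: np.ndarray
    dual_residuals: np.ndarray
    iterations_run: int
    converged: bool


def tv3d(volume: Volume | np.ndarray) -> float:
    """Isotropic 3D total variation with forward differences and replicate
    boundary (the trailing difference along each axis is zero)."""
    d = volume.data if isinstance(volume, Volume) else np.asarray(volume, float)
    gz = np.diff(d, axis=0, append=d[-1:, :, :])
    gy = np.diff(d, axis=1, append=d[:, -1:, :])
    gx = np.diff(d, axis=2, append=d[:, :, -1:])
    return float(np.sqrt(gz**2 + gy**2 + gx**2).sum())


def psf_axial_fwhm(psf: PSFStack) -> float:
    """Axial FWHM (um) of the PSF's per-slice peak-intensity profile.

    Gaussian-fit when possible, half-max crossing otherwise.  Used for the
    reconstruction depth-range clip.
    """
    from .metrics import fwhm_gaussian  # local import to avoid a cycle

    profile = psf.data.max(axis=(1, 2))
    dz = float(np.diff(psf.z_positions_um)[0]) if psf.n_z > 1 else 1.0
    try:
        return fwhm_gaussian(profile, dz)
    except (ValueError, RuntimeError):
        half = profile.min() + 0.5 * (profile.max() - profile.min())
        above = np.nonzero(profile >= half)[0]
        return dz * max(len(above), 1)


def _soft(v: np.ndarray, t: float) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


def _prox_tv(v: np.ndarray, t: float) -> np.ndarray:
    if t <= 0:
        return v
    # denoise_tv_chambolle solves argmin_u 1/2||u - v||^2 + w TV(u); shift to
    # a nonnegative working range for numerical robustness of the dual ascent.
    lo = v.min()
    return denoise_tv_chambolle(v - lo, weight=t, eps=1e-6, max_num_iter=200) + lo


def reconstruct(frame: LightFieldFrame, psf: PSFStack,
                settings: ReconSettings = ReconSettings(),
                x0: np.ndarray | None = None) -> ReconResult:
    """Reconstruct a 3D volume from one light-field frame by ADMM.

    Returns the solution with per-iteration objective and residual traces;
    non-convergence within ``max_iters`` sets ``converged=False`` rather than
    raising.
    """
    y = np.asarray(frame.data, dtype=np.float64)
    if np.any(~np.isfinite(y)):
        raise ValueError("measurement contains NaN or infinite values")
    V, U = psf.canvas_shape
    Y, X = y.shape[0] - V + 1, y.shape[1] - U + 1
    if Y < 1 or X < 1:
        raise ValueError("frame canvas smaller than the PSF canvas")
    op = FLFOperator(psf, (Y, X))
    shape = (psf.n_z, Y, X)

    rho = settings.admm_rho
    # Splits carrying an identity prox contribute only damping; skip them.
    use_l1 = settings.lambda_l1 > 0
    use_tv = settings.lambda_tv > 0
    use_nn = settings.nonnegativity
    n_splits = int(use_l1) + int(use_tv) + int(use_nn)
    Aty = op.adjoint(y)

    x = np.zeros(shape) if x0 is None else np.asarray(x0, float).copy()
    z1 = x.copy()
    z2 = x.copy()
    z3 = x.copy()
    u1 = np.zeros(shape)
    u2 = np.zeros(shape)
    u3 = np.zeros(shape)

    def cg_solve(rhs: np.ndarray, x_init: np.ndarray) -> np.ndarray:
        # (H^T H + n_splits * rho * I) x = rhs
        xk = x_init.copy()
        r = rhs - (op.normal(xk) + n_splits * rho * xk)
        p = r.copy()
        rs = float((r * r).sum())
        rhs_norm = float((rhs * rhs).sum()) or 1.0
        for _ in range(settings.cg_iters):
            if rs / rhs_norm < settings.cg_tol:
                break
            Ap = op.normal(p) + n_splits * rho * p
            alpha = rs / float((p * Ap).sum())
            xk += alpha * p
            r -= alpha * Ap
            rs_new = float((r * r).sum())
            p = r + (rs_new / rs) * p
            rs = rs_new
        return xk

    def objective(v: np.ndarray) -> float:
        resid = op.forward(v) - y
        obj = 0.5 * float((resid * resid).sum())
        if settings.lambda_l1 > 0:
            obj += settings.lambda_l1 * float(np.abs(v).sum())
        if settings.lambda_tv > 0:
            obj += settings.lambda_tv * tv3d(v)
        return obj

    obj_trace: list[float] = []
    pri_trace: list[float] = []
    dua_trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, settings.max_iters + 1):
        x_prev = x
        rhs = Aty.copy()
        if use_l1:
            rhs += rho * (z1 - u1)
        if use_tv:
            rhs += rho * (z2 - u2)
        if use_nn:
            rhs += rho * (z3 - u3)
        x = cg_solve(rhs, x_prev)

        z1_old, z2_old, z3_old = z1, z2, z3
        pri2 = dua2 = 0.0
        if use_l1:
            z1 = _soft(x + u1, settings.lambda_l1 / rho)
            u1 = u1 + x - z1
            pri2 += ((x - z1)**2).sum()
            dua2 += ((z1 - z1_old)**2).sum()
        if use_tv:
            z2 = _prox_tv(x + u2, settings.lambda_tv / rho)
            u2 = u2 + x - z2
            pri2 += ((x - z2)**2).sum()
            dua2 += ((z2 - z2_old)**2).sum()
        if use_nn:
            z3 = np.maximum(x + u3, 0.0)
            u3 = u3 + x - z3
            pri2 += ((x - z3)**2).sum()
            dua2 += ((z3 - z3_old)**2).sum()

        pri = np.sqrt(pri2)
        dua = rho * np.sqrt(dua2)
        # Evaluate the merged objective at the feasible (projected) iterate.
        x_eval = np.maximum(x, 0.0) if settings.nonnegativity else x
        obj_trace.append(objective(x_eval))
        pri_trace.append(float(pri))
        dua_trace.append(float(dua))

        dx = np.linalg.norm(x - x_prev)
        if dx <= settings.rel_tol * max(np.linalg.norm(x_prev), 1e-30):
            converged = True
            break

    x_final = np.maximum(x, 0.0) if settings.nonnegativity else x.copy()

    if settings.depth_clip_axial_fwhm_multiplier > 0 and psf.n_z > 1:
        fwhm = psf_axial_fwhm(psf)
        z = psf.z_positions_um
        z_focus = float(z[int(np.argmax(psf.data.max(axis=(1, 2))))])
        keep = np.abs(z - z_focus) <= settings.depth_clip_axial_fwhm_multiplier * fwhm
        x_final = x_final * keep[:, None, None]

    dz = float(np.diff(psf.z_positions_um)[0]) if psf.n_z > 1 else psf.pixel_um
    vol = Volume(data=x_final,
                 voxel_size_um=(psf.pixel_um, psf.pixel_um, dz),
                 z_positions_um=psf.z_positions_um)
    return ReconResult(volume=vol,
                       objective_trace=np.asarray(obj_trace),
                       primal_residuals=np.asarray(pri_trace),
                       dual_residuals=np.asarray(dua_trace),
                       iterations_run=it,
                       converged=converged)
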