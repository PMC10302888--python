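"""FLF image formation: the 2D camera measurement is the axial sum of 2D
convolutions between each object slice and its depth-dependent PSF,

    y = sum_z  x_z (*) h_z ,

with (*) a *linear* (zero-padded) convolution: wrap-around would leak signal
between elemental images, which the physical field stop prevents.  The frame
canvas is sized to the full convolution support, (V + Y - 1, U + X - 1) for a
(V, U) PSF canvas and (Y, X) object grid, so the operator and its adjoint
(per-depth correlation, valid region) form an exact transpose pair — FFTs
with this padding introduce no circular overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import numpy.fft as fft

from .optics import PSFStack

__all__ = ["Volume", "LightFieldFrame", "FLFOperator", "project", "adjoint"]


@dataclass
class Volume:
    """A 3D fluorophore-density volume on a (z, y, x) voxel grid."""

    data: np.ndarray
    voxel_size_um: tuple[float, float, float]
    z_positions_um: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.z_positions_um = np.asarray(self.z_positions_um, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D (z, y, x)")
        if len(self.z_positions_um) != self.data.shape[0]:
            raise ValueError("z_positions_um must match the volume z axis")


@dataclass
class LightFieldFrame:
    """One 2D light-field camera frame with its elemental-image layout."""

    data: np.ndarray
    elemental_layout: list[tuple[int, int, int, int]] | None = None
    exposure_tag: Literal["ir_on", "ir_off", "plain"] = "plain"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("frame data must be 2D (v, u)")
        if self.elemental_layout is not None:
            self._check_disjoint()

    def _check_disjoint(self) -> None:
        boxes = self.elemental_layout
        for i in range(len(boxes)):
            for j in range(i + 1, len(boxes)):
                a, b = boxes[i], boxes[j]
                if a[0] < b[1] and b[0] < a[1] and a[2] < b[3] and b[2] < a[3]:
                    raise ValueError("elemental bounding boxes must be disjoint")


def _frame_layout(psf: PSFStack, frame_shape: tuple[int, int]):
    """Tile the frame canvas evenly by the lenslet grid (metadata only)."""
    if psf.lenslet_boxes is None:
        return None
    n = len(psf.lenslet_boxes)
    rows = int(round(np.sqrt(n))) if int(round(np.sqrt(n)))**2 == n else 1
    cols = n // rows
    rh, cw = frame_shape[0] // rows, frame_shape[1] // cols
    return [(i * rh, (i + 1) * rh, j * cw, (j + 1) * cw)
            for i in range(rows) for j in range(cols)]


class FLFOperator:
    """The linear forward operator H and its exact adjoint, FFT-cached.

    Parameters
    ----------
    psf : PSFStack
        Depth-dependent composite-canvas PSFs (defines V, U and the z grid).
    object_shape_yx : tuple of int
        Lateral object-grid shape (Y, X).
    """

    def __init__(self, psf: PSFStack, object_shape_yx: tuple[int, int]):
        self.psf = psf
        self.object_shape_yx = tuple(object_shape_yx)
        V, U = psf.canvas_shape
        Y, X = self.object_shape_yx
        self.frame_shape = (V + Y - 1, U + X - 1)
        self._Hf = fft.rfft2(psf.data, s=self.frame_shape)

    def forward(self, volume_data: np.ndarray) -> np.ndarray:
        """y = sum_z x_z (*) h_z on the full linear-convolution canvas."""
        x = np.asarray(volume_data, dtype=np.float64)
        if x.shape[0] != self.psf.n_z or x.shape[1:] != self.object_shape_yx:
            raise ValueError(
                f"volume shape {x.shape} incompatible with operator geometry "
                f"({self.psf.n_z}, {self.object_shape_yx})")
        Xf = fft.rfft2(x, s=self.frame_shape)
        return fft.irfft2((Xf * self._Hf).sum(axis=0), s=self.frame_shape)

    def adjoint(self, frame_data: np.ndarray) -> np.ndarray:
        """(H^T y)_z = valid-region correlation of the frame with h_z."""
        y = np.asarray(frame_data, dtype=np.float64)
        if y.shape != self.frame_shape:
            raise ValueError(f"frame shape {y.shape} != {self.frame_shape}")
        Yf = fft.rfft2(y)
        out = fft.irfft2(Yf[None] * np.conj(self._Hf), s=self.frame_shape)
        Ys, Xs = self.object_shape_yx
        return np.ascontiguousarray(out[:, :Ys, :Xs])

    def normal(self, volume_data: np.ndarray) -> np.ndarray:
        """H^T H x without leaving Fourier space for the intermediate frame."""
        x = np.asarray(volume_data, dtype=np.float64)
        Xf = fft.rfft2(x, s=self.frame_shape)
        Gf = (Xf * self._Hf).sum(axis=0)
        out = fft.irfft2(Gf[None] * np.conj(self._Hf), s=self.frame_shape)
        Ys, Xs = self.object_shape_yx
        return np.ascontiguousarray(out[:, :Ys, :Xs])


def project(volume: Volume, psf: PSFStack) -> LightFieldFrame:
    """Project a volume through the light-field system onto one camera frame.

    Raises on mismatched z grids or an empty volume; clips the FFT round-off
    (~1e-16 relative) so the returned frame is nonnegative.
    """
    if volume.data.shape[0] != psf.n_z or not np.allclose(
            volume.z_positions_um, psf.z_positions_um, atol=1e-6):
        raise ValueError("volume and PSF stack must share the same z grid")
    if volume.data.size == 0:
        raise ValueError("empty volume")
    op = FLFOperator(psf, volume.data.shape[1:])
    y = np.maximum(op.forward(volume.data), 0.0)
    return LightFieldFrame(data=y, elemental_layout=_frame_layout(psf, op.frame_shape))


def adjoint(frame: LightFieldFrame, psf: PSFStack,
            object_shape_yx: tuple[int, int] | None = None) -> Volume:
    """Apply the transpose operator H^T to a camera frame.

    ``object_shape_yx`` defaults to the largest grid consistent with the
    frame and PSF canvas sizes.
    """
    V, U = psf.canvas_shape
    if object_shape_yx is None:
        fy, fx = frame.data.shape
        object_shape_yx = (fy - V + 1, fx - U + 1)
        if object_shape_yx[0] < 1 or object_shape_yx[1] < 1:
            raise ValueError("frame smaller than the PSF canvas")
    op = FLFOperator(psf, object_shape_yx)
    x = op.adjoint(frame.data)
    dz = (np.diff(psf.z_positions_um)[0] if psf.n_z > 1 else psf.pixel_um)
    return Volume(data=x, voxel_size_um=(psf.pixel_um, psf.pixel_um, dz),
                  z_positions_um=psf.z_positions_um)
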