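"""Mid-infrared photothermal (MIP) signal extraction from paired frames.

A thermosensitive fluorophore dims while the mid-IR pump heats its
surroundings (~1% per kelvin), so the photothermal contrast at pump
wavenumber nu lives in the difference between the IR-off and IR-on camera
frames.  The FMIP ratio signal normalizes that difference by the IR-off
fluorescence, making it proportional to the local IR absorption and
independent of dye concentration and detection gain.

Sign convention: positive signal = fluorescence decreased under IR heating
(off - on).  Negative pixels/voxels are retained, not clipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
from skimage.registration import phase_cross_correlation

from .forward import LightFieldFrame, Volume
from .optics import PSFStack
from .recon import ReconResult, ReconSettings, reconstruct

__all__ = ["FramePair", "fmip_difference", "fmip_ratio", "reconstruct_fmip_volume"]

logger = logging.getLogger(__name__)


@dataclass
class FramePair:
    """One IR-on / IR-off light-field frame pair at a single pump wavenumber."""

    ir_on: LightFieldFrame
    ir_off: LightFieldFrame
    wavenumber_cm1: float

    def __post_init__(self) -> None:
        if self.ir_on.data.shape != self.ir_off.data.shape:
            raise ValueError("IR-on and IR-off frames must share canvas geometry")
        if self.ir_on.exposure_tag not in ("ir_on", "plain") or \
           self.ir_off.exposure_tag not in ("ir_off", "plain"):
            raise ValueError("frame exposure tags inconsistent with pair roles")


def _check_drift(pair: FramePair, max_shift_px: float = 0.5) -> None:
    """Log (never correct) any apparent on/off registration drift."""
    off = pair.ir_off.data
    if off.max() <= 0:
        return
    try:
        shift, _, _ = phase_cross_correlation(off, pair.ir_on.data,
                                              upsample_factor=10,
                                              normalization=None)
    except (ValueError, ZeroDivisionError):
        return
    if np.hypot(*shift) > max_shift_px:
        logger.warning("IR-on/IR-off drift of %.2f px detected (not corrected)",
                       float(np.hypot(*shift)))


def fmip_difference(pair: FramePair) -> LightFieldFrame:
    """Photothermal difference frame, IR-off minus IR-on (unclipped)."""
    _check_drift(pair)
    return LightFieldFrame(data=pair.ir_off.data - pair.ir_on.data,
                           elemental_layout=pair.ir_off.elemental_layout,
                           exposure_tag="plain")


def default_ratio_floor(frame: LightFieldFrame) -> float:
    """Division guard: 1% of the frame's 99th-percentile intensity."""
    return 0.01 * float(np.percentile(frame.data, 99.0))


def fmip_ratio(pair: FramePair, floor: float | None = None) -> np.ma.MaskedArray:
    """Ratio signal (off - on) / off, masked where IR-off is below ``floor``."""
    if floor is None:
        floor = default_ratio_floor(pair.ir_off)
    if floor <= 0:
        raise ValueError("floor must be positive")
    off = pair.ir_off.data
    ratio = (off - pair.ir_on.data) / np.maximum(off, floor)
    return np.ma.masked_array(ratio, mask=off < floor)


def reconstruct_fmip_volume(
    pair: FramePair,
    psf: PSFStack,
    settings: ReconSettings = ReconSettings(),
    mode: Literal["diff-then-recon", "recon-then-diff"] = "diff-then-recon",
    frame_scale: float | None = None,
) -> Volume:
    """3D photothermal volume from one frame pair.

    diff-then-recon (default): deconvolve the single difference frame — the
    sign that dominates the difference is reconstructed under the
    nonnegativity constraint and restored afterwards, so only two frames are
    consumed per volume (half the camera frame rate).  recon-then-diff:
    deconvolve both frames independently and subtract the volumes.

    ``frame_scale`` divides the frames before solving and rescales the volume
    after, so the (absolute) regularization weights act on a normalized
    measurement; pass one common scale across a wavenumber sweep to preserve
    the spectral shape.
    """
    s = 1.0 if not frame_scale else float(frame_scale)
    if mode == "diff-then-recon":
        diff = fmip_difference(pair).data
        pos = float(np.clip(diff, 0, None).sum())
        neg = float(np.clip(-diff, 0, None).sum())
        sign = 1.0 if pos >= neg else -1.0
        res = reconstruct(LightFieldFrame(data=sign * diff / s), psf, settings)
        out = res.volume
        out.data = sign * s * out.data
        return out
    if mode == "recon-then-diff":
        off = reconstruct(LightFieldFrame(data=pair.ir_off.data / s), psf,
                          settings).volume
        on = reconstruct(LightFieldFrame(data=pair.ir_on.data / s), psf,
                         settings).volume
        off.data = s * (off.data - on.data)
        return off
    raise ValueError(f"unknown mode {mode!r}")
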