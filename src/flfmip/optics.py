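"""Optical configuration, light-field PSF simulation and bead calibration.

A Fourier light-field (FLF) microscope places a lenslet array at a
pupil-conjugate plane, so each lenslet sees one angular sub-aperture of the
objective pupil and forms its own perspective "elemental image" on a shared
camera canvas.  Depth is encoded as parallax: a point source displaced by
``z`` from the nominal focal plane appears laterally shifted in each
elemental image, at a rate set by the chief-ray angle of that lenslet's
sub-aperture, and its spot widens with defocus.

All simulation is carried out on a sample-plane-referred grid: one "pixel"
equals one lateral voxel (``voxel_size_um[0]``), so PSF stacks plug directly
into the volumetric forward model without a magnification bookkeeping layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage, special

__all__ = [
    "OpticalConfig",
    "PSFStack",
    "BeadStack",
    "simulate_psf_stack",
    "calibrate_psf_from_beads",
]

Normalization = Literal["per-slice-sum-one", "global-peak-one"]


@dataclass(frozen=True)
class OpticalConfig:
    """Instrument parameters of the FLF fluorescence arm.

    Defaults reproduce a high-NA subcellular configuration: a 100x / 0.95 NA
    dry objective, a 2 x 2 lenslet array occupying the pupil diameter with
    occupancy ratio ``N = 2``, 520 nm pulsed excitation and ~560 nm emission.
    ``camera_pixel_um`` is a free parameter of the hardware description and is
    not used by the sample-plane-referred simulation.
    """

    numerical_aperture: float = 0.95
    magnification: float = 100.0
    excitation_wavelength_nm: float = 520.0
    emission_wavelength_nm: float = 560.0
    lenslet_grid: tuple[int, int] = (2, 2)
    lenslet_occupancy_N: float = 2.0
    fourier_lens_focal_mm: float = 150.0
    camera_pixel_um: float = 6.5
    voxel_size_um: tuple[float, float, float] = (0.3, 0.3, 0.35)
    z_range_um: tuple[float, float] = (-2.625, 2.625)
    fov_um: tuple[float, float] = (19.2, 19.2)

    def __post_init__(self) -> None:
        if not (0.0 < self.numerical_aperture <= 1.0):
            raise ValueError("numerical_aperture must lie in (0, 1]")
        if self.magnification <= 0:
            raise ValueError("magnification must be positive")
        for name in ("excitation_wavelength_nm", "emission_wavelength_nm",
                     "fourier_lens_focal_mm", "camera_pixel_um",
                     "lenslet_occupancy_N"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.emission_wavelength_nm < self.excitation_wavelength_nm:
            raise ValueError("emission wavelength must be >= excitation (Stokes shift)")
        if any(n < 1 for n in self.lenslet_grid):
            raise ValueError("lenslet_grid entries must be >= 1")
        if self.lenslet_occupancy_N < 1:
            raise ValueError("lenslet_occupancy_N must be >= 1")
        if any(v <= 0 for v in self.voxel_size_um) or any(v <= 0 for v in self.fov_um):
            raise ValueError("voxel and FOV sizes must be positive")
        if not self.z_range_um[0] < self.z_range_um[1]:
            raise ValueError("z_range_um must satisfy z_min < z_max")

    # --- derived geometry -------------------------------------------------

    @property
    def subaperture_na(self) -> float:
        """Effective NA of one lenslet sub-aperture, NA / N."""
        return self.numerical_aperture / self.lenslet_occupancy_N

    def z_grid_um(self) -> np.ndarray:
        """Axial sample positions spanning ``z_range_um`` at the voxel dz."""
        z0, z1 = self.z_range_um
        dz = self.voxel_size_um[2]
        n = int(round((z1 - z0) / dz)) + 1
        return z0 + dz * np.arange(n)

    def lateral_shape(self) -> tuple[int, int]:
        """(ny, nx) of the object grid covering the FOV."""
        dx = self.voxel_size_um[0]
        return (int(round(self.fov_um[1] / dx)), int(round(self.fov_um[0] / dx)))

    def lenslet_pupil_fractions(self) -> np.ndarray:
        """Per-lenslet pupil-plane centers as fractions of the pupil radius.

        The pupil diameter spans ``N`` lenslet pitches, so the pitch is
        ``2 / N`` in pupil-radius units and the grid is centered on the axis.
        Shape (rows * cols, 2) in (row, col) order.
        """
        rows, cols = self.lenslet_grid
        pitch = 2.0 / self.lenslet_occupancy_N
        fr = (np.arange(rows) - (rows - 1) / 2.0) * pitch
        fc = (np.arange(cols) - (cols - 1) / 2.0) * pitch
        return np.array([(r, c) for r in fr for c in fc])

    def parallax_rates_um_per_um(self) -> np.ndarray:
        """Lateral elemental-spot shift per unit defocus, per lenslet.

        The chief ray through a lenslet centered at pupil fraction f makes an
        angle theta with sin(theta) = f * NA; a source defocused by z shifts
        by z * tan(theta) in that elemental image.  Shape (n_lenslets, 2).
        """
        frac = self.lenslet_pupil_fractions()
        s = np.clip(frac * self.numerical_aperture, -0.999, 0.999)
        return s / np.sqrt(1.0 - s**2)

    def infocus_spot_sigma_um(self) -> float:
        """Gaussian sigma of the diffraction-limited elemental spot at focus."""
        lam_um = self.emission_wavelength_nm * 1e-3
        fwhm = 0.51 * lam_um / self.subaperture_na
        return fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))

    def defocus_sigma_rate(self) -> float:
        """Spot-width growth rate with |z| from the sub-aperture cone angle."""
        s = min(self.subaperture_na, 0.999)
        return 0.5 * s / math.sqrt(1.0 - s**2)


@dataclass
class PSFStack:
    """Depth-indexed 2D light-field PSFs: the calibrated system response H.

    ``data`` is (z, v, u) with one composite camera-canvas PSF per depth;
    all elemental sub-spots of a given depth live on the same canvas.
    """

    data: np.ndarray
    z_positions_um: np.ndarray
    pixel_um: float
    normalization: Normalization = "per-slice-sum-one"
    lenslet_boxes: list[tuple[int, int, int, int]] | None = None
    bead_centroids_px: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.z_positions_um = np.asarray(self.z_positions_um, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("PSF data must be a 3D (z, v, u) array")
        if len(self.z_positions_um) != self.data.shape[0]:
            raise ValueError("z_positions_um length must match the z axis")
        if np.any(self.data < 0):
            raise ValueError("PSF data must be nonnegative")
        dz = np.diff(self.z_positions_um)
        if len(dz):
            if np.any(dz <= 0):
                raise ValueError("z_positions_um must be strictly increasing")
            if np.ptp(dz) > 1e-6 * abs(dz[0]):
                raise ValueError("z spacing must be uniform")

    @property
    def n_z(self) -> int:
        return self.data.shape[0]

    @property
    def canvas_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def normalized(self, normalization: Normalization | None = None) -> "PSFStack":
        """Return a copy normalized per-slice-sum-one or global-peak-one."""
        norm = normalization or self.normalization
        out = self.data.copy()
        if norm == "per-slice-sum-one":
            sums = out.sum(axis=(1, 2), keepdims=True)
            sums[sums == 0] = 1.0
            out /= sums
        elif norm == "global-peak-one":
            peak = out.max()
            if peak > 0:
                out /= peak
        else:
            raise ValueError(f"unknown normalization {norm!r}")
        return replace(self, data=out, normalization=norm)

    def resample_z(self, new_z_um: Sequence[float]) -> "PSFStack":
        """Linearly interpolate the stack onto a new axial grid.

        Used to move a finely-stepped calibration stack (e.g. 0.1 um bead
        scan) onto a coarser reconstruction grid.  Renormalizes afterwards.
        """
        new_z = np.asarray(new_z_um, dtype=np.float64)
        z = self.z_positions_um
        if new_z.min() < z.min() - 1e-9 or new_z.max() > z.max() + 1e-9:
            raise ValueError("requested z positions fall outside the calibrated range")
        idx = np.clip(np.searchsorted(z, new_z, side="right") - 1, 0, len(z) - 2)
        w = (new_z - z[idx]) / (z[idx + 1] - z[idx])
        out = ((1.0 - w)[:, None, None] * self.data[idx]
               + w[:, None, None] * self.data[idx + 1])
        return replace(self, data=out, z_positions_um=new_z,
                       bead_centroids_px=None).normalized()


@dataclass
class BeadStack:
    """A raw bead-scan z-stack: one camera image per axial stage position."""

    data: np.ndarray
    z_positions_um: np.ndarray
    pixel_um: float


def _elemental_canvas(cfg: OpticalConfig) -> tuple[int, list[tuple[int, int, int, int]], np.ndarray]:
    """Canvas layout: per-lenslet cell size, boxes and reference centers (px)."""
    ny, nx = cfg.lateral_shape()
    dx = cfg.voxel_size_um[0]
    zmax = max(abs(cfg.z_range_um[0]), abs(cfg.z_range_um[1]))
    rate = np.abs(cfg.parallax_rates_um_per_um()).max() if cfg.lenslet_grid != (1, 1) else 0.0
    sigma_max = math.hypot(cfg.infocus_spot_sigma_um(), cfg.defocus_sigma_rate() * zmax)
    margin = int(math.ceil((zmax * rate + 4.0 * sigma_max) / dx)) + 2
    cell = max(ny, nx) + 2 * margin
    rows, cols = cfg.lenslet_grid
    boxes = []
    centers = []
    for i in range(rows):
        for j in range(cols):
            r0, c0 = i * cell, j * cell
            boxes.append((r0, r0 + cell, c0, c0 + cell))
            centers.append(((r0 + r0 + cell - 1) / 2.0, (c0 + c0 + cell - 1) / 2.0))
    return cell, boxes, np.array(centers)


def _spot(shape: tuple[int, int], center: tuple[float, float], sigma_px: float,
          kind: str) -> np.ndarray:
    rr = np.arange(shape[0])[:, None] - center[0]
    cc = np.arange(shape[1])[None, :] - center[1]
    r2 = rr**2 + cc**2
    if kind == "gaussian":
        return np.exp(-r2 / (2.0 * sigma_px**2))
    # Airy: first zero at 1.22 * pi in the argument of J1; scale so the core
    # FWHM matches the Gaussian parameterization (FWHM_airy ~ 1.029 lambda/2NA).
    fwhm_px = 2.0 * math.sqrt(2.0 * math.log(2.0)) * sigma_px
    a = 3.2327 / (fwhm_px / 2.0)  # half-max of (2 J1(x)/x)^2 at x = 1.6163
    x = a * np.sqrt(r2)
    with np.errstate(invalid="ignore", divide="ignore"):
        amp = np.where(x == 0.0, 1.0, (2.0 * special.j1(x) / np.where(x == 0, 1, x))**2)
    return amp


def simulate_psf_stack(
    cfg: OpticalConfig,
    model_kind: Literal["gaussian-parallax", "airy-parallax"] = "gaussian-parallax",
    normalization: Normalization = "per-slice-sum-one",
) -> PSFStack:
    """Simulate the depth-dependent composite light-field PSF stack.

    Each depth slice composites one elemental spot per lenslet on a single
    canvas.  The spot belonging to the lenslet at pupil fraction f is
    displaced from its reference center by ``z * tan(asin(f * NA))`` per axis
    (linear parallax) and widened as ``sigma(z) = hypot(sigma0, k |z|)``
    (geometric defocus of the sub-aperture cone).
    """
    if model_kind not in ("gaussian-parallax", "airy-parallax"):
        raise ValueError(f"unknown PSF model {model_kind!r}")
    z = cfg.z_grid_um()
    if len(z) < 3:
        raise ValueError("z range must cover at least 3 slices")
    cell, boxes, centers = _elemental_canvas(cfg)
    rows, cols = cfg.lenslet_grid
    canvas = (rows * cell, cols * cell)
    if canvas[0] > 8192 or canvas[1] > 8192:
        raise ValueError("lenslet grid exceeds the maximum canvas size")
    dx = cfg.voxel_size_um[0]
    rates = cfg.parallax_rates_um_per_um()  # (n_lenslets, 2) um/um
    sigma0 = cfg.infocus_spot_sigma_um()
    k = cfg.defocus_sigma_rate()
    kind = "gaussian" if model_kind == "gaussian-parallax" else "airy"

    data = np.zeros((len(z), *canvas))
    for iz, zi in enumerate(z):
        sigma_px = math.hypot(sigma0, k * zi) / dx
        for il, (cr, cc) in enumerate(centers):
            shift_px = rates[il] * zi / dx
            ctr = (cr + shift_px[0], cc + shift_px[1])
            r0, r1, c0, c1 = boxes[il]
            data[iz, r0:r1, c0:c1] += _spot((cell, cell),
                                            (ctr[0] - r0, ctr[1] - c0),
                                            sigma_px, kind)
    stack = PSFStack(data=data, z_positions_um=z, pixel_um=dx,
                     normalization=normalization, lenslet_boxes=boxes)
    return stack.normalized()


def calibrate_psf_from_beads(
    stack: BeadStack | np.ndarray,
    cfg: OpticalConfig,
    background_percentile: float = 0.10,
    z_positions_um: Sequence[float] | None = None,
    pixel_um: float | None = None,
    normalization: Normalization = "per-slice-sum-one",
) -> PSFStack:
    """Calibrate a PSF stack from a single-bead axial scan.

    Per slice: subtract a percentile background floor, clip at zero, then
    normalize.  The scan must contain exactly one bead — i.e. exactly one
    bright spot per lenslet; more candidates raise an ambiguity error, a
    featureless stack raises a no-bead error.  The intensity-weighted bead
    centroid is recorded per slice for drift inspection.
    """
    if isinstance(stack, BeadStack):
        data = np.asarray(stack.data, dtype=np.float64)
        z_positions_um = stack.z_positions_um
        pixel_um = stack.pixel_um
    else:
        data = np.asarray(stack, dtype=np.float64)
        if z_positions_um is None:
            z_positions_um = cfg.z_grid_um()
        if pixel_um is None:
            pixel_um = cfg.voxel_size_um[0]
    if data.ndim != 3 or data.shape[0] < 1:
        raise ValueError("bead stack must be a 3D (z, v, u) array")
    if not (0.0 <= background_percentile < 1.0):
        raise ValueError("background_percentile must lie in [0, 1)")

    floors = np.percentile(data, background_percentile * 100.0, axis=(1, 2),
                           keepdims=True)
    clean = np.clip(data - floors, 0.0, None)
    if clean.max() <= 0:
        raise ValueError("no bead found: stack is empty after background subtraction")

    # Spot counting on the z-projection: one bead yields one spot per lenslet.
    proj = clean.sum(axis=0)
    peak = proj.max()
    if peak <= 0:
        raise ValueError("no bead found in the z-projection")
    labels, n_spots = ndimage.label(proj > 0.3 * peak)
    n_expected = cfg.lenslet_grid[0] * cfg.lenslet_grid[1]
    if n_spots == 0:
        raise ValueError("no bead found: no spot exceeds the detection threshold")
    if n_spots > n_expected:
        raise ValueError(
            f"ambiguous calibration: {n_spots} candidate spots for "
            f"{n_expected} lenslets — more than one bead in the imaging area?")

    centroids = np.array([
        ndimage.center_of_mass(s) if s.sum() > 0 else (np.nan, np.nan)
        for s in clean
    ])
    out = PSFStack(data=clean, z_positions_um=np.asarray(z_positions_um, float),
                   pixel_um=float(pixel_um), normalization=normalization,
                   bead_centroids_px=centroids)
    return out.normalized()
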