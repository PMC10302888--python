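"""Synthetic phantoms with ground truth for every acquisition the pipeline
consumes: fluorophore volumes with per-band IR absorption maps, paired
IR-on/IR-off light-field frames, and single-bead PSF calibration z-stacks.

The photothermal physics is encoded multiplicatively at the object: the pump
at wavenumber nu raises the local temperature in proportion to the local
absorption, and the fluorescence dims by ``modulation_per_kelvin`` (default
1 %/K for thermosensitive dyes) per kelvin of rise, so

    m(r) = modulation_per_kelvin * temperature_rise_K
           * sum_bands Lhat_band(nu) * absorption_band(r),

with each band's Lorentzian Lhat normalized to 1 at its center.  Heat
diffusion during the ~50 ns pump pulse spreads over ~0.17 um, below a voxel,
so the temperature field is taken as locally proportional to absorption.
Camera noise is Poisson photon noise at a configurable peak photon budget
plus additive Gaussian read noise, applied independently to the on and off
frames.  All randomness flows from ``PhantomSpec.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .forward import LightFieldFrame, Volume, project
from .mip import FramePair
from .optics import BeadStack, OpticalConfig, PSFStack
from .spectra import lorentzian

__all__ = [
    "LorentzianBand",
    "NoiseModel",
    "PhantomSpec",
    "LIPID_ESTER_BAND",
    "LIPID_13C_BAND",
    "AMIDE_I_BAND",
    "generate_volume",
    "generate_frame_pair",
    "generate_bead_calibration_stack",
]


@dataclass(frozen=True)
class LorentzianBand:
    """One vibrational absorption band: center, half-width, peak amplitude."""

    center_cm1: float
    hwhm_cm1: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.hwhm_cm1 <= 0:
            raise ValueError("hwhm_cm1 must be positive")
        if self.amplitude < 0:
            raise ValueError("band amplitude must be nonnegative")

    def response(self, wavenumber_cm1: float) -> float:
        """Unit-peak Lorentzian response at the pump wavenumber."""
        return float(lorentzian(wavenumber_cm1, self.center_cm1,
                                self.hwhm_cm1, 1.0))


#: Ester C=O stretch of endogenous (de novo) lipids.
LIPID_ESTER_BAND = LorentzianBand(1744.0, 10.0, 1.0)
#: 13C-shifted carbonyl of lipids built from labeled fatty acids.
LIPID_13C_BAND = LorentzianBand(1704.0, 10.0, 1.0)
#: Protein amide-I backbone stretch (bacteria imaging).
AMIDE_I_BAND = LorentzianBand(1650.0, 12.0, 1.0)


@dataclass(frozen=True)
class NoiseModel:
    """Camera noise: Poisson at ``peak_photons`` for the brightest IR-off
    pixel, plus Gaussian read noise (photon units).  ``None`` = noiseless."""

    peak_photons: float | None = 1e5
    read_noise_photons: float = 2.0


@dataclass(frozen=True)
class PhantomSpec:
    """Scene description for the synthetic generator.

    ``bands`` holds one band list per object class; objects are assigned to
    classes cyclically, so e.g. ``((LIPID_ESTER_BAND,), (LIPID_13C_BAND,))``
    alternates endogenous and isotope-labeled droplets.
    """

    kind: Literal["beads", "rods-on-tilted-substrate", "cell-with-droplets"] = "beads"
    n_objects: int = 5
    object_size_um: float = 0.5          # rod length / droplet default radius
    tilt_deg: float = 20.0               # substrate tilt (rods)
    droplet_radius_range_um: tuple[float, float] = (0.4, 0.8)
    bands: tuple[tuple[LorentzianBand, ...], ...] = ((LIPID_ESTER_BAND,),)
    modulation_per_kelvin: float = 0.01
    temperature_rise_K: float = 1.0
    noise: NoiseModel = NoiseModel()
    seed: int = 0
    positions_um: tuple[tuple[float, float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.n_objects < 1:
            raise ValueError("n_objects must be >= 1")
        if self.object_size_um <= 0 or any(r <= 0 for r in self.droplet_radius_range_um):
            raise ValueError("object sizes must be positive")
        if self.modulation_per_kelvin < 0 or self.temperature_rise_K < 0:
            raise ValueError("modulation and temperature rise must be nonnegative")


def _grids(cfg: OpticalConfig):
    z = cfg.z_grid_um()
    ny, nx = cfg.lateral_shape()
    dx, dy, dz = cfg.voxel_size_um
    return z, ny, nx, dx, dy, dz


def _empty_volume(cfg: OpticalConfig) -> Volume:
    z, ny, nx, dx, dy, dz = _grids(cfg)
    return Volume(data=np.zeros((len(z), ny, nx)),
                  voxel_size_um=cfg.voxel_size_um, z_positions_um=z)


def _sphere_mask(cfg: OpticalConfig, center_um: np.ndarray, radius_um: float
                 ) -> np.ndarray:
    z, ny, nx, dx, dy, dz = _grids(cfg)
    zz = z[:, None, None]
    yy = (dy * np.arange(ny))[None, :, None]
    xx = (dx * np.arange(nx))[None, None, :]
    r2 = ((zz - center_um[2]) ** 2 + (yy - center_um[1]) ** 2
          + (xx - center_um[0]) ** 2)
    return r2 <= radius_um**2


def generate_volume(spec: PhantomSpec, cfg: OpticalConfig
                    ) -> tuple[Volume, dict[LorentzianBand, Volume], dict]:
    """Build the fluorophore volume plus one absorption map per band.

    Returns ``(fluorescence, {band: absorption Volume}, truth)`` where
    ``truth`` records object positions (um, in (x, y, z)), classes and sizes.
    Band amplitudes are folded into the absorption maps, so downstream
    modulation uses unit-peak line shapes.
    """
    rng = np.random.default_rng(spec.seed)
    z, ny, nx, dx, dy, dz = _grids(cfg)
    fluor = np.zeros((len(z), ny, nx))
    absorption: dict[LorentzianBand, np.ndarray] = {}
    for cls in spec.bands:
        for band in cls:
            absorption.setdefault(band, np.zeros_like(fluor))

    positions: list[tuple[float, float, float]] = []
    classes: list[int] = []
    sizes: list[float] = []

    def add_density(mask_or_idx, weight, cls_idx):
        bands = spec.bands[cls_idx % len(spec.bands)]
        if isinstance(mask_or_idx, tuple):
            fluor[mask_or_idx] += weight
            for band in bands:
                absorption[band][mask_or_idx] += weight * band.amplitude
        else:
            fluor[mask_or_idx] += weight
            for band in bands:
                absorption[band][mask_or_idx] += weight * band.amplitude

    if spec.kind == "beads":
        pts = _bead_positions(spec, cfg, rng)
        for i, p in enumerate(pts):
            idx = _nearest_voxel(cfg, p)
            add_density(idx, 1.0, i)
            positions.append(tuple(p))
            classes.append(i % len(spec.bands))
            sizes.append(0.175)
    elif spec.kind == "rods-on-tilted-substrate":
        _add_rods(spec, cfg, rng, add_density, positions, classes, sizes)
    elif spec.kind == "cell-with-droplets":
        _add_cell_with_droplets(spec, cfg, rng, add_density, positions,
                                classes, sizes)
    else:
        raise ValueError(f"unknown phantom kind {spec.kind!r}")

    vol = Volume(data=fluor, voxel_size_um=cfg.voxel_size_um, z_positions_um=z)
    maps = {b: Volume(data=a, voxel_size_um=cfg.voxel_size_um,
                      z_positions_um=z) for b, a in absorption.items()}
    truth = {"positions_um": positions, "classes": classes, "sizes_um": sizes,
             "kind": spec.kind}
    return vol, maps, truth


def _nearest_voxel(cfg: OpticalConfig, pos_um: Sequence[float]
                   ) -> tuple[int, int, int]:
    z, ny, nx, dx, dy, dz = _grids(cfg)
    x_um, y_um, z_um = pos_um
    iz = int(np.clip(round((z_um - z[0]) / dz), 0, len(z) - 1))
    iy = int(np.clip(round(y_um / dy), 0, ny - 1))
    ix = int(np.clip(round(x_um / dx), 0, nx - 1))
    return (iz, iy, ix)


def _bead_positions(spec: PhantomSpec, cfg: OpticalConfig,
                    rng: np.random.Generator) -> np.ndarray:
    z, ny, nx, dx, dy, dz = _grids(cfg)
    if spec.positions_um is not None:
        return np.asarray(spec.positions_um, dtype=float)
    if spec.n_objects == 1:
        # Deterministic centered bead (exactly on a voxel center).
        return np.array([[(nx // 2) * dx, (ny // 2) * dy, z[len(z) // 2]]])
    margin_xy = 4
    margin_z = 1
    pts = np.column_stack([
        rng.uniform(margin_xy * dx, (nx - 1 - margin_xy) * dx, spec.n_objects),
        rng.uniform(margin_xy * dy, (ny - 1 - margin_xy) * dy, spec.n_objects),
        rng.uniform(z[margin_z], z[-1 - margin_z], spec.n_objects),
    ])
    return pts


def _add_rods(spec, cfg, rng, add_density, positions, classes, sizes):
    """Rod-shaped objects (bacteria-like) whose centroids lie on a plane
    tilted about the y axis, so depth spans the z range as x advances."""
    z, ny, nx, dx, dy, dz = _grids(cfg)
    slope = np.tan(np.deg2rad(spec.tilt_deg))
    x_lo, x_hi = 4 * dx, (nx - 5) * dx
    x_mid = 0.5 * (x_lo + x_hi)
    for i in range(spec.n_objects):
        xc = rng.uniform(x_lo, x_hi)
        yc = rng.uniform(4 * dy, (ny - 5) * dy)
        zc = float(np.clip(slope * (xc - x_mid), z[0], z[-1]))
        zc = float(z[int(np.argmin(np.abs(z - zc)))])  # snap to a slice
        theta = rng.uniform(0, np.pi)
        half = spec.object_size_um / 2.0
        n_seg = max(int(np.ceil(spec.object_size_um / min(dx, dy))) * 2 + 1, 3)
        for t in np.linspace(-half, half, n_seg):
            p = (xc + t * np.cos(theta), yc + t * np.sin(theta), zc)
            add_density(_nearest_voxel(cfg, p), 1.0 / n_seg, i)
        positions.append((xc, yc, zc))
        classes.append(i % len(spec.bands))
        sizes.append(spec.object_size_um)


def _add_cell_with_droplets(spec, cfg, rng, add_density, positions, classes,
                            sizes):
    """Spherical lipid droplets scattered in a cell body, sparing a central
    nucleus region (droplets accumulate in the cytoplasm)."""
    z, ny, nx, dx, dy, dz = _grids(cfg)
    cx, cy = (nx // 2) * dx, (ny // 2) * dy
    cell_r = 0.45 * min(nx * dx, ny * dy)
    nucleus_r = 0.4 * cell_r
    r_lo, r_hi = spec.droplet_radius_range_um
    placed = 0
    attempts = 0
    while placed < spec.n_objects and attempts < 200 * spec.n_objects:
        attempts += 1
        radius = rng.uniform(r_lo, r_hi)
        rho = rng.uniform(nucleus_r + radius, cell_r - radius)
        phi = rng.uniform(0, 2 * np.pi)
        x_um = cx + rho * np.cos(phi)
        y_um = cy + rho * np.sin(phi)
        z_um = rng.uniform(z[0] + radius, z[-1] - radius) \
            if z[-1] - z[0] > 2 * radius else 0.5 * (z[0] + z[-1])
        mask = _sphere_mask(cfg, np.array([x_um, y_um, z_um]), radius)
        if not mask.any():
            continue
        add_density(mask, 1.0, placed)
        positions.append((x_um, y_um, z_um))
        classes.append(placed % len(spec.bands))
        sizes.append(radius)
        placed += 1
    if placed < spec.n_objects:
        raise ValueError("could not fit the requested droplets in the FOV")


def modulation_field(absorption: dict[LorentzianBand, Volume],
                     wavenumber_cm1: float, spec: PhantomSpec) -> np.ndarray:
    """Fractional fluorescence dimming m(r) at the given pump wavenumber."""
    m = None
    for band, vol in absorption.items():
        term = (spec.modulation_per_kelvin * spec.temperature_rise_K
                * band.response(wavenumber_cm1) * vol.data)
        m = term if m is None else m + term
    if m is None:
        raise ValueError("no absorption bands supplied")
    return m


def _apply_noise(frame: np.ndarray, scale: float, noise: NoiseModel,
                 rng: np.random.Generator) -> np.ndarray:
    counts = rng.poisson(frame * scale).astype(np.float64)
    counts += rng.normal(0.0, noise.read_noise_photons, size=frame.shape)
    return counts / scale


def generate_frame_pair(fluorescence: Volume,
                        absorption: dict[LorentzianBand, Volume],
                        psf: PSFStack,
                        wavenumber_cm1: float,
                        spec: PhantomSpec,
                        rng: np.random.Generator | None = None) -> FramePair:
    """Simulate one IR-on / IR-off frame pair at a pump wavenumber.

    The IR-off frame images the unperturbed fluorophores; the IR-on frame
    images ``fluorescence * (1 - m)`` with the modulation field m defined in
    the module docstring.  Poisson + read noise is then applied per frame.
    """
    m = modulation_field(absorption, wavenumber_cm1, spec)
    if m.max() > 1.0:
        raise ValueError("unphysical spec: modulation exceeds 100%")
    off = project(fluorescence, psf)
    on_vol = Volume(data=fluorescence.data * (1.0 - m),
                    voxel_size_um=fluorescence.voxel_size_um,
                    z_positions_um=fluorescence.z_positions_um)
    on = project(on_vol, psf)

    if spec.noise.peak_photons:
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        peak = off.data.max()
        scale = spec.noise.peak_photons / peak if peak > 0 else 1.0
        off_data = _apply_noise(off.data, scale, spec.noise, rng)
        on_data = _apply_noise(on.data, scale, spec.noise, rng)
    else:
        off_data, on_data = off.data, on.data

    layout = off.elemental_layout
    return FramePair(
        ir_on=LightFieldFrame(data=on_data, elemental_layout=layout,
                              exposure_tag="ir_on"),
        ir_off=LightFieldFrame(data=off_data, elemental_layout=layout,
                               exposure_tag="ir_off"),
        wavenumber_cm1=wavenumber_cm1)


def generate_bead_calibration_stack(psf: PSFStack,
                                    noise: NoiseModel | None = None,
                                    seed: int = 0,
                                    amplitude: float = 1000.0) -> BeadStack:
    """Synthesize a single-bead axial calibration scan from a PSF stack.

    Each slice is the PSF at that depth scaled to ``amplitude`` peak photons
    at focus, with optional Poisson + read noise; feed the result to
    :func:`flfmip.optics.calibrate_psf_from_beads`.
    """
    rng = np.random.default_rng(seed)
    peak = psf.data.max()
    data = psf.data * (amplitude / peak if peak > 0 else 1.0)
    if noise is not None and noise.peak_photons:
        data = rng.poisson(data).astype(np.float64)
        data += rng.normal(0.0, noise.read_noise_photons, size=data.shape)
        data = np.clip(data, 0.0, None)
    return BeadStack(data=data, z_positions_um=psf.z_positions_um.copy(),
                     pixel_um=psf.pixel_um)
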