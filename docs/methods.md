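# Methods

## Optical model

The simulated instrument is a Fourier light-field fluorescence microscope: a
lenslet array at a pupil-conjugate plane splits the objective pupil into
angular sub-apertures, each forming one elemental image on a shared camera
canvas. Everything is computed on a sample-plane-referred grid (one PSF pixel
= one lateral voxel), which removes magnification bookkeeping from the
forward model.

The depth-dependent PSF is phenomenological, not wave-optical. For a lenslet
centered at pupil fraction `f` (per axis), a point source defocused by `z`
shifts laterally by `z · tan(asin(f · NA))` in that lenslet's elemental
image — depth is encoded purely as parallax, which is exactly how the real
system derives axial resolution. The elemental spot is a Gaussian (or Airy)
whose width grows with defocus, `σ(z) = hypot(σ₀, k·z)`, with

- `σ₀` from the diffraction limit of one sub-aperture
  (`FWHM ≈ 0.51 λ_em / (NA/N)`, `N` = pupil occupancy of the lenslet array),
- `k = ½ tan(asin(NA/N))`, the geometric blur growth of the sub-aperture
  cone.

For the default configuration (NA 0.95, N 2, λ_em 560 nm) this gives
σ₀ ≈ 0.26 μm and a parallax rate of ±0.54 μm lateral shift per μm of
defocus per axis. The canvas is tiled into one cell per lenslet with a
margin sized to the worst-case parallax excursion plus 4σ of spot support,
so elemental images never overlap — mirroring the field stop that prevents
crosstalk in hardware.

Defaults match the reference instrument: 100×/0.95 NA, 2×2 lenslets with
occupancy 2, 520/560 nm excitation/emission, 150 mm Fourier lens, and a
64×64×16 voxel reconstruction grid at 0.3×0.3×0.35 μm (5.6 μm depth range).
The camera pixel size is carried in the configuration but unused by the
sample-referred simulation.

### PSF calibration

`calibrate_psf_from_beads` emulates the one-time instrument calibration: a
single sub-resolution bead scanned axially in 100 nm steps. Each slice gets
a percentile background floor (default 10th percentile) subtracted and is
clipped at zero — the real procedure is unpublished, so the simplest robust
estimator was chosen. One bead must yield exactly one spot per lenslet in
the z-projection; more candidate spots raise an ambiguity error rather than
guessing. Because reconstruction grids use a coarser z step (350 nm) than
the calibration scan (100 nm), `PSFStack.resample_z` linearly interpolates
calibrated slices onto the reconstruction grid and renormalizes.

PSF stacks are normalized per-slice-sum-one by default so the forward model
conserves flux slice by slice; this makes the adjoint and flux tests exact.

## Forward model and adjoint

The camera frame is the axial sum of 2D **linear** convolutions between each
object slice and its depth's PSF. Zero-padded (never circular) convolution
is essential: wrap-around would leak light between elemental images. The
frame canvas is the full convolution support `(V+Y−1, U+X−1)`, so the
FFT-implemented operator and its adjoint (per-depth valid-region
correlation) are exact transposes — verified to 1e-8 in inner-product tests
and against a shifted-kernel brute-force oracle to 1e-10. Operators run in
float64; stored images may be float32.

## Reconstruction

The inverse problem is

```
min_x  ½‖Hx − y‖² + λ₁‖x‖₁ + λ_TV·TV₃D(x)   s.t. x ≥ 0,
```

with isotropic 3D total variation on forward differences and replicate
boundaries. Nonnegativity is enforced even though the data term alone does
not require it — fluorophore density is physical. The solver is a
fixed-penalty consensus ADMM with one block per active term:

- data step: conjugate gradients on `(HᵀH + Kρ)x = Hᵀy + ρΣ(z_i − u_i)` in
  operator form (no matrix materialization), warm-started, default 8
  iterations;
- l1 block: soft-thresholding at `λ₁/ρ`;
- TV block: Chambolle's isotropic TV proximal step
  (`skimage.restoration.denoise_tv_chambolle`, tight tolerance), while the
  TV *objective* is evaluated by this package's own `tv3d` (tested against a
  nested-loop oracle) — prox and functional stay independent;
- nonnegativity block: projection.

Splits whose proximal map is the identity (λ = 0, or nonnegativity off) are
skipped entirely; they contribute only damping. The merged objective is
traced at the nonnegatively projected iterate and is monotone after a short
burn-in in all tested conditions. Stopping: relative iterate change below
`rel_tol` (1e-6) or `max_iters` (60); non-convergence is reported in the
result flags, never raised.

Regularization weights are absolute, so callers normalize the measurement
(the workflows scale frames to unit peak, or to a sweep-wide common peak for
spectra, and rescale the volume afterwards). With ρ fixed, the ADMM path is
exactly positively homogeneous: scaling `y` and both λ's by `c` scales every
iterate by `c`.

Defaults λ₁ = 1e-3, λ_TV = 1e-4, ρ = 1 (for unit-peak frames) were chosen
on the bead phantom. After solving, slices farther than 2× the axial PSF
FWHM from the nominal focal plane are zeroed — outside that range the
parallax encoding no longer constrains the solution.

## Photothermal extraction

FMIP signals use the sign convention off − on (positive = fluorescence lost
under heating); negative values are retained, not clipped. The ratio signal
`(off − on)/max(off, floor)` is gain-invariant and proportional to the local
absorption; the division floor defaults to 1% of the frame's 99th-percentile
intensity, and sub-floor pixels are masked. No on/off registration is
performed — the snapshot geometry makes drift unlikely — but an apparent
shift above 0.5 px (phase cross-correlation) is logged.

3D FMIP volumes default to **diff-then-recon**: deconvolve the single
difference frame, applying nonnegativity after factoring out the dominant
sign. The alternative recon-then-diff (two reconstructions, subtract) is
provided for comparison; with priors off the two coincide by linearity.

## Synthetic phantoms

Phantom scenes mirror the instrument's specimen classes: sub-voxel beads
(resolution), rods on a tilted plane so depth spans the z-range (bacteria on
a tilted substrate), and spherical lipid droplets in a cell body sparing a
central nucleus. Each object class carries Lorentzian absorption bands;
defaults are the lipid ester C=O at 1744 cm⁻¹, the ¹³C-shifted carbonyl at
1704 cm⁻¹ and amide-I at 1650 cm⁻¹, all with ~10 cm⁻¹ HWHM (band widths are
not published for the dye-coupled measurement; 10 cm⁻¹ is typical of
condensed-phase carbonyl bands). The 1744 → 1704 placement follows the
photothermal peaks observed in cells; the FTIR mixture shift (~30 cm⁻¹) is a
separate printed fact and is not conflated with it.

The photothermal physics is applied multiplicatively at the object:

```
m(r) = (modulation per kelvin) × (temperature rise) × Σ_bands L̂_b(ν) A_b(r)
ir_off = H·x,   ir_on = H·(x · (1 − m))
```

with each band's Lorentzian normalized to 1 at its center. Modulation depth
defaults to 1%/K; the scene temperature rise is a free parameter (default
1 K — the actual rise is not published). The temperature field is taken
proportional to absorption with no diffusion blur, because the thermal
diffusion length over a 50 ns pulse (~0.17 μm) is below a voxel. Camera
noise is Poisson at a configurable peak-photon budget plus Gaussian read
noise, drawn independently for on and off frames; all randomness flows from
the phantom seed, and a fixed seed reproduces outputs byte-for-byte.

What the phantoms do **not** emulate: photobleaching kinetics (sweeps are
simply capped at six wavenumbers, as in practice), heat accumulation and
decay between pulses, optical aberrations, depth-dependent magnification,
and specimen motion. Passing tests therefore demonstrate correctness of the
computational chain under the stated optical model, not robustness to every
artifact of real acquisitions.

## Spectral analysis

Spectra are ROI means of FMIP volumes per pump wavenumber, with standard
deviations across replicate sweeps when several are supplied. Band fitting
is nonlinear least squares of `A·γ²/((ν−ν₀)²+γ²) + b` (constant baseline,
standing in for water absorption; a functional form was never published).
With six points, one component is the default; two free-width components
require ≥ 8 points or a fixed width. Five initial centers spanning the
sampled range guard against local minima, and the fitted center is bounded
to the sampled window plus half a sampling step — with sparse sampling a
band cannot be honestly localized farther out, and the bound keeps
edge-of-window bands (like 1744 cm⁻¹ in a sweep ending at 1745) from chasing
noise. A fit whose amplitude is within 3× the residual noise is flagged
center-unreliable.

The isotope peak ratio is the ROI-mean FMIP at 1704 over that at 1744;
per-droplet ratios use Otsu segmentation of the 1744 volume with connected
components of ≥ 4 voxels (an unpublished but conventional choice) and report
mean/median/quartiles/extrema.

## Resolution metrics

Bead FWHMs come from Gaussian fits (amplitude, center, σ, offset) to 1D
profiles through each bead's voxel maximum along x, y and z, with quadratic
sub-voxel peak refinement for the reported position; FWHM = 2√(2 ln 2)·σ.
Flat profiles raise a no-peak error; multi-modal profiles are flagged.
Beads closer than 3× the expected FWHM are excluded as overlapping. The
thermal diffusion length uses `L = √(4Dτ)` with water's diffusivity
D = 1.38×10⁻⁷ m²/s as the documented, overridable default; τ = 50 ns gives
166 nm.

## Benchmark problem sizes

The end-to-end bead benchmark runs the full instrument configuration on a
64×64×16 grid (the instrument's own ~60 μm FOV is scaled to 19.2 μm at the
same voxel pitch, keeping optics and depth range faithful while the problem
stays desk-sized); it reconstructs in under a minute on one CPU. The
spectral benchmark uses a 32×32×6 grid with a 0.6 μm droplet, six pump
wavenumbers from 1690 to 1745 cm⁻¹, and a photon budget of 2×10⁶ peak
photons, which places the per-pixel photothermal difference at SNR ≈ 10 for
a 1% modulation (`SNR ≈ 0.01·√(budget/2)`).

## Known limitations

- The PSF model is geometric; diffraction, aberrations and lenslet
  manufacturing effects are out of scope, so absolute resolution figures
  reflect the model, not the hardware.
- Chambolle's TV prox is itself iterative; with very large λ_TV/ρ its
  inexactness can perturb late ADMM iterates (tight internal tolerances are
  used).
- The FMIP ratio equals the modulation field exactly only where the
  modulation is constant over a source's support; spatial mixtures blend
  through the PSF.
- Quantitative concentration calibration of FMIP intensities is explicitly
  out of scope.
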