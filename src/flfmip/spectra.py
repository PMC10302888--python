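"""FMIP spectra: assembly over pump wavenumbers, Lorentzian fitting, and
isotope peak-ratio statistics.

A vibrational absorption band is modeled as a Lorentzian

    L(nu) = A * gamma^2 / ((nu - nu0)^2 + gamma^2) + b,

with center nu0 (cm^-1), half width at half maximum gamma, amplitude A (the
value at band center above baseline) and a constant baseline b attributed to
solvent (water) absorption.  The ester C=O stretch of endogenous lipids sits
at 1744 cm^-1; 13C substitution of the carbonyl shifts it to 1704 cm^-1, so
the 1704/1744 intensity ratio traces the fraction of lipid built from
exogenous 13C-labeled fatty acids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .forward import Volume

__all__ = [
    "FMIPSpectrum",
    "LorentzianFit",
    "PeakRatioResult",
    "lorentzian",
    "extract_spectrum",
    "fit_lorentzian",
    "peak_ratio",
]

INSTRUMENT_RANGE_CM1 = (1175.0, 1800.0)


def lorentzian(nu, center_cm1, hwhm_cm1, amplitude, baseline=0.0):
    """Lorentzian line shape, normalized to ``amplitude`` at its center."""
    nu = np.asarray(nu, dtype=np.float64)
    return amplitude * hwhm_cm1**2 / ((nu - center_cm1) ** 2 + hwhm_cm1**2) + baseline


@dataclass
class FMIPSpectrum:
    """FMIP ratio signal sampled at a handful of pump wavenumbers."""

    wavenumbers_cm1: np.ndarray
    signal: np.ndarray
    signal_sd: np.ndarray
    n_replicates: int = 1

    def __post_init__(self) -> None:
        self.wavenumbers_cm1 = np.asarray(self.wavenumbers_cm1, dtype=np.float64)
        self.signal = np.asarray(self.signal, dtype=np.float64)
        self.signal_sd = np.asarray(self.signal_sd, dtype=np.float64)
        if not (len(self.wavenumbers_cm1) == len(self.signal) == len(self.signal_sd)):
            raise ValueError("wavenumbers, signal and sd must have equal length")
        if np.any(np.diff(self.wavenumbers_cm1) <= 0):
            raise ValueError("wavenumbers must be strictly increasing")
        lo, hi = INSTRUMENT_RANGE_CM1
        if self.wavenumbers_cm1.min() < lo or self.wavenumbers_cm1.max() > hi:
            raise ValueError(f"wavenumbers must lie within {lo}-{hi} cm^-1")

    def to_csv(self, path) -> None:
        """Write (wavenumber, mean, sd, n) rows."""
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["wavenumber_cm1", "mean", "sd", "n"])
            for wn, s, sd in zip(self.wavenumbers_cm1, self.signal,
                                 self.signal_sd):
                w.writerow([wn, s, sd, self.n_replicates])


@dataclass
class LorentzianFit:
    center_cm1: float
    hwhm_cm1: float
    amplitude: float
    baseline: float
    rss: float
    se_center: float
    center_reliable: bool = True


def extract_spectrum(volumes, roi: np.ndarray) -> FMIPSpectrum:
    """Mean FMIP signal over an ROI, per pump wavenumber.

    ``volumes`` is either one sweep — a sequence of ``(wavenumber, Volume)``
    pairs — or several replicate sweeps (e.g. one per cell), in which case the
    signal is the mean of per-replicate ROI means and the SD is taken across
    replicates.
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("ROI is empty")
    seq = list(volumes)
    if not seq:
        raise ValueError("no volumes supplied")
    # A single sweep is a sequence of (wavenumber, Volume) pairs; replicates
    # are a sequence of such sweeps.
    first = seq[0]
    if isinstance(first, (list, tuple)) and len(first) == 2 and \
            isinstance(first[1], Volume):
        sweeps = [seq]
    else:
        sweeps = [list(s) for s in seq]

    per_rep = []
    wn_ref = None
    for sweep in sweeps:
        wns = np.array([float(w) for w, _ in sweep])
        if len(np.unique(wns)) != len(wns):
            raise ValueError("duplicate wavenumbers within one sweep")
        order = np.argsort(wns)
        wns = wns[order]
        vols = [sweep[i][1] for i in order]
        if wn_ref is None:
            wn_ref = wns
        elif not np.allclose(wns, wn_ref):
            raise ValueError("replicate sweeps sample different wavenumbers")
        if len(wns) < 3:
            raise ValueError("at least 3 wavenumbers are required")
        per_rep.append([float(np.mean(v.data[roi])) for v in vols])

    arr = np.asarray(per_rep)  # (n_rep, n_wn)
    sd = arr.std(axis=0, ddof=1) if len(arr) > 1 else np.zeros(arr.shape[1])
    return FMIPSpectrum(wavenumbers_cm1=wn_ref, signal=arr.mean(axis=0),
                        signal_sd=sd, n_replicates=len(arr))


def _fit_once(wn, sig, p0, bounds):
    popt, pcov = curve_fit(
        lambda nu, *p: _model(nu, p), wn, sig, p0=p0, bounds=bounds,
        maxfev=20000)
    rss = float(((sig - _model(wn, popt)) ** 2).sum())
    return popt, pcov, rss


def _model(nu, params):
    # params: (A, c, g) per component + trailing baseline b
    n = (len(params) - 1) // 3
    out = np.full_like(np.asarray(nu, float), params[-1])
    for i in range(n):
        A, c, g = params[3 * i: 3 * i + 3]
        out = out + lorentzian(nu, c, g, A)
    return out


def fit_lorentzian(spec: FMIPSpectrum, n_components: int = 1,
                   fixed_hwhm_cm1: float | None = None) -> list[LorentzianFit]:
    """Fit one or two Lorentzian components plus a constant baseline.

    Uses multistart nonlinear least squares (5 initial centers spanning the
    sampled range) to dodge local minima with sparse sampling.  With few
    points (photobleaching caps a sweep at ~6 wavenumbers) a two-component
    fit is only attempted with >= 8 points or a fixed width.  Fits are
    returned sorted by center; a fit whose amplitude is indistinguishable
    from the residual noise has ``center_reliable=False``.
    """
    wn = spec.wavenumbers_cm1
    sig = spec.signal
    n_par = 3 * n_components + 1 if fixed_hwhm_cm1 is None else 2 * n_components + 1
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    if len(wn) < n_par + 1:
        raise ValueError("underdetermined fit: need at least n_params + 1 points")
    if n_components == 2 and fixed_hwhm_cm1 is None and len(wn) < 8:
        raise ValueError("two free-width components need >= 8 points "
                         "(or pass fixed_hwhm_cm1)")

    span = wn[-1] - wn[0]
    g0 = fixed_hwhm_cm1 if fixed_hwhm_cm1 is not None else max(span / 4.0, 1.0)
    b0 = float(sig.min())
    a0 = float(sig.max() - sig.min())
    centers0 = np.linspace(wn[0], wn[-1], 5)

    # A band center cannot be localized more than about half a sampling step
    # beyond the measured window; bounding it there keeps edge bands (e.g. a
    # peak at the last sampled wavenumber) from chasing noise far out of range.
    margin = 0.5 * float(np.mean(np.diff(wn)))
    lo_c, hi_c = wn[0] - margin, wn[-1] + margin
    best = None
    for c0 in centers0:
        if n_components == 1:
            p0 = [a0, c0, g0, b0]
            lo = [0.0, lo_c, 1e-3, -np.inf]
            hi = [np.inf, hi_c, 10.0 * max(span, g0), np.inf]
        else:
            c1 = min(c0 + span / 2.0, hi_c)
            p0 = [a0, c0, g0, a0 / 2.0, c1, g0, b0]
            lo = [0.0, lo_c, 1e-3, 0.0, lo_c, 1e-3, -np.inf]
            hi = [np.inf, hi_c, 10.0 * max(span, g0), np.inf, hi_c,
                  10.0 * max(span, g0), np.inf]
        if fixed_hwhm_cm1 is not None:
            for i in range(n_components):
                j = 3 * i + 2
                p0[j] = fixed_hwhm_cm1
                lo[j] = fixed_hwhm_cm1 * (1 - 1e-9)
                hi[j] = fixed_hwhm_cm1 * (1 + 1e-9)
        try:
            popt, pcov, rss = _fit_once(wn, sig, p0, (lo, hi))
        except RuntimeError:
            continue
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
    if best is None:
        raise RuntimeError("Lorentzian fit did not converge from any start")
    popt, pcov, rss = best

    dof = max(len(wn) - len(popt), 1)
    noise = np.sqrt(rss / dof)
    fits = []
    for i in range(n_components):
        A, c, g = popt[3 * i: 3 * i + 3]
        var_c = pcov[3 * i + 1, 3 * i + 1] if np.all(np.isfinite(pcov)) else np.inf
        se_c = float(np.sqrt(max(var_c, 0.0)))
        reliable = bool(A > 3.0 * noise and A > 1e-12 and se_c < span)
        fits.append(LorentzianFit(center_cm1=float(c), hwhm_cm1=float(abs(g)),
                                  amplitude=float(A), baseline=float(popt[-1]),
                                  rss=rss, se_center=se_c,
                                  center_reliable=reliable))
    return sorted(fits, key=lambda f: f.center_cm1)


@dataclass
class PeakRatioResult:
    ratio: float
    per_droplet: list[float]
    summary: dict


def _segment_droplets(reference: np.ndarray, min_voxels: int) -> np.ndarray:
    pos = reference[reference > 0]
    if pos.size == 0:
        return np.zeros_like(reference, dtype=int)
    try:
        thr = threshold_otsu(reference)
    except ValueError:
        thr = 0.5 * reference.max()
    labels = cc_label(reference > thr)
    counts = np.bincount(labels.ravel())
    for lab in range(1, len(counts)):
        if counts[lab] < min_voxels:
            labels[labels == lab] = 0
    return labels


def peak_ratio(vol_1704: Volume, vol_1744: Volume,
               roi: np.ndarray | None = None,
               min_component_voxels: int = 4) -> PeakRatioResult:
    """Isotope ratio: ROI-mean FMIP at 1704 cm^-1 over that at 1744 cm^-1.

    Also segments droplets (Otsu threshold on the 1744 volume, connected
    components of >= ``min_component_voxels`` voxels) and reports per-droplet
    ratios with quartile/mean/median/extrema summary.
    """
    a = vol_1704.data
    b = vol_1744.data
    if a.shape != b.shape:
        raise ValueError("volumes must be co-registered (same shape)")
    if roi is None:
        roi = b > 0
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("ROI is empty")
    denom = float(np.mean(b[roi]))
    if denom <= 0:
        raise ValueError("1744 cm^-1 ROI mean is nonpositive")
    ratio = float(np.mean(a[roi])) / denom

    labels = _segment_droplets(np.where(roi, b, 0.0), min_component_voxels)
    per = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        m = labels == lab
        d = float(np.mean(b[m]))
        if d > 0:
            per.append(float(np.mean(a[m])) / d)
    if per:
        arr = np.asarray(per)
        summary = {"mean": float(arr.mean()), "median": float(np.median(arr)),
                   "q25": float(np.percentile(arr, 25)),
                   "q75": float(np.percentile(arr, 75)),
                   "min": float(arr.min()), "max": float(arr.max()),
                   "n": len(per)}
    else:
        summary = {"n": 0}
    return PeakRatioResult(ratio=ratio, per_droplet=per, summary=summary)
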