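import numpy as np
import pytest

from flfmip import (FMIPSpectrum, Volume, extract_spectrum, fit_lorentzian,
                    lorentzian, peak_ratio)


def vol(data):
    d = np.asarray(data, dtype=float)
    return Volume(data=d, voxel_size_um=(0.3, 0.3, 0.35),
                  z_positions_um=0.35 * np.arange(d.shape[0]))


def band_spectrum(center, hwhm=10.0, amp=0.01, baseline=0.002,
                  wn=np.linspace(1690.0, 1745.0, 6)):
    return FMIPSpectrum(wavenumbers_cm1=wn,
                        signal=lorentzian(wn, center, hwhm, amp, baseline),
                        signal_sd=np.zeros(len(wn)))


class TestExtractSpectrum:
    def test_single_voxel_roi_reads_voxel_values(self):
        wns = [1690.0, 1710.0, 1744.0]
        vals = [0.001, 0.004, 0.01]
        vols = [(w, vol(np.full((2, 3, 3), v))) for w, v in zip(wns, vals)]
        roi = np.zeros((2, 3, 3), bool)
        roi[1, 1, 1] = True
        spec = extract_spectrum(vols, roi)
        assert np.allclose(spec.signal, vals)
        assert spec.n_replicates == 1

    def test_identical_replicates_have_zero_sd(self):
        wns = [1690.0, 1710.0, 1744.0]
        sweep = [(w, vol(np.full((2, 3, 3), 0.01 * i)))
                 for i, w in enumerate(wns, 1)]
        spec = extract_spectrum([sweep, sweep, sweep], np.ones((2, 3, 3), bool))
        assert spec.n_replicates == 3
        assert np.allclose(spec.signal_sd, 0.0)

    def test_empty_roi_rejected(self):
        sweep = [(w, vol(np.ones((2, 3, 3)))) for w in (1690.0, 1710.0, 1744.0)]
        with pytest.raises(ValueError, match="ROI"):
            extract_spectrum(sweep, np.zeros((2, 3, 3), bool))

    def test_duplicate_wavenumbers_rejected(self):
        sweep = [(1700.0, vol(np.ones((2, 3, 3)))) for _ in range(3)]
        with pytest.raises(ValueError, match="duplicate"):
            extract_spectrum(sweep, np.ones((2, 3, 3), bool))

    def test_csv_export_roundtrips(self, tmp_path):
        spec = band_spectrum(1744.0)
        path = tmp_path / "spec.csv"
        spec.to_csv(path)
        rows = path.read_text().strip().splitlines()
        assert rows[0] == "wavenumber_cm1,mean,sd,n"
        assert len(rows) == 7

    def test_out_of_range_wavenumber_rejected(self):
        with pytest.raises(ValueError):
            FMIPSpectrum(wavenumbers_cm1=np.array([900.0, 1700.0, 1744.0]),
                         signal=np.zeros(3), signal_sd=np.zeros(3))


class TestFitLorentzian:
    @pytest.mark.parametrize("center", [1744.0, 1704.0])
    def test_exact_model_recovery(self, center):
        """Noiseless six-point spectra from the model are fitted to within
        0.1 cm^-1 in center."""
        fit = fit_lorentzian(band_spectrum(center))[0]
        assert fit.center_cm1 == pytest.approx(center, abs=0.1)
        assert fit.hwhm_cm1 == pytest.approx(10.0, rel=0.01)
        assert fit.amplitude == pytest.approx(0.01, rel=0.01)
        assert fit.baseline == pytest.approx(0.002, abs=1e-4)
        assert fit.center_reliable

    def test_machine_precision_on_generating_model(self):
        fit = fit_lorentzian(band_spectrum(1720.0, wn=np.linspace(1690, 1745, 9)))[0]
        assert fit.rss < 1e-18  # ~1e-16 relative to the squared signal scale

    def test_flat_spectrum_flagged_unreliable(self):
        wn = np.linspace(1690.0, 1745.0, 6)
        spec = FMIPSpectrum(wavenumbers_cm1=wn, signal=np.full(6, 0.002),
                            signal_sd=np.zeros(6))
        fit = fit_lorentzian(spec)[0]
        assert fit.amplitude == pytest.approx(0.0, abs=1e-6)
        assert not fit.center_reliable

    def test_two_components_need_more_points(self):
        with pytest.raises(ValueError):
            fit_lorentzian(band_spectrum(1744.0), n_components=2)

    def test_two_component_fit_with_fixed_width(self):
        wn = np.linspace(1690.0, 1750.0, 13)
        sig = lorentzian(wn, 1704.0, 10.0, 0.01) \
            + lorentzian(wn, 1744.0, 10.0, 0.006) + 0.001
        spec = FMIPSpectrum(wavenumbers_cm1=wn, signal=sig,
                            signal_sd=np.zeros(len(wn)))
        fits = fit_lorentzian(spec, n_components=2, fixed_hwhm_cm1=10.0)
        assert fits[0].center_cm1 == pytest.approx(1704.0, abs=0.5)
        assert fits[1].center_cm1 == pytest.approx(1744.0, abs=0.5)

    def test_monte_carlo_center_separation(self):
        """At spectral SNR >= 10 the fitted 1744- and 1704-band centers keep
        their 40 cm^-1 separation within 2 cm^-1, and each center is biased
        by < 1 cm^-1 (100 noisy draws)."""
        rng = np.random.default_rng(123)
        wn = np.linspace(1690.0, 1745.0, 6)
        amp, noise_sd = 0.01, 0.001  # SNR 10
        cents = {1744.0: [], 1704.0: []}
        for center in cents:
            clean = lorentzian(wn, center, 10.0, amp, 0.002)
            for _ in range(100):
                spec = FMIPSpectrum(
                    wavenumbers_cm1=wn,
                    signal=clean + rng.normal(0, noise_sd, wn.shape),
                    signal_sd=np.full(wn.shape, noise_sd))
                cents[center].append(fit_lorentzian(spec)[0].center_cm1)
        for center, vals in cents.items():
            assert abs(np.mean(vals) - center) < 1.0
        sep = np.mean(cents[1744.0]) - np.mean(cents[1704.0])
        assert sep == pytest.approx(40.0, abs=2.0)


class TestPeakRatio:
    def test_identical_volumes_ratio_one(self):
        d = np.zeros((3, 8, 8))
        d[1, 2:5, 2:5] = 1.0
        res = peak_ratio(vol(d), vol(d.copy()))
        assert res.ratio == pytest.approx(1.0)

    def test_zero_isotope_volume_ratio_zero(self):
        d = np.zeros((3, 8, 8))
        d[1, 2:5, 2:5] = 1.0
        res = peak_ratio(vol(np.zeros_like(d)), vol(d))
        assert res.ratio == 0.0

    def test_nonpositive_denominator_rejected(self):
        z = np.zeros((3, 8, 8))
        with pytest.raises(ValueError):
            peak_ratio(vol(z), vol(z), roi=np.ones_like(z, bool))

    def test_half_isotope_phantom_matches_closed_form(self):
        """Two equal-amplitude droplets, one isotope-shifted; volumes sampled
        exactly at the two band centers reproduce the analytic line-shape
        ratio."""
        g = 10.0
        off_band = lorentzian(1704.0, 1744.0, g, 1.0)  # = lorentzian(1744, 1704, g, 1)
        d_1744 = np.zeros((3, 12, 12))
        d_1704 = np.zeros((3, 12, 12))
        a = (slice(1, 2), slice(2, 5), slice(2, 5))     # endogenous droplet
        b = (slice(1, 2), slice(7, 10), slice(7, 10))   # isotope droplet
        d_1744[a] = 1.0
        d_1744[b] = off_band
        d_1704[a] = off_band
        d_1704[b] = 1.0
        res = peak_ratio(vol(d_1704), vol(d_1744),
                         roi=(d_1744 > 0))
        expected = (off_band + 1.0) / (1.0 + off_band)
        assert res.ratio == pytest.approx(expected, abs=1e-12)
        # Segmentation references the 1744 volume (by design), so only the
        # endogenous droplet clears the Otsu threshold; its per-droplet ratio
        # is the off-band line-shape factor.
        assert res.summary["n"] == 1
        assert res.per_droplet[0] == pytest.approx(off_band, rel=1e-9)

    def test_gain_invariance(self):
        rng = np.random.default_rng(5)
        d1 = rng.random((3, 8, 8))
        d2 = rng.random((3, 8, 8)) + 0.1
        roi = np.ones_like(d1, bool)
        r1 = peak_ratio(vol(d1), vol(d2), roi=roi)
        r2 = peak_ratio(vol(9.3 * d1), vol(9.3 * d2), roi=roi)
        assert r1.ratio == pytest.approx(r2.ratio, rel=1e-12)
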