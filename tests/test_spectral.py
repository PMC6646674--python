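import numpy as np
import pytest

from canopytraits import spectral
from canopytraits.synthetic import gen_spectrum

WL = np.arange(380.0, 1101.0, 1.0)


def _flat_spectrum(value: float) -> spectral.Spectrum:
    mask = (WL >= 450) & (WL <= 820)
    return spectral.Spectrum(WL, np.full_like(WL, value), mask)


def _piecewise_spectrum(bands: dict[float, float]) -> spectral.Spectrum:
    """Reflectance constant in a +-5 nm window around each requested band."""
    refl = np.full_like(WL, 0.2)
    for c, v in bands.items():
        refl[np.abs(WL - c) <= 5.0] = v
    mask = (WL >= 450) & (WL <= 820)
    return spectral.Spectrum(WL, refl, mask)


class TestCalibration:
    def test_self_calibration_gives_panel_reflectance(self):
        scan = spectral.RawScan(WL, np.full_like(WL, 1000.0))
        panel = spectral.RawScan(WL, np.full_like(WL, 1000.0), role="panel")
        spec = spectral.calibrate_reflectance(scan, panel, 0.99)
        np.testing.assert_allclose(spec.reflectance, 0.99)

    def test_half_counts_half_reflectance(self):
        scan = spectral.RawScan(WL, np.full_like(WL, 500.0))
        panel = spectral.RawScan(WL, np.full_like(WL, 1000.0), role="panel")
        spec = spectral.calibrate_reflectance(scan, panel, 0.99)
        assert spec.reflectance[0] == pytest.approx(0.495)

    def test_snr_window_mask(self):
        scan = spectral.RawScan(WL, np.full_like(WL, 500.0))
        panel = spectral.RawScan(WL, np.full_like(WL, 1000.0), role="panel")
        spec = spectral.calibrate_reflectance(scan, panel)
        assert not spec.snr_mask[WL == 900.0][0]
        assert not spec.snr_mask[WL == 440.0][0]
        assert spec.snr_mask[WL == 600.0][0]

    def test_grid_mismatch_rejected(self):
        scan = spectral.RawScan(WL[:-1], np.full(len(WL) - 1, 500.0))
        panel = spectral.RawScan(WL, np.full_like(WL, 1000.0), role="panel")
        with pytest.raises(spectral.CalibrationError):
            spectral.calibrate_reflectance(scan, panel)

    def test_zero_panel_counts_in_usable_range_rejected(self):
        counts = np.full_like(WL, 1000.0)
        counts[WL == 600.0] = 0.0
        panel = spectral.RawScan(WL, counts, role="panel")
        scan = spectral.RawScan(WL, np.full_like(WL, 500.0))
        with pytest.raises(spectral.CalibrationError):
            spectral.calibrate_reflectance(scan, panel)

    def test_idempotent_against_unit_panel(self):
        scan = spectral.RawScan(WL, np.full_like(WL, 500.0))
        panel = spectral.RawScan(WL, np.full_like(WL, 1000.0), role="panel")
        once = spectral.calibrate_reflectance(scan, panel, 1.0)
        unit = spectral.RawScan(WL, np.ones_like(WL), role="panel")
        twice = spectral.calibrate_reflectance(
            spectral.RawScan(WL, once.reflectance), unit, 1.0
        )
        np.testing.assert_allclose(twice.reflectance, once.reflectance)

    def test_repeat_snr_criterion(self):
        repeats = np.tile(np.full_like(WL, 1000.0), (3, 1))
        noisy = WL >= 700.0  # make one region fail mean/std >= 20
        repeats[0, noisy] = 500.0
        repeats[1, noisy] = 1500.0
        panel = spectral.RawScan(WL, np.full_like(WL, 1000.0), role="panel")
        scan = spectral.RawScan(WL, repeats.mean(axis=0))
        spec = spectral.calibrate_reflectance(scan, panel, canopy_repeats=repeats)
        assert spec.snr_mask[WL == 600.0][0]
        assert not spec.snr_mask[WL == 750.0][0]

    def test_outlier_rejected_average(self):
        clean = np.full_like(WL, 1000.0)
        scans = [spectral.RawScan(WL, clean) for _ in range(4)]
        spike = clean.copy()
        spike[100] = 50000.0
        scans.append(spectral.RawScan(WL, spike))
        avg = spectral.average_scans(scans)
        assert avg.counts[100] == pytest.approx(1000.0)


class TestBandSampling:
    def test_constant_spectrum_any_center(self):
        spec = _flat_spectrum(0.3)
        for c in (550.0, 670.0, 800.0):
            assert spectral.sample_band(spec, c) == pytest.approx(0.3)

    def test_linear_spectrum_symmetric_weights(self):
        a, b = 0.01, 4e-4
        mask = (WL >= 450) & (WL <= 820)
        spec = spectral.Spectrum(WL, a + b * WL, mask)
        for c in (550.0, 670.0, 800.0):
            assert spectral.sample_band(spec, c) == pytest.approx(a + b * c, abs=1e-6)

    def test_masked_center_unusable(self):
        spec = _flat_spectrum(0.3)
        with pytest.raises(spectral.BandUnusableError):
            spectral.sample_band(spec, 900.0)


class TestIndices:
    def test_ndvi_zero_when_bands_equal(self):
        spec = _piecewise_spectrum({670.0: 0.2, 800.0: 0.2})
        assert spectral.ndvi(spec) == pytest.approx(0.0, abs=1e-12)

    def test_ndvi_arithmetic(self):
        spec = _piecewise_spectrum({670.0: 0.05, 800.0: 0.50})
        assert spectral.ndvi(spec) == pytest.approx(0.8182, abs=1e-4)

    def test_mtci_arithmetic(self):
        spec = _piecewise_spectrum({754.0: 0.40, 709.0: 0.20, 681.0: 0.10})
        assert spectral.mtci(spec) == pytest.approx(2.0, abs=1e-9)

    def test_mtci_undefined_when_denominator_zero(self):
        spec = _piecewise_spectrum({709.0: 0.2, 681.0: 0.2})
        with pytest.raises(spectral.BandUnusableError):
            spectral.mtci(spec)

    def test_mcari2_against_hand_computation(self):
        r800, r670, r550 = 0.5, 0.05, 0.10
        spec = _piecewise_spectrum({800.0: r800, 670.0: r670, 550.0: r550})
        num = 1.5 * (2.5 * (r800 - r670) - 1.3 * (r800 - r550))
        den = np.sqrt((2 * r800 + 1) ** 2 - (6 * r800 - 5 * np.sqrt(r670))) - 0.5
        assert spectral.mcari2(spec) == pytest.approx(num / den, abs=1e-9)
        assert spectral.mcari2(spec) == pytest.approx(0.94997, abs=1e-4)

    def test_mcari2_literal_denominator_variant_differs(self):
        spec = _piecewise_spectrum({800.0: 0.5, 670.0: 0.05, 550.0: 0.10})
        assert spectral.mcari2(spec, literal_denominator=True) != pytest.approx(
            spectral.mcari2(spec)
        )

    def test_scale_invariance_and_sensitivity(self, rng):
        # NDVI and MTCI are ratio indices; MCARI2 is intensity-sensitive
        for _ in range(10):
            base = _piecewise_spectrum(
                {
                    550.0: rng.uniform(0.05, 0.2),
                    670.0: rng.uniform(0.02, 0.15),
                    681.0: rng.uniform(0.02, 0.15),
                    709.0: rng.uniform(0.15, 0.3),
                    754.0: rng.uniform(0.3, 0.5),
                    800.0: rng.uniform(0.35, 0.6),
                }
            )
            k = rng.uniform(0.5, 1.5)
            scaled = spectral.Spectrum(base.wavelengths, k * base.reflectance, base.snr_mask)
            assert spectral.ndvi(scaled) == pytest.approx(spectral.ndvi(base), rel=1e-9)
            assert spectral.mtci(scaled) == pytest.approx(spectral.mtci(base), rel=1e-9)
            if abs(k - 1) > 0.05:
                assert spectral.mcari2(scaled) != pytest.approx(spectral.mcari2(base), rel=1e-3)

    def test_plot_index_averages_reflectance_not_indices(self):
        s1 = _piecewise_spectrum({670.0: 0.05, 800.0: 0.50})
        s2 = _piecewise_spectrum({670.0: 0.15, 800.0: 0.30})
        avg_refl = spectral.plot_index([s1, s2], "ndvi")
        per_scan = spectral.plot_index([s1, s2], "ndvi", average_first=False)
        r800, r670 = 0.40, 0.10
        assert avg_refl == pytest.approx((r800 - r670) / (r800 + r670), abs=1e-9)
        assert avg_refl != pytest.approx(per_scan, abs=1e-4)


class TestSyntheticSpectra:
    def test_full_canopy_high_ndvi(self):
        canopy_scan, panel, _ = gen_spectrum(1.0, seed=0)
        spec = spectral.calibrate_reflectance(canopy_scan, panel, 0.99)
        assert spectral.ndvi(spec) > 0.7

    def test_bare_soil_low_ndvi(self):
        canopy_scan, panel, _ = gen_spectrum(0.0, seed=0)
        spec = spectral.calibrate_reflectance(canopy_scan, panel, 0.99)
        assert spectral.ndvi(spec) < 0.3

    def test_ndvi_monotone_in_mix_fraction(self):
        vals = []
        for mix in (0.0, 0.25, 0.5, 0.75, 1.0):
            c, p, _ = gen_spectrum(mix, seed=1)
            vals.append(spectral.ndvi(spectral.calibrate_reflectance(c, p, 0.99)))
        assert vals == sorted(vals)
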