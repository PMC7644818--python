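"""Axis estimation, profile extraction, sinusoid and trough fits."""

import numpy as np
import pytest

import granametry as g
from granametry.errors import DetectionError, FitQualityError, ValidationError
from granametry.profiles import FWHM_PER_SIGMA, dominant_period


def make_profile(x, y):
    return g.IntensityProfile(x, y, float(x[1] - x[0]))


def autocorr_period(values, spacing):
    """Independent oracle: first non-zero autocorrelation peak lag."""
    y = values - values.mean()
    ac = np.correlate(y, y, mode="full")[y.size - 1:]
    # first local max after the zero-lag peak has decayed
    k = 1
    while k < ac.size - 1 and ac[k] > ac[k + 1]:
        k += 1
    seg = ac[k:]
    lag = k + int(np.argmax(seg[: min(seg.size, 4 * k + 50)]))
    return lag * spacing


class TestEstimateAxis:
    @pytest.mark.parametrize("tilt", [0.0, 17.0, -32.0])
    def test_recovers_render_tilt(self, tilt):
        geom = g.make_grana_truth(gap_nm=4.0, lm_nm=12.0, n_layers=8,
                                  diameter_nm=150.0, tilt_deg=tilt)
        opts = g.RenderOptions(nm_per_px=0.5, psf_sigma_px=1.0,
                               noise_model="gaussian", snr=5.0, seed=11)
        img, _ = g.render_grana(geom, opts)
        assert g.estimate_axis(img) == pytest.approx(tilt, abs=0.5)

    def test_uniform_roi_raises(self):
        img = g.CalibratedImage(np.full((64, 64), 100.0), 0.5)
        with pytest.raises(DetectionError):
            g.estimate_axis(img)

    def test_pure_noise_raises(self):
        rng = np.random.default_rng(0)
        img = g.CalibratedImage(rng.normal(100, 10, (128, 128)), 0.5)
        with pytest.raises(DetectionError):
            g.estimate_axis(img)

    def test_rotation_equivariance(self):
        """estimate(rotate(img, theta)) = estimate(img) + theta within 1 deg."""
        from scipy.ndimage import rotate

        geom = g.make_grana_truth(gap_nm=4.0, lm_nm=12.0, n_layers=8,
                                  diameter_nm=150.0, tilt_deg=5.0)
        opts = g.RenderOptions(nm_per_px=0.5, psf_sigma_px=1.0,
                               noise_model="gaussian", snr=8.0, seed=4)
        img, _ = g.render_grana(geom, opts)
        base = g.estimate_axis(img)
        for theta in (10.0, 25.0):
            rot = rotate(img.pixels, theta, reshape=False, order=1,
                         mode="constant", cval=8000.0)
            est = g.estimate_axis(g.CalibratedImage(rot, 0.5))
            assert ((est - base - theta + 90) % 180) - 90 == pytest.approx(0.0, abs=1.0)


class TestExtractProfile:
    def test_contrast_preserved_on_clean_stack(self, clean_stack):
        img, rec, roi = clean_stack
        prof = g.extract_profile(img, roi, 0.0, band_px=10)
        assert prof.values.max() - prof.values.min() == pytest.approx(20000.0, rel=0.01)

    def test_wider_band_reduces_noise(self, dark_geometry):
        opts = g.RenderOptions(nm_per_px=0.5, psf_sigma_px=0.0,
                               noise_model="gaussian", snr=5.0, seed=21)
        img, rec = g.render_grana(dark_geometry, opts)
        from granametry.pipeline import roi_for_record

        roi = roi_for_record(rec, img)
        # flat bright-plateau segment of the profile: residual SD is noise
        def plateau_sd(band):
            prof = g.extract_profile(img, roi, 0.0, band_px=band)
            v = prof.values
            sel = v > np.percentile(v, 80)
            return v[sel].std()

        assert plateau_sd(15) < 0.5 * plateau_sd(1)

    def test_band_outside_image_raises(self, clean_stack):
        img, _, _ = clean_stack
        nr, nc = img.shape
        roi = g.RoiSpec(center=((nr - 1) / 2, 2.0), half_axis_px=nr / 2 + 30,
                        half_lat_px=5)
        with pytest.raises(ValidationError):
            g.extract_profile(img, roi, 0.0, band_px=10)

    def test_nm_scale_equivariance(self, clean_stack):
        """Scaling nm_per_px by k scales all nm outputs by exactly k."""
        img, _, roi = clean_stack
        p1 = g.extract_profile(img, roi, 0.0, band_px=4)
        p2 = g.extract_profile(img.with_scale(img.nm_per_px * 3.0), roi, 0.0, band_px=4)
        assert np.allclose(p2.positions_nm, 3.0 * p1.positions_nm)
        assert np.array_equal(p2.values, p1.values)


class TestFitSinusoid:
    def test_pure_sinusoid_exact(self):
        x = np.arange(0, 120, 0.25)
        y = 50 + 10 * np.sin(2 * np.pi * x / 17.0 + 0.7)
        fit = g.fit_sinusoid(make_profile(x, y))
        assert fit.period_nm == pytest.approx(17.0, abs=1e-3)
        assert fit.r_squared > 0.999

    def test_square_wave_matches_autocorrelation_oracle(self):
        x = np.arange(0, 160, 0.5)
        y = np.where((x % 16.9) < 12.22, 28000.0, 8000.0)
        fit = g.fit_sinusoid(make_profile(x, y))
        oracle = autocorr_period(y, 0.5)
        assert fit.period_nm == pytest.approx(oracle, rel=0.02)
        assert fit.period_nm == pytest.approx(16.9, rel=0.02)

    def test_constant_profile_raises(self):
        x = np.arange(0, 50, 0.5)
        with pytest.raises(FitQualityError):
            g.fit_sinusoid(make_profile(x, np.full_like(x, 5.0)))

    def test_too_few_periods_raises(self):
        x = np.arange(0, 30, 0.25)
        y = np.sin(2 * np.pi * x / 17.0)
        with pytest.raises(g.InsufficientDataError):
            g.fit_sinusoid(make_profile(x, y))

    @pytest.mark.parametrize("period,snr_amp", [(13.0, 5.0), (17.0, 3.0), (23.0, 10.0)])
    def test_noisy_period_within_one_spacing_of_autocorr(self, period, snr_amp):
        rng = np.random.default_rng(int(period * 10))
        x = np.arange(0, 12 * period, 0.5)
        amp = 100.0
        y = amp * np.sin(2 * np.pi * x / period) + rng.normal(0, amp / snr_amp, x.size)
        fit = g.fit_sinusoid(make_profile(x, y))
        assert abs(fit.period_nm - autocorr_period(y, 0.5)) <= 0.5
        assert fit.period_nm == pytest.approx(period, abs=0.5)


class TestTroughFwhm:
    @pytest.mark.parametrize("sigma,expected", [(2.0, 4.7096), (1.0, 2.3548)])
    def test_exact_gaussian_trough(self, sigma, expected):
        x = np.arange(-15, 15, 0.1)
        y = 100.0 - 40.0 * np.exp(-0.5 * (x / sigma) ** 2)
        fit = g.fit_trough_fwhm(make_profile(x, y), 0.0, 20.0)
        assert fit.fwhm_nm == pytest.approx(expected, abs=1e-3)
        assert fit.fwhm_nm / fit.sigma_nm == pytest.approx(FWHM_PER_SIGMA, abs=1e-6)

    def test_fwhm_sigma_ratio_is_universal(self):
        fit = g.PeakFit(center_nm=0.0, sigma_nm=3.3, r_squared=0.9)
        assert fit.fwhm_nm / fit.sigma_nm == pytest.approx(2.35482, abs=1e-5)

    def test_two_troughs_in_window_raises(self):
        x = np.arange(-20, 20, 0.1)
        y = (100.0 - 40.0 * np.exp(-0.5 * ((x - 6) / 1.5) ** 2)
             - 40.0 * np.exp(-0.5 * ((x + 6) / 1.5) ** 2))
        with pytest.raises(FitQualityError):
            g.fit_trough_fwhm(make_profile(x, y), 0.0, 30.0)

    def test_crossing_mode_agrees_on_exact_gaussian(self):
        x = np.arange(-15, 15, 0.05)
        y = 100.0 - 40.0 * np.exp(-0.5 * (x / 2.0) ** 2)
        fit = g.fit_trough_fwhm(make_profile(x, y), 0.0, 16.0, mode="crossing")
        assert fit.fwhm_nm == pytest.approx(4.7096, abs=0.06)


class TestDominantPeriod:
    def test_matches_known_frequency(self):
        x = np.arange(0, 170, 0.5)
        y = np.sin(2 * np.pi * x / 17.0)
        assert dominant_period(make_profile(x, y)) == pytest.approx(17.0, rel=0.02)
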