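"""Synthetic micrograph renderer: exactness, determinism, cohort plumbing."""

import dataclasses

import numpy as np
import pytest

import granametry as g
from granametry.errors import ResolutionError, ValidationError
from granametry.simulate import GroundTruthRecord, sample_cohort

from conftest import column_run_lengths


class TestRenderGrana:
    def test_noiseless_columns_match_run_length_oracle(self, clean_stack):
        """Commanded widths are reproduced to the pixel in every column
        (verified by brute-force run-length counting)."""
        img, rec, _ = clean_stack
        geom = rec.geometry
        lm_px = round(geom.lm_nm / img.nm_per_px)
        mid = img.shape[1] // 2
        for col_idx in (mid - 30, mid, mid + 30):
            runs, starts = column_run_lengths(img.pixels[:, col_idx], 18000.0)
            assert len(runs) == geom.n_layers
            assert np.all(np.abs(runs - lm_px) <= 1)
            gaps = np.diff(starts) - runs[:-1]
            assert np.all(np.abs(gaps - round(geom.gap_nm / img.nm_per_px)) <= 1)

    def test_integer_width_runs_are_exact(self):
        """Integer-pixel stripe widths give exactly piecewise-constant
        columns: bright runs of lm/nm_per_px px, dark runs of gap/nm_per_px."""
        geom = g.make_grana_truth(gap_nm=4.0, lm_nm=12.0, n_layers=5, diameter_nm=60.0)
        opts = g.RenderOptions(nm_per_px=0.5, psf_sigma_px=0.0, noise_model="none")
        img, _ = g.render_grana(geom, opts)
        col = img.pixels[:, img.shape[1] // 2]
        assert set(np.unique(col)) == {8000.0, 28000.0}
        runs, starts = column_run_lengths(col, 18000.0)
        assert list(runs) == [24] * 5
        assert list(np.diff(starts) - runs[:-1]) == [8] * 4

    def test_same_seed_is_bit_identical(self, dark_geometry, study_options):
        a, _ = g.render_grana(dark_geometry, study_options)
        b, _ = g.render_grana(dark_geometry, study_options)
        assert np.array_equal(a.pixels, b.pixels)

    def test_different_seed_differs(self, dark_geometry, study_options):
        other = dataclasses.replace(study_options, seed=study_options.seed + 1)
        a, _ = g.render_grana(dark_geometry, study_options)
        b, _ = g.render_grana(dark_geometry, other)
        assert not np.array_equal(a.pixels, b.pixels)

    def test_subpixel_repeat_raises_resolution_error(self):
        geom = g.make_grana_truth(gap_nm=0.5, lm_nm=1.0, n_layers=5)
        with pytest.raises(ResolutionError):
            g.render_grana(geom, g.RenderOptions(nm_per_px=1.0))

    def test_blur_and_noise_leave_truth_unchanged(self, dark_geometry):
        clean = g.RenderOptions(nm_per_px=0.5, psf_sigma_px=0.0, noise_model="none")
        dirty = g.RenderOptions(nm_per_px=0.5, psf_sigma_px=3.0,
                                noise_model="poisson_gaussian", snr=3.0, seed=1)
        _, rec_clean = g.render_grana(dark_geometry, clean)
        _, rec_dirty = g.render_grana(dark_geometry, dirty)
        assert rec_clean.geometry == rec_dirty.geometry

    def test_noise_sd_matches_snr_definition(self, dark_geometry):
        """SNR = (bright - dark) / noise SD on a flat background region."""
        opts = g.RenderOptions(nm_per_px=0.5, psf_sigma_px=0.0,
                               noise_model="gaussian", snr=5.0, seed=3)
        img, _ = g.render_grana(dark_geometry, opts)
        corner = img.pixels[:12, :12]  # pure background
        assert corner.std() == pytest.approx(20000.0 / 5.0, rel=0.15)


class TestRenderLamella:
    def test_hpf_single_band_width(self):
        geom = g.make_lamella_truth(15.7, length_nm=100.0)
        img, _ = g.render_lamella(
            geom, g.RenderOptions(nm_per_px=0.5, psf_sigma_px=0.0, noise_model="none")
        )
        runs, _ = column_run_lengths(img.pixels[:, img.shape[1] // 2], 18000.0)
        assert len(runs) == 1
        assert runs[0] in (31, 32)  # 15.7 nm / 0.5 nm/px = 31.4 px

    def test_microwave_has_three_gray_levels(self):
        geom = g.make_lamella_truth(15.2, length_nm=50.0, membrane_nm=5.1, lumen_nm=5.0)
        opts = g.RenderOptions(nm_per_px=0.3, psf_sigma_px=0.0, noise_model="none",
                               contrast_mode="MICROWAVE")
        img, _ = g.render_lamella(geom, opts)
        interior = img.pixels[:, img.shape[1] // 2]
        # away from anti-aliased edges, exactly the three class levels appear
        levels = {6000.0, 18000.0, 30000.0}
        assert levels <= set(np.unique(interior))
        assert set(np.unique(interior)) - levels <= set(
            v for v in np.unique(interior) if 6000.0 < v < 30000.0
        )

    def test_microwave_subband_widths_prescale(self):
        """Dark-bright-dark sub-bands carry the commanded membrane/lumen
        widths before blur."""
        geom = g.make_lamella_truth(15.2, length_nm=50.0, membrane_nm=5.1, lumen_nm=5.0)
        opts = g.RenderOptions(nm_per_px=0.3, psf_sigma_px=0.0, noise_model="none",
                               contrast_mode="MICROWAVE")
        img, _ = g.render_lamella(geom, opts)
        col = img.pixels[:, img.shape[1] // 2]
        dark_runs, _ = column_run_lengths(-col, -12000.0)  # below stroma
        bright_runs, _ = column_run_lengths(col, 24000.0)
        assert len(dark_runs) == 2 and len(bright_runs) == 1
        assert np.all(np.abs(dark_runs * 0.3 - 5.1) <= 0.6)
        assert abs(bright_runs[0] * 0.3 - 5.0) <= 0.6

    def test_microwave_without_components_rejected(self):
        geom = g.make_lamella_truth(15.7)
        with pytest.raises(ValidationError):
            g.render_lamella(geom, g.RenderOptions(contrast_mode="MICROWAVE"))


class TestRenderOptionsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"nm_per_px": 0.0},
            {"psf_sigma_px": -1.0},
            {"contrast_mode": "SEM"},
            {"noise_model": "salt"},
            {"snr": 0.0},
            {"contrast_mode": "HPF", "intensity_levels": {"stripe": 1.0}},
            {"contrast_mode": "HPF",
             "intensity_levels": {"stripe": 1.0, "background": 1.0}},
        ],
    )
    def test_invalid_options(self, kwargs):
        with pytest.raises(ValidationError):
            g.RenderOptions(**kwargs)


class TestCohorts:
    def _tiny_config(self, count=2):
        return {
            "render": {"nm_per_px": 0.5, "psf_sigma_px": 1.0, "snr": 5.0,
                       "contrast_mode": "HPF"},
            "conditions": {
                "dark": {"kind": "grana", "count": count,
                         "gap_nm": {"mean": 4.68, "sd": 0.3},
                         "lm_nm": {"mean": 12.22, "sd": 0.8},
                         "n_layers": 6, "diameter_nm": 80.0,
                         "tilt_deg": {"min": -10, "max": 10}},
            },
        }

    def test_count_zero_gives_empty_manifest(self, tmp_path):
        manifest = g.generate_cohort(self._tiny_config(count=0), tmp_path, seed=0)
        assert len(manifest) == 0
        assert not list(tmp_path.glob("*.tif"))

    def test_counts_and_manifest_rows_match(self, tmp_path):
        cfg = self._tiny_config(count=3)
        cfg["conditions"]["light"] = dict(cfg["conditions"]["dark"])
        manifest = g.generate_cohort(cfg, tmp_path, seed=5)
        assert len(manifest) == 6
        assert len(list(tmp_path.glob("*.tif"))) == 6
        assert set(manifest["condition"]) == {"dark", "light"}

    def test_same_seed_identical_manifests(self, tmp_path):
        m1 = g.generate_cohort(self._tiny_config(), tmp_path / "a", seed=9)
        m2 = g.generate_cohort(self._tiny_config(), tmp_path / "b", seed=9)
        assert m1.equals(m2)

    def test_manifest_truths_satisfy_repeat_identity(self, tmp_path):
        g.generate_cohort(self._tiny_config(count=3), tmp_path, seed=2)
        for rec in g.load_manifest(tmp_path / "manifest.csv"):
            geom = rec.geometry
            assert geom.repeat_nm == geom.gap_nm + geom.lm_nm

    def test_truth_record_roundtrips_through_row(self, dark_geometry, study_options):
        _, rec = g.render_grana(dark_geometry, study_options, condition="dark")
        back = GroundTruthRecord.from_row(rec.to_row())
        assert back.geometry == rec.geometry
        assert back.options == rec.options
        assert back.condition == rec.condition

    def test_unknown_config_key_rejected(self):
        cfg = self._tiny_config()
        cfg["conditions"]["dark"]["repeat_nm"] = 17.0
        with pytest.raises(ValidationError):
            list(sample_cohort(cfg, seed=0))
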