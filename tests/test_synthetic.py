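"""Generators: forward-model correctness, determinism, validation."""

import numpy as np
import pandas as pd
import pytest

from fibrilmech import synthetic
from fibrilmech.force_spectroscopy import read_curve_tsv, write_curve_tsv
from fibrilmech.topography import TopographyImage


class TestForceCurveGenerator:
    def test_in_contact_force_follows_cone_law(self, pbs_curve_spec):
        """Beyond contact, F must equal (2/π)tanθ·E/(1−ν²)·δ² exactly."""
        curve = synthetic.generate_force_curve(pbs_curve_spec)
        z, d = curve.segment_arrays("approach")
        k = curve.spring_constant
        z0 = pbs_curve_spec.contact_point_nm
        force = k * d
        delta = (z - z0) - d
        contact = z > z0
        c = synthetic.sneddon_prefactor_nn_per_nm2(pbs_curve_spec)
        np.testing.assert_allclose(force[contact], c * delta[contact] ** 2, rtol=1e-12)
        # pre-contact baseline is exactly zero for a noiseless spec
        assert np.all(force[~contact] == 0.0)

    def test_channels_consistent_with_spring_constant(self, pbs_curve_spec):
        """Piezo travel = indentation + bending: z − z0 = δ + F/k in contact."""
        curve = synthetic.generate_force_curve(pbs_curve_spec)
        z, d = curve.segment_arrays("approach")
        z0 = pbs_curve_spec.contact_point_nm
        contact = z > z0
        delta = (z - z0) - d
        np.testing.assert_allclose((z - z0)[contact], (delta + d)[contact], rtol=1e-12)
        assert delta[contact].max() == pytest.approx(
            pbs_curve_spec.max_indentation_nm, rel=1e-9
        )

    def test_zero_indentation_gives_flat_curve(self):
        spec = synthetic.CurveSimSpec(modulus_true_pa=1e9, max_indentation_nm=0.0)
        curve = synthetic.generate_force_curve(spec)
        assert np.all(curve.deflection_nm == 0.0)

    def test_same_seed_reproduces_curve(self):
        spec = synthetic.CurveSimSpec(modulus_true_pa=1e7, noise_sd_nn=0.1, seed=42)
        c1 = synthetic.generate_force_curve(spec)
        c2 = synthetic.generate_force_curve(spec)
        np.testing.assert_array_equal(c1.deflection_nm, c2.deflection_nm)

    def test_drift_appears_on_baseline(self):
        spec = synthetic.CurveSimSpec(modulus_true_pa=1e7, drift_slope_nn_per_nm=0.01)
        curve = synthetic.generate_force_curve(spec)
        z, d = curve.segment_arrays("approach")
        pre = z < spec.contact_point_nm
        slope = np.polyfit(z[pre], curve.spring_constant * d[pre], 1)[0]
        assert slope == pytest.approx(0.01, rel=1e-6)

    @pytest.mark.parametrize(
        "bad",
        [
            {"modulus_true_pa": -1.0},
            {"modulus_true_pa": float("nan")},
            {"modulus_true_pa": 1e6, "poisson_sample": 0.6},
            {"modulus_true_pa": 1e6, "noise_sd_nn": -0.1},
            {"modulus_true_pa": 1e6, "points_per_segment": 8},
        ],
    )
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            synthetic.CurveSimSpec(**bad)

    def test_tsv_round_trip(self, tmp_path, pbs_curve_spec):
        curve = synthetic.generate_force_curve(pbs_curve_spec)
        path = tmp_path / "curve.tsv"
        write_curve_tsv(curve, path)
        back = read_curve_tsv(path)
        np.testing.assert_allclose(back.z_nm, curve.z_nm, rtol=1e-8)
        np.testing.assert_allclose(back.deflection_nm, curve.deflection_nm, rtol=1e-6,
                                   atol=1e-12)
        assert back.spring_constant == curve.spring_constant
        assert back.medium == curve.medium


class TestFibrilImageGenerator:
    def test_wet_peak_height_is_dry_times_swelling(self):
        """26 nm dry at fold 2.6 → crest reaches 67.6 nm (± banding)."""
        spec = synthetic.FibrilImageSpec(
            height_dry_nm=26.0, swelling_true=2.6, band_amplitude_frac=0.0,
            fibril_width_nm=60.0, substrate_roughness_sd_nm=0.0,
            image_shape=(128, 384),
        )
        wet = synthetic.generate_fibril_image(spec, state="wet")
        assert wet.heights_nm.max() == pytest.approx(67.6, abs=0.15)
        dry = synthetic.generate_fibril_image(spec, state="dry")
        assert dry.heights_nm.max() == pytest.approx(26.0, abs=0.1)

    def test_zero_band_amplitude_gives_flat_crest(self):
        spec = synthetic.FibrilImageSpec(
            band_amplitude_frac=0.0, substrate_roughness_sd_nm=0.0,
            image_shape=(96, 320),
        )
        image = synthetic.generate_fibril_image(spec, state="dry")
        crest = image.heights_nm[image.heights_nm.shape[0] // 2, :]
        assert np.ptp(crest) < 1e-9

    def test_crest_variance_matches_substrate_roughness_when_unbanded(self):
        spec = synthetic.FibrilImageSpec(
            band_amplitude_frac=0.0, substrate_roughness_sd_nm=0.3,
            image_shape=(96, 320), seed=5,
        )
        image = synthetic.generate_fibril_image(spec, state="dry")
        crest = image.heights_nm[image.heights_nm.shape[0] // 2, :]
        assert np.var(crest) == pytest.approx(0.3**2, rel=0.35)

    def test_tip_dilation_broadens_but_preserves_crest(self):
        base = synthetic.FibrilImageSpec(
            band_amplitude_frac=0.0, substrate_roughness_sd_nm=0.0,
            image_shape=(96, 320),
        )
        dilated_spec = synthetic.FibrilImageSpec(
            band_amplitude_frac=0.0, substrate_roughness_sd_nm=0.0,
            image_shape=(96, 320), tip_radius_nm=10.0,
        )
        plain = synthetic.generate_fibril_image(base, "dry").heights_nm
        dilated = synthetic.generate_fibril_image(dilated_spec, "dry").heights_nm
        assert dilated.max() == pytest.approx(plain.max(), abs=1e-9)
        assert (dilated > 1.0).sum() > (plain > 1.0).sum()

    def test_image_too_small_rejected(self):
        spec = synthetic.FibrilImageSpec(fibril_width_nm=200.0, image_shape=(32, 64))
        with pytest.raises(ValueError, match="too small"):
            synthetic.generate_fibril_image(spec, state="dry")

    def test_nyquist_validation(self):
        with pytest.raises(ValueError, match="Nyquist"):
            synthetic.FibrilImageSpec(d_period_nm=3.0, pixel_size_nm=2.0)

    def test_tiff_round_trip(self, tmp_path):
        spec = synthetic.FibrilImageSpec(image_shape=(64, 128), seed=3)
        image = synthetic.generate_fibril_image(spec, state="dry")
        path = tmp_path / "fibril.tif"
        image.to_tiff(path)
        back = TopographyImage.from_tiff(path)
        np.testing.assert_allclose(back.heights_nm, image.heights_nm, atol=1e-4)
        assert back.pixel_size_nm == image.pixel_size_nm
        assert back.state == "dry"

    def test_ascii_round_trip(self, tmp_path):
        spec = synthetic.FibrilImageSpec(image_shape=(64, 96), fibril_width_nm=30.0, seed=3)
        image = synthetic.generate_fibril_image(spec, state="wet")
        path = tmp_path / "fibril.txt"
        image.to_ascii(path)
        back = TopographyImage.from_ascii(path)
        np.testing.assert_allclose(back.heights_nm, image.heights_nm, rtol=1e-6)
        assert back.pixel_size_nm == image.pixel_size_nm


class TestCohortGenerator:
    def test_group_sizes_and_labels(self):
        spec = synthetic.CohortSimSpec(
            groups=(
                synthetic.GroupSpec("WT", "PBS", 3.3e6, 0.5e6, 10),
                synthetic.GroupSpec("OIM", "PBS", 16.2e6, 3.0e6, 8),
            ),
            seed=0,
        )
        cohort = synthetic.generate_cohort(spec)
        assert len(cohort) == 18
        counts = cohort.groupby("genotype").size()
        assert counts["WT"] == 10 and counts["OIM"] == 8
        assert set(cohort["medium"]) == {"PBS"}
        assert cohort["fibril_id"].is_unique

    def test_zero_sd_gives_constant_group(self):
        spec = synthetic.CohortSimSpec(
            groups=(synthetic.GroupSpec("WT", "air", 5e9, 0.0, 5),), seed=1
        )
        cohort = synthetic.generate_cohort(spec)
        assert np.all(cohort["modulus_Pa"] == 5e9)

    def test_same_seed_identical_tables(self):
        spec = synthetic.CohortSimSpec(
            groups=(synthetic.GroupSpec("WT", "PBS", 3.3e6, 0.5e6, 6),), seed=7
        )
        pd.testing.assert_frame_equal(
            synthetic.generate_cohort(spec), synthetic.generate_cohort(spec)
        )

    @pytest.mark.parametrize("distribution", ["lognormal", "normal-truncated-at-0"])
    def test_large_sample_mean_matches_spec(self, distribution):
        """Sample mean of 10⁴ draws must fall within 3 standard errors."""
        mean, sd, n = 16.2e6, 3.0e6, 10_000
        spec = synthetic.CohortSimSpec(
            groups=(synthetic.GroupSpec("OIM", "PBS", mean, sd, n),),
            distribution=distribution,
            seed=11,
        )
        values = synthetic.generate_cohort(spec)["modulus_Pa"]
        se = sd / np.sqrt(n)
        assert abs(values.mean() - mean) < 3 * se

    def test_cohort_csv_round_trip(self, tmp_path):
        spec = synthetic.CohortSimSpec(
            groups=(synthetic.GroupSpec("WT", "PBS", 3.3e6, 0.5e6, 4),), seed=2
        )
        cohort = synthetic.generate_cohort(spec)
        path = tmp_path / "cohort.csv"
        synthetic.write_cohort_csv(cohort, path)
        back = synthetic.read_cohort_csv(path)
        pd.testing.assert_frame_equal(back, cohort)
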