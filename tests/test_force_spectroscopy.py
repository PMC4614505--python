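"""Contact-mechanics chain: unit oracles, round trips, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibrilmech import force_spectroscopy as fs
from fibrilmech import synthetic


class TestThermalCalibration:
    def test_equipartition_arithmetic(self):
        """var(d)=1.69×10⁻² nm² at 294 K gives k ≈ 0.24 N/m (k_B·T/var)."""
        var = 1.69e-2
        rng = np.random.default_rng(0)
        # build a series with exactly that variance
        d = rng.normal(0, 1, 200_000)
        d = (d - d.mean()) / d.std() * np.sqrt(var)
        k = fs.thermal_spring_constant(d, temperature_k=294.0, correction=1.0)
        expected = 1.380649e-23 * 294.0 / (var * 1e-18)
        assert k == pytest.approx(expected, rel=1e-9)
        assert k == pytest.approx(0.24, abs=0.01)

    def test_doubling_variance_halves_k(self, rng):
        d = rng.normal(0, 0.1, 10_000)
        k1 = fs.thermal_spring_constant(d)
        k2 = fs.thermal_spring_constant(d * np.sqrt(2))
        assert k2 == pytest.approx(k1 / 2, rel=1e-9)

    def test_recovers_stiff_lever_from_simulated_noise(self):
        """Equipartition recovery of the 8.3 N/m lever from 10⁵ samples."""
        k_true, t_k = 8.3, 294.0
        sd_nm = np.sqrt(1.380649e-23 * t_k / k_true) * 1e9
        d = np.random.default_rng(3).normal(0, sd_nm, 100_000)
        k = fs.thermal_spring_constant(d, temperature_k=t_k, correction=1.0)
        assert k == pytest.approx(k_true, rel=0.05)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            fs.thermal_spring_constant(np.zeros(100))


class TestForceSeparation:
    def test_rigid_sample_limit(self):
        """d ≡ 0 → δ = z − z0 and F ≡ 0."""
        n = 64
        z = np.linspace(0, 100, n)
        curve = fs.ForceCurve(z, np.zeros(n), np.array(["approach"] * n),
                              calibration=fs.CantileverCalibration(0.24))
        delta, force = fs.to_force_and_separation(curve, 50.0)
        np.testing.assert_allclose(delta, z - 50.0, atol=1e-12)
        np.testing.assert_allclose(force, 0.0, atol=1e-12)

    def test_force_is_k_times_deflection(self):
        """k = 0.24 N/m at 10 nm deflection → 2.4 nN."""
        z = np.linspace(0, 100, 64)
        d = np.where(z > 50, 10.0, 0.0)
        curve = fs.ForceCurve(z, d, np.array(["approach"] * 64),
                              calibration=fs.CantileverCalibration(0.24))
        _, force = fs.to_force_and_separation(curve, 50.0, smooth_window=0)
        assert force.max() == pytest.approx(2.4, rel=1e-9)

    def test_max_separation_matches_generator_truth(self, pbs_curve_spec):
        curve = synthetic.generate_force_curve(pbs_curve_spec)
        delta, _ = fs.to_force_and_separation(curve, pbs_curve_spec.contact_point_nm)
        assert delta.max() == pytest.approx(pbs_curve_spec.max_indentation_nm, rel=0.01)

    def test_missing_calibration_raises(self):
        z = np.linspace(0, 10, 32)
        curve = fs.ForceCurve(z, np.zeros(32), np.array(["approach"] * 32))
        with pytest.raises(ValueError, match="calibration"):
            fs.to_force_and_separation(curve, 5.0)


class TestContactPoint:
    def test_noiseless_curve_recovers_spec_contact_point(self, pbs_curve_spec):
        curve = synthetic.generate_force_curve(pbs_curve_spec)
        spacing = np.median(np.diff(curve.segment_arrays("approach")[0]))
        result = fs.find_contact_point(curve)
        assert result.found
        assert abs(result.z0_nm - pbs_curve_spec.contact_point_nm) < spacing

    def test_flat_noise_curve_flags_no_contact(self, rng):
        n = 256
        z = np.linspace(0, 200, n)
        d = rng.normal(0, 0.05, n)
        curve = fs.ForceCurve(z, d, np.array(["approach"] * n),
                              calibration=fs.CantileverCalibration(0.24))
        result = fs.find_contact_point(curve)
        assert not result.found
        assert np.isnan(result.z0_nm)

    def test_noisy_contact_point_within_three_spacings(self):
        """Median error ≤ 3 sample spacings at 2% peak-force noise, 20 seeds."""
        base = synthetic.CurveSimSpec(modulus_true_pa=16.2e6)
        noise = 0.02 * synthetic.max_force_nn(base)
        errors = []
        for seed in range(20):
            spec = synthetic.CurveSimSpec(modulus_true_pa=16.2e6,
                                          noise_sd_nn=noise, seed=seed)
            curve = synthetic.generate_force_curve(spec)
            spacing = np.median(np.diff(curve.segment_arrays("approach")[0]))
            res = fs.find_contact_point(curve)
            errors.append(abs(res.z0_nm - spec.contact_point_nm) / spacing)
        assert np.median(errors) <= 3.0


class TestContactStiffness:
    def test_quadratic_analytic_slope(self):
        """F = C·δ² with F(100 nm) = 10 nN → S_c = 2C·δmax = 0.2 N/m."""
        delta = np.linspace(0, 100, 200)
        force = 1e-3 * delta**2
        fit = fs.contact_stiffness(delta, force)
        assert fit.s_c_n_per_m == pytest.approx(0.2, rel=1e-9)
        assert fit.exponent == pytest.approx(2.0, abs=1e-9)

    def test_linear_law_returns_its_slope(self):
        delta = np.linspace(0, 50, 100)
        force = 0.7 * delta
        fit = fs.contact_stiffness(delta, force)
        assert fit.s_c_n_per_m == pytest.approx(0.7, rel=1e-9)

    def test_noisy_quadratic_within_five_percent(self):
        """S_c within 5% of the analytic slope over 20 seeds."""
        delta = np.linspace(0, 100, 400)
        clean = 1e-3 * delta**2
        estimates = []
        for seed in range(20):
            noisy = clean + np.random.default_rng(seed).normal(0, 0.02 * clean.max(),
                                                               len(delta))
            fit = fs.contact_stiffness(delta, noisy)
            estimates.append(fit.s_c_n_per_m)
        assert np.median(np.abs(np.array(estimates) / 0.2 - 1)) < 0.05

    def test_non_monotone_segment_rejected(self):
        delta = np.linspace(0, 100, 100)
        force = np.sin(delta / 5.0)  # oscillating, clearly not indentation-like
        with pytest.raises(ValueError, match="monoton"):
            fs.contact_stiffness(delta, force)


class TestDepthAreaModuli:
    def test_contact_depth_arithmetic(self):
        """h_max 100 nm, P 10 nN, S 0.2 N/m, ε 0.75 → h_c = 62.5 nm."""
        assert fs.contact_depth(100.0, 10.0, 0.2, epsilon=0.75) == pytest.approx(62.5)
        assert fs.contact_depth(100.0, 10.0, 0.2, epsilon=0.0) == pytest.approx(100.0)

    def test_cone_depth_closed_form(self, pbs_curve_spec):
        """For the Sneddon cone with ε = 2(π−2)/π, h_c = (2/π)·δmax exactly."""
        curve = synthetic.generate_force_curve(pbs_curve_spec)
        res = fs.analyze_curve(curve)
        assert res.h_c_nm == pytest.approx((2 / np.pi) * res.h_max_nm, rel=1e-4)

    def test_negative_depth_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            assert fs.contact_depth(1.0, 100.0, 0.2) == 0.0

    def test_ideal_cone_area(self):
        """A_c = π·tan²(35°)·h_c²; at h_c = 20 nm this is ≈ 616.1 nm²."""
        fn = fs.TipAreaFunction(theta_deg=35.0)
        assert fn.area_nm2(20.0) == pytest.approx(np.pi * np.tan(np.radians(35)) ** 2 * 400,
                                                  rel=1e-12)
        assert fn.area_nm2(20.0) == pytest.approx(616.12, abs=0.01)
        assert fn.area_nm2(0.0) == 0.0

    def test_calibrated_polynomial_area(self):
        fn = fs.TipAreaFunction(coefficients=(24.5,), source="calibrated")
        assert fn.area_nm2(10.0) == pytest.approx(2450.0)

    def test_area_function_json_round_trip(self, tmp_path):
        fn = fs.TipAreaFunction(theta_deg=35.0, coefficients=(24.5, 3.0, 1.0),
                                source="calibrated")
        path = tmp_path / "area.json"
        fn.to_json(path)
        back = fs.TipAreaFunction.from_json(path)
        assert back == fn

    def test_reduced_modulus_oracle(self):
        """S_c 0.2 N/m on A_c 2450 nm² at β=1 → E_r ≈ 3.58 MPa."""
        e_r = fs.reduced_modulus(0.2, 2450.0, beta=1.0)
        expected = np.sqrt(np.pi) / 2 * 0.2 / np.sqrt(2450e-18)
        assert e_r == pytest.approx(expected, rel=1e-12)
        assert e_r == pytest.approx(3.581e6, rel=1e-3)

    @given(scale=st.floats(1.0226 * 1.0001, 1.0849))
    @settings(max_examples=25, deadline=None)
    def test_beta_scaling_inverse(self, scale):
        assert fs.reduced_modulus(0.2, 2450.0, beta=scale) == pytest.approx(
            fs.reduced_modulus(0.2, 2450.0, beta=1.0) / scale, rel=1e-12
        )

    def test_area_quadrupled_halves_er(self):
        assert fs.reduced_modulus(0.2, 4 * 2450.0) == pytest.approx(
            fs.reduced_modulus(0.2, 2450.0) / 2, rel=1e-12
        )

    @given(
        s1=st.floats(0.01, 10.0), s2=st.floats(0.01, 10.0),
        a1=st.floats(10.0, 1e6), a2=st.floats(10.0, 1e6),
    )
    @settings(max_examples=50, deadline=None)
    def test_er_monotone_in_stiffness_and_area(self, s1, s2, a1, a2):
        """E_r increases with S_c at fixed A_c and decreases with A_c."""
        if s1 < s2:
            assert fs.reduced_modulus(s1, a1) <= fs.reduced_modulus(s2, a1)
        if a1 < a2:
            assert fs.reduced_modulus(s1, a2) <= fs.reduced_modulus(s1, a1)

    def test_sample_modulus_simplified(self):
        assert fs.sample_modulus(4e6, nu_sample=0.5) == pytest.approx(3e6)
        assert fs.sample_modulus(4e6, nu_sample=0.0) == pytest.approx(4e6)

    def test_two_body_correction_at_stiff_end(self):
        """Near 13 GPa the rigid-indenter shortcut is ~9–10% low (Si tip)."""
        e_r = 13e9 / (1 - 0.5**2)  # reduced modulus whose shortcut gives 13 GPa
        simplified = fs.sample_modulus(e_r, mode="simplified")
        two_body = fs.sample_modulus(e_r, mode="two_body")
        excess = two_body / simplified - 1
        assert 0.08 < excess < 0.12

    def test_two_body_agrees_with_simplified_in_hydrated_regime(self):
        """Below 100 MPa the two formulations differ by < 0.1%."""
        for e_s in (5e6, 16.2e6, 100e6):
            e_r = e_s / (1 - 0.5**2)
            assert fs.sample_modulus(e_r, mode="two_body") == pytest.approx(
                fs.sample_modulus(e_r, mode="simplified"), rel=1e-3
            )

    def test_two_body_nonphysical_rejected(self):
        limit = 169e9 / (1 - 0.27**2)
        with pytest.raises(ValueError, match="non-physical"):
            fs.sample_modulus(limit * 1.01, mode="two_body")


class TestAnalyzeCurve:
    def test_unit_audit_si_vs_afm_units(self, pbs_curve_spec):
        """The nm/nN chain must agree with a hand-built SI chain to 1e-6."""
        curve = synthetic.generate_force_curve(pbs_curve_spec)
        res = fs.analyze_curve(curve)
        # SI recomputation from the same measured quantities
        s_c = res.s_c_n_per_m                       # N/m already SI
        a_c_m2 = res.a_c_nm2 * 1e-18
        e_r_si = np.sqrt(np.pi) / 2 * s_c / np.sqrt(a_c_m2)
        e_sample_si = (1 - res.nu_sample**2) * e_r_si
        assert res.e_sample_pa == pytest.approx(e_sample_si, rel=1e-6)

    def test_flat_curve_marked_invalid_and_excluded(self):
        flat = synthetic.generate_force_curve(
            synthetic.CurveSimSpec(modulus_true_pa=1e9, max_indentation_nm=0.0,
                                   noise_sd_nn=0.001, seed=9)
        )
        good = synthetic.generate_force_curve(
            synthetic.CurveSimSpec(modulus_true_pa=16.2e6, seed=1)
        )
        table = fs.analyze_batch([flat, good])
        assert list(table["valid"]) == [False, True]
        assert table.loc[0, "reason"] == "no-contact"
        valid = table[table["valid"]]
        assert len(valid) == 1 and np.isfinite(valid["e_sample_pa"]).all()

    def test_config_echoed_into_result(self, pbs_curve_spec):
        curve = synthetic.generate_force_curve(pbs_curve_spec)
        res = fs.analyze_curve(curve, config=fs.AnalysisConfig(nu_sample=0.4))
        assert res.nu_sample == 0.4
        assert res.config["nu_sample"] == 0.4
        assert res.beta == 1.0

    def test_batch_group_mean_recovery_with_noise(self):
        """8 noisy hydrated-state curves recover the group mean within 10%."""
        truth = 16.2e6
        curves = []
        for seed in range(8):
            spec = synthetic.CurveSimSpec(modulus_true_pa=truth, seed=seed)
            spec = synthetic.CurveSimSpec(
                **{**spec.__dict__, "noise_sd_nn": 0.02 * synthetic.max_force_nn(spec)}
            )
            curves.append(synthetic.generate_force_curve(spec))
        table = fs.analyze_batch(curves)
        mean = table.loc[table["valid"], "e_sample_pa"].mean()
        assert mean == pytest.approx(truth, rel=0.10)
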