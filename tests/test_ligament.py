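"""Viscoelastic bundle model: strain kinematics, recruitment density,
stress integrals against independent oracles, forces, fits, and limits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from landrisk import ligament as lig
from landrisk.exceptions import (
    InsufficientDataError,
    InvalidParameterError,
    ShapeError,
)

A = lig.A_ACL
P = lig.P_ACL

# σ(ε=0.10, ε̇=0) for the default constants, frozen from a 1e6-node
# trapezoid evaluation of the recruitment integral (agrees to 1e-11 MPa).
SIGMA_010_STATIC = 0.00905396865642949


def dense_trapezoid_stress(eps, rate, spec, nodes=1_000_001):
    """Brute-force oracle: trapezoid rule on a dense uniform grid."""
    if eps <= 0:
        return 0.0
    s = np.linspace(0.0, eps, nodes)
    a, b = spec.weibull_shape, spec.weibull_scale
    w = (a / b) * np.where(s > 0, (s / b) ** (a - 1.0), 0.0) * np.exp(-((s / b) ** a))
    integrand = w * (spec.elastic_modulus * (eps - s) + spec.viscosity * rate)
    return max(float(np.trapezoid(integrand, s)), 0.0)


class TestStrainKinematics:
    @pytest.mark.parametrize(
        "le, lr, expected",
        [(33.0, 30.0, 0.10), (30.0, 30.0, 0.0), (23.36 * 1.05, 23.36, 0.05)],
    )
    def test_engineering_strain(self, le, lr, expected):
        assert lig.compute_strain(le, lr) == pytest.approx(expected)

    def test_slack_strain_is_negative(self):
        assert lig.compute_strain(28.0, 30.0) < 0

    def test_nonpositive_resting_length_rejected(self):
        with pytest.raises(InvalidParameterError):
            lig.compute_strain(30.0, 0.0)

    def test_constant_strain_has_zero_rate(self):
        rate = lig.compute_strain_rate(np.full(50, 0.07), dt=0.005)
        assert np.allclose(rate, 0.0)

    def test_linear_strain_rate_exact(self):
        t = np.arange(0, 0.5, 0.005)
        rate = lig.compute_strain_rate(0.2 * t, dt=0.005)
        assert np.allclose(rate, 0.2)

    def test_sinusoid_rate_matches_analytic_derivative(self):
        dt = 1e-4
        t = np.arange(0, 0.2, dt)
        omega = 2 * np.pi * 5
        rate = lig.compute_strain_rate(0.05 * np.sin(omega * t), dt)
        analytic = 0.05 * omega * np.cos(omega * t)
        assert np.max(np.abs(rate - analytic)[1:-1]) < 0.05 * omega**2 * dt**2 * 10

    def test_single_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            lig.compute_strain_rate([0.1], dt=0.005)


class TestRecruitmentDensity:
    def test_zero_at_origin_for_shape_above_one(self):
        assert lig.weibull_recruitment_density(0.0, 4.5, 0.3) == 0.0

    def test_negative_strain_has_no_recruitment(self):
        assert lig.weibull_recruitment_density(-0.2, 4.5, 0.3) == 0.0

    def test_value_at_scale_parameter(self):
        # pdf(β) = (α/β)·e⁻¹ for any Weibull
        assert lig.weibull_recruitment_density(0.3, 4.5, 0.3) == pytest.approx(
            (4.5 / 0.3) * np.exp(-1.0)
        )

    def test_density_normalizes_to_one(self):
        s = np.linspace(0, 3.0, 2_000_001)
        pdf = lig.weibull_recruitment_density(s, 4.5, 0.3)
        assert np.trapezoid(pdf, s) == pytest.approx(1.0, abs=1e-8)

    def test_matches_scipy_weibull(self):
        s = np.linspace(0.01, 1.2, 40)
        ours = lig.weibull_recruitment_density(s, 4.5, 0.3)
        ref = sps.weibull_min.pdf(s, c=4.5, scale=0.3)
        assert np.allclose(ours, ref, rtol=1e-12)

    def test_invalid_shape_rejected(self):
        with pytest.raises(InvalidParameterError):
            lig.weibull_recruitment_density(0.1, -1.0, 0.3)


class TestNominalStress:
    def test_slack_and_zero_strain_give_zero(self):
        assert lig.nominal_axial_stress(0.0, 5.0, A) == 0.0
        assert lig.nominal_axial_stress(-0.05, 5.0, A) == 0.0

    def test_static_stress_matches_frozen_oracle_value(self):
        sigma = lig.nominal_axial_stress(0.10, 0.0, A)
        assert sigma == pytest.approx(SIGMA_010_STATIC, rel=1e-8)

    def test_viscous_increment_is_eta_rate_times_cdf(self):
        s0 = lig.nominal_axial_stress(0.10, 0.0, A)
        s1 = lig.nominal_axial_stress(0.10, 1.0, A)
        expected = A.viscosity * 1.0 * lig.weibull_recruitment_cdf(0.10)
        assert s1 - s0 == pytest.approx(expected, rel=1e-8)

    def test_monotone_in_strain_at_fixed_rate(self):
        eps = np.linspace(0.01, 0.5, 25)
        sigma = [lig.nominal_axial_stress(e, 2.0, A) for e in eps]
        assert np.all(np.diff(sigma) > 0)

    def test_negative_rate_clamps_total_at_zero(self):
        # strong unloading: viscous term would push the total negative
        assert lig.nominal_axial_stress(0.10, -100.0, A) == 0.0

    def test_decomposition_sums_and_matches_quadrature(self):
        dec = lig.stress_decomposition(0.2, 2.0, A)
        assert dec.total == pytest.approx(dec.elastic + dec.viscous)
        assert dec.pressure == 0.0
        assert dec.total == pytest.approx(lig.nominal_axial_stress(0.2, 2.0, A), rel=1e-8)

    def test_decomposition_viscous_over_eta_rate_is_cdf(self):
        dec = lig.stress_decomposition(0.2, 2.0, A)
        assert dec.viscous / (A.viscosity * 2.0) == pytest.approx(
            lig.weibull_recruitment_cdf(0.2), rel=1e-12
        )

    def test_zero_rate_decomposition_is_purely_elastic(self):
        dec = lig.stress_decomposition(0.15, 0.0, A)
        assert dec.viscous == 0.0
        assert dec.total == dec.elastic

    def test_slack_decomposition_all_zero(self):
        dec = lig.stress_decomposition(-0.01, 3.0, A)
        assert (dec.elastic, dec.viscous, dec.total) == (0.0, 0.0, 0.0)

    def test_series_path_agrees_with_scalar_quadrature(self):
        eps = np.array([-0.02, 0.0, 0.05, 0.12, 0.3, 0.6])
        rate = np.array([1.0, 2.0, 0.0, 3.0, -0.5, 1.5])
        series = lig.stress_series(eps, rate, A)
        scalar = [lig.nominal_axial_stress(e, r, A) for e, r in zip(eps, rate)]
        assert np.allclose(series, scalar, rtol=1e-7, atol=1e-12)

    def test_series_against_dense_trapezoid(self):
        for eps, rate in [(0.05, 0.0), (0.2, 1.5), (0.45, 4.0)]:
            got = float(lig.stress_series([eps], [rate], A)[0])
            assert got == pytest.approx(dense_trapezoid_stress(eps, rate, A), rel=1e-7)


class TestForces:
    def test_unit_stress_times_area(self):
        assert lig.ligament_force(1.0, A) == pytest.approx(20.7)

    def test_zero_stress_zero_force(self):
        assert lig.ligament_force(0.0, P) == 0.0

    def test_printed_posterolateral_arithmetic(self):
        force = lig.ligament_force(82.9, P)
        assert force == pytest.approx(1599.97)
        assert force < P.max_isometric_force  # just under the cap: not flagged

    def test_negative_stress_rejected(self):
        with pytest.raises(InvalidParameterError):
            lig.ligament_force(-1.0, A)

    def test_total_force_examples(self):
        assert np.array_equal(lig.total_acl_force([0, 0], [0, 0]), [0, 0])
        assert np.array_equal(lig.total_acl_force([100, 200], [50, 50]), [150, 250])

    def test_total_force_length_mismatch(self):
        with pytest.raises(ShapeError):
            lig.total_acl_force([1.0, 2.0], [1.0])

    @given(
        st.lists(st.floats(0, 1e3), min_size=1, max_size=20),
        st.lists(st.floats(0, 1e3), min_size=1, max_size=20),
    )
    @settings(max_examples=50, deadline=None)
    def test_total_force_commutative_and_linear(self, a, b):
        n = min(len(a), len(b))
        fa, fp = np.array(a[:n]), np.array(b[:n])
        assert np.array_equal(lig.total_acl_force(fa, fp), lig.total_acl_force(fp, fa))
        assert np.allclose(lig.total_acl_force(fa, fp), fa + fp)


class TestElongationMapping:
    def test_constant_mapping_gives_zero_strain(self):
        mapping = lig.ElongationMapping(coefficients=(A.resting_length,))
        le = lig.acl_elongation_from_knee_flexion(np.linspace(0, 90, 10), mapping)
        assert np.allclose(lig.compute_strain(le, A.resting_length), 0.0)

    def test_linear_mapping_known_slope(self):
        mapping = lig.ElongationMapping(coefficients=(0.05, 30.0))
        le = lig.acl_elongation_from_knee_flexion([0.0, 40.0], mapping)
        assert np.allclose(le, [30.0, 32.0])

    def test_out_of_range_flexion_rejected(self):
        mapping = lig.ElongationMapping(coefficients=(0.05, 30.0), flexion_range=(0, 90))
        with pytest.raises(InvalidParameterError):
            lig.acl_elongation_from_knee_flexion([100.0], mapping)


class TestMaterialFit:
    def test_exact_sixth_order_curve_recovered(self, rng):
        coeffs = np.array([2.0, -1.0, 0.5, 3.0, -2.0, 1.0, 0.25])
        x = np.linspace(0, 1, 15)
        fit = lig.fit_material_polynomial([(x, np.polyval(coeffs, x))])
        assert np.allclose(fit.coefficients, coeffs, atol=1e-8)
        assert fit.fit_residual < 1e-9

    def test_identical_curves_mean_equals_single_fit(self):
        x = np.linspace(0, 1, 20)
        y = np.polyval([1, 0, -2, 0, 1, 0, 0], x)
        one = lig.fit_material_polynomial([(x, y)])
        three = lig.fit_material_polynomial([(x, y)] * 3)
        assert np.allclose(one.coefficients, three.coefficients)
        assert three.sample_count == 3

    def test_noisy_curves_match_normal_equations_oracle(self, rng):
        coeffs = np.array([0.5, -0.2, 1.0, 0.0, -1.0, 2.0, 0.1])
        x = np.linspace(0, 1, 60)
        curves = []
        oracle_coeffs = []
        for _ in range(5):
            y = np.polyval(coeffs, x) + rng.normal(0, 0.01, x.size)
            curves.append((x, y))
            V = np.vander(x, 7)
            oracle_coeffs.append(np.linalg.solve(V.T @ V, V.T @ y))
        fit = lig.fit_material_polynomial(curves)
        assert np.allclose(fit.coefficients, np.mean(oracle_coeffs, axis=0), atol=1e-6)

    def test_too_few_points_rejected(self):
        x = np.linspace(0, 1, 5)
        with pytest.raises(InsufficientDataError):
            lig.fit_material_polynomial([(x, x)])


class TestStrainLimits:
    def test_zero_strain_empty_report(self):
        report = lig.strain_limit_check(np.zeros(100), A)
        assert not report.any_violation

    def test_single_sample_over_passive_cap(self):
        eps = np.zeros(50)
        eps[10] = 0.16
        report = lig.strain_limit_check(eps, A)
        assert list(report.passive_violation_indices) == [10]

    def test_ramp_crossing_onset_index(self):
        eps = np.linspace(0.0, 0.30, 301)  # crosses 0.15 at index 151
        report = lig.strain_limit_check(eps, A)
        assert report.passive_violation_indices[0] == 151

    def test_junction_window_checked_against_its_own_cap(self):
        eps = np.full(100, 0.05)  # below passive cap, above junction cap
        report = lig.strain_limit_check(eps, A, junction_window=(0, 20))
        assert len(report.junction_violation_indices) == 20
        assert not len(report.passive_violation_indices)


class TestBundleSpecs:
    def test_printed_bundle_parameters(self):
        assert (A.resting_length, A.cross_sectional_area, A.max_isometric_force) == (
            30.0, 20.7, 1500.0,
        )
        assert (P.resting_length, P.cross_sectional_area, P.max_isometric_force) == (
            23.36, 19.3, 1600.0,
        )
        assert A.elastic_modulus == 70.0 and A.viscosity == 20.0
        assert A.weibull_shape == 4.5 and A.weibull_scale == 0.3

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"resting_length": -1.0},
            {"cross_sectional_area": 0.0},
            {"elastic_modulus": -5.0},
            {"weibull_shape": 0.0},
            {"weibull_location": 0.1},
            {"passive_strain_cap": 1.5},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        base = dict(name="x", resting_length=30.0, cross_sectional_area=20.0,
                    max_isometric_force=1500.0)
        base.update(kwargs)
        with pytest.raises(InvalidParameterError):
            lig.LigamentBundleSpec(**base)

    def test_registry_roundtrip(self, tmp_path):
        path = tmp_path / "bundles.yaml"
        path.write_text("A-ACL:\n  elastic_modulus: 80.0\n")
        reg = lig.load_bundle_registry(path)
        assert reg["A-ACL"].elastic_modulus == 80.0
        assert reg["A-ACL"].resting_length == 30.0  # inherited default
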