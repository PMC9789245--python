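"""Tissue dielectric model: Cole-Cole evaluation, admittivity, QS criterion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vestfem.dielectrics import (
    EPS0,
    GABRIEL_COLE_COLE,
    AdmittivityTensor,
    ColeColeParams,
    TissueProperty,
    admittivity,
    default_property,
    evaluate_cole_cole,
    interp_property,
    property_bounds,
    qs_ratio,
    scale_nerve_conductivity,
)

# Frozen with an independently coded complex-arithmetic Cole-Cole sum
# (direct evaluation of the dispersion terms, separate from the package path).
ORACLE_2KHZ = {
    "cerebrospinal_fluid": (2.0000000000926152, 108.99999488763748),
    "cortical_bone": (0.020236067996650755, 1700.4361991596481),
}


class TestColeCole:
    def test_no_dispersion_terms_reduce_to_static_values(self):
        p = ColeColeParams(eps_inf=5.0, terms=(), sigma_ionic=1.3)
        for f in (0.0, 50.0, 1e5):
            sigma, eps = evaluate_cole_cole(p, f)
            assert sigma == pytest.approx(1.3)
            assert eps == pytest.approx(5.0)

    @pytest.mark.parametrize("tissue,f,expected", [
        ("cerebrospinal_fluid", 2e3, ORACLE_2KHZ["cerebrospinal_fluid"]),
        ("cortical_bone", 2e3, ORACLE_2KHZ["cortical_bone"]),
    ])
    def test_published_parameterizations_match_oracle(self, tissue, f, expected):
        sigma, eps = evaluate_cole_cole(GABRIEL_COLE_COLE[tissue], f)
        assert sigma == pytest.approx(expected[0], rel=1e-12)
        assert eps == pytest.approx(expected[1], rel=1e-12)

    def test_conductivity_nondecreasing_over_sweep_band(self):
        freqs = np.logspace(2, np.log10(5e5), 200)
        for tissue, params in GABRIEL_COLE_COLE.items():
            sigma, eps = evaluate_cole_cole(params, freqs)
            assert np.all(np.diff(sigma) >= -1e-15), tissue
            assert np.all(sigma > 0) and np.all(eps > 0), tissue

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            evaluate_cole_cole(GABRIEL_COLE_COLE["cortical_bone"], -1.0)
        with pytest.raises(ValueError):
            ColeColeParams(eps_inf=4.0, terms=((1.0, -1e-9, 0.1),), sigma_ionic=1.0)
        with pytest.raises(ValueError):
            ColeColeParams(eps_inf=4.0, terms=((1.0, 1e-9, 1.0),), sigma_ionic=1.0)


class TestAdmittivity:
    def test_zero_permittivity_and_dc_are_purely_real(self):
        assert admittivity(1.7, 0.0, 5e4) == pytest.approx(1.7 + 0j)
        assert admittivity(1.7, 300.0, 0.0) == pytest.approx(1.7 + 0j)

    def test_csf_at_2khz_imaginary_part(self):
        gamma = admittivity(2.0, 109.0, 2e3)
        # hand evaluation of 2*pi*2000*eps0*109
        assert gamma.imag == pytest.approx(1.2127627781914456e-05, rel=1e-12)
        assert gamma.real == 2.0

    def test_imaginary_magnitude_equals_sigma_times_qs_ratio(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            s = 10 ** rng.uniform(-3, 1)
            e = 10 ** rng.uniform(0, 7)
            f = 10 ** rng.uniform(1, 6)
            assert abs(admittivity(s, e, f).imag) == pytest.approx(
                s * qs_ratio(s, e, f), rel=1e-14
            )

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            admittivity(np.nan, 1.0, 1.0)
        with pytest.raises(ValueError):
            admittivity(1.0, np.inf, 1.0)


class TestQsRatio:
    def test_dc_ratio_is_zero(self):
        assert qs_ratio(0.5, 1e6, 0.0) == 0.0

    def test_zero_conductivity_rejected(self):
        with pytest.raises(ValueError):
            qs_ratio(0.0, 100.0, 1e3)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        sigma=st.floats(1e-3, 10.0),
        eps=st.floats(1.0, 1e7),
        f=st.floats(1.0, 4.9e5),
        factor=st.floats(1.01, 10.0),
    )
    def test_strictly_increasing_in_frequency(self, sigma, eps, f, factor):
        assert qs_ratio(sigma, eps, f * factor) > qs_ratio(sigma, eps, f)


class TestTissueProperty:
    def test_knot_validation(self):
        with pytest.raises(ValueError):
            TissueProperty("x", [100.0, 100.0], [1.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            TissueProperty("x", [100.0, 200.0], [1.0, -1.0], [1.0, 1.0])

    def test_interp_exact_at_knots(self):
        prop = default_property("cortical_bone")
        s, e = interp_property(prop, prop.freq_knots)
        assert s == pytest.approx(prop.sigma_knots, rel=1e-12)
        assert e == pytest.approx(prop.eps_knots, rel=1e-12)

    def test_interp_reproduces_power_law(self):
        # a power law is a straight line in the (log f, log value) spline space
        f = np.logspace(2, 5, 13)
        prop = TissueProperty("pl", f, 0.02 * (f / 100) ** 0.31, 1e4 * (f / 100) ** -0.7)
        fq = np.sqrt(f[:-1] * f[1:])  # log-midpoints
        s, e = interp_property(prop, fq)
        assert s == pytest.approx(0.02 * (fq / 100) ** 0.31, rel=1e-9)
        assert e == pytest.approx(1e4 * (fq / 100) ** -0.7, rel=1e-9)

    def test_extrapolation_rejected(self):
        prop = default_property("cerebrospinal_fluid")
        with pytest.raises(ValueError):
            interp_property(prop, 10.0)
        with pytest.raises(ValueError):
            interp_property(prop, 1e7)

    def test_table_round_trip(self, tmp_path):
        prop = default_property("spinal_cord")
        path = tmp_path / "nerve.tsv"
        prop.to_table(path)
        back = TissueProperty.from_table(path, "spinal_cord")
        np.testing.assert_array_equal(back.freq_knots, prop.freq_knots)
        np.testing.assert_array_equal(back.sigma_knots, prop.sigma_knots)
        np.testing.assert_array_equal(back.eps_knots, prop.eps_knots)


class TestNerveScaling:
    def test_identity_when_target_equals_base(self):
        base = default_property("spinal_cord")
        s100, _ = interp_property(base, 100.0)
        scaled = scale_nerve_conductivity(base, s100)
        np.testing.assert_allclose(scaled.sigma_knots, base.sigma_knots, rtol=1e-12)

    def test_doubling_target_doubles_all_knots(self):
        base = default_property("spinal_cord")
        s100, _ = interp_property(base, 100.0)
        scaled = scale_nerve_conductivity(base, 2 * s100)
        np.testing.assert_allclose(scaled.sigma_knots, 2 * base.sigma_knots, rtol=1e-12)
        np.testing.assert_array_equal(scaled.eps_knots, base.eps_knots)

    def test_scale_factor_matches_hand_arithmetic(self):
        # base sigma(100 Hz)=0.0295 and target 1.1 S/m force k ~ 37.29
        f = np.array([100.0, 1e3, 1e4])
        base = TissueProperty("n", f, np.array([0.0295, 0.03, 0.04]), np.ones(3))
        scaled = scale_nerve_conductivity(base, 1.1)
        assert scaled.sigma_knots[0] == pytest.approx(1.1, rel=1e-12)
        assert scaled.sigma_knots[1] / base.sigma_knots[1] == pytest.approx(
            1.1 / 0.0295, rel=1e-12
        )

    def test_nonpositive_target_rejected(self):
        base = default_property("spinal_cord")
        with pytest.raises(ValueError):
            scale_nerve_conductivity(base, 0.0)


class TestPropertyBounds:
    def test_fractional_half_on_known_value(self):
        f = np.array([100.0, 1e3])
        prop = TissueProperty("n", f, np.array([0.0295, 0.0295]), np.array([1.0, 1.0]))
        lo, hi = property_bounds(prop, "fractional", fraction=0.5)
        assert lo.sigma_knots[0] == pytest.approx(0.01475)
        assert hi.sigma_knots[0] == pytest.approx(0.04425)
        assert lo.bound_tag == "lower" and hi.bound_tag == "upper"

    def test_median_log_distance_identity_and_decade(self):
        prop = default_property("cortical_bone")
        lo, hi = property_bounds(prop, "median_log_distance", literature=prop)
        np.testing.assert_allclose(lo.sigma_knots, prop.sigma_knots, rtol=1e-9)
        np.testing.assert_allclose(hi.eps_knots, prop.eps_knots, rtol=1e-9)

        lit = TissueProperty(
            prop.name, prop.freq_knots, prop.sigma_knots * 10, prop.eps_knots * 10
        )
        lo, hi = property_bounds(prop, "median_log_distance", literature=lit)
        np.testing.assert_allclose(hi.sigma_knots, prop.sigma_knots * 10, rtol=1e-9)
        np.testing.assert_allclose(lo.sigma_knots, prop.sigma_knots / 10, rtol=1e-9)

    def test_bounds_bracket_default_at_every_knot(self):
        for tissue in GABRIEL_COLE_COLE:
            prop = default_property(tissue)
            lit = TissueProperty(
                prop.name, prop.freq_knots, prop.sigma_knots * 1.8, prop.eps_knots * 0.6
            )
            for mode, kw in [
                ("fractional", {"fraction": 0.5}),
                ("median_log_distance", {"literature": lit}),
            ]:
                lo, hi = property_bounds(prop, mode, **kw)
                assert np.all(lo.sigma_knots < prop.sigma_knots)
                assert np.all(prop.sigma_knots < hi.sigma_knots)
                assert np.all(lo.eps_knots < prop.eps_knots)
                assert np.all(prop.eps_knots < hi.eps_knots)

    def test_missing_literature_rejected(self):
        prop = default_property("cortical_bone")
        with pytest.raises(ValueError):
            property_bounds(prop, "median_log_distance")
        short = TissueProperty("b", [1e3, 1e4], [1.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            property_bounds(prop, "median_log_distance", literature=short)


class TestAdmittivityTensor:
    def test_isotropic_and_uniaxial_agree_for_equal_eigenvalues(self):
        g = 0.5 + 0.01j
        iso = AdmittivityTensor.isotropic(g)
        uni = AdmittivityTensor.uniaxial(g, g, [0.3, -0.5, 0.81])
        np.testing.assert_allclose(iso.value, uni.value, atol=1e-16)

    def test_uniaxial_eigenstructure(self):
        t = AdmittivityTensor.uniaxial(0.33 + 0.02j, 0.033 + 0.002j, [0, 0, 1])
        assert t.value[2, 2] == pytest.approx(0.33 + 0.02j)
        assert t.value[0, 0] == pytest.approx(0.033 + 0.002j)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            AdmittivityTensor(np.diag([1.0, 1.0, -1.0]).astype(complex))
        with pytest.raises(ValueError):
            AdmittivityTensor.uniaxial(1.0, 0.1, [0, 0, 0])
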