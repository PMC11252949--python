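"""Closed-form signal models: limits, invariants, and quadrature oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

import lacdiff as ld
from lacdiff.exceptions import NumericalError
from lacdiff.models import sphere_bessel_roots, cylinder_bessel_roots


def stick_quadrature(b, D):
    """Independent orientation-average oracle for the stick powder signal."""
    return quad(lambda x: np.exp(-b * D * x * x), 0, 1, epsabs=1e-13, epsrel=1e-13)[0]


class TestStickPowder:
    def test_no_weighting_no_attenuation(self):
        assert ld.stick_powder_signal(0.0, 0.40) == 1.0

    def test_small_bD_taylor_expansion(self):
        # 1 - bD/3 + (bD)^2/10 for bD = 0.01
        assert ld.stick_powder_signal(0.025, 0.40) == pytest.approx(0.9966766666, abs=1e-6)

    def test_matches_quadrature_at_high_b(self):
        # frozen from the quadrature oracle at b=20, D=0.52
        assert ld.stick_powder_signal(20, 0.52) == pytest.approx(0.2748059026617778, abs=1e-8)

    def test_matches_quadrature_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            b = rng.uniform(0.01, 25.0)
            D = rng.uniform(0.05, 1.5)
            assert ld.stick_powder_signal(b, D) == pytest.approx(
                stick_quadrature(b, D), abs=1e-8)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            ld.stick_powder_signal(-1.0, 0.4)
        with pytest.raises(ValueError):
            ld.stick_powder_signal(1.0, 0.0)

    @given(st.floats(0.05, 1.5), st.floats(0.05, 1.5))
    @settings(max_examples=30, deadline=None)
    def test_strictly_decreasing_in_b_and_D(self, D1, D2):
        b = np.linspace(0.0, 25.0, 40)
        s = np.atleast_1d(ld.stick_powder_signal(b, D1))
        assert np.all(np.diff(s) < 0)
        if D2 > D1:
            s2 = np.atleast_1d(ld.stick_powder_signal(b[1:], D2))
            assert np.all(s2 < s[1:])


class TestSphereGPD:
    def test_b_zero(self, scheme):
        assert ld.sphere_gpd_signal(scheme, 0.0, 3.1, 0.40) == 1.0

    def test_fully_restricted_limit(self, scheme):
        # negligible displacement in a 10 nm sphere: no attenuation
        for b in (0.02, 5.0, 20.0):
            assert ld.sphere_gpd_signal(scheme, b, 0.01, 0.40) >= 0.999

    def test_slow_diffusion_limit(self, scheme):
        assert ld.sphere_gpd_signal(scheme, 20.0, 3.1, 1e-6) >= 0.999

    def test_monotone_in_b(self, scheme):
        b = np.linspace(0, 25, 60)
        s = np.atleast_1d(ld.sphere_gpd_signal(scheme, b, 3.1, 0.40))
        assert s[0] == 1.0
        assert np.all(np.diff(s) <= 0)
        assert np.all((s > 0) & (s <= 1))

    def test_long_time_narrow_pulse_limit(self, scheme):
        # at t_d >> r^2/D positions decorrelate: phase variance q^2*2<z^2>
        # with <z^2> = r^2/5, so ln S -> -b r^2 / (5 t_d)
        sch = ld.AcquisitionScheme(b_values=scheme.b_values, t_d=5000.0)
        r, D, b = 2.0, 0.5, 10.0
        expected = np.exp(-b * r**2 / (5 * sch.t_d))
        assert ld.sphere_gpd_signal(sch, b, r, D) == pytest.approx(expected, rel=1e-4)

    def test_invalid_arguments(self, scheme):
        with pytest.raises(ValueError):
            ld.sphere_gpd_signal(scheme, 1.0, -1.0, 0.4)
        with pytest.raises(ValueError):
            ld.sphere_gpd_signal(scheme, 1.0, 3.1, -0.4)

    def test_quasi_free_regime_converges(self, scheme):
        # large sphere, slow diffusion: series needs escalation + tail
        # completion; result must approach the free diffusivity from below
        adc = ld.sphere_apparent_diffusivity(scheme, 12.0, 0.02)
        assert 0 < adc < 0.02

    def test_finite_pulse_reduces_to_narrow_pulse(self, scheme):
        # delta << Delta: Murday-Cotts converges to the narrow-pulse value
        delta = 0.005
        Delta = scheme.t_d + delta / 3.0
        fp = ld.AcquisitionScheme(b_values=scheme.b_values, t_d=scheme.t_d,
                                  delta=delta, Delta=Delta, pulse_model="finite_pulse")
        s_fp = ld.sphere_gpd_signal(fp, 10.0, 3.1, 0.40)
        s_np = ld.sphere_gpd_signal(scheme, 10.0, 3.1, 0.40)
        assert s_fp == pytest.approx(s_np, rel=1e-3)

    def test_finite_pulse_attenuates_less(self, scheme):
        # long pulses average out displacement: weaker attenuation
        fp = ld.AcquisitionScheme(b_values=scheme.b_values, t_d=scheme.t_d,
                                  delta=20.0, Delta=scheme.t_d + 20.0 / 3.0,
                                  pulse_model="finite_pulse")
        assert ld.sphere_gpd_signal(fp, 10.0, 3.1, 0.40) > \
            ld.sphere_gpd_signal(scheme, 10.0, 3.1, 0.40)


class TestCylinderPowder:
    def test_stick_limit(self, scheme):
        for b in (1.0, 5.0, 10.0, 20.0):
            assert ld.cylinder_powder_signal(scheme, b, 0.01, 0.40) == pytest.approx(
                ld.stick_powder_signal(b, 0.40), abs=1e-3)

    def test_b_zero(self, scheme):
        assert ld.cylinder_powder_signal(scheme, 0.0, 1.0, 0.40) == 1.0

    def test_monotone_in_b(self, scheme):
        b = np.linspace(0, 25, 60)
        s = np.atleast_1d(ld.cylinder_powder_signal(scheme, b, 1.0, 0.40))
        assert np.all(np.diff(s) <= 0) and s[0] == 1.0

    def test_thicker_cylinder_attenuates_more(self, scheme):
        # larger radius frees up radial displacement
        s_thin = ld.cylinder_powder_signal(scheme, 10.0, 0.5, 0.40)
        s_thick = ld.cylinder_powder_signal(scheme, 10.0, 3.0, 0.40)
        assert s_thick < s_thin


class TestSticksSpheres:
    def test_pure_component_limits(self, scheme):
        b = 10.0
        assert ld.sticks_spheres_signal(scheme, b, 0.4, 3.1, 0.0) == \
            ld.stick_powder_signal(b, 0.4)
        assert ld.sticks_spheres_signal(scheme, b, 0.4, 3.1, 1.0) == \
            ld.sphere_gpd_signal(scheme, b, 3.1, 0.4)

    def test_mixture_is_arithmetic_mean_at_half(self, scheme):
        b = 10.0
        mix = ld.sticks_spheres_signal(scheme, b, 0.4, 3.1, 0.5)
        mean = 0.5 * (ld.stick_powder_signal(b, 0.4)
                      + ld.sphere_gpd_signal(scheme, b, 3.1, 0.4))
        assert mix == pytest.approx(mean, rel=1e-15)

    @given(st.floats(0.0, 1.0))
    @settings(max_examples=25, deadline=None)
    def test_linear_in_fraction(self, f):
        scheme = ld.default_scheme()
        b = 13.0
        stick = ld.stick_powder_signal(b, 0.4)
        sphere = ld.sphere_gpd_signal(scheme, b, 3.1, 0.4)
        assert ld.sticks_spheres_signal(scheme, b, 0.4, 3.1, f) == pytest.approx(
            f * sphere + (1 - f) * stick, rel=1e-14)

    def test_fraction_out_of_range(self, scheme):
        with pytest.raises(ValueError):
            ld.sticks_spheres_signal(scheme, 1.0, 0.4, 3.1, 1.2)


def test_bessel_roots_match_known_values():
    # first eigenvalues of the sphere (j1'=0) and cylinder (J1'=0) conditions
    assert sphere_bessel_roots(5)[:2] == pytest.approx([2.0815759, 5.9403699], abs=1e-6)
    assert cylinder_bessel_roots(5)[0] == pytest.approx(1.8411838, abs=1e-6)


def test_series_sums_match_moment_identities():
    # sum 1/(x^2(x^2-2)) = 1/10 (sphere), sum 1/(x^2(x^2-1)) = 1/8 (cylinder):
    # the long-time variance of position inside the compartment
    x2 = sphere_bessel_roots(400) ** 2
    assert np.sum(1 / (x2 * (x2 - 2))) == pytest.approx(0.1, abs=1e-6)
    y2 = cylinder_bessel_roots(400) ** 2
    assert np.sum(1 / (y2 * (y2 - 1))) == pytest.approx(0.125, abs=1e-6)
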