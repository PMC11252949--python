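"""Lactate prediction, two-pool fitting, and the biexponential comparator."""

import numpy as np
import pytest

import lacdiff as ld
from lacdiff.fitting import FitOptions
from lacdiff.lactate import two_pool_signal


@pytest.fixture()
def s_intra(scheme, default_micro):
    return ld.predict_intracellular_lactate(
        default_micro, ld.LactateScaling(1.3), scheme)


def lac_curve(b, S, sd=None):
    return ld.AttenuationCurve(metabolite="Lac", subject_id="a1",
                               group="control", b=b, S=S, sd=sd)


class TestPredictIntracellularLactate:
    def test_identity_scaling_reproduces_metabolite_curve(self, scheme, default_micro):
        pred = ld.predict_intracellular_lactate(
            default_micro, ld.LactateScaling(1.0), scheme)
        ref = np.atleast_1d(ld.sticks_spheres_signal(
            scheme, scheme.b_values, 0.40, 3.1, 0.5))
        assert np.allclose(pred.S, ref)

    def test_unit_signal_at_b_zero(self, scheme, default_micro):
        pred = ld.predict_intracellular_lactate(
            default_micro, ld.LactateScaling(1.3), scheme,
            b_grid=np.array([0.0, 5.0, 20.0]))
        assert pred.S[0] == 1.0

    def test_faster_lactate_attenuates_more(self, scheme, default_micro):
        s13 = ld.predict_intracellular_lactate(default_micro, ld.LactateScaling(1.3), scheme)
        s10 = ld.predict_intracellular_lactate(default_micro, ld.LactateScaling(1.0), scheme)
        assert np.all(s13.S < s10.S)

    def test_invalid_scaling_rejected(self, scheme, default_micro):
        with pytest.raises(ValueError):
            ld.predict_intracellular_lactate(default_micro, ld.LactateScaling(0.8), scheme)
        with pytest.raises(ValueError):
            ld.predict_intracellular_lactate(default_micro, ld.LactateScaling(2.5), scheme)


class TestTwoPoolFit:
    def test_pure_intracellular_gives_zero_fraction(self, scheme, s_intra):
        lac = lac_curve(s_intra.b, s_intra.S / s_intra.S[0])
        comp = ld.fit_two_pool(lac, s_intra)
        assert comp.f_extra <= 0.01

    def test_noiseless_recovery(self, scheme, s_intra):
        S = two_pool_signal(s_intra.b, 0.36, 1.3, s_intra.S)
        lac = lac_curve(s_intra.b, S / S[0])
        comp = ld.fit_two_pool(lac, s_intra)
        assert comp.f_extra == pytest.approx(0.36, abs=1e-3)
        assert comp.D_extra == pytest.approx(1.3, abs=1e-3)

    def test_grid_mismatch_rejected(self, scheme, s_intra):
        b = s_intra.b.copy()
        b[3] += 0.5
        lac = lac_curve(b, s_intra.S)
        with pytest.raises(ValueError, match="grid"):
            ld.fit_two_pool(lac, s_intra)

    def test_forward_model_is_convex_combination(self, s_intra):
        b = s_intra.b
        for f, D in [(0.2, 0.8), (0.36, 1.3), (0.9, 2.5)]:
            m = two_pool_signal(b, f, D, s_intra.S)
            lo = np.minimum(np.exp(-b * D), s_intra.S)
            hi = np.maximum(np.exp(-b * D), s_intra.S)
            assert np.all(m >= lo - 1e-12) and np.all(m <= hi + 1e-12)


class TestBiexponential:
    def test_monoexponential_input_is_degenerate(self, scheme):
        b = scheme.b_values
        S = np.exp(-b * 0.5)
        fit = ld.biexponential_fit(lac_curve(b, S / S[0]))
        # either both rates collapse to 0.5 or one fraction vanishes
        assert fit.degenerate or (
            fit.D_fast == pytest.approx(0.5, rel=0.05)
            and fit.D_slow == pytest.approx(0.5, rel=0.05))
        dominant = fit.D_fast if fit.f_fast > 0.5 else fit.D_slow
        assert dominant == pytest.approx(0.5, rel=0.02)

    def test_noiseless_biexponential_recovery(self, scheme):
        b = scheme.b_values
        f, Df, Ds = 0.3, 1.0, 0.1
        S = f * np.exp(-b * Df) + (1 - f) * np.exp(-b * Ds)
        fit = ld.biexponential_fit(lac_curve(b, S / S[0]))
        assert fit.f_fast == pytest.approx(f, abs=1e-6)
        assert fit.D_fast == pytest.approx(Df, abs=1e-6)
        assert fit.D_slow == pytest.approx(Ds, abs=1e-6)
        assert fit.D_fast >= fit.D_slow

    def test_biexponential_nests_monoexponential(self, scheme, s_intra):
        """The monoexponential is the D_fast = D_slow special case, so the
        biexponential cost can never exceed the best monoexponential cost."""
        from scipy.optimize import minimize_scalar

        rng = np.random.default_rng(31)
        b = s_intra.b
        for _ in range(20):
            f = rng.uniform(0.15, 0.5)
            D = rng.uniform(0.8, 2.0)
            S = two_pool_signal(b, f, D, s_intra.S)
            S = np.maximum(S * (1 + 0.01 * rng.standard_normal(b.size)), 1e-6)
            y = S / S[0]
            lac = lac_curve(b, y)
            bi = ld.biexponential_fit(lac)

            def mono_cost(d):
                m = np.exp(-b * d)
                return float(np.sum((m / m[0] - y) ** 2))

            best_mono = minimize_scalar(mono_cost, bounds=(1e-3, 10), method="bounded").fun
            assert bi.fit_cost <= best_mono + 1e-9

    def test_too_few_points_rejected(self):
        b = np.array([0.02, 1.0, 5.0, 20.0])
        with pytest.raises(ValueError):
            ld.biexponential_fit(lac_curve(b, np.exp(-0.3 * (b - b[0]))))
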