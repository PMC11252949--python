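"""Pooling and sticks-and-spheres fitting: oracle examples and recovery."""

import numpy as np
import pytest

import lacdiff as ld
from lacdiff.fitting import FitOptions


def make_curve(metabolite, S, b, subject="a1", group="control", sd=None):
    return ld.AttenuationCurve(metabolite=metabolite, subject_id=subject,
                               group=group, b=b, S=S, sd=sd)


class TestPooling:
    def test_identical_curves_pool_to_themselves(self, scheme):
        b = scheme.b_values
        S = np.exp(-0.1 * b) / np.exp(-0.1 * b[0])
        pooled = ld.pool_intracellular([make_curve("NAA", S, b), make_curve("Ins", S, b)])
        assert np.allclose(pooled.S, S)
        assert np.allclose(pooled.sd, 0.0)
        assert pooled.metabolite == "pooled"

    def test_pointwise_arithmetic_mean(self):
        b = np.array([0.02, 1.0, 5.0, 20.0])
        s1 = np.array([1.0, 0.9, 0.8, 0.6])
        s2 = np.array([1.0, 0.8, 0.6, 0.4])
        pooled = ld.pool_intracellular([make_curve("NAA", s1, b), make_curve("Ins", s2, b)])
        assert pooled.S[2] == pytest.approx(0.7)

    def test_mismatched_grids_rejected(self):
        b1 = np.array([0.02, 1.0, 5.0, 20.0])
        b2 = np.array([0.02, 2.0, 5.0, 20.0])
        S = np.array([1.0, 0.9, 0.8, 0.6])
        with pytest.raises(ValueError, match="mismatch"):
            ld.pool_intracellular([make_curve("NAA", S, b1), make_curve("Ins", S, b2)])

    def test_missing_reference_metabolite_rejected(self, scheme):
        b = scheme.b_values
        S = np.exp(-0.1 * b) / np.exp(-0.1 * b[0])
        with pytest.raises(ValueError, match="Ins"):
            ld.pool_intracellular([make_curve("NAA", S, b)])

    def test_pooling_reduces_noise(self, scheme, default_micro):
        """Averaging NAA and Ins from the same geometry beats either alone."""
        b = scheme.b_values
        truth = np.atleast_1d(ld.sticks_spheres_signal(
            scheme, b, default_micro.D_intra, default_micro.r_soma,
            default_micro.f_sphere))
        truth = truth / truth[0]
        rng = np.random.default_rng(99)
        rmse = lambda s: np.sqrt(np.mean((s / s[0] - truth) ** 2))  # noqa: E731
        r_pool, r_naa, r_ins = [], [], []
        for _ in range(100):
            noisy = [truth * (1 + 0.02 * rng.standard_normal(b.size)) for _ in range(2)]
            curves = [make_curve("NAA", np.maximum(noisy[0], 1e-6), b),
                      make_curve("Ins", np.maximum(noisy[1], 1e-6), b)]
            pooled = ld.pool_intracellular(curves)
            r_pool.append(rmse(pooled.S))
            r_naa.append(rmse(curves[0].S))
            r_ins.append(rmse(curves[1].S))
        # averaging two independent noise draws cuts the expected RMSE by ~1/sqrt(2)
        assert np.mean(r_pool) < 0.8 * np.mean(r_naa)
        assert np.mean(r_pool) < 0.8 * np.mean(r_ins)


class TestMicrostructureFit:
    def test_noiseless_recovery_within_one_percent(self, scheme, noiseless_pooled):
        m = ld.fit_microstructure(noiseless_pooled, scheme)
        assert m.D_intra == pytest.approx(0.40, rel=0.01)
        assert m.r_soma == pytest.approx(3.1, rel=0.01)
        assert m.f_sphere == pytest.approx(0.5, rel=0.01)

    def test_underdetermined_data_rejected(self, scheme):
        b = np.array([0.02, 20.0])
        curve = make_curve("pooled", np.array([1.0, 0.5]), b)
        with pytest.raises(ValueError, match="b-values"):
            ld.fit_microstructure(curve, scheme)

    def test_narrow_b_range_rejected(self, scheme):
        b = np.array([5.0, 6.0, 7.0, 8.0, 9.0])
        curve = make_curve("pooled", np.exp(-0.1 * (b - b[0])), b)
        with pytest.raises(ValueError, match="decade"):
            ld.fit_microstructure(curve, scheme)

    def test_cost_at_optimum_beats_truth_on_noisy_data(self, scheme, default_micro):
        rng = np.random.default_rng(5)
        b = scheme.b_values
        S = np.atleast_1d(ld.sticks_spheres_signal(scheme, b, 0.40, 3.1, 0.5))
        S = S / S[0] * (1 + 0.02 * rng.standard_normal(b.size))
        curve = make_curve("pooled", np.maximum(S, 1e-6), b)
        m = ld.fit_microstructure(curve, scheme)

        def cost(D, r, f):
            model = np.atleast_1d(ld.sticks_spheres_signal(scheme, b, D, r, f))
            model = model / model[0]
            return float(np.sum((model - curve.normalized().S) ** 2))

        assert m.fit_cost <= cost(0.40, 3.1, 0.5) + 1e-12

    def test_refit_is_idempotent(self, scheme):
        m0 = ld.MicrostructureParams(D_intra=0.35, r_soma=4.0, f_sphere=0.6)
        S = np.atleast_1d(ld.sticks_spheres_signal(
            scheme, scheme.b_values, m0.D_intra, m0.r_soma, m0.f_sphere))
        curve = make_curve("pooled", S / S[0], scheme.b_values)
        m1 = ld.fit_microstructure(curve, scheme)
        S1 = np.atleast_1d(ld.sticks_spheres_signal(
            scheme, scheme.b_values, m1.D_intra, m1.r_soma, m1.f_sphere))
        curve1 = make_curve("pooled", S1 / S1[0], scheme.b_values)
        m2 = ld.fit_microstructure(curve1, scheme)
        assert m2.D_intra == pytest.approx(m1.D_intra, abs=1e-6)
        assert m2.r_soma == pytest.approx(m1.r_soma, abs=1e-6)

    def test_fixed_f_sphere_mode(self, scheme, noiseless_pooled):
        m = ld.fit_microstructure(noiseless_pooled, scheme,
                                  FitOptions(fix_f_sphere=0.5))
        assert m.f_sphere == 0.5
        assert m.D_intra == pytest.approx(0.40, rel=0.01)
        assert m.r_soma == pytest.approx(3.1, rel=0.01)

    def test_cylinders_only_geometry_roundtrip(self, scheme):
        S = np.atleast_1d(ld.cylinder_powder_signal(scheme, scheme.b_values, 2.0, 0.45))
        curve = make_curve("pooled", S / S[0], scheme.b_values)
        m = ld.fit_microstructure(curve, scheme, geometry="cylinders")
        assert m.geometry == "cylinders"
        assert m.D_intra == pytest.approx(0.45, rel=0.01)
        assert m.r_soma == pytest.approx(2.0, rel=0.01)

    def test_bootstrap_ci_reported(self, scheme, default_micro):
        rng = np.random.default_rng(17)
        b = scheme.b_values
        S = np.atleast_1d(ld.sticks_spheres_signal(scheme, b, 0.40, 3.1, 0.5))
        S = np.maximum(S / S[0] * (1 + 0.02 * rng.standard_normal(b.size)), 1e-6)
        curve = make_curve("pooled", S, b)
        m = ld.fit_microstructure(
            curve, scheme, FitOptions(n_starts=1, bootstrap_draws=30, seed=3))
        assert m.ci is not None and len(m.ci) == 3
        assert m.ci[0] > 0

    def test_group_level_bias_small(self, scheme):
        """Cohort-level pooled fits show negligible median bias at 2% noise.

        Between-animal jitter is off so per-cohort truth is exact; the
        statistic is the median signed error across cohorts.
        """
        errs = []
        for s in range(100):
            cfg = ld.SyntheticCohortConfig(seed=1000 + s, between_animal_cv=0.0)
            curves = ld.generate_cohort(cfg)
            pooled = ld.pool_intracellular(
                [c for c in curves if c.metabolite in ("NAA", "Ins")])
            m = ld.fit_microstructure(pooled, scheme, FitOptions(n_starts=2))
            errs.append((m.D_intra - 0.40, m.r_soma - 3.1))
        errs = np.array(errs)
        assert abs(np.median(errs[:, 0])) < 0.02
        assert abs(np.median(errs[:, 1])) < 0.4
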