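"""Model fitting: recovery, identifiability guards, bootstrap errors."""

import numpy as np
import pytest

from stackfit.curves import ForceExtensionCurve
from stackfit.elasticity import StackedElasticParams, UnstackedElasticParams, tc_extension
from stackfit.extraction import average_molecules
from stackfit.fitting import (
    FitConfig,
    bootstrap_errors,
    fit_all_procedure2,
    fit_gamma2,
    fit_salt_laws,
    fit_st,
    fit_tc,
)
from stackfit.gamma2 import Gamma2Params, annotate_tracks, fec_mixed, rescale_purine_extension
from stackfit.stmodel import ChainSpec, StackingParams, fec_finite
from stackfit.synthetic import NoiseModel, gen_fec

FAST = FitConfig(multistart=1, seed=0)


def _loop_curve(N, sp, eU, eS, f_grid, salt=1.0):
    c = fec_finite(ChainSpec(N), sp, eU, eS, f_grid, per_base=True)
    c.N_loop = N
    c.salt_M = salt
    return c


class TestFitTc:
    def test_noise_free_exact_recovery(self, f_grid):
        truth = UnstackedElasticParams(l_U=0.652, a=0.65, delta0=0.40, delta_slope=0.0109)
        curves = []
        for C in (0.01, 0.05, 0.1, 0.5, 1.0):
            eU = truth.at_salt(C)
            curves.append(ForceExtensionCurve(f_grid, tc_extension(eU, f_grid),
                                              per_base=True, salt_M=C))
        res = fit_tc(curves, FAST)
        assert res.params["l_U"] == pytest.approx(0.652, abs=1e-4)
        assert res.params["a"] == pytest.approx(0.65, abs=1e-3)
        assert res.params["delta0"] == pytest.approx(0.40, abs=1e-3)
        assert res.params["delta_slope"] == pytest.approx(0.0109, abs=1e-4)
        assert res.residual_sum_sq < 1e-8

    def test_noisy_recovery_within_three_se(self, f_grid):
        truth = UnstackedElasticParams()
        curves = []
        for C in (0.01, 0.05, 0.1, 0.5, 1.0):
            eU = truth.at_salt(C)
            mean = ForceExtensionCurve(f_grid, tc_extension(eU, f_grid), per_base=True,
                                       N=75, N_loop=75, salt_M=C)
            reps = [gen_fec(mean, NoiseModel(), seed=int(1000 * C) + k) for k in range(5)]
            curves.append(average_molecules(reps, f_grid))
        res = fit_tc(curves, FitConfig(multistart=2, seed=3))
        se = bootstrap_errors(lambda cs: fit_tc(cs, FAST), curves, n=30, seed=4)
        for name, true_val in (("l_U", 0.652), ("a", 0.65), ("delta0", 0.40)):
            assert abs(res.params[name] - true_val) < 3 * max(se[name], 1e-4)

    def test_single_salt_freezes_radius_law(self, f_grid, eU):
        curve = ForceExtensionCurve(f_grid, tc_extension(eU, f_grid), per_base=True, salt_M=1.0)
        with pytest.warns(UserWarning, match="jointly identified"):
            res = fit_tc([curve], FAST)
        assert res.params["delta0"] == 0.40  # frozen at initial value

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fit_tc([], FAST)


class TestFitSt:
    def test_noise_free_exact_recovery(self, eU, eS, poly_da, f_grid):
        curves = [_loop_curve(N, poly_da, eU, eS, f_grid) for N in (20, 40)]
        res = fit_st(curves, eU, FAST)
        assert res.params["eps_ST"] == pytest.approx(0.14, abs=1e-5)
        assert res.params["gamma_ST"] == pytest.approx(0.86, abs=1e-4)
        assert res.params["l_S"] == pytest.approx(0.386, abs=1e-4)
        assert res.params["p_S"] == pytest.approx(9.9, abs=1e-2)

    def test_curve_order_invariance(self, eU, eS, poly_da, f_grid):
        curves = [_loop_curve(N, poly_da, eU, eS, f_grid) for N in (20, 40)]
        noisy = [gen_fec(c, NoiseModel(), seed=i) for i, c in enumerate(curves)]
        a = fit_st(noisy, eU, FAST)
        b = fit_st(noisy[::-1], eU, FAST)
        for k in a.params:
            assert a.params[k] == pytest.approx(b.params[k], rel=1e-5)

    def test_single_length_widens_gamma_uncertainty(self, eU, eS, poly_da, f_grid):
        """Cooperativity needs finite-size leverage: one length is weakly
        identifying, two lengths pin gamma down."""
        def make(Ns, seed0):
            out = []
            for N in Ns:
                mean = _loop_curve(N, poly_da, eU, eS, f_grid)
                reps = [gen_fec(mean, NoiseModel(), seed=seed0 + N + k) for k in range(3)]
                out.append(average_molecules(reps, f_grid))
            return out

        one = make([20], 50)
        two = make([20, 40], 50)
        se_one = bootstrap_errors(lambda cs: fit_st(cs, eU, FAST), one, n=12, seed=6)
        se_two = bootstrap_errors(lambda cs: fit_st(cs, eU, FAST), two, n=12, seed=6)
        assert se_one["gamma_ST"] > 2 * se_two["gamma_ST"]

    def test_misspecified_elasticity_leaves_residual_trend(self, eU, eS, poly_da, f_grid):
        # fitting stacking-model data with the unstacked model alone leaves
        # strongly autocorrelated residuals
        curve = _loop_curve(40, poly_da, eU, eS, f_grid)
        res = fit_tc([ForceExtensionCurve(curve.f, curve.x, per_base=True, salt_M=1.0)],
                     FitConfig(multistart=1, seed=0))
        assert res.per_curve_autocorr[0] > 0.9


@pytest.fixture(scope="module")
def salt_curves(eU, eS):
    f_grid = np.arange(5.0, 45.01, 1.0)
    truth = {"m_eps": 0.004, "m_gamma": 0.05, "p_inf": 9.9, "m_p": 0.3}
    curves = []
    for C in (0.01, 0.05, 0.1, 0.5, 1.0):
        sp = StackingParams(0.14 + truth["m_eps"] * np.log(C),
                            0.86 + truth["m_gamma"] * np.log(C))
        eS_C = StackedElasticParams(l_S=0.386, p_inf=truth["p_inf"],
                                    m_p=truth["m_p"], C=C)
        curves.append(_loop_curve(40, sp, eU.at_salt(C), eS_C, f_grid, salt=C))
    return curves, truth


class TestFitSaltLaws:
    def test_noise_free_slopes_recovered(self, salt_curves, eU):
        curves, truth = salt_curves
        res = fit_salt_laws(curves, eU, anchors={"eps_ST": 0.14, "gamma_ST": 0.86},
                            config=FAST)
        assert res.params["m_eps"] == pytest.approx(truth["m_eps"], abs=2e-4)
        assert res.params["m_gamma"] == pytest.approx(truth["m_gamma"], abs=2e-3)
        assert res.params["p_inf"] == pytest.approx(truth["p_inf"], abs=0.1)
        assert res.params["m_p"] == pytest.approx(truth["m_p"], abs=0.1)

    def test_too_few_salts_rejected(self, salt_curves, eU):
        curves, _ = salt_curves
        with pytest.raises(ValueError, match="salt conditions"):
            fit_salt_laws(curves[:2], eU, anchors={"eps_ST": 0.14, "gamma_ST": 0.86})

    def test_missing_anchor_rejected(self, salt_curves, eU):
        curves, _ = salt_curves
        with pytest.raises(ValueError, match="anchor"):
            fit_salt_laws(curves, eU, anchors={"eps_ST": 0.14})


@pytest.fixture(scope="module")
def mixed_setup(eU):
    ann = annotate_tracks("T" + "A" * 9 + "T" + "A" * 6 + "T" + "A" * 8 + "T").tile(4)
    laws = {"eps_ST": 0.14, "m_eps": 0.004, "gamma_ST": 0.86, "m_gamma": 0.05}
    p_law = {"p_inf": 9.9, "m_p": 0.3}
    f_grid = np.arange(5.0, 45.01, 1.0)

    def make(g2_0, m_g2, salts):
        curves = []
        for C in salts:
            sp = StackingParams(laws["eps_ST"] + laws["m_eps"] * np.log(C),
                                laws["gamma_ST"] + laws["m_gamma"] * np.log(C))
            g2 = g2_0 + m_g2 * np.log(C)
            eS_C = StackedElasticParams(l_S=0.386, p_inf=p_law["p_inf"],
                                        m_p=p_law["m_p"], C=C)
            eU_C = eU.at_salt(C)
            mix = fec_mixed(ann, Gamma2Params(sp, g2), eU_C, eS_C, f_grid)
            x_b = rescale_purine_extension(mix.x, ann, eU_C, f_grid)
            curves.append(ForceExtensionCurve(f_grid, x_b, per_base=True, salt_M=C))
        return curves

    return ann, laws, p_law, make


class TestFitGamma2:
    def test_degenerate_gamma2_equals_gamma_st(self, mixed_setup, eU):
        ann, laws, p_law, make = mixed_setup
        curves = make(0.86, 0.05, (0.01, 0.1, 1.0))
        res = fit_gamma2(curves, ann, eU, laws, p_law, FAST)
        assert res.params["gamma2_0"] == pytest.approx(0.86, abs=0.01)
        assert res.params["m_gamma2"] == pytest.approx(0.05, abs=0.01)

    def test_published_law_recovery_with_noise(self, mixed_setup, eU):
        ann, laws, p_law, make = mixed_setup
        clean = make(0.5, 0.08, (0.01, 0.1, 1.0))
        noisy = []
        for i, c in enumerate(clean):
            c.N_loop = ann.n_stackable
            noisy.append(gen_fec(c, NoiseModel(), seed=80 + i))
        res = fit_gamma2(noisy, ann, eU, laws, p_law, FAST)
        se = bootstrap_errors(lambda cs: fit_gamma2(cs, ann, eU, laws, p_law, FAST),
                              noisy, n=15, seed=8)
        assert abs(res.params["gamma2_0"] - 0.5) < 3 * max(se["gamma2_0"], 0.01)
        assert abs(res.params["m_gamma2"] - 0.08) < 3 * max(se["m_gamma2"], 0.005)

    def test_shared_slope_variant_consistent(self, mixed_setup, eU):
        ann, laws, p_law, make = mixed_setup
        curves = make(0.5, 0.05, (0.01, 0.1, 1.0))
        free = fit_gamma2(curves, ann, eU, laws, p_law, FAST)
        shared = fit_gamma2(curves, ann, eU, laws, p_law, FAST, shared_slope=0.05)
        assert shared.params["m_gamma2"] == 0.05
        assert shared.params["gamma2_0"] == pytest.approx(free.params["gamma2_0"], abs=0.02)


class TestProcedure2:
    def test_noise_free_global_recovery(self, eU):
        f_grid = np.arange(5.0, 45.01, 1.0)
        ann = annotate_tracks("T" + "A" * 9 + "T" + "A" * 6 + "T" + "A" * 8 + "T").tile(4)
        truth = dict(eps0=0.14, m_eps=0.004, gamma0=0.86, m_gamma=0.05,
                     gamma2_0=0.5, m_gamma2=0.08, l_S=0.386, p_inf=9.9, m_p=0.3)
        pure, mixed = [], []
        for C in (0.01, 0.1, 1.0):
            sp = StackingParams(truth["eps0"] + truth["m_eps"] * np.log(C),
                                truth["gamma0"] + truth["m_gamma"] * np.log(C))
            eS_C = StackedElasticParams(l_S=truth["l_S"], p_inf=truth["p_inf"],
                                        m_p=truth["m_p"], C=C)
            eU_C = eU.at_salt(C)
            for N in (20, 40):
                pure.append(_loop_curve(N, sp, eU_C, eS_C, f_grid, salt=C))
            g2 = truth["gamma2_0"] + truth["m_gamma2"] * np.log(C)
            mix = fec_mixed(ann, Gamma2Params(sp, g2), eU_C, eS_C, f_grid)
            x_b = rescale_purine_extension(mix.x, ann, eU_C, f_grid)
            mixed.append(ForceExtensionCurve(f_grid, x_b, per_base=True, salt_M=C))
        res = fit_all_procedure2(pure, mixed, ann, eU,
                                 FitConfig(multistart=1, seed=0), init=dict(truth))
        for k, v in truth.items():
            assert res.params[k] == pytest.approx(v, abs=max(0.02 * abs(v), 2e-3)), k


class TestBootstrap:
    def _linear_fit(self, curves):
        # one-parameter slope fit through the origin, closed-form oracle
        from stackfit.fitting import FitResult

        c = curves[0]
        w = 1.0 if c.se is None else 1.0 / c.se**2
        slope = float(np.sum(w * c.f * c.x) / np.sum(w * c.f**2))
        return FitResult(params={"slope": slope})

    def test_linear_toy_matches_analytic_se(self):
        rng = np.random.default_rng(21)
        f = np.linspace(1, 40, 120)
        sigma = 0.5
        x = 0.3 * f + rng.normal(0, sigma, f.size)
        curve = ForceExtensionCurve(f, x)
        se = bootstrap_errors(self._linear_fit, [curve], n=400, seed=3)
        analytic = sigma / np.sqrt(np.sum(f**2))
        assert se["slope"] == pytest.approx(analytic, rel=0.15)

    def test_zero_noise_zero_se(self):
        f = np.linspace(1, 40, 60)
        curve = ForceExtensionCurve(f, 0.3 * f)
        se = bootstrap_errors(self._linear_fit, [curve], n=50, seed=1)
        assert se["slope"] < 1e-12

    def test_seed_determinism(self):
        rng = np.random.default_rng(5)
        f = np.linspace(1, 40, 60)
        curve = ForceExtensionCurve(f, 0.3 * f + rng.normal(0, 0.2, f.size))
        a = bootstrap_errors(self._linear_fit, [curve], n=40, seed=9)
        b = bootstrap_errors(self._linear_fit, [curve], n=40, seed=9)
        assert a == b

    def test_molecule_resampling_unit(self):
        rng = np.random.default_rng(6)
        f = np.linspace(1, 40, 30)
        curves = [ForceExtensionCurve(f, 0.3 * f + rng.normal(0, 0.2, f.size))
                  for _ in range(6)]

        def fit_many(cs):
            from stackfit.fitting import FitResult

            num = sum(np.sum(c.f * c.x) for c in cs)
            den = sum(np.sum(c.f**2) for c in cs)
            return FitResult(params={"slope": float(num / den)})

        se = bootstrap_errors(fit_many, curves, n=60, seed=2, unit="molecules")
        assert 0 < se["slope"] < 0.01
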