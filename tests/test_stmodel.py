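"""Transfer-matrix thermodynamics of the stacking chain and its closed forms."""

import numpy as np
import pytest

from stackfit.constants import DEFAULT_CONSTANTS, KCAL_PER_MOL_TO_PN_NM
from stackfit.elasticity import (
    StackedElasticParams,
    UnstackedElasticParams,
    tc_extension,
    tc_stretch_work,
    wlc_extension,
    wlc_stretch_work,
)
from stackfit.stmodel import (
    ChainSpec,
    StackingParams,
    correlation_length,
    delta_g0,
    enumerate_oracle,
    f_max,
    fec_finite,
    fec_infinite,
    free_energy_finite,
    stacked_fraction,
    xi_max,
    _finite_logZ_meanNS,
)

KT = DEFAULT_CONSTANTS.kT_kcal_mol


def _random_params(rng):
    return (
        StackingParams(eps_ST=rng.uniform(0.0, 0.4), gamma_ST=rng.uniform(0.0, 1.5)),
        UnstackedElasticParams(C=rng.uniform(0.02, 1.0)),
        StackedElasticParams(p_inf=rng.uniform(3.0, 20.0), C=1.0),
    )


class TestHandEnumeration:
    def test_single_base_two_boundary_bonds(self, eU, eS):
        sp = StackingParams(0.0, 0.86)
        bg = sp.beta_gamma
        Z_hand = np.exp(2 * bg) + np.exp(-2 * bg)
        G = free_energy_finite(ChainSpec(1), sp, eU, eS, 0.0)
        assert G == pytest.approx(-KT * np.log(Z_hand), rel=1e-12)
        phi = stacked_fraction(ChainSpec(1), sp, eU, eS, 0.0)
        assert phi == pytest.approx(np.exp(-2 * bg) / Z_hand, rel=1e-12)

    def test_two_bases(self, eU, eS):
        sp = StackingParams(0.0, 0.86)
        bg = sp.beta_gamma
        Z_hand = np.exp(3 * bg) + 3 * np.exp(-bg)
        G = free_energy_finite(ChainSpec(2), sp, eU, eS, 0.0)
        assert G == pytest.approx(-KT * np.log(Z_hand), rel=1e-12)
        # <N_S> = (2 + 1 + 1) e^{-bg} / Z over states SS, SU, US
        phi = stacked_fraction(ChainSpec(2), sp, eU, eS, 0.0)
        assert phi == pytest.approx(2 * np.exp(-bg) / Z_hand, rel=1e-12)

    def test_gamma_zero_factorizes(self, eU, eS):
        sp = StackingParams(0.2, 0.0)
        f = 8.0
        const = sp.constants
        beta = const.beta_pN_nm
        bS = beta * (0.2 * KCAL_PER_MOL_TO_PN_NM + wlc_stretch_work(eS, f, const))
        bU = beta * tc_stretch_work(eU, f, const)
        for N in (1, 3, 7):
            G = free_energy_finite(ChainSpec(N), sp, eU, eS, f)
            G_hand = -KT * N * np.log(np.exp(bS) + np.exp(bU))
            assert G == pytest.approx(G_hand, rel=1e-12)

    def test_gamma_zero_symmetric_half_stacked(self, eU, eS):
        phi = stacked_fraction(ChainSpec(10), StackingParams(0.0, 0.0), eU, eS, 0.0)
        assert phi == pytest.approx(0.5, rel=1e-12)


class TestOracleEquivalence:
    @pytest.mark.parametrize("N", [1, 2, 5, 9, 14])
    def test_transfer_matrix_matches_enumeration(self, N, eU, eS):
        rng = np.random.default_rng(42 + N)
        for _ in range(6):
            sp, eU_r, eS_r = _random_params(rng)
            f = rng.uniform(0.0, 45.0)
            _, mean_NS_enum, _, info = enumerate_oracle(ChainSpec(N), sp, eU_r, eS_r, f)
            logZ, mean_NS = _finite_logZ_meanNS(ChainSpec(N), sp, eU_r, eS_r, f)
            assert logZ[0] == pytest.approx(info["logZ"], rel=1e-10, abs=1e-10)
            assert mean_NS[0] == pytest.approx(mean_NS_enum, rel=1e-10, abs=1e-12)

    def test_enumeration_refuses_large_chain(self, eU, eS, poly_da):
        with pytest.raises(ValueError):
            enumerate_oracle(ChainSpec(17), poly_da, eU, eS, 1.0)


class TestThermodynamicConsistency:
    def test_extension_equals_minus_dG_df(self, eU, eS, poly_da, f_grid):
        chain = ChainSpec(20)
        fec = fec_finite(chain, poly_da, eU, eS, f_grid)
        h = 1e-3
        Gp = free_energy_finite(chain, poly_da, eU, eS, f_grid + h)
        Gm = free_energy_finite(chain, poly_da, eU, eS, f_grid - h)
        X_num = -(Gp - Gm) / (2 * h) * KCAL_PER_MOL_TO_PN_NM
        assert np.max(np.abs(X_num - fec.x) / fec.x) < 1e-5

    def test_no_overflow_long_chain_high_cooperativity(self, eU, eS):
        G = free_energy_finite(ChainSpec(10_000), StackingParams(0.0, 2.0), eU, eS, 0.0)
        assert np.isfinite(G)

    def test_high_force_fully_unstacked(self, eU, eS, poly_da):
        fec = fec_finite(ChainSpec(20), poly_da, eU, eS, np.array([45.0]), per_base=True)
        assert fec.x[0] == pytest.approx(tc_extension(eU, 45.0), rel=1e-3)

    def test_strong_stacking_zero_force_all_stacked(self, eU, eS):
        sp = StackingParams(5.0, 0.86)
        phi = stacked_fraction(ChainSpec(20), sp, eU, eS, 0.0)
        assert phi > 0.999

    def test_stacked_fraction_decreasing_in_force_increasing_in_N(self, eU, eS, poly_da):
        f = 12.0
        phi20 = stacked_fraction(ChainSpec(20), poly_da, eU, eS, f)
        phi40 = stacked_fraction(ChainSpec(40), poly_da, eU, eS, f)
        assert phi40 > phi20
        phis = stacked_fraction(ChainSpec(40), poly_da, eU, eS, np.array([5.0, 15.0, 30.0]))
        assert phis[0] > phis[1] > phis[2]


class TestInfiniteChain:
    def test_gamma_zero_independent_base_average(self, eU, eS):
        sp = StackingParams(0.12, 0.0)
        f = np.array([10.0, 20.0])
        const = sp.constants
        beta = const.beta_pN_nm
        A = 0.5 * (
            sp.eps_ST * KCAL_PER_MOL_TO_PN_NM
            + wlc_stretch_work(eS, f, const)
            - tc_stretch_work(eU, f, const)
        )
        w = np.exp(beta * A)
        xS, xU = wlc_extension(eS, f, const), tc_extension(eU, f, const)
        expected = (xS * w + xU / w) / (w + 1 / w)
        fec = fec_infinite(sp, eU, eS, f)
        assert np.allclose(fec.x, expected, rtol=1e-10)

    def test_finite_size_convergence(self, eU, eS, poly_da):
        f = np.array([15.0, 15.5])
        xi = fec_infinite(poly_da, eU, eS, f).x
        gaps = []
        for N in (500, 4000, 40_000):
            xN = fec_finite(ChainSpec(N), poly_da, eU, eS, f, per_base=True).x
            gaps.append(np.max(np.abs(xN - xi)))
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[1] < 1e-3 and gaps[2] < 1e-4

    def test_finite_size_ordering_below_shoulder(self, eU, eS, poly_da):
        # shorter chains stack less: larger extension below the transition
        f = np.array([12.0])
        xs = [fec_finite(ChainSpec(N), poly_da, eU, eS, f, per_base=True).x[0]
              for N in (10, 20, 40)]
        x_inf = fec_infinite(poly_da, eU, eS, f).x[0]
        assert xs[0] > xs[1] > xs[2] > x_inf

    def test_shoulder_inflection_between_10_and_25_pN(self, eU, eS, poly_da):
        f = np.arange(5.0, 35.0, 0.25)
        x = fec_infinite(poly_da, eU, eS, f).x
        curv = np.gradient(np.gradient(x, f), f)
        sign_changes = f[1:][np.diff(np.sign(curv)) != 0]
        assert np.any((sign_changes > 10) & (sign_changes < 25))


class TestDeltaG0:
    def test_poly_da_and_dgda_printed_values(self, poly_da, poly_dgda):
        assert delta_g0(poly_da) == pytest.approx(0.14, abs=0.03)
        assert delta_g0(poly_dgda) == pytest.approx(0.07, abs=0.03)

    def test_infinite_cooperativity_limit(self):
        assert delta_g0(StackingParams(0.23, 50.0)) == pytest.approx(0.23, rel=1e-9)

    def test_zero_eps_closed_form(self):
        sp = StackingParams(0.0, 0.86)
        expected = KT * np.log(1 + np.exp(-2 * sp.beta_gamma))
        assert delta_g0(sp) == pytest.approx(expected, rel=1e-12)

    def test_approaches_eps_exponentially_in_gamma(self):
        # rigorous sandwich: eps <= DG0 <= eps + kT e^{-4bg} e^{-h}/(2 sinh h)
        # from sqrt(sinh^2 h + d) <= sinh h + d/(2 sinh h) and ln(1+x) <= x
        for eps, gamma in [(0.14, 0.86), (0.02, 0.67), (0.18, 0.5), (0.3, 1.2)]:
            sp = StackingParams(eps, gamma)
            h = sp.beta_eps / 2.0
            bound = KT * np.exp(-4 * sp.beta_gamma) * np.exp(-h) / (2 * np.sinh(h))
            assert eps - 1e-12 <= delta_g0(sp) <= eps + bound

    def test_lower_bound_half_eps(self):
        for gamma in (0.0, 0.2, 1.0):
            assert delta_g0(StackingParams(0.2, gamma)) >= 0.1 - 1e-12


class TestCorrelationLength:
    def test_zero_force_poly_da_is_4_bases(self, poly_da, eU, eS):
        assert correlation_length(poly_da, eU, eS, 0.0) == pytest.approx(4.0, abs=0.5)

    def test_gamma_zero_vanishes(self, eU, eS):
        assert correlation_length(StackingParams(0.1, 0.0), eU, eS, 10.0) == 0.0

    def test_matches_eigenvalue_ratio(self, poly_da, eU, eS):
        # independent oracle: eigendecomposition of the symmetrized 2x2 matrix
        const = poly_da.constants
        beta = const.beta_pN_nm
        for f in (0.0, 10.0, 18.0, 30.0):
            bA = beta * 0.5 * (
                poly_da.eps_ST * KCAL_PER_MOL_TO_PN_NM
                + wlc_stretch_work(eS, f, const)
                - tc_stretch_work(eU, f, const)
            )
            g = poly_da.beta_gamma
            T = np.array(
                [
                    [np.exp(g + bA), np.exp(-g)],
                    [np.exp(-g), np.exp(g - bA)],
                ]
            )
            lam = np.sort(np.abs(np.linalg.eigvals(T)))[::-1]
            xi_eig = -1.0 / np.log(lam[1] / lam[0])
            assert correlation_length(poly_da, eU, eS, f) == pytest.approx(xi_eig, rel=1e-10)

    def test_single_global_maximum_then_decay(self, poly_da, eU, eS):
        # xi depends on force only through |A(f)|; the global maximum sits at
        # the single zero of A and xi decays monotonically past it.  (Below
        # the peak xi is not monotone: the stiff stacked state stretches more
        # easily than the unstacked one at low force, so |A| first grows.)
        f = np.linspace(0.0, 60.0, 400)
        xi = correlation_length(poly_da, eU, eS, f)
        k = np.argmax(xi)
        assert xi[k] == pytest.approx(xi_max(poly_da), rel=1e-3)
        assert np.all(np.diff(xi[k:]) < 0)
        assert correlation_length(poly_da, eU, eS, 150.0) < 0.2


class TestXiMaxAndFMax:
    def test_closed_form_matches_numerical_max(self, poly_da, eU, eS):
        f = np.linspace(0.01, 60.0, 12_000)
        xi_num = correlation_length(poly_da, eU, eS, f).max()
        assert xi_max(poly_da) == pytest.approx(xi_num, rel=1e-6)

    def test_printed_values(self, poly_da, poly_dgda):
        assert xi_max(poly_dgda) == pytest.approx(5.0, abs=0.5)
        assert 9.0 <= xi_max(poly_da) <= 10.0

    def test_small_gamma_limit(self):
        assert xi_max(StackingParams(0.1, 1e-3)) < 0.2
        with pytest.raises(ValueError):
            xi_max(StackingParams(0.1, 0.0))

    def test_fmax_poly_da_near_18pN(self, poly_da, eU, eS):
        assert f_max(poly_da, eU, eS) == pytest.approx(18.0, abs=2.0)

    def test_fmax_is_argmax_of_xi(self, poly_da, eU, eS):
        f = np.linspace(0.01, 60.0, 12_000)
        xi = correlation_length(poly_da, eU, eS, f)
        assert f_max(poly_da, eU, eS) == pytest.approx(f[np.argmax(xi)], abs=0.1)

    def test_zero_eps_transition_at_origin(self, eU, eS):
        assert f_max(StackingParams(0.0, 0.86), eU, eS) == 0.0

    def test_no_transition_raises(self, eU, eS):
        with pytest.raises(ValueError, match="no stacking-unstacking transition"):
            f_max(StackingParams(10.0, 0.86), eU, eS)
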