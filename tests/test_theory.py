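"""Scaling theory: closed forms vs quadrature, crossover scales, fixed points."""

import mpmath as mp
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, optimize

from cmpnet import theory as th
from cmpnet.theory import TheoryParams


P35 = TheoryParams(3.5, 3)
P32 = TheoryParams(3.2, 3)


def pdf(k, gamma, kmin):
    return (gamma - 1) * kmin ** (gamma - 1) * k ** (-gamma)


def quad_nonisolated(ka, params):
    """Defining integral of N_NI/N by high-precision adaptive quadrature."""
    g, kmin = params.gamma, params.kmin
    kc = float(th.kc(ka, params))
    with mp.workdps(35):
        gm, km, kcm = mp.mpf(g), mp.mpf(kmin), mp.mpf(kc)
        val = mp.quad(
            lambda k: (gm - 1) * km ** (gm - 1) * k**-gm * (1 - mp.e ** (-k / kcm)),
            [ka, 10 * ka, 100 * ka, mp.inf],
        )
    return float(val)


def quad_isolated_r2(ka, params):
    g, kmin = params.gamma, params.kmin
    kc = float(th.kc(ka, params))
    with mp.workdps(35):
        gm, km, kcm = mp.mpf(g), mp.mpf(kmin), mp.mpf(kc)
        val = mp.quad(
            lambda k: (gm - 1) * km ** (gm - 1) * k**-gm * mp.e ** (-k / kcm),
            [2 * ka, 10 * ka, mp.inf],
        )
    return float(val)


class TestElementaryScales:
    def test_k0_star_printed_anchors(self):
        assert th.k0_star(P32) == pytest.approx(729, rel=1e-9)
        assert th.k0_star(P35) == pytest.approx(27, rel=1e-12)
        with pytest.raises(ValueError):
            th.k0_star(TheoryParams(2.8, 3))

    def test_k0_star_equals_bisection_root(self):
        # kc(k) = k solved independently
        for params in (P32, P35, TheoryParams(4.0, 3), TheoryParams(5.0, 2)):
            root = optimize.brentq(
                lambda k: float(th.kc(k, params)) - k,
                params.kmin + 1e-9, 1e9, xtol=1e-12, rtol=1e-14,
            )
            assert th.k0_star(params) == pytest.approx(root, rel=1e-9)

    def test_kc_at_kmin_and_inverse_relation(self):
        assert float(th.kc(3, P35)) == 1.0
        assert float(th.kc(27, P35)) == pytest.approx(27.0)

    def test_active_fraction_values(self):
        assert float(th.active_fraction(3, P35)) == 1.0
        assert float(th.active_fraction(27, P35)) == pytest.approx(
            9**-2.5, rel=1e-12
        )
        with pytest.raises(ValueError):
            th.active_fraction(2, P35)

    def test_mean_active_neighbors_quadrature_and_monotonicity(self):
        # degree-weighted mean over active nodes of k * Pa, by quadrature
        for params in (TheoryParams(2.5, 3), P35):
            g, kmin = params.gamma, params.kmin
            for ka in (5.0, 50.0):
                pa = float(th.prob_active_neighbor(ka, params))
                with mp.workdps(30):
                    gm, km = mp.mpf(g), mp.mpf(kmin)
                    num = float(mp.quad(
                        lambda k: (gm - 1) * km ** (gm - 1) * k ** (1 - gm) * pa,
                        [ka, 100 * ka, mp.inf],
                    ))
                den = float(th.active_fraction(ka, params))
                assert th.mean_active_neighbors(ka, params) == pytest.approx(
                    num / den, rel=1e-8
                )
        # gamma < 3 grows with ka, gamma > 3 decays
        assert th.mean_active_neighbors(100, TheoryParams(2.5, 3)) > \
            th.mean_active_neighbors(10, TheoryParams(2.5, 3))
        assert th.mean_active_neighbors(100, P35) < th.mean_active_neighbors(10, P35)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    gamma=st.floats(2.1, 6.0),
    kmin=st.integers(1, 5),
    ratio=st.floats(1.0, 1e3),
)
def test_kc_times_pa_is_one(gamma, kmin, ratio):
    params = TheoryParams(gamma, kmin)
    ka = kmin * ratio
    assert float(th.kc(ka, params)) * float(
        th.prob_active_neighbor(ka, params)
    ) == pytest.approx(1.0, rel=1e-12)


class TestIncompleteGamma:
    @pytest.mark.parametrize("a", [-0.3, -1.5, -2.2, -2.5, -3.0, -4.0])
    @pytest.mark.parametrize("x", [0.05, 0.5, 2.0, 8.0])
    def test_against_mpmath(self, a, x):
        ref = float(mp.gammainc(a, x, mp.inf))
        assert th.upper_incomplete_gamma(a, x) == pytest.approx(ref, rel=1e-9)

    def test_positive_argument_passthrough(self):
        assert th.upper_incomplete_gamma(2.5, 1.3) == pytest.approx(
            float(mp.gammainc(2.5, 1.3, mp.inf)), rel=1e-12
        )


class TestClosedFormsVsQuadrature:
    @pytest.mark.parametrize("gamma", [3.2, 3.5, 4.0, 5.0])
    def test_nonisolated_and_isolated(self, gamma):
        params = TheoryParams(gamma, 3)
        for ratio in (1, 2, 5, 10, 50, 100, 1000):
            ka = 3.0 * ratio
            q1 = quad_nonisolated(ka, params)
            assert th.f_nonisolated(ka, params) == pytest.approx(q1, rel=1e-6)
            q2 = quad_isolated_r2(ka, params)
            assert th.f_isolated_r2(ka, params) == pytest.approx(q2, rel=1e-6)

    def test_kc_infinite_limits(self):
        # Pa -> 0 (huge kc): no active neighbours, and all isolated nodes of
        # degree >= 2 ka keep range >= 2
        params = TheoryParams(3.5, 3)
        big = TheoryParams(3.5, 3)
        ka = 10.0
        # emulate kc -> infinity by evaluating the defining integrals directly
        val, _ = integrate.quad(lambda k: pdf(k, 3.5, 3), 2 * ka, np.inf)
        assert val == pytest.approx((2 * ka / 3) ** (1 - 3.5), rel=1e-8)

    def test_large_ka_asymptotics(self):
        # the expansion forms are approached from below as ka/kc -> 0; the
        # convergence is slow for gamma near 3 (error ~ ka/kc), reaching the
        # few-percent level around 10^3 k0*
        for params in (P35, TheoryParams(4.0, 3)):
            k0 = th.k0_star(params)
            ratios = [
                th.f_nonisolated(mult * k0, params)
                / float(th.f_nonisolated_asymptotic(mult * k0, params))
                for mult in (10, 100, 1000)
            ]
            assert ratios[0] < ratios[1] < ratios[2] <= 1.0 + 1e-9
            assert ratios[2] == pytest.approx(1.0, rel=0.05)
            assert th.f_isolated_r2(1000 * k0, params) == pytest.approx(
                float(th.f_isolated_r2_asymptotic(1000 * k0, params)), rel=0.05
            )


class TestS1:
    @pytest.mark.parametrize("gamma,slope", [(3.5, -3.0), (4.0, -4.0)])
    def test_asymptotic_log_slope(self, gamma, slope):
        params = TheoryParams(gamma, 3)
        ks = np.geomspace(1e3, 1e5, 12)
        vals = [th.f_nonisolated(float(k), params) for k in ks]
        fit = np.polyfit(np.log(ks), np.log(vals), 1)[0]
        assert fit == pytest.approx(slope, abs=0.05)

    def test_bounded_by_active_fraction(self):
        for ka in (3, 10, 100, 1000):
            assert th.S1(float(ka), P35) <= float(th.active_fraction(ka, P35)) + 1e-12


class TestK1Star:
    def test_closed_form_equals_numeric_crossing(self):
        for gamma in (3.2, 3.5, 4.0, 5.0, 6.0):
            params = TheoryParams(gamma, 3)
            assert th.k1_star(params) == pytest.approx(
                th.k1_star_numeric(params), rel=1e-6
            )

    def test_minimum_network_size_anchor(self):
        # min over gamma of k1*^(gamma-1) ~ 4.2e5, attained near gamma ~ 5
        gammas = np.linspace(3.05, 8.0, 2000)
        sizes = [th.k1_star(TheoryParams(g, 3)) ** (g - 1) for g in gammas]
        i = int(np.argmin(sizes))
        assert sizes[i] == pytest.approx(4.2e5, rel=0.05)
        assert gammas[i] == pytest.approx(5.0, abs=0.3)

    def test_decreasing_in_gamma(self):
        vals = [th.k1_star(TheoryParams(g, 3)) for g in np.linspace(3.2, 6.0, 30)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestDistantHubMechanism:
    def test_d_of_k_boundaries(self):
        assert float(th.d_of_k(3, P35)) == 1.0
        near3 = TheoryParams(3.0001, 3)
        assert float(th.d_of_k(1e6, near3)) == pytest.approx(1.0, abs=1e-2)
        with pytest.raises(ValueError):
            th.d_of_k(10, TheoryParams(3.5, 3, kappa=0.9))

    def test_omega_residual_and_growth(self):
        for ka in (3, 10, 1e3, 1e6):
            w = th.omega(float(ka), P35)
            c = 0.5 / np.log(P35.kappa_value())
            assert w == pytest.approx(1 + c * np.log(w * ka / 3), abs=1e-8)
        # omega grows ~ ln(ka): increments per decade approach a constant
        ws = [th.omega(10.0**e, P35) for e in (3, 6, 9, 12)]
        incs = np.diff(ws)
        assert np.all(incs > 0)
        assert incs[2] == pytest.approx(incs[1], rel=0.15)

    def test_omega_near_gamma3(self):
        assert th.omega(1e4, TheoryParams(3.0001, 3)) == pytest.approx(1.0, abs=1e-2)

    def test_S2_identities_and_slope(self):
        for ka in (3, 30, 300):
            assert th.S2(float(ka), P35) <= float(th.active_fraction(ka, P35))
        ks = np.geomspace(1e3, 1e6, 10)
        vals = [th.S2(float(k), P35) for k in ks]
        slope = np.polyfit(np.log(ks), np.log(vals), 1)[0]
        assert (1 - 3.5) - 0.3 <= slope <= (1 - 3.5)

    def test_kc_dominates_kx_asymptotically(self):
        # kc grows as a power > 1 of ka while kx only logarithmically faster
        # than ka, so kc/kx diverges; at ka = 1e6 the ratio is already ~40
        ka = 1e6
        kx = th.omega(ka, P35) * ka
        assert float(th.kc(ka, P35)) > 10 * kx
        ka2 = 1e9
        assert float(th.kc(ka2, P35)) / (th.omega(ka2, P35) * ka2) > \
            float(th.kc(ka, P35)) / kx


class TestK2Star:
    def test_residual_and_shape(self):
        scales = th.k2_star(P35)
        k2 = scales.k2_star
        lhs = 10 ** th._log10_f_nonisolated_mp(k2, P35)
        rhs = th.S2(k2, P35)
        assert lhs == pytest.approx(rhs, rel=1e-5)
        assert scales.N2_star == pytest.approx(k2 ** (3.5 - 1))
        # decreasing in gamma
        k2s = [th.k2_star(TheoryParams(g, 3)).k2_star for g in (3.3, 3.7, 4.5, 6.0)]
        assert all(a > b for a, b in zip(k2s, k2s[1:]))

    def test_scale_ordering(self):
        for gamma in (3.5, 4.0, 5.0):
            s = th.k2_star(TheoryParams(gamma, 3))
            assert s.k0_star < s.k1_star < s.k2_star


class TestEffectiveThreshold:
    def test_preasymptotic_arithmetic(self):
        est = th.effective_ka_threshold(1e3, P35, regime="preasymptotic")
        assert est.value == pytest.approx(300.0, rel=1e-9)
        assert not est.asymptotic

    def test_gamma_lt3_rule(self):
        est = th.effective_ka_threshold(1e3, TheoryParams(2.5, 3))
        assert est.value == 1e3 and not est.asymptotic

    def test_regime_selector_feasible_sizes(self):
        # any feasible kmax (N <= 1e8) sits below k2*: Eq.-24 branch chosen
        for gamma in (3.5, 4.0, 5.0, 6.0):
            params = TheoryParams(gamma, 3)
            kmax_feasible = (1e8) ** (1 / (gamma - 1))
            est = th.effective_ka_threshold(kmax_feasible, params, regime="auto")
            assert not est.asymptotic

    def test_near_gamma3_rejected(self):
        with pytest.raises(ValueError):
            th.effective_ka_threshold(100, TheoryParams(3.01, 3))
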