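"""Fixation probabilities, rates, and the implicit coalescence solver."""

import math

import numpy as np
import pytest
from scipy import special

from vzero.dfe import DFESpec, dfe_integral, scale_dfe
from vzero.mssm import (
    NoRootError,
    airy_least_negative_zero,
    critical_population_size,
    fixation_rate,
    pfix_diffusion,
    pfix_mssm,
    solve_Tc,
    tc_ne_heuristic,
    v_rate,
)
from vzero.scaled import eta_on_surface, surface_residual


def test_airy_zero_matches_scipy_tables():
    z0 = airy_least_negative_zero()
    assert z0 == pytest.approx(float(special.ai_zeros(1)[0][0]), abs=1e-12)
    assert round(z0, 2) == -2.34


class TestPfix:
    def test_neutral_is_one_over_N(self):
        assert pfix_mssm(0.0, 100.0, 1e6) == pytest.approx(1e-6, rel=1e-12)
        assert pfix_diffusion(0.0, 100.0, 1e6) == pytest.approx(1e-6, rel=1e-9)

    def test_unit_scaled_effect(self):
        assert pfix_mssm(0.01, 100.0, 1e6) == pytest.approx(math.e / 1e6, rel=1e-12)

    def test_sign_symmetry_product(self):
        p = pfix_mssm(0.02, 150.0, 1e4) * pfix_mssm(-0.02, 150.0, 1e4)
        assert p == pytest.approx(1e-8, rel=1e-12)

    def test_monotone_in_s(self):
        s = np.linspace(-0.05, 0.05, 30)
        assert np.all(np.diff(pfix_mssm(s, 200.0, 1e5)) > 0)

    def test_diffusion_strong_beneficial_asymptote(self):
        # 4 Tc s / N for Tc*s >> 1
        assert pfix_diffusion(0.1, 100.0, 1e6) == pytest.approx(
            4 * 100 * 0.1 / 1e6, rel=1e-12
        )

    def test_diffusion_strong_deleterious_asymptote(self):
        Tc, s, N = 100.0, -0.05, 1e6
        expect = (4 * Tc * abs(s) / N) * math.exp(-4 * Tc * abs(s))
        assert pfix_diffusion(s, Tc, N) == pytest.approx(expect, rel=1e-6)

    def test_linear_coefficients_differ_by_factor_two(self):
        # p_mssm ~ (1 + Tc s)/N but p_diff ~ (1 + 2 Tc s)/N for small Tc s
        Tc, N, s = 50.0, 1e5, 1e-6
        slope_mssm = (pfix_mssm(s, Tc, N) - pfix_mssm(0, Tc, N)) / s
        slope_diff = (pfix_diffusion(s, Tc, N) - pfix_diffusion(0, Tc, N)) / s
        assert slope_diff / slope_mssm == pytest.approx(2.0, rel=1e-3)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            pfix_mssm(0.01, -1.0, 100)
        with pytest.raises(ValueError):
            pfix_diffusion(0.01, 10.0, 0.5)


class TestRates:
    def test_tc_to_zero_limits(self):
        d = DFESpec("two_effect", sb=0.01, sd=0.03, eta=0.2)
        mean = dfe_integral(d, "gamma", Tc=1.0)  # = mean effect for Tc=1
        U = 0.05
        assert v_rate(1e4, U, d, 1e-9) == pytest.approx(U * mean, rel=1e-6)
        assert fixation_rate(1e4, U, d, 1e-9) == pytest.approx(U, rel=1e-6)

    def test_v_vanishes_on_the_balance_surface(self):
        gb, gd, Tc = 0.8, 1.4, 500.0
        eta = eta_on_surface(gb, gd, "two_effect", "v0")
        d = DFESpec("two_effect", sb=gb / Tc, sd=gd / Tc, eta=eta)
        U = 0.01
        assert abs(v_rate(1e6, U, d, Tc)) < 1e-12 * U * gb / Tc

    def test_F_equals_U_on_the_balance_surface(self):
        gb, gd, Tc = 0.8, 1.4, 500.0
        eta = eta_on_surface(gb, gd, "two_effect", "FU")
        d = DFESpec("two_effect", sb=gb / Tc, sd=gd / Tc, eta=eta)
        U = 0.01
        assert fixation_rate(1e6, U, d, Tc) == pytest.approx(U, rel=1e-12)

    def test_deleterious_only_declines(self):
        d = DFESpec("two_effect", sb=0.01, sd=0.02, eta=0.0)
        U, Tc = 0.05, 100.0
        assert v_rate(1e4, U, d, Tc) == pytest.approx(
            -U * 0.02 * math.exp(-Tc * 0.02), rel=1e-12
        )

    def test_strong_purifying_F_vanishes(self):
        d = DFESpec("two_effect", sb=0.01, sd=0.1, eta=0.0)
        assert fixation_rate(1e4, 0.05, d, 500.0) < 1e-10

    def test_linear_in_U(self):
        d = DFESpec("two_effect", sb=0.005, sd=0.01, eta=0.3)
        Tc = 200.0
        assert v_rate(1e5, 0.06, d, Tc) == pytest.approx(
            3 * v_rate(1e5, 0.02, d, Tc), rel=1e-12
        )
        assert fixation_rate(1e5, 0.06, d, Tc) == pytest.approx(
            3 * fixation_rate(1e5, 0.02, d, Tc), rel=1e-12
        )

    def test_sign_matches_scaled_residual(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            d = DFESpec(
                "two_effect",
                sb=rng.uniform(1e-4, 1e-2),
                sd=rng.uniform(1e-4, 1e-2),
                eta=rng.uniform(0.01, 1.0),
            )
            Tc = rng.uniform(10, 500)
            v = v_rate(1e5, 0.01, d, Tc)
            r = surface_residual(scale_dfe(d, Tc), "v0")
            assert math.copysign(1, v) == math.copysign(1, r)


class TestSolveTc:
    def _relation_residual(self, N, U, dfe, Tc):
        """Independent evaluation of the printed relation from raw integrals."""
        I_v = dfe_integral(dfe, "v", Tc=Tc)
        I_xc = dfe_integral(dfe, "xc", Tc=Tc)
        I_b3 = dfe_integral(dfe, "b3", Tc=Tc)
        I_e8 = dfe_integral(dfe, "eq8", Tc=Tc)
        z0 = airy_least_negative_zero()
        v = U * I_v / Tc
        b = (0.5 * U * I_b3 / Tc**2) ** (1 / 3)
        xc = U * I_xc - b * z0 - 1.0 / Tc
        return Tc * (xc - U) - 0.5 * v * Tc**2 + U * Tc * I_e8 - math.log(N * xc)

    def test_self_consistency_sweep(self):
        cases = [
            (1e6, 1e-2, DFESpec("two_effect", sb=1e-3, sd=1e-3, eta=0.1)),
            (1e5, 0.05, DFESpec("two_effect", sb=5e-3, sd=1e-2, eta=0.3)),
            (1e3, 0.1, DFESpec("two_effect", sb=0.01, sd=0.02, eta=0.1)),
            (1e6, 0.01, DFESpec("exponential_pair", sb=3e-4, sd=6e-4, eta=0.2)),
        ]
        for N, U, dfe in cases:
            sol = solve_Tc(N, U, dfe)
            assert abs(self._relation_residual(N, U, dfe, sol.Tc)) < 1e-8
            assert 0 < sol.Tc <= N
            assert sol.xc > 0 and sol.b > 0

    def test_reported_rates_match_direct_evaluation(self):
        N, U = 1e5, 0.02
        d = DFESpec("two_effect", sb=2e-3, sd=4e-3, eta=0.2)
        sol = solve_Tc(N, U, d)
        assert sol.v == pytest.approx(v_rate(N, U, d, sol.Tc), rel=1e-12)
        assert sol.F == pytest.approx(fixation_rate(N, U, d, sol.Tc), rel=1e-12)

    def test_more_background_selection_shortens_coalescence(self):
        # raising the deleterious supply Ud at fixed beneficial supply Ub
        # strengthens background selection and shortens coalescence
        N, Ub = 1e5, 1e-3
        tcs = []
        for Ud in (0.02, 0.05, 0.1):
            d = DFESpec("two_effect", sb=2e-3, sd=5e-3, eta=Ub / Ud)
            tcs.append(solve_Tc(N, Ub + Ud, d).Tc)
        assert tcs[0] > tcs[1] > tcs[2]

    def test_no_root_reports_sign_pattern(self):
        d = DFESpec("two_effect", sb=1e-4, sd=0.03, eta=0.0)
        with pytest.raises(NoRootError, match="sign pattern"):
            solve_Tc(1e6, 1e-2, d)


class TestNeHeuristic:
    def test_no_deleterious_gives_census_size(self):
        d = DFESpec("two_effect", sb=1e-3, sd=1e-3, eta=1.0)
        assert tc_ne_heuristic(2e5, 0.0, d) == 2e5

    def test_strong_selection_classic_limit(self):
        # Tc -> N exp(-Ud/sd) when Tc*sd >> 1
        N, Ud, sd = 1e5, 0.02, 0.02
        d = DFESpec("two_effect", sb=1e-4, sd=sd, eta=0.0)
        tc = tc_ne_heuristic(N, Ud, d)
        assert tc * sd > 10
        assert tc == pytest.approx(N * math.exp(-Ud / sd), rel=1e-2)

    def test_weak_selection_fixed_point(self):
        # kernel (1-e^{-Tc s})/s -> Tc: solves Tc = N exp(-Ud*Tc*sd*...) with
        # the full integral; check the residual of the printed fixed point
        N, Ud, sd = 1e3, 1e-5, 1e-5
        d = DFESpec("two_effect", sb=1e-4, sd=sd, eta=0.0)
        tc = tc_ne_heuristic(N, Ud, d)
        rhs = N * math.exp(-Ud * (1 - math.exp(-tc * sd)) / sd)
        assert tc == pytest.approx(rhs, rel=1e-10)
        # with Ud*Tc small, weak effects barely reduce Tc below N
        # kernel limit (1-e^{-Tc s})/s -> Tc holds to O(Tc*sd/2) here
        assert tc == pytest.approx(N * math.exp(-Ud * tc), rel=1e-4)
        assert tc == pytest.approx(N, rel=0.02)

    def test_strong_feedback_converges(self):
        d = DFESpec("two_effect", sb=1e-4, sd=0.01, eta=0.0)
        tc = tc_ne_heuristic(1e5, 0.1, d)
        rhs = 1e5 * math.exp(-0.1 * (1 - math.exp(-tc * 0.01)) / 0.01)
        assert tc == pytest.approx(rhs, rel=1e-8)


class TestCriticalPopulationSize:
    def test_v_changes_sign_at_N0(self):
        U = 0.05
        d = DFESpec("two_effect", sb=2e-3, sd=5e-3, eta=0.02)
        N0 = critical_population_size(U, d, bracket=(1e3, 1e9))
        v_above = solve_Tc(N0 * 3, U, d).v
        v_below = solve_Tc(N0 / 3, U, d).v
        assert v_above > 0 > v_below
        assert abs(solve_Tc(N0, U, d).v) < 1e-10

    def test_larger_beneficial_fraction_lowers_N0(self):
        U = 0.05
        d1 = DFESpec("two_effect", sb=2e-3, sd=5e-3, eta=0.02)
        d2 = DFESpec("two_effect", sb=2e-3, sd=5e-3, eta=0.03)
        assert critical_population_size(U, d2, bracket=(1e3, 1e9)) < \
            critical_population_size(U, d1, bracket=(1e3, 1e9))

    def test_always_adapting_has_no_sign_change(self):
        U = 0.05
        d = DFESpec("two_effect", sb=5e-3, sd=5e-3, eta=0.9)
        with pytest.raises(NoRootError):
            critical_population_size(U, d, bracket=(1e3, 1e8))
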