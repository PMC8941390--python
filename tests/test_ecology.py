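"""Life-history integration, equilibria, continuation and stability."""


import numpy as np
import pytest
from scipy.integrate import solve_ivp

from ontoradiate import (
    ModelParameters,
    ResourceEnvironment,
    ResidentCoalition,
    growth_curve,
    integrate_life_history,
    resource_balance_residual,
    solve_equilibrium,
)
from ontoradiate.model_core import (
    fecundity_rate,
    growth_rate,
    mortality_rate,
)
from ontoradiate.ecology import (
    CohortSimulator,
    bistability_window,
    continue_in_parameter,
    set_parameter,
)


def time_domain_life_history(x, env, params, s_min=1e-14):
    """Independent oracle: adaptive time-domain integration of the cohort
    ODEs dm/dt = g, dS/dt = -mu S, dB/dt = beta S, stopping at maturation."""

    def rhs(t, y):
        m, S, B = y
        m = min(m, params.m_mat)
        return [float(growth_rate(m, x, env, params)),
                -float(mortality_rate(m, x, env, params)) * S,
                float(fecundity_rate(m, x, env, params)) * S]

    def hit_shift(t, y):
        return y[0] - params.m_shift
    hit_shift.direction = 1.0

    def hit_mat(t, y):
        return y[0] - params.m_mat * (1 - 1e-12)
    hit_mat.terminal = True
    hit_mat.direction = 1.0

    sol = solve_ivp(rhs, (0.0, 1e7), [params.m_b, 1.0, 0.0],
                    events=[hit_shift, hit_mat], rtol=1e-10, atol=1e-14,
                    method="LSODA", max_step=50.0)
    if len(sol.t_events[1]) == 0:
        return {"matured": False, "R0": 0.0}
    t_mat = sol.t_events[1][0]
    S_mat = sol.y_events[1][0][1]
    mu_ad = float(mortality_rate(params.m_mat, x, env, params))
    beta = float(fecundity_rate(params.m_mat, x, env, params))
    return {"matured": True, "t_mat": t_mat, "S_mat": S_mat,
            "R0": S_mat * beta / mu_ad}


class TestLifeHistory:
    def test_empty_environment_gives_zero_R0(self, params):
        env = ResourceEnvironment(0.0, np.zeros(params.n_resources))
        lh = integrate_life_history(1.0, env, params)
        assert lh.R0 == 0.0
        assert not lh.matured

    def test_matches_time_domain_oracle(self, params, pristine):
        lh = integrate_life_history(1.0, pristine, params)
        ref = time_domain_life_history(1.0, pristine, params)
        assert ref["matured"] and lh.matured
        assert lh.R0 == pytest.approx(ref["R0"], rel=1e-6)
        assert lh.S_mat == pytest.approx(ref["S_mat"], rel=1e-6)
        assert lh.age_at_maturation == pytest.approx(ref["t_mat"], rel=1e-6)

    def test_matches_oracle_in_depleted_environment(self, eq_high):
        # slow-growth regime: long juvenile phase through depleted resources
        env, p = eq_high.env, eq_high.params
        lh = integrate_life_history(1.0, env, p)
        ref = time_domain_life_history(1.0, env, p)
        assert lh.R0 == pytest.approx(ref["R0"], rel=1e-6)

    def test_invariants(self, eq_high):
        lh = eq_high.life_histories[0]
        assert np.all(np.diff(lh.mass) >= -1e-12)
        assert np.all(np.diff(lh.survival) <= 1e-12)
        assert lh.survival[0] == 1.0
        assert np.all(np.diff(lh.offspring) >= -1e-12)
        assert lh.offspring[-1] == pytest.approx(lh.R0, rel=1e-12)
        assert np.all(lh.consumption >= 0)

    def test_resident_neutral_at_equilibrium(self, eq_high):
        lh = eq_high.life_histories[0]
        assert lh.R0 == pytest.approx(1.0, abs=1e-6)


class TestGrowthCurve:
    def test_supply_accelerates_development(self, eq_low, eq_high):
        glow = growth_curve(1.0, eq_low.env, eq_low.params)
        ghigh = growth_curve(1.0, eq_high.env, eq_high.params)
        assert ghigh.attrs["age_at_shift"] < glow.attrs["age_at_shift"]

    def test_pristine_is_upper_envelope(self, params, pristine, eq_high):
        g_best = growth_curve(1.0, pristine, params)
        g_eq = growth_curve(1.0, eq_high.env, params)
        assert g_best.attrs["age_at_maturation"] <= g_eq.attrs["age_at_maturation"]


class TestEquilibrium:
    def test_consumer_free_environment_is_pristine(self, params):
        coal = ResidentCoalition([1.0], [0.0])
        env = ResourceEnvironment.pristine(params)
        res = resource_balance_residual(coal, env, params)
        assert np.allclose(res, 0.0, atol=1e-12)

    def test_balance_linear_in_birth_rates(self, eq_high):
        p = eq_high.params
        coal = eq_high.coalition
        doubled = ResidentCoalition(coal.traits, 2 * coal.b)
        r1 = resource_balance_residual(coal, eq_high.env, p,
                                       eq_high.life_histories)
        r2 = resource_balance_residual(doubled, eq_high.env, p,
                                       eq_high.life_histories)
        supply = p.delta * (p.R_max - eq_high.env.vector)
        depl1, depl2 = supply - r1, supply - r2
        assert np.allclose(depl2, 2 * depl1, rtol=1e-12)

    def test_equilibrium_residuals(self, eq_high, eq_low):
        for eq in (eq_high, eq_low):
            res = resource_balance_residual(eq.coalition, eq.env, eq.params,
                                            eq.life_histories)
            scaled = res / (eq.params.delta * eq.params.R_max)
            assert np.max(np.abs(scaled)) < 1e-7
            for lh, b in zip(eq.life_histories, eq.coalition.b):
                if b > 0:
                    assert abs(lh.R0 - 1.0) < 1e-6

    def test_densities_within_bounds(self, eq_high):
        v = eq_high.env.vector
        assert np.all(v > 0)
        assert np.all(v <= eq_high.params.R_max + 1e-12)

    def test_unsustainable_supply_reports_extinction(self):
        p = set_parameter(ModelParameters(R_c_max=1e-4), "supply_s", 1e-5)
        eq = solve_equilibrium([1.0], p)
        assert np.all(eq.coalition.b == 0.0)
        assert np.allclose(eq.env.vector, p.R_max)

    def test_supply_regimes_match_size_structure(self, eq_low, eq_high):
        # low supply: specific resources stay high, few large individuals;
        # high supply: specific resource strongly depleted, biomass in
        # the large size classes
        rc = 1.0
        assert eq_low.env.vector[1] > 0.5 * rc
        assert eq_high.env.vector[1] < 0.1 * rc
        lo, hi = eq_low, eq_high
        large_lo = sum(b * lh.standing_large
                       for b, lh in zip(lo.coalition.b, lo.life_histories))
        large_hi = sum(b * lh.standing_large
                       for b, lh in zip(hi.coalition.b, hi.life_histories))
        assert large_hi > 5 * large_lo


@pytest.fixture(scope="module")
def branch():
    return continue_in_parameter([1.0], ModelParameters(), "supply_s",
                                 (0.02, 0.25), classify="none",
                                 max_points=120)


class TestContinuationAndStability:
    def test_fold_pair_brackets_bistability(self, branch):
        win = bistability_window(branch)
        assert win is not None
        lo, hi = win
        assert 0.025 < lo < hi < 0.2

    def test_folds_match_multistart_bruteforce(self, branch):
        # inside the window the equilibrium is non-unique, outside unique
        from ontoradiate.ecology import find_stable_equilibria
        lo, hi = bistability_window(branch)
        mid = 0.5 * (lo + hi)
        p_in = set_parameter(ModelParameters(), "supply_s", mid)
        eqs_in = find_stable_equilibria([1.0], p_in, classify=False)
        assert len(eqs_in) >= 2
        p_out = set_parameter(ModelParameters(), "supply_s", hi * 1.8)
        eqs_out = find_stable_equilibria([1.0], p_out, classify=False)
        assert len(eqs_out) == 1

    def test_hysteresis_between_branches(self, branch):
        # within the window the branch set contains two distinct stable
        # size-structure regimes at (nearly) the same parameter value
        lo, hi = bistability_window(branch)
        mid = 0.5 * (lo + hi)
        df = branch.points
        near = df[np.abs(df["parameter"] - mid) < 0.35 * (hi - lo)]
        assert near["R_s"].max() / near["R_s"].min() > 1.5


class TestCohortSimulator:
    def test_consumer_free_relaxation(self, params):
        sim = CohortSimulator([1.0], params, envv=0.2 * params.R_max)
        sim.run(400.0)
        assert np.allclose(sim.envv, params.R_max, rtol=1e-3)

    def test_holds_stable_equilibrium(self, eq_high):
        sim = CohortSimulator.from_equilibrium(eq_high)
        sim.run(4000.0)
        assert np.allclose(sim.envv, eq_high.env.vector, rtol=0.25)

    def test_mass_balance_step(self, params):
        # one step: supply - outflow - grazing accounts for the change in R
        sim = CohortSimulator([1.0], params, envv=0.5 * params.R_max, dt=0.5)
        sim.masses[0] = np.array([0.5, 10.0])
        sim.numbers[0] = np.array([1.0, 0.05])
        m0 = sim.masses[0].copy()
        n0 = sim.numbers[0].copy()
        r0 = sim.envv.copy()
        sim.step()
        # semi-implicit update: (R1 - R0)/dt == delta (Rmax - R1) - G R1
        from ontoradiate.model_core import consumption_rates
        got = (sim.envv - r0) / sim.dt
        graz = consumption_rates(m0, 1.0, r0, params)
        # grazing evaluated at the old state, scaled by the implicit ratio
        g_rate = (graz * n0[:, None]).sum(axis=0) / r0
        expect = params.delta * (params.R_max - sim.envv) - g_rate * sim.envv
        assert np.allclose(got, expect, rtol=1e-6, atol=1e-12)
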