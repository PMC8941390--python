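"""Invasion fitness, selection gradients, branching and radiation outcomes."""


import numpy as np
import pytest

from ontoradiate import ModelParameters, solve_equilibrium
from ontoradiate.ecology import CohortSimulator, set_parameter
from ontoradiate.adaptive_dynamics import (
    classify_singularity,
    count_species,
    evolve_traits,
    find_singular_points,
    invasion_fitness,
    selection_gradient,
)
from ontoradiate.pipeline import build_fixture


class TestInvasionFitness:
    def test_resident_neutrality(self, eq_high):
        s = invasion_fitness(1.0, eq_high)
        assert abs(s) < 1e-6

    def test_resident_neutrality_random_params(self):
        # the defining identity s(x_res | E_res) = 0 across parameter draws
        for seed in range(8):
            p = build_fixture("random-params", seed)
            x = float(np.random.default_rng(seed).uniform(0.0, 2.0))
            try:
                eq = solve_equilibrium([x], p)
            except Exception:
                continue
            if np.all(eq.coalition.b == 0):
                continue
            assert abs(invasion_fitness(x, eq)) < 1e-6

    def test_gradient_toward_nearest_peak(self, eq_low):
        # under low supply a resident below theta_1 is pushed up towards it
        p = eq_low.params
        eq = solve_equilibrium([0.5], p)
        assert selection_gradient(0, eq) > 0

    def test_gradient_matches_five_point_stencil(self, eq_high):
        g2 = selection_gradient(0, eq_high)
        h = 1e-3
        x = 1.0
        s = [invasion_fitness(x + k * h, eq_high) for k in (-2, -1, 1, 2)]
        g5 = (s[0] - 8 * s[1] + 8 * s[2] - s[3]) / (12 * h)
        assert g2 == pytest.approx(g5, rel=1e-4, abs=1e-6)

    def test_invasion_sign_against_dynamic_oracle(self, eq_high):
        """A mutant with s > 0 grows when rare in the simulated resident
        ecology; one with s < 0 declines (two-species cohort dynamics)."""
        p = eq_high.params
        for x_mut in (1.8, 0.2):
            s = invasion_fitness(x_mut, eq_high)
            sim = CohortSimulator.from_equilibrium(eq_high)
            # seed a rare mutant cohort population: 1% of resident newborns
            sim.traits = np.array([1.0, x_mut])
            from ontoradiate.model_core import attack_vector
            sim.attack = [attack_vector(x, p) for x in sim.traits]
            lh = eq_high.life_histories[0]
            b_mut = 0.01 * eq_high.coalition.b[0]
            mu_ad = p.mu0 * p.m_mat ** p.mort_exp
            sim.masses.append(np.array([p.m_mat]))
            sim.numbers.append(np.array([b_mut * lh.S_mat / mu_ad]))
            n0 = sim.numbers[1].sum() * 1.0
            sim.run(4000.0)
            n1 = (sim.masses[1] >= p.m_mat) @ sim.numbers[1] \
                if len(sim.numbers[1]) else 0.0
            grew = n1 > n0
            assert grew == (s > 0), (x_mut, s, n0, n1)


class TestSingularPoints:
    def test_low_supply_attractor_is_css(self, params_low):
        pts = find_singular_points(params_low, (0.6, 2.2), n_scan=9)
        css = [p for p in pts if p.classification == "CSS"]
        assert len(css) >= 1
        assert any(abs(p.x - 1.2) < 0.4 for p in css)

    def test_translation_invariance(self):
        # shifting every optimum leaves the classification unchanged
        p0 = ModelParameters(m_shift=0.0, R_s_max=2.0)
        p1 = p0.with_(theta_1=p0.theta_1 + 3.0)
        c = 0.5 * (p0.theta[1] + p0.theta[-1])
        s0 = classify_singularity(c, p0)
        s1 = classify_singularity(c + 3.0, p1)
        assert s0.classification == s1.classification
        assert s0.curvature == pytest.approx(s1.curvature, rel=1e-5, abs=1e-6)

    def test_default_spacing_attractor_is_branching(self):
        # no diet shift, spacing 2.5: the interior attractor branches
        p = ModelParameters(m_shift=0.0, R_s_max=2.0)
        traj = evolve_traits([7.75], p, allow_branching=False, max_steps=300)
        sp = classify_singularity(float(traj.final_coalition[0]), p)
        assert sp.classification == "branching"

    def test_narrow_spacing_no_branching(self):
        # spacing well below the branching window: the resource array is
        # effectively one broad resource and the attractor is not a
        # branching point
        p = ModelParameters(m_shift=0.0, R_s_max=2.0, peak_spacing=0.45)
        traj = evolve_traits([0.5 * (p.theta[1] + p.theta[-1]) + 0.1], p,
                             allow_branching=False, max_steps=300)
        sp = classify_singularity(float(traj.final_coalition[0]), p)
        assert sp.classification != "branching"


class TestEvolveTraits:
    def test_low_supply_single_specialist(self, params_low):
        traj = evolve_traits([0.0], params_low, max_steps=400)
        assert count_species(traj.final_coalition) == 1
        assert abs(traj.final_coalition[0] - 1.0) < 0.5

    def test_deterministic_given_config(self, params_low):
        t1 = evolve_traits([0.3], params_low, max_steps=60)
        t2 = evolve_traits([0.3], params_low, max_steps=60)
        assert np.array_equal(t1.traits[-1], t2.traits[-1])

    def test_mirror_symmetry(self):
        """Reflecting the trait axis about the peak-array centre maps
        trajectories onto mirrored trajectories (tau_s = inf)."""
        p = set_parameter(ModelParameters(), "supply_s", 0.06)
        centre = 0.5 * (p.theta[1] + p.theta[-1])
        fwd = evolve_traits([centre - 2.0], p, max_steps=40)
        bwd = evolve_traits([centre + 2.0], p, max_steps=40)
        for xs_f, xs_b in zip(fwd.traits, bwd.traits):
            assert np.allclose(np.sort(xs_f), np.sort(2 * centre - xs_b),
                               atol=2e-4)

    def test_count_species_separation_rule(self):
        assert count_species([1.0, 1.01, 3.5]) == 2
        assert count_species([1.0]) == 1
        assert count_species([]) == 0


class TestSpeciesCountGrid:
    def test_low_productivity_cells_stay_monomorphic(self):
        """At very low relative productivity of the shared resource and a
        weak juvenile trade-off, no radiation unfolds from either initial
        ecological state, and the bistable flag equals the count
        disagreement by construction."""
        from ontoradiate.adaptive_dynamics import species_count_grid
        p = ModelParameters(tau_s=20.0)
        grid = species_count_grid(
            p, ("productivity_ratio", np.array([0.25])),
            ("m_shift", np.array([5.0])),
            evolve_kwargs={"max_steps": 250},
        )
        assert len(grid) == 1
        row = grid.iloc[0]
        assert row["error"] == ""
        assert row["count_small_start"] <= 1
        assert row["count_large_start"] <= 1
        assert bool(row["bistable"]) == (
            row["count_small_start"] != row["count_large_start"])
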