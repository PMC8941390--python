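"""Genetics, mate choice, stepping, clustering and reproductive isolation."""

import math

import numpy as np
import pytest

from ontoradiate.model_core import ModelParameters
from ontoradiate.ecology import set_parameter, solve_equilibrium
from ontoradiate.ibm import (
    GeneticParameters,
    Genotype,
    IBMConfig,
    choose_mate,
    cluster_species,
    initial_state,
    make_offspring,
    mate_choice_weights,
    phenotype_from_genotype,
    reproductive_isolation,
    run_ibm,
    step,
)
from ontoradiate.pipeline import build_fixture

GEN = GeneticParameters()


class TestGenetics:
    def test_phenotype_additivity(self):
        g = Genotype(np.zeros(2 * GEN.F_x), np.zeros(2 * GEN.F_a))
        assert phenotype_from_genotype(g) == (0.0, 0.0)
        g2 = Genotype(np.full(2 * GEN.F_x, 0.25), np.ones(2 * GEN.F_a))
        x, a = phenotype_from_genotype(g2)
        assert x == pytest.approx(2 * GEN.F_x * 0.25)
        assert a == 1.0

    def test_no_mutation_conserves_alleles(self):
        rng = np.random.default_rng(0)
        gen = GeneticParameters(nu=0.0)
        m = Genotype(np.arange(2 * gen.F_x, dtype=float),
                     np.linspace(-1, 1, 2 * gen.F_a))
        f = Genotype(100.0 + np.arange(2 * gen.F_x, dtype=float),
                     np.linspace(-0.5, 0.5, 2 * gen.F_a))
        child = make_offspring(m, f, gen, rng)
        parental = set(m.x_alleles) | set(f.x_alleles)
        assert set(child.x_alleles) <= parental

    def test_midparent_expectation_without_mutation(self):
        rng = np.random.default_rng(1)
        gen = GeneticParameters(nu=0.0)
        m = Genotype(np.random.default_rng(2).normal(size=2 * gen.F_x),
                     np.zeros(2 * gen.F_a))
        f = Genotype(np.random.default_rng(3).normal(size=2 * gen.F_x),
                     np.zeros(2 * gen.F_a))
        xs = [phenotype_from_genotype(make_offspring(m, f, gen, rng))[0]
              for _ in range(4000)]
        mid = 0.5 * (m.x_alleles.sum() + f.x_alleles.sum())
        se = np.std(xs) / math.sqrt(len(xs))
        assert np.mean(xs) == pytest.approx(mid, abs=4 * se)

    def test_mutated_fraction_binomial_oracle(self):
        rng = np.random.default_rng(4)
        gen = GeneticParameters(nu=0.1, sigma=0.5)
        m = Genotype(np.zeros(2 * gen.F_x), np.zeros(2 * gen.F_a))
        n_off = 6000
        changed = 0
        total = 0
        for _ in range(n_off):
            c = make_offspring(m, m, gen, rng)
            changed += int(np.sum(c.x_alleles != 0.0))
            total += len(c.x_alleles)
        p_hat = changed / total
        sd = math.sqrt(gen.nu * (1 - gen.nu) / total)
        assert abs(p_hat - gen.nu) < 3 * sd

    def test_a_alleles_clamped(self):
        rng = np.random.default_rng(5)
        gen = GeneticParameters(nu=1.0, sigma=5.0)
        m = Genotype(np.zeros(2 * gen.F_x), np.ones(2 * gen.F_a))
        for _ in range(50):
            c = make_offspring(m, m, gen, rng)
            assert np.all(np.abs(c.a_alleles) <= 1.0)


class TestMateChoice:
    def test_random_mating_uniform(self):
        w = mate_choice_weights(0.0, 0.0, np.array([0.0, 1.0, 9.0]), GEN)
        assert np.allclose(w, 1.0)

    def test_self_matching_maximum(self):
        w = mate_choice_weights(2.0, 1.0, np.array([2.0, 2.5, 5.0]), GEN)
        assert np.argmax(w) == 0

    def test_disassortative_prefers_distant(self):
        w = mate_choice_weights(0.0, -1.0, np.array([0.0, 3.0]), GEN)
        assert w[1] > w[0]

    def test_sampling_matches_weights(self):
        """Empirical mate-sampling frequencies agree with the analytic
        weights within binomial error."""
        rng = np.random.default_rng(6)
        xc = np.array([0.0, 0.5, 1.0, 2.0])
        a, xm = 0.8, 0.4
        w = mate_choice_weights(xm, a, xc, GEN)
        pexp = w / w.sum()
        n = 100_000
        counts = np.bincount(
            [choose_mate(xm, a, xc, GEN, rng) for _ in range(n)],
            minlength=len(xc))
        for k in range(len(xc)):
            sd = math.sqrt(pexp[k] * (1 - pexp[k]) / n)
            assert abs(counts[k] / n - pexp[k]) < 4 * sd


class TestStep:
    def test_empty_population_resources_relax(self):
        cfg, state = build_fixture("small-ibm-state", seed=0)
        state.mass = state.mass[:0]
        state.buffer = state.buffer[:0]
        state.x_alleles = state.x_alleles[:0]
        state.a_alleles = state.a_alleles[:0]
        state.x, state.a = state.x[:0], state.a[:0]
        state.ids = state.ids[:0]
        state.mother, state.father = state.mother[:0], state.father[:0]
        state.resources = 0.3 * cfg.params.R_max
        r_prev = state.resources.copy()
        for _ in range(300):
            step(state, cfg)
            assert np.all(state.resources >= r_prev - 1e-12)
            r_prev = state.resources.copy()
        assert np.allclose(state.resources, cfg.params.R_max, rtol=1e-3)

    def test_monomorphic_without_mutation_stays_monomorphic(self):
        cfg, state = build_fixture("small-ibm-state", seed=1)
        cfg = cfg.with_(genetics=GeneticParameters(V=200.0, nu=0.0))
        for _ in range(400):
            step(state, cfg)
        assert state.n > 0
        assert np.allclose(state.x, cfg.x0, atol=1e-12)
        assert np.allclose(state.a, cfg.a0, atol=1e-12)

    def test_phenotype_genotype_consistency(self):
        cfg, state = build_fixture("small-ibm-state", seed=2)
        for _ in range(300):
            step(state, cfg)
        assert np.allclose(state.x, state.x_alleles.sum(axis=1))
        assert np.allclose(state.a, state.a_alleles.mean(axis=1))

    def test_large_volume_matches_deterministic_resources(self, eq_high):
        """Deterministic-limit check: with a large volume, the realized
        resource densities fluctuate around the equilibrium values."""
        p = eq_high.params
        cfg = IBMConfig(params=p, genetics=GeneticParameters(V=20000.0),
                        x0=1.0, n0=6000, t_max=3000.0, record_every=250.0)
        res = run_ibm(cfg, seed=3)
        tail = res.series[res.series.time > 1500.0]
        assert not res.extinct
        r1 = tail["R_1"].mean()
        assert r1 == pytest.approx(eq_high.env.vector[1], rel=0.5)
        rs = tail["R_s"].mean()
        assert rs == pytest.approx(eq_high.env.vector[0], rel=0.5)


class TestReproducibility:
    def test_same_seed_bit_identical(self):
        p = set_parameter(ModelParameters(), "supply_s", 0.2)
        cfg = IBMConfig(params=p, genetics=GeneticParameters(V=500.0),
                        x0=0.0, n0=150, t_max=400.0, record_every=100.0)
        r1 = run_ibm(cfg, seed=7)
        r2 = run_ibm(cfg, seed=7)
        assert r1.snapshots.equals(r2.snapshots)
        assert r1.series.equals(r2.series)
        assert r1.mating_records == r2.mating_records

    def test_different_seed_differs(self):
        p = set_parameter(ModelParameters(), "supply_s", 0.2)
        cfg = IBMConfig(params=p, genetics=GeneticParameters(V=500.0),
                        x0=0.0, n0=150, t_max=400.0, record_every=100.0)
        r1 = run_ibm(cfg, seed=7)
        r2 = run_ibm(cfg, seed=8)
        assert not r1.series.equals(r2.series)

    def test_rng_state_roundtrip(self):
        cfg, state = build_fixture("small-ibm-state", seed=3)
        st = state.rng_state()
        draws1 = state.rng.random(5).tolist()
        state.set_rng_state(st)
        draws2 = state.rng.random(5).tolist()
        assert draws1 == draws2


class TestClusteringAndRI:
    def test_single_cluster(self):
        labels, n = cluster_species([2.0, 2.0, 2.0])
        assert n == 1

    def test_three_separated_clusters(self):
        rng = np.random.default_rng(0)
        xs = np.concatenate([1.0 + 0.05 * rng.normal(size=30),
                             3.5 + 0.05 * rng.normal(size=30),
                             6.0 + 0.05 * rng.normal(size=30)])
        labels, n = cluster_species(xs)
        assert n == 3
        # labels ordered by mean trait
        assert labels[np.argmin(xs)] == 0
        assert labels[np.argmax(xs)] == 2

    def test_count_stable_under_threshold_variation(self):
        rng = np.random.default_rng(1)
        xs = np.concatenate([th + 0.08 * rng.normal(size=40)
                             for th in (1.0, 3.5, 6.0, 8.5)])
        counts = {cluster_species(xs, g)[1] for g in (0.3, 0.5, 0.8)}
        assert counts == {4}

    def test_ri_ground_truths(self):
        for seed in range(6):
            records, edges, ri_true = build_fixture("mating-log", seed)
            ri = reproductive_isolation(records, edges)
            assert ri == pytest.approx(ri_true, abs=1e-9)

    def test_ri_random_pairing_near_zero(self):
        rng = np.random.default_rng(2)
        xs = np.concatenate([np.full(200, 0.0), np.full(200, 5.0)])
        recs = []
        for t in range(2000):
            i, j = rng.choice(len(xs), size=2, replace=False)
            recs.append((float(t), i, j, xs[i], xs[j]))
        ri = reproductive_isolation(recs, [2.5])
        assert abs(ri) < 0.06

    def test_ri_complete_isolation(self):
        recs = [(0.0, 1, 2, 0.0, 0.0), (1.0, 3, 4, 5.0, 5.0)] * 50
        assert reproductive_isolation(recs, [2.5]) == 1.0

    def test_ri_empty_window_missing(self):
        assert math.isnan(reproductive_isolation([], [2.5]))
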