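"""Stochastic individual-based eco-genetic simulator.

Individuals carry the same size-structured life history as the
deterministic engines — semi-chemostat resources in a finite volume
``V``, ontogenetic diet shift at ``m_shift``, determinate growth at
``m_mat`` — plus an additive diploid multi-locus genetic architecture:
``F_x`` loci whose allelic values *sum* to the niche trait ``x`` and
``F_a`` loci whose allelic values *average* to the assortative-mating
trait ``a`` (each a-allele bounded in [-1, 1]).  Mating is self-matching:
a spawning female weights mature males by the similarity of their niche
trait to her own, with a strength set by her own ``a``; ``a = 0`` is
random mating, negative ``a`` disassortative.  Loci recombine freely and
alleles mutate with probability ``nu`` by a Gaussian kernel of width
``sigma``.

All randomness flows from a single ``numpy.random.Generator``; a run is
bit-reproducible from its (config, seed) pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model_core import ModelParameters, SHARED, attack_vector, diet_weight_matrix

__all__ = [
    "GeneticParameters",
    "Genotype",
    "Individual",
    "IBMState",
    "IBMConfig",
    "IBMResult",
    "phenotype_from_genotype",
    "choose_mate",
    "mate_choice_weights",
    "make_offspring",
    "initial_state",
    "step",
    "run_ibm",
    "cluster_species",
    "reproductive_isolation",
]


@dataclass(frozen=True)
class GeneticParameters:
    """Genetic architecture and stochastic-simulation constants."""

    F_x: int = 8            # diploid loci coding the niche trait
    F_a: int = 8            # diploid loci coding the assortative-mating trait
    nu: float = 0.1         # mutation probability per allele
    sigma: float = 0.01     # mutation-kernel standard deviation
    sigma_mate: float = 1.0 # width of the self-matching mate-choice function
    V: float = 1e3          # system volume, m^3

    def __post_init__(self) -> None:
        if self.F_x < 1 or self.F_a < 1:
            raise ValueError("locus counts must be >= 1")
        if not (0.0 <= self.nu <= 1.0):
            raise ValueError("mutation probability must be in [0, 1]")
        if self.sigma <= 0 or self.sigma_mate <= 0 or self.V <= 0:
            raise ValueError("sigma, sigma_mate and V must be positive")


@dataclass
class Genotype:
    """Diploid allele arrays: ``x_alleles`` (2 F_x,), ``a_alleles`` (2 F_a,)."""

    x_alleles: np.ndarray
    a_alleles: np.ndarray

    def __post_init__(self) -> None:
        self.x_alleles = np.asarray(self.x_alleles, dtype=float).ravel()
        self.a_alleles = np.asarray(self.a_alleles, dtype=float).ravel()
        if np.any(np.abs(self.a_alleles) > 1.0 + 1e-12):
            raise ValueError("a-alleles must lie in [-1, 1]")


def phenotype_from_genotype(genotype: Genotype) -> tuple[float, float]:
    """Niche trait = sum of x-alleles; mating trait = mean of a-alleles."""
    return float(genotype.x_alleles.sum()), float(genotype.a_alleles.mean())


@dataclass
class Individual:
    """A single agent (scalar view of one slot of the state arrays)."""

    id: int
    mass: float
    genotype: Genotype
    x: float
    a: float
    buffer: float = 0.0
    alive: bool = True
    mother_id: int = -1
    father_id: int = -1


@dataclass
class IBMState:
    """Struct-of-arrays population state plus resources, time and RNG."""

    mass: np.ndarray            # (N,)
    buffer: np.ndarray          # reproductive-energy buffer (g)
    x_alleles: np.ndarray       # (N, 2 F_x)
    a_alleles: np.ndarray       # (N, 2 F_a)
    x: np.ndarray               # phenotypes, cached
    a: np.ndarray
    ids: np.ndarray             # (N,) unique int64
    mother: np.ndarray
    father: np.ndarray
    resources: np.ndarray       # (1 + n_resources,)
    time: float
    next_id: int
    rng: np.random.Generator
    mating_log: list = field(default_factory=list)  # (t, mother, father, x_m, x_f)

    @property
    def n(self) -> int:
        return len(self.mass)

    def individual(self, i: int) -> Individual:
        g = Genotype(self.x_alleles[i].copy(), self.a_alleles[i].copy())
        return Individual(int(self.ids[i]), float(self.mass[i]), g,
                          float(self.x[i]), float(self.a[i]),
                          float(self.buffer[i]), True,
                          int(self.mother[i]), int(self.father[i]))

    def rng_state(self) -> dict:
        return self.rng.bit_generator.state

    def set_rng_state(self, state: dict) -> None:
        self.rng.bit_generator.state = state


# ---------------------------------------------------------------------------
# genetics
# ---------------------------------------------------------------------------

def mate_choice_weights(x_mother: float, a_mother: float,
                        x_candidates: np.ndarray,
                        gen: GeneticParameters,
                        floor: float = 1e-3) -> np.ndarray:
    """Unnormalized self-matching mate-choice weights.

    For ``a > 0`` similarity is favoured, ``w = exp(-a^2 d^2 / 2 sigma_m^2)``
    with ``d = |x_mother - x_candidate|``; ``a = 0`` is uniform; for
    ``a < 0`` dissimilarity is favoured, ``w = floor + 1 - exp(...)`` (the
    uniform floor keeps the weights positive when all candidates are
    identical to the chooser).
    """
    d2 = (np.asarray(x_candidates, dtype=float) - x_mother) ** 2
    if a_mother == 0.0:
        return np.ones_like(d2)
    g = np.exp(-(a_mother * a_mother) * d2 / (2.0 * gen.sigma_mate ** 2))
    if a_mother > 0.0:
        return g
    return floor + 1.0 - g


def choose_mate(x_mother: float, a_mother: float,
                x_candidates: np.ndarray, gen: GeneticParameters,
                rng: np.random.Generator) -> int:
    """Sample the index of the father among the candidates (>= 1 required)."""
    x_candidates = np.asarray(x_candidates, dtype=float)
    if len(x_candidates) == 0:
        raise ValueError("no mating candidates")
    w = mate_choice_weights(x_mother, a_mother, x_candidates, gen)
    tot = w.sum()
    if tot <= 0.0:
        w = np.ones_like(w)
        tot = w.sum()
    return int(rng.choice(len(x_candidates), p=w / tot))


def make_offspring(mother: Genotype, father: Genotype,
                   gen: GeneticParameters, rng: np.random.Generator) -> Genotype:
    """Free recombination plus per-allele Gaussian mutation."""
    x_m = _gametes(mother.x_alleles.reshape(1, -1), rng)[0]
    x_f = _gametes(father.x_alleles.reshape(1, -1), rng)[0]
    a_m = _gametes(mother.a_alleles.reshape(1, -1), rng)[0]
    a_f = _gametes(father.a_alleles.reshape(1, -1), rng)[0]
    x_all = np.concatenate([x_m, x_f])
    a_all = np.concatenate([a_m, a_f])
    x_all = _mutate(x_all.reshape(1, -1), gen, rng, bounded=False)[0]
    a_all = _mutate(a_all.reshape(1, -1), gen, rng, bounded=True)[0]
    return Genotype(x_all, a_all)


def _gametes(alleles: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One haploid gamete per row: per locus, one of the two parental alleles.

    ``alleles`` has shape (n, 2 F) laid out as F maternal then F paternal
    copies; returns shape (n, F).
    """
    n, twoF = alleles.shape
    F = twoF // 2
    pick = rng.integers(0, 2, size=(n, F))
    idx = np.arange(F) + pick * F
    return np.take_along_axis(alleles, idx, axis=1)


def _mutate(alleles: np.ndarray, gen: GeneticParameters,
            rng: np.random.Generator, bounded: bool) -> np.ndarray:
    mask = rng.random(alleles.shape) < gen.nu
    kicks = rng.normal(0.0, gen.sigma, size=alleles.shape)
    out = alleles + mask * kicks
    if bounded:
        out = np.clip(out, -1.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# state construction and stepping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IBMConfig:
    """Run configuration for the individual-based simulation."""

    params: ModelParameters = field(default_factory=ModelParameters)
    genetics: GeneticParameters = field(default_factory=GeneticParameters)
    x0: float = 0.0             # ancestral niche trait
    a0: float = 0.0             # ancestral assortative-mating trait
    n0: int = 600               # founding population size
    init_profile: str = "juvenile"  # 'juvenile' | 'small' | 'large' | 'newborn'
    t_max: float = 20000.0      # days
    dt: float = 1.0
    record_every: float = 200.0
    ri_window: float = 1000.0   # days of matings pooled per RI estimate
    gap_split: float = 0.5      # trait gap defining species clusters
    mate_pool_max: int = 200    # subsample of candidate fathers (speed)

    def with_(self, **kw) -> "IBMConfig":
        return replace(self, **kw)


def _monomorphic_genotype(x0: float, a0: float, gen: GeneticParameters):
    return (np.full(2 * gen.F_x, x0 / (2 * gen.F_x)),
            np.full(2 * gen.F_a, a0))


def initial_state(config: IBMConfig, seed: int) -> IBMState:
    """Monomorphic founding population with the configured mass profile.

    Profiles: ``'newborn'`` all at ``m_b``; ``'juvenile'`` log-uniform over
    the juvenile range; ``'small'`` log-uniform below ``m_shift`` (a
    population dominated by small individuals); ``'large'`` log-uniform
    above ``m_shift`` (dominated by large individuals).
    """
    p, gen = config.params, config.genetics
    rng = np.random.default_rng(seed)
    n0 = config.n0
    lo, hi = {
        "newborn": (p.m_b, p.m_b),
        "juvenile": (p.m_b, p.m_mat),
        "small": (p.m_b, min(p.m_shift, p.m_mat)),
        "large": (min(p.m_shift, 0.99 * p.m_mat), p.m_mat),
    }[config.init_profile]
    if hi > lo:
        mass = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n0))
    else:
        mass = np.full(n0, lo)
    xa, aa = _monomorphic_genotype(config.x0, config.a0, gen)
    x_alleles = np.tile(xa, (n0, 1))
    a_alleles = np.tile(aa, (n0, 1))
    return IBMState(
        mass=mass,
        buffer=np.zeros(n0),
        x_alleles=x_alleles,
        a_alleles=a_alleles,
        x=x_alleles.sum(axis=1),
        a=a_alleles.mean(axis=1),
        ids=np.arange(n0, dtype=np.int64),
        mother=np.full(n0, -1, dtype=np.int64),
        father=np.full(n0, -1, dtype=np.int64),
        resources=p.R_max.copy(),
        time=0.0,
        next_id=n0,
        rng=rng,
    )


def step(state: IBMState, config: IBMConfig) -> IBMState:
    """Advance the population by one time step (in place; returns state).

    Fixed event order: (1) feeding, growth and buffer filling; (2)
    resource update (supply minus realized grazing); (3) mortality;
    (4) spawning with mate choice, recombination and mutation.
    """
    p, gen = config.params, config.genetics
    dt = config.dt
    rng = state.rng
    m = state.mass
    n = len(m)
    if n == 0:
        # resources relax towards their maxima
        state.resources = state.resources + dt * p.delta * (p.R_max - state.resources)
        state.time += dt
        return state

    # (1) feeding and growth
    w = diet_weight_matrix(m, p)
    A = attack_vector(state.x, p)
    e_j = w * A * (m[:, None] ** p.q) * state.resources
    etot = e_j.sum(axis=1)
    imax = p.h * m ** p.n_intake
    intake = etot * imax / (etot + imax)
    net = p.alpha * intake - p.k_maint * m ** p.p_met
    juv = m < p.m_mat
    gpos = np.maximum(net, 0.0)
    expo = 1.0 - p.n_intake
    c = gpos / np.maximum(m ** p.n_intake, 1e-300)
    m_new = (m ** expo + expo * c * dt) ** (1.0 / expo)
    state.mass = np.where(juv, np.minimum(m_new, p.m_mat), m)
    state.buffer = state.buffer + np.where(juv, 0.0, gpos) * dt

    # (2) semi-chemostat resources minus realized grazing (per volume)
    graz = (e_j * (imax / (etot + imax))[:, None]).sum(axis=0) / gen.V
    G = graz / np.maximum(state.resources, 1e-30)
    state.resources = (state.resources + dt * p.delta * p.R_max) / (
        1.0 + dt * (p.delta + G)
    )

    # (3) mortality
    mu = p.mu0 * state.mass ** p.mort_exp \
        + p.xi_starv * np.maximum(-net, 0.0) / state.mass
    survive = rng.random(n) >= -np.expm1(-mu * dt)

    # (4) spawning: mothers whose buffer covers at least one egg
    egg_cost = p.m_b / p.eps_egg
    mature = state.mass >= p.m_mat
    spawners = np.flatnonzero(mature & survive & (state.buffer >= egg_cost))
    moms, dads, clutch = [], [], []
    if len(spawners) > 0:
        cand_idx = np.flatnonzero(mature & survive)
        for i in spawners:
            pool = cand_idx[cand_idx != i]
            if len(pool) == 0:
                continue  # no available father this event
            if len(pool) > config.mate_pool_max:
                pool = rng.choice(pool, size=config.mate_pool_max, replace=False)
            j = pool[choose_mate(state.x[i], state.a[i], state.x[pool], gen, rng)]
            n_off = int(state.buffer[i] // egg_cost)
            state.buffer[i] -= n_off * egg_cost
            state.mating_log.append(
                (state.time, int(state.ids[i]), int(state.ids[j]),
                 float(state.x[i]), float(state.x[j]))
            )
            moms.append(i)
            dads.append(int(j))
            clutch.append(n_off)
    offspring_n = int(sum(clutch))
    if offspring_n:
        # one row per offspring: free recombination then mutation, batched
        mi = np.repeat(moms, clutch)
        fi = np.repeat(dads, clutch)
        ox = np.concatenate([
            _gametes(state.x_alleles[mi], rng),
            _gametes(state.x_alleles[fi], rng),
        ], axis=1)
        oa = np.concatenate([
            _gametes(state.a_alleles[mi], rng),
            _gametes(state.a_alleles[fi], rng),
        ], axis=1)
        ox = _mutate(ox, gen, rng, bounded=False)
        oa = _mutate(oa, gen, rng, bounded=True)
        off_mother = state.ids[mi]
        off_father = state.ids[fi]

    # apply mortality, append offspring
    keep = survive
    mass = state.mass[keep]
    buffer = state.buffer[keep]
    x_all = state.x_alleles[keep]
    a_all = state.a_alleles[keep]
    xs = state.x[keep]
    as_ = state.a[keep]
    ids = state.ids[keep]
    mo = state.mother[keep]
    fa = state.father[keep]
    if offspring_n:
        k = offspring_n
        mass = np.concatenate([mass, np.full(k, p.m_b)])
        buffer = np.concatenate([buffer, np.zeros(k)])
        x_all = np.concatenate([x_all, ox])
        a_all = np.concatenate([a_all, oa])
        xs = np.concatenate([xs, ox.sum(axis=1)])
        as_ = np.concatenate([as_, oa.mean(axis=1)])
        ids = np.concatenate([ids, state.next_id + np.arange(k, dtype=np.int64)])
        mo = np.concatenate([mo, off_mother])
        fa = np.concatenate([fa, off_father])
        state.next_id += k
    state.mass, state.buffer = mass, buffer
    state.x_alleles, state.a_alleles = x_all, a_all
    state.x, state.a = xs, as_
    state.ids, state.mother, state.father = ids, mo, fa
    state.time += dt
    return state


# ---------------------------------------------------------------------------
# clustering and reproductive isolation
# ---------------------------------------------------------------------------

def cluster_species(traits, gap_split: float = 0.5):
    """One-dimensional gap clustering of niche traits.

    Splits the sorted traits wherever adjacent values differ by more than
    ``gap_split``; returns ``(assignment, n_clusters)`` with clusters
    numbered in order of increasing mean trait.
    """
    xs = np.atleast_1d(np.asarray(traits, dtype=float))
    if len(xs) == 0:
        raise ValueError("need at least one individual to cluster")
    order = np.argsort(xs)
    sorted_x = xs[order]
    breaks = np.flatnonzero(np.diff(sorted_x) > gap_split)
    labels_sorted = np.zeros(len(xs), dtype=int)
    for b in breaks:
        labels_sorted[b + 1:] += 1
    labels = np.empty(len(xs), dtype=int)
    labels[order] = labels_sorted
    return labels, len(breaks) + 1


def reproductive_isolation(mating_records, cluster_edges) -> float:
    """Reproductive-isolation index of a window of matings, in [0, 1].

    ``cluster_edges`` are the trait values separating clusters (e.g. the
    midpoints of the gaps found by :func:`cluster_species`).  Each mating
    partner is assigned to a cluster by its recorded niche trait.  With
    ``p_obs`` the observed fraction of between-cluster matings and
    ``p_exp = 1 - sum_k f_k^2`` the fraction expected under random mating
    given the partner cluster frequencies ``f_k``,

        RI = 1 - p_obs / p_exp,   clipped to [0, 1];

    0 means random mating across clusters, 1 complete isolation.  Returns
    ``nan`` when the window is empty or only one cluster is represented.
    """
    recs = list(mating_records)
    if not recs:
        return math.nan
    edges = np.sort(np.atleast_1d(np.asarray(cluster_edges, dtype=float)))
    xm = np.array([r[-2] for r in recs])
    xf = np.array([r[-1] for r in recs])
    cm = np.searchsorted(edges, xm)
    cf = np.searchsorted(edges, xf)
    allc = np.concatenate([cm, cf])
    _, counts = np.unique(allc, return_counts=True)
    freqs = counts / counts.sum()
    p_exp = 1.0 - float(np.sum(freqs ** 2))
    if p_exp <= 0.0:
        return math.nan
    p_obs = float(np.mean(cm != cf))
    return float(np.clip(1.0 - p_obs / p_exp, 0.0, 1.0))


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------

@dataclass
class IBMResult:
    """Snapshots, mating records and final state of one simulation."""

    snapshots: pd.DataFrame      # time, id, mass, x, a, mature
    series: pd.DataFrame         # time, n, n_mature, mean_a, n_clusters, RI, resources
    state: IBMState
    config: IBMConfig
    seed: int
    extinct: bool = False

    @property
    def mating_records(self) -> list:
        return self.state.mating_log


def run_ibm(config: IBMConfig, seed: int,
            snapshot_mature_only: bool = True) -> IBMResult:
    """Run the individual-based model to ``t_max`` (explicit seed required).

    Records, every ``record_every`` days, the phenotypes of the mature
    individuals, the population mean assortative-mating trait, the
    species-cluster count of the mature niche traits, and the
    reproductive-isolation index of the matings in the trailing
    ``ri_window`` days.
    """
    if seed is None:
        raise ValueError("an explicit seed is required")
    state = initial_state(config, seed)
    snaps, series = [], []
    nsteps = int(round(config.t_max / config.dt))
    rec = max(int(round(config.record_every / config.dt)), 1)
    extinct = False
    for k in range(nsteps):
        step(state, config)
        if (k + 1) % rec == 0 or k == nsteps - 1:
            _record(state, config, snaps, series, snapshot_mature_only)
        if state.n == 0:
            extinct = True
            _record(state, config, snaps, series, snapshot_mature_only)
            break
    return IBMResult(
        snapshots=pd.DataFrame(
            snaps, columns=["time", "id", "mass", "x", "a", "mature"]),
        series=pd.DataFrame(series),
        state=state, config=config, seed=seed, extinct=extinct,
    )


def _record(state: IBMState, config: IBMConfig, snaps: list, series: list,
            mature_only: bool) -> None:
    p = config.params
    mature = state.mass >= p.m_mat
    sel = np.flatnonzero(mature) if mature_only else np.arange(state.n)
    for i in sel:
        snaps.append((state.time, int(state.ids[i]), float(state.mass[i]),
                      float(state.x[i]), float(state.a[i]), bool(mature[i])))
    row = {
        "time": state.time,
        "n": state.n,
        "n_mature": int(mature.sum()),
        "mean_a": float(state.a.mean()) if state.n else math.nan,
        "R_s": state.resources[SHARED],
    }
    for j in range(p.n_resources):
        row[f"R_{j + 1}"] = state.resources[SHARED + 1 + j]
    if mature.any():
        labels, ncl = cluster_species(state.x[mature], config.gap_split)
        row["n_clusters"] = ncl
        xs = np.sort(state.x[mature])
        gaps = np.flatnonzero(np.diff(xs) > config.gap_split)
        edges = [0.5 * (xs[g] + xs[g + 1]) for g in gaps]
        window = [r for r in state.mating_log
                  if r[0] > state.time - config.ri_window]
        row["RI"] = (reproductive_isolation(window, edges)
                     if ncl >= 2 and window else math.nan)
    else:
        row["n_clusters"] = 0
        row["RI"] = math.nan
    series.append(row)
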