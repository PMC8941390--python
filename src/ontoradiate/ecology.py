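"""Population-level ecology at equilibrium.

The population dynamics are those of a physiologically structured
population: a density ``b_i`` of newborns per unit volume and time enters
at mass ``m_b``, individuals grow, die and reproduce according to the
individual-level rates of :mod:`.model_core`, and resources follow
semi-chemostat dynamics ``dR_j/dt = delta (R_j,max - R_j) - grazing``.

Because residents at equilibrium experience a constant environment, the
life history reduces to one-dimensional quadratures along body mass:

* age at mass,    ``t(m)   = int dm' / g(m')``
* survival,       ``ln S(m) = -int mu(m') / g(m') dm'``
* lifetime consumption per newborn, ``C_j = int c_j(m') S(m') / g(m') dm'``

with the adult stage (determinate growth at ``m_mat``) closed
analytically.  Equilibria satisfy ``R0_i = 1`` for every extant resident
together with the resource balance, and are located with a quasi-Newton
root solve; branches are traced in any parameter by pseudo-arclength
continuation.  Stability is classified by simulating a cohort-discretized
approximation of the full dynamics from a perturbed state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_simpson
from scipy.optimize import root

from .model_core import (
    SHARED,
    ModelParameters,
    ResourceEnvironment,
    attack_vector,
)

__all__ = [
    "LifeHistorySolution",
    "ResidentCoalition",
    "EquilibriumState",
    "EquilibriumError",
    "integrate_life_history",
    "growth_curve",
    "resource_balance_residual",
    "solve_equilibrium",
    "find_stable_equilibria",
    "continue_in_parameter",
    "BranchSet",
    "bistability_window",
    "CohortSimulator",
    "classify_stability",
    "set_parameter",
    "get_parameter",
]

# default numerical controls
N_GRID = 385          # quadrature points per mass segment (odd, Simpson)
S_MIN = 1e-12         # survival cutoff for time-domain truncation
R0_TOL = 1e-8         # |ln R0| tolerance at equilibrium
BALANCE_TOL = 1e-8    # scaled resource-balance tolerance
B_FLOOR = 1e-14       # birth rates below this count as extinct


class EquilibriumError(RuntimeError):
    """Raised when no equilibrium could be located; carries diagnostics."""

    def __init__(self, message: str, best_residual: float | None = None):
        super().__init__(message)
        self.best_residual = best_residual


# ---------------------------------------------------------------------------
# life-history integration
# ---------------------------------------------------------------------------

@dataclass
class LifeHistorySolution:
    """Life history of one trait value in a fixed resource environment."""

    x: float
    age: np.ndarray          # days
    mass: np.ndarray         # g
    survival: np.ndarray     # S(age), from 1
    offspring: np.ndarray    # cumulative expected offspring B(age)
    R0: float                # lifetime reproductive number
    consumption: np.ndarray  # lifetime discounted consumption C_j per newborn (g)
    matured: bool
    ln_S_mat: float          # ln survival to maturation (-inf if never)
    age_at_shift: float      # nan if the diet shift is never reached
    age_at_maturation: float # nan if maturation is never reached
    stagnation_mass: float   # nan unless growth stalls before maturation
    standing_small: float    # int m S dt over m < m_shift (g day per newborn)
    standing_large: float    # same over m >= m_shift

    @property
    def S_mat(self) -> float:
        return math.exp(self.ln_S_mat) if self.ln_S_mat > -745 else 0.0


def _segment_weights(side: str, params: ModelParameters) -> np.ndarray | None:
    """Fixed diet-weight row for a 'pre' or 'post' shift segment."""
    n = params.n_resources
    w = np.zeros(1 + n)
    if side == "pre":
        w[SHARED] = 1.0
    elif side == "post":
        w[SHARED] = 1.0 if params.shift_mode == "broadening" else 0.0
        w[SHARED + 1:] = 1.0
    else:
        return None  # gradual: mass-dependent
    return w


def _segments(params: ModelParameters) -> list[tuple[float, float, str]]:
    mb, msh, mmat = params.m_b, params.m_shift, params.m_mat
    if params.shift_mode == "gradual":
        return [(mb, mmat, "auto")]
    if msh <= mb:
        return [(mb, mmat, "post")]
    if msh >= mmat:
        return [(mb, mmat, "pre")]
    return [(mb, msh, "pre"), (msh, mmat, "post")]


def _adult_side(params: ModelParameters) -> str:
    if params.shift_mode == "gradual":
        return "auto"
    return "post" if params.m_mat >= params.m_shift else "pre"


def _rates_at(m: np.ndarray, a: np.ndarray, envv: np.ndarray,
              params: ModelParameters, side: str):
    """Vital rates along a mass grid with a fixed diet side.

    Returns (growth, mortality, per-resource consumption, net energy).
    """
    if side == "auto":
        from .model_core import diet_weight_matrix
        w = diet_weight_matrix(m, params)
    else:
        w = np.broadcast_to(_segment_weights(side, params), m.shape + (len(envv),))
    e_j = w * a * (m[:, None] ** params.q) * envv
    etot = e_j.sum(axis=-1)
    imax = params.h * m ** params.n_intake
    intake = etot * imax / (etot + imax)
    net = params.alpha * intake - params.k_maint * m ** params.p_met
    growth = np.maximum(net, 0.0)
    mu = params.mu0 * m ** params.mort_exp \
        + params.xi_starv * np.maximum(-net, 0.0) / m
    cons = e_j * (imax / (etot + imax))[:, None]
    return growth, mu, cons, net


def integrate_life_history(
    x: float,
    env,
    params: ModelParameters,
    n_grid: int = N_GRID,
) -> LifeHistorySolution:
    """Integrate the life history of trait ``x`` in a fixed environment.

    Quadrature is composite Simpson on a log-mass grid per diet segment,
    with the diet-shift discontinuity an exact segment boundary.  If net
    energy turns non-positive before maturation the individual stalls
    there: it keeps consuming and dying (with the starvation surcharge)
    but never matures, so ``R0 = 0``.
    """
    envv = env.vector if isinstance(env, ResourceEnvironment) else np.asarray(env, float)
    a = attack_vector(x, params)
    nres = len(envv)

    ages: list[np.ndarray] = []
    masses: list[np.ndarray] = []
    ln_surv: list[np.ndarray] = []
    C = np.zeros(nres)
    stand = {"small": 0.0, "large": 0.0}
    t0, lnS0 = 0.0, 0.0
    age_at_shift = math.nan
    stagnation_mass = math.nan
    matured = True

    for m_lo, m_hi, side in _segments(params):
        xi = np.linspace(math.log(m_lo), math.log(m_hi), n_grid)
        m = np.exp(xi)
        m[0], m[-1] = m_lo, m_hi
        g, mu, cons, net = _rates_at(m, a, envv, params, side)

        stalled = g <= 0.0
        if stalled.any():
            k = int(np.argmax(stalled))
            if k == 0:
                # stalls immediately at the segment boundary
                m_star, mu_star, c_star = m[0], mu[0], cons[0]
                S_star = math.exp(lnS0) if lnS0 > -745 else 0.0
                C += c_star * S_star / mu_star
                side_key = "small" if m_star < params.m_shift else "large"
                stand[side_key] += m_star * S_star / mu_star
                stagnation_mass = m_star
                matured = False
                ages.append(np.array([t0]))
                masses.append(np.array([m_star]))
                ln_surv.append(np.array([lnS0]))
                break
            xi = xi[:k]
            m, g, mu, cons = m[:k], g[:k], mu[:k], cons[:k]

        inv_g = m / g  # dt/dxi
        t = t0 + cumulative_simpson(inv_g, x=xi, initial=0.0)
        lnS = lnS0 + cumulative_simpson(-mu * inv_g, x=xi, initial=0.0)
        with np.errstate(under="ignore"):
            S = np.exp(np.maximum(lnS, -745.0))
            S[lnS <= -745.0] = 0.0
        C += _simpson(cons * (S * inv_g)[:, None], xi)
        bio = _simpson_cum(m * S * inv_g, xi)
        small_mask = m < params.m_shift
        if small_mask.all():
            stand["small"] += bio[-1]
        elif not small_mask.any():
            stand["large"] += bio[-1]
        else:
            ksplit = int(np.argmin(small_mask))
            stand["small"] += bio[max(ksplit - 1, 0)]
            stand["large"] += bio[-1] - bio[max(ksplit - 1, 0)]

        ages.append(t)
        masses.append(m)
        ln_surv.append(lnS)
        if math.isnan(age_at_shift) and m_hi >= params.m_shift > m_lo:
            age_at_shift = float(t[-1])
        if params.m_shift <= params.m_b and math.isnan(age_at_shift):
            age_at_shift = 0.0

        if stalled.any():
            m_star, mu_star, c_star = m[-1], mu[-1], cons[-1]
            S_star = S[-1]
            C += c_star * S_star / mu_star
            side_key = "small" if m_star < params.m_shift else "large"
            stand[side_key] += m_star * S_star / mu_star
            stagnation_mass = float(m_star)
            matured = False
            break
        t0, lnS0 = float(t[-1]), float(lnS[-1])

    age = np.concatenate(ages)
    mass = np.concatenate(masses)
    lnS_all = np.concatenate(ln_surv)

    R0 = 0.0
    age_at_mat = math.nan
    ln_S_mat = -math.inf
    B = np.zeros_like(age)
    if matured:
        age_at_mat = t0
        ln_S_mat = lnS0
        S_mat = math.exp(ln_S_mat) if ln_S_mat > -745 else 0.0
        g_ad, mu_ad, c_ad, net_ad = _rates_at(
            np.array([params.m_mat]), a, envv, params, _adult_side(params)
        )
        mu_ad = float(mu_ad[0])
        net_ad = float(net_ad[0])
        beta = params.eps_egg * max(net_ad, 0.0) / params.m_b
        R0 = S_mat * beta / mu_ad
        C += c_ad[0] * S_mat / mu_ad
        side_key = "large" if params.m_mat >= params.m_shift else "small"
        stand[side_key] += params.m_mat * S_mat / mu_ad
        # append an adult tail so that B(final age) == R0
        s_tail = np.array([0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 40.0])
        age = np.concatenate([age, age_at_mat + s_tail / mu_ad])
        mass = np.concatenate([mass, np.full(s_tail.shape, params.m_mat)])
        lnS_all = np.concatenate([lnS_all, ln_S_mat - s_tail])
        B = np.concatenate([B, R0 * -np.expm1(-s_tail)])
        B[-1] = R0

    with np.errstate(under="ignore"):
        surv = np.exp(np.maximum(lnS_all, -745.0))
        surv[lnS_all <= -745.0] = 0.0

    return LifeHistorySolution(
        x=float(x), age=age, mass=mass, survival=surv, offspring=B,
        R0=float(R0), consumption=C, matured=matured, ln_S_mat=ln_S_mat,
        age_at_shift=age_at_shift, age_at_maturation=age_at_mat,
        stagnation_mass=stagnation_mass,
        standing_small=stand["small"], standing_large=stand["large"],
    )


def _simpson(y: np.ndarray, x: np.ndarray):
    from scipy.integrate import simpson
    return simpson(y, x=x, axis=0)


def _simpson_cum(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    return cumulative_simpson(y, x=x, initial=0.0)


def growth_curve(x: float, env, params: ModelParameters,
                 n_grid: int = N_GRID) -> pd.DataFrame:
    """Age–mass trajectory with the diet-shift and maturation crossings.

    Returns a data frame with columns ``age``, ``mass``, ``survival`` and
    attributes ``age_at_shift`` / ``age_at_maturation`` in ``df.attrs``.
    """
    lh = integrate_life_history(x, env, params, n_grid=n_grid)
    df = pd.DataFrame({"age": lh.age, "mass": lh.mass, "survival": lh.survival})
    df.attrs["age_at_shift"] = lh.age_at_shift
    df.attrs["age_at_maturation"] = lh.age_at_maturation
    df.attrs["stagnation_mass"] = lh.stagnation_mass
    return df


# ---------------------------------------------------------------------------
# coalition, equilibrium state
# ---------------------------------------------------------------------------

@dataclass
class ResidentCoalition:
    """Resident species: niche traits and population birth rates."""

    traits: np.ndarray   # (N,)
    b: np.ndarray        # newborns m^-3 day^-1, (N,)

    def __post_init__(self) -> None:
        self.traits = np.atleast_1d(np.asarray(self.traits, dtype=float))
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        if self.traits.shape != self.b.shape:
            raise ValueError("traits and b must have the same length")

    @property
    def n_species(self) -> int:
        return len(self.traits)

    @property
    def extant(self) -> np.ndarray:
        return self.b > B_FLOOR


@dataclass
class EquilibriumState:
    coalition: ResidentCoalition
    env: ResourceEnvironment
    params: ModelParameters
    stability: str = "unknown"   # 'stable' | 'unstable' | 'unknown'
    residual_norm: float = math.nan
    life_histories: list[LifeHistorySolution] = field(default_factory=list)

    @property
    def traits(self) -> np.ndarray:
        return self.coalition.traits


def resource_balance_residual(coalition: ResidentCoalition, env,
                              params: ModelParameters,
                              life_histories=None) -> np.ndarray:
    """Semi-chemostat balance ``delta (R_max - R) - sum_i b_i C_ij``."""
    envv = env.vector if isinstance(env, ResourceEnvironment) else np.asarray(env, float)
    if life_histories is None:
        life_histories = [
            integrate_life_history(x, envv, params) for x in coalition.traits
        ]
    grazing = np.zeros_like(envv)
    for bi, lh in zip(coalition.b, life_histories):
        grazing += bi * lh.consumption
    return params.delta * (params.R_max - envv) - grazing


# ---------------------------------------------------------------------------
# equilibrium solving
# ---------------------------------------------------------------------------

def _b_guess(traits: np.ndarray, envv: np.ndarray,
             params: ModelParameters) -> np.ndarray:
    """Birth rates consistent with total supply at the guessed environment."""
    lhs = [integrate_life_history(x, envv, params) for x in traits]
    supply = float(np.sum(params.delta * (params.R_max - envv)))
    supply = max(supply, 1e-3 * float(np.sum(params.delta * params.R_max)))
    ctot = np.array([max(lh.consumption.sum(), 1e-9) for lh in lhs])
    return np.full(len(traits), supply) / (len(traits) * ctot)


def default_guesses(traits, params: ModelParameters) -> list[dict]:
    """Deterministic multi-start list covering both size-structure regimes."""
    traits = np.atleast_1d(np.asarray(traits, dtype=float))
    rmax = params.R_max
    guesses = []
    for fs, fc, bscale in [(0.9, 0.9, 0.1), (0.5, 0.5, 1.0), (0.85, 0.25, 1.0),
                           (0.08, 0.85, 1.0), (0.95, 0.95, 0.02),
                           (0.3, 0.08, 1.0), (0.5, 0.9, 0.3), (0.02, 0.4, 1.0)]:
        envv = rmax * np.concatenate(([fs], np.full(params.n_resources, fc)))
        guesses.append({"env": envv,
                        "b": bscale * _b_guess(traits, envv, params)})
    # juvenile-bottleneck starts: shared resource just above the density at
    # which newborn growth stalls (feeding level = critical feeding level)
    if params.m_shift > params.m_b:
        r_crit = (params.f_crit / (1.0 - params.f_crit)
                  * params.h / params.A_max
                  * params.m_b ** (params.n_intake - params.q))
        for fac in (1.12, 1.4):
            rs = min(fac * r_crit, 0.95 * rmax[SHARED])
            envv = np.concatenate(([rs], 0.92 * rmax[1:]))
            guesses.append({"env": envv, "b": _b_guess(traits, envv, params)})
    return guesses


def _solve_fixed_coalition(traits: np.ndarray, params: ModelParameters,
                           envv0: np.ndarray, b0: np.ndarray):
    """Root solve on (log R, b) for a fixed set of residents."""
    n = len(traits)

    def residual(u):
        envv = np.exp(np.clip(u[: len(envv0)], -60.0, 10.0))
        b = u[len(envv0):]
        lhs = [integrate_life_history(x, envv, params) for x in traits]
        graz = np.zeros_like(envv)
        for bi, lh in zip(b, lhs):
            graz += bi * lh.consumption
        bal = (params.delta * (params.R_max - envv) - graz) / (
            params.delta * params.R_max
        )
        r0 = np.array([math.log(max(lh.R0, 1e-30)) for lh in lhs])
        return np.concatenate([bal, r0])

    u0 = np.concatenate([np.log(np.maximum(envv0, 1e-20)), b0])
    sol = root(residual, u0, method="hybr", options={"xtol": 1e-12, "maxfev": 4000})
    envv = np.exp(np.clip(sol.x[: len(envv0)], -60.0, 10.0))
    b = sol.x[len(envv0):]
    res = residual(sol.x)
    return sol, envv, b, float(np.max(np.abs(res)))


def solve_equilibrium(
    traits,
    params: ModelParameters,
    guess: dict | EquilibriumState | None = None,
    classify: bool = False,
    tol: float = 1e-7,
) -> EquilibriumState:
    """Solve for the ecological equilibrium of a resident coalition.

    Unknowns are the log resource densities and the linear birth rates;
    residents for which no positive birth rate exists are removed and
    reported extinct (``b = 0``).  Raises :class:`EquilibriumError` when
    no starting point converges.
    """
    traits = np.atleast_1d(np.asarray(traits, dtype=float))
    # residents that cannot replace themselves even in the consumer-free
    # environment can never persist (R0 is monotone in the resources)
    pristine = params.R_max
    viable = np.array([
        integrate_life_history(x, pristine, params).R0 > 1.0 for x in traits
    ])
    if not viable.any():
        env = ResourceEnvironment.pristine(params)
        coal = ResidentCoalition(traits, np.zeros(len(traits)))
        return EquilibriumState(coal, env, params, "stable", 0.0, [
            integrate_life_history(x, pristine, params) for x in traits
        ])
    if guess is None:
        starts = default_guesses(traits, params)
    elif isinstance(guess, EquilibriumState):
        b0 = np.maximum(guess.coalition.b, B_FLOOR * 10)
        if len(b0) != len(traits):
            b0 = np.full(len(traits), max(b0.mean(), B_FLOOR * 10))
        starts = [{"env": guess.env.vector.copy(), "b": b0}]
        starts += default_guesses(traits, params)
    else:
        starts = [guess] + default_guesses(traits, params)

    keep = np.arange(len(traits))
    best = math.inf
    for attempt in range(len(traits) + 1):
        sub = traits[keep]
        if len(sub) == 0:
            env = ResourceEnvironment.pristine(params)
            coal = ResidentCoalition(traits, np.zeros(len(traits)))
            return EquilibriumState(coal, env, params, "stable", 0.0, [])
        solved = None
        for st in starts:
            b0 = np.asarray(st["b"], dtype=float)
            if len(b0) != len(sub):
                b0 = np.full(len(sub), max(float(np.mean(b0)), B_FLOOR * 10))
            sol, envv, b, resnorm = _solve_fixed_coalition(
                sub, params, np.asarray(st["env"], float), b0
            )
            best = min(best, resnorm)
            if resnorm < tol:
                solved = (envv, b, resnorm)
                break
        if solved is None:
            raise EquilibriumError(
                f"no equilibrium found for traits {traits}", best_residual=best
            )
        envv, b, resnorm = solved
        if np.all(b > -1e-10) and np.all(b[b > 0] >= 0):
            b = np.maximum(b, 0.0)
            negligible = b <= B_FLOOR
            if negligible.any() and not negligible.all():
                keep = keep[~negligible]
                starts = [{"env": envv, "b": b[~negligible]}] + starts
                continue
            full_b = np.zeros(len(traits))
            full_b[keep] = b
            coal = ResidentCoalition(traits, full_b)
            env = ResourceEnvironment.from_vector(envv)
            lhs = [integrate_life_history(x, envv, params) for x in traits]
            state = EquilibriumState(coal, env, params, "unknown", resnorm, lhs)
            if classify:
                state.stability = classify_stability(state, params)
            return state
        # drop the most negative resident and retry
        worst = keep[int(np.argmin(b))]
        keep = keep[keep != worst]
        starts = [{"env": envv, "b": np.maximum(b[b > 0], B_FLOOR * 10)}] + starts
    raise EquilibriumError(f"no equilibrium found for traits {traits}",
                           best_residual=best)


def find_stable_equilibria(traits, params: ModelParameters,
                           classify: bool = True) -> list[EquilibriumState]:
    """Multi-start search returning the distinct equilibria (deduplicated).

    Used to expose ecological bistability: with an ontogenetic diet shift
    there may be one equilibrium dominated by stunted small individuals
    and one dominated by large individuals.
    """
    traits = np.atleast_1d(np.asarray(traits, dtype=float))
    found: list[EquilibriumState] = []
    for st in default_guesses(traits, params):
        try:
            eq = solve_equilibrium(traits, params, guess=st)
        except EquilibriumError:
            continue
        dup = False
        for other in found:
            if np.allclose(other.env.vector, eq.env.vector, rtol=1e-4) and \
               np.allclose(other.coalition.b, eq.coalition.b, rtol=1e-3,
                           atol=B_FLOOR):
                dup = True
                break
        if not dup:
            found.append(eq)
    if classify:
        for eq in found:
            eq.stability = classify_stability(eq, params)
    return found


# ---------------------------------------------------------------------------
# parameter handling and continuation
# ---------------------------------------------------------------------------

def set_parameter(params: ModelParameters, name: str, value: float) -> ModelParameters:
    """Set a continuation parameter; ``supply_s`` means ``delta * R_s_max``."""
    if name == "supply_s":
        return params.with_(R_s_max=value / params.delta)
    if name == "productivity_ratio":  # R_s_max / R_c_max at fixed R_c_max
        rc = float(np.mean(np.atleast_1d(params.R_c_max)))
        return params.with_(R_s_max=value * rc)
    return params.with_(**{name: value})


def get_parameter(params: ModelParameters, name: str) -> float:
    if name == "supply_s":
        return params.delta * params.R_s_max
    if name == "productivity_ratio":
        rc = float(np.mean(np.atleast_1d(params.R_c_max)))
        return params.R_s_max / rc
    return float(getattr(params, name))


@dataclass
class BranchSet:
    """Equilibria along a parameter: continuation points, folds, stability."""

    points: pd.DataFrame
    folds: list[float]
    parameter: str

    def stable_mask(self) -> np.ndarray:
        return (self.points["stability"] == "stable").to_numpy()


def _point_record(p_val: float, eq: EquilibriumState, params: ModelParameters) -> dict:
    rec = {"parameter": p_val}
    envv = eq.env.vector
    rec["R_s"] = envv[SHARED]
    for j in range(params.n_resources):
        rec[f"R_{j + 1}"] = envv[SHARED + 1 + j]
    small = large = 0.0
    for bi, lh in zip(eq.coalition.b, eq.life_histories):
        rec_small = bi * lh.standing_small
        rec_large = bi * lh.standing_large
        small += rec_small
        large += rec_large
    rec["biomass_small"] = small
    rec["biomass_large"] = large
    for i, (xi, bi) in enumerate(zip(eq.coalition.traits, eq.coalition.b)):
        rec[f"x_{i + 1}"] = xi
        rec[f"b_{i + 1}"] = bi
    rec["residual"] = eq.residual_norm
    return rec


def continue_in_parameter(
    traits,
    params: ModelParameters,
    parameter: str,
    p_range: tuple[float, float],
    step: float | None = None,
    max_points: int = 400,
    classify: str = "simulate",
    start_guess=None,
) -> BranchSet:
    """Pseudo-arclength continuation of an equilibrium branch.

    Tracks the branch from ``p_range[0]`` towards ``p_range[1]``, passing
    around folds (where the branch turns back in the parameter).  The
    ``stability`` column is classified per fold-delimited segment: one
    cohort-simulation classification per segment (``classify='simulate'``),
    every point inheriting its segment's label; folds swap stability.
    """
    traits = np.atleast_1d(np.asarray(traits, dtype=float))
    p_lo, p_hi = float(p_range[0]), float(p_range[1])
    span = abs(p_hi - p_lo)
    if step is None:
        step = span / 80.0
    direction = 1.0 if p_hi >= p_lo else -1.0

    p0 = p_lo
    eq0 = solve_equilibrium(traits, set_parameter(params, parameter, p0),
                            guess=start_guess)
    nres = 1 + params.n_resources

    def pack(eq: EquilibriumState, p: float) -> np.ndarray:
        return np.concatenate([
            np.log(np.maximum(eq.env.vector, 1e-20)),
            np.log(np.maximum(eq.coalition.b, 1e-20)),
            [p / max(span, 1e-12)],
        ])

    def solve_at(p: float, guess_eq: EquilibriumState) -> EquilibriumState:
        return solve_equilibrium(
            traits, set_parameter(params, parameter, p), guess=guess_eq
        )

    records: list[dict] = []
    eqs: list[EquilibriumState] = [eq0]
    ps: list[float] = [p0]
    records.append(_point_record(p0, eq0, params))

    # second point by natural continuation
    p1 = p0 + direction * step
    eq1 = solve_at(p1, eq0)
    eqs.append(eq1)
    ps.append(p1)
    records.append(_point_record(p1, eq1, params))

    p_floor = 1e-9 * max(abs(p_lo), abs(p_hi), 1.0)
    # cap on the per-step change of the pinned (fastest) log coordinate
    dc_max = 0.25

    folds: list[float] = []
    stretch = 1.0
    fails = 0
    while len(records) < max_points:
        z_prev, z_curr = pack(eqs[-2], ps[-2]), pack(eqs[-1], ps[-1])
        secant = z_curr - z_prev
        if np.linalg.norm(secant) == 0:
            break
        # pin the fastest-moving coordinate and predict along the secant
        c = int(np.argmax(np.abs(secant)))
        dc = float(np.clip(secant[c] * stretch, -dc_max, dc_max))
        z_pred = z_curr + secant * (dc / secant[c])
        c_target = z_curr[c] + dc

        def aug(u):
            envv = np.exp(np.clip(u[:nres], -60.0, 10.0))
            b = np.exp(np.clip(u[nres:-1], -60.0, 20.0))
            p = max(u[-1] * span, p_floor)
            pr = set_parameter(params, parameter, p)
            lhs = [integrate_life_history(x, envv, pr) for x in traits]
            graz = np.zeros_like(envv)
            for bi, lh in zip(b, lhs):
                graz += bi * lh.consumption
            bal = (pr.delta * (pr.R_max - envv) - graz) / (pr.delta * pr.R_max)
            r0 = np.array([math.log(max(lh.R0, 1e-30)) for lh in lhs])
            return np.concatenate([bal, r0, [u[c] - c_target]])

        sol = root(aug, z_pred, method="hybr", options={"xtol": 1e-12})
        ok = sol.success and np.max(np.abs(aug(sol.x)[:-1])) < 1e-7
        if not ok:
            stretch *= 0.5
            fails += 1
            if fails > 14:
                break
            continue
        fails = 0
        stretch = min(stretch * 1.4, 1.5)
        envv = np.exp(np.clip(sol.x[:nres], -60.0, 10.0))
        b = np.exp(np.clip(sol.x[nres:-1], -60.0, 20.0))
        p_new = max(sol.x[-1] * span, p_floor)
        pr = set_parameter(params, parameter, p_new)
        lhs = [integrate_life_history(x, envv, pr) for x in traits]
        eq_new = EquilibriumState(
            ResidentCoalition(traits, b), ResourceEnvironment.from_vector(envv),
            pr, "unknown", float(np.max(np.abs(aug(sol.x)[:-1]))), lhs,
        )
        # fold detection: parameter direction reversal
        if len(ps) >= 2 and (p_new - ps[-1]) * (ps[-1] - ps[-2]) < 0:
            folds.append(ps[-1])
        eqs.append(eq_new)
        ps.append(p_new)
        records.append(_point_record(p_new, eq_new, params))
        lo, hi = min(p_lo, p_hi), max(p_lo, p_hi)
        if p_new > hi + 1e-12 or p_new < lo - 1e-12:
            break
        if np.all(b <= B_FLOOR):
            break

    df = pd.DataFrame(records)
    # stability per fold-delimited segment
    labels = np.array(["unknown"] * len(df), dtype=object)
    seg_bounds = [0]
    for f in folds:
        idx = int(np.argmin(np.abs(df["parameter"].to_numpy() - f)))
        seg_bounds.append(idx)
    seg_bounds.append(len(df))
    seg_bounds = sorted(set(seg_bounds))
    seg_label = None
    for s, (i0, i1) in enumerate(zip(seg_bounds[:-1], seg_bounds[1:])):
        if i1 <= i0:
            continue
        if classify == "simulate":
            if seg_label is None:
                mid = (i0 + i1) // 2
                seg_label = classify_stability(eqs[mid], eqs[mid].params)
            labels[i0:i1] = seg_label
            seg_label = "unstable" if seg_label == "stable" else "stable"
        elif classify == "fold-rule":
            lab = "stable" if s % 2 == 0 else "unstable"
            labels[i0:i1] = lab
        else:
            labels[i0:i1] = "unknown"
    df["stability"] = labels
    for eq, lab in zip(eqs, labels):
        eq.stability = str(lab)
    return BranchSet(points=df, folds=folds, parameter=parameter)


def bistability_window(branch: BranchSet) -> tuple[float, float] | None:
    """Parameter interval with two stable equilibria, from the fold pair."""
    if len(branch.folds) < 2:
        return None
    lo, hi = sorted(branch.folds[:2])
    return (lo, hi)


# ---------------------------------------------------------------------------
# cohort-discretized dynamics (stability classification, invasion oracle)
# ---------------------------------------------------------------------------

class CohortSimulator:
    """Deterministic cohort approximation of the full structured dynamics.

    Each species is a set of cohorts ``(mass, number density)``; newborns
    enter at ``m_b``, cohorts grow with the transformed Euler update on
    ``m^(1-n)`` (exact for mass-power growth with a frozen feeding level),
    numbers decay by the realized mortality, and resources follow a
    positivity-preserving semi-implicit semi-chemostat update.
    """

    def __init__(self, traits, params: ModelParameters, envv=None,
                 dt: float = 1.0, max_cohorts: int = 600,
                 n_floor: float = 1e-16):
        self.params = params
        self.traits = np.atleast_1d(np.asarray(traits, dtype=float))
        self.attack = [attack_vector(x, params) for x in self.traits]
        self.envv = (params.R_max.copy() if envv is None
                     else np.asarray(envv, dtype=float).copy())
        self.dt = dt
        self.max_cohorts = max_cohorts
        self.n_floor = n_floor
        self.masses = [np.empty(0) for _ in self.traits]
        self.numbers = [np.empty(0) for _ in self.traits]
        self.time = 0.0

    @classmethod
    def from_equilibrium(cls, eq: EquilibriumState, n_cohorts: int = 120,
                         **kw) -> "CohortSimulator":
        sim = cls(eq.coalition.traits, eq.params, envv=eq.env.vector, **kw)
        p = eq.params
        for i, (bi, lh) in enumerate(zip(eq.coalition.b, eq.life_histories)):
            if bi <= B_FLOOR or not lh.matured:
                continue
            jmask = lh.mass < p.m_mat
            ages = lh.age[jmask]
            m = lh.mass[jmask]
            S = lh.survival[jmask]
            idx = np.unique(np.linspace(0, len(ages) - 1, n_cohorts).astype(int))
            a_edges = ages[idx]
            m_nodes = m[idx]
            S_nodes = S[idx]
            da = np.diff(a_edges)
            n_c = bi * 0.5 * (S_nodes[:-1] + S_nodes[1:]) * da
            m_c = np.sqrt(m_nodes[:-1] * m_nodes[1:])
            keep = n_c > sim.n_floor
            m_c, n_c = m_c[keep], n_c[keep]
            # adult cohort
            mu_ad = p.mu0 * p.m_mat ** p.mort_exp
            n_ad = bi * lh.S_mat / mu_ad
            sim.masses[i] = np.concatenate([m_c, [p.m_mat]])
            sim.numbers[i] = np.concatenate([n_c, [n_ad]])
        return sim

    def total_biomass(self) -> float:
        return float(sum((m * n).sum() for m, n in zip(self.masses, self.numbers)))

    def biomass_split(self) -> tuple[float, float]:
        small = large = 0.0
        for m, n in zip(self.masses, self.numbers):
            sm = m < self.params.m_shift
            small += float((m[sm] * n[sm]).sum())
            large += float((m[~sm] * n[~sm]).sum())
        return small, large

    def step(self) -> None:
        p = self.params
        dt = self.dt
        grazing = np.zeros_like(self.envv)
        births = np.zeros(len(self.traits))
        from .model_core import diet_weight_matrix

        new_masses, new_numbers = [], []
        for i, x in enumerate(self.traits):
            m, n = self.masses[i], self.numbers[i]
            if len(m) == 0:
                new_masses.append(m)
                new_numbers.append(n)
                continue
            w = diet_weight_matrix(m, p)
            e_j = w * self.attack[i] * (m[:, None] ** p.q) * self.envv
            etot = e_j.sum(axis=-1)
            imax = p.h * m ** p.n_intake
            intake = etot * imax / (etot + imax)
            net = p.alpha * intake - p.k_maint * m ** p.p_met
            mu = p.mu0 * m ** p.mort_exp + p.xi_starv * np.maximum(-net, 0.0) / m
            grazing += (e_j * (imax / (etot + imax))[:, None] * n[:, None]).sum(axis=0)
            juv = m < p.m_mat
            gpos = np.maximum(net, 0.0)
            births[i] = float(
                (p.eps_egg * gpos[~juv] / p.m_b * n[~juv]).sum()
            )
            # growth: exact step of dm/dt = c m^n with frozen c
            mn = m.copy()
            c = np.where(m > 0, gpos / np.maximum(m ** p.n_intake, 1e-300), 0.0)
            expo = 1.0 - p.n_intake
            mn_new = (m ** expo + expo * c * dt * juv) ** (1.0 / expo)
            mn = np.minimum(np.where(juv, mn_new, m), p.m_mat)
            n = n * np.exp(-mu * dt)
            new_masses.append(mn)
            new_numbers.append(n)

        for i in range(len(self.traits)):
            m, n = new_masses[i], new_numbers[i]
            if births[i] * dt > 0:
                m = np.concatenate([[self.params.m_b], m])
                n = np.concatenate([[births[i] * dt], n])
            keep = n > self.n_floor
            m, n = m[keep], n[keep]
            # merge adult cohorts (all at m_mat) and thin when oversized
            ad = m >= self.params.m_mat
            if ad.sum() > 1:
                n_ad = n[ad].sum()
                m, n = np.concatenate([m[~ad], [self.params.m_mat]]), \
                    np.concatenate([n[~ad], [n_ad]])
            if len(m) > self.max_cohorts:
                order = np.argsort(m)
                m, n = m[order], n[order]
                # pairwise merge of the closest neighbours, number-weighted
                k = len(m) - self.max_cohorts
                gaps = np.diff(np.log(np.maximum(m, 1e-300)))
                idx = np.argsort(gaps)[:k]
                drop = np.zeros(len(m), dtype=bool)
                for j in sorted(idx, reverse=True):
                    if drop[j] or drop[j + 1]:
                        continue
                    tot = n[j] + n[j + 1]
                    if tot > 0:
                        m[j] = (m[j] * n[j] + m[j + 1] * n[j + 1]) / tot
                    n[j] = tot
                    drop[j + 1] = True
                m, n = m[~drop], n[~drop]
            self.masses[i], self.numbers[i] = m, n

        # semi-implicit positivity-preserving resource update
        G = grazing / np.maximum(self.envv, 1e-30)
        self.envv = (self.envv + dt * p.delta * p.R_max) / (1.0 + dt * (p.delta + G))
        self.time += dt

    def run(self, t_max: float, record_every: float = math.inf) -> pd.DataFrame:
        rows = []
        nsteps = int(round(t_max / self.dt))
        rec = max(int(round(record_every / self.dt)), 1) \
            if math.isfinite(record_every) else nsteps + 1
        for k in range(nsteps):
            self.step()
            if (k + 1) % rec == 0 or k == nsteps - 1:
                small, large = self.biomass_split()
                row = {"time": self.time, "R_s": self.envv[SHARED],
                       "biomass_small": small, "biomass_large": large}
                for j in range(self.params.n_resources):
                    row[f"R_{j + 1}"] = self.envv[SHARED + 1 + j]
                rows.append(row)
        return pd.DataFrame(rows)


def classify_stability(eq: EquilibriumState, params: ModelParameters | None = None,
                       perturbation: float = 0.05, t_max: float = 12000.0,
                       dt: float = 1.0) -> str:
    """Classify an equilibrium by perturb-and-simulate.

    The equilibrium is discretized into cohorts, all numbers scaled by
    ``1 + perturbation`` and resources nudged towards their maxima, then
    the cohort dynamics are run; the equilibrium is stable when the
    resource state returns to (a small neighbourhood of) the equilibrium
    rather than diverging to a different attractor.
    """
    params = params or eq.params
    if not np.any(eq.coalition.b > B_FLOOR):
        return "stable"  # consumer-free semi-chemostat state
    sim = CohortSimulator.from_equilibrium(eq, dt=dt)
    sim.numbers = [n * (1.0 + perturbation) for n in sim.numbers]
    sim.envv = sim.envv * (1.0 - perturbation) + params.R_max * perturbation
    ref = eq.env.vector
    sim.run(t_max * 0.25)
    d_early = np.linalg.norm(np.log(np.maximum(sim.envv, 1e-12) / np.maximum(ref, 1e-12)))
    sim.run(t_max * 0.75)
    d_late = np.linalg.norm(np.log(np.maximum(sim.envv, 1e-12) / np.maximum(ref, 1e-12)))
    if d_late < max(0.5 * d_early, 0.02):
        return "stable"
    return "unstable"
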