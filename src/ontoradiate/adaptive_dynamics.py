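"""Invasion analysis and long-term evolution of the niche trait.

Mutations are assumed rare and of small effect: the ecology settles on its
equilibrium between mutation events, and a mutant's fate is decided by its
invasion fitness, the log lifetime reproductive number in the resident
environment, ``s(x_mut) = ln R0(x_mut | E_resident)``.  Residents are
neutral (``s = 0``) at equilibrium.  Evolution proceeds by a trait
substitution sequence: each resident climbs its local selection gradient;
a resident that converges on a fitness minimum (an evolutionary branching
point) splits into two diverging daughters.  The engine is fully
deterministic — there is no random number generator anywhere in it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ecology import (
    EquilibriumError,
    EquilibriumState,
    integrate_life_history,
    solve_equilibrium,
)
from .model_core import ModelParameters

__all__ = [
    "SingularPoint",
    "EvoTrajectory",
    "invasion_fitness",
    "selection_gradient",
    "find_singular_points",
    "classify_singularity",
    "evolve_traits",
    "branching_distance_threshold",
    "species_count_grid",
    "count_species",
]

GRAD_STEP = 1e-4        # central-difference step for the selection gradient
CURV_STEP = 0.05        # step for the mutant curvature (second difference)
GRAD_TOL = 1e-3         # |gradient| below which a resident sits at a singular point
CURV_TOL = 1e-4         # |curvature| below which classification is degenerate
EPS_BRANCH = 0.05       # daughter offset at a branching event (trait units)


def invasion_fitness(x_mut: float, eq: EquilibriumState,
                     params: ModelParameters | None = None) -> float:
    """Log lifetime reproductive number of a rare mutant in ``eq``'s environment."""
    params = params or eq.params
    lh = integrate_life_history(x_mut, eq.env, params)
    return math.log(max(lh.R0, 1e-300))


def selection_gradient(resident: int | float, eq: EquilibriumState,
                       params: ModelParameters | None = None,
                       step: float = GRAD_STEP) -> float:
    """Local fitness gradient d s / d x_mut at a resident's trait value.

    ``resident`` may be an index into the coalition or a trait value.
    Central finite difference in the (fixed) resident environment.
    """
    params = params or eq.params
    x = (eq.coalition.traits[resident]
         if isinstance(resident, (int, np.integer)) else float(resident))
    sp = invasion_fitness(x + step, eq, params)
    sm = invasion_fitness(x - step, eq, params)
    return (sp - sm) / (2.0 * step)


def _mutant_curvature(x: float, eq: EquilibriumState, params: ModelParameters,
                      step: float = CURV_STEP) -> float:
    """Second derivative of invasion fitness in the fixed environment."""
    s0 = invasion_fitness(x, eq, params)
    sp = invasion_fitness(x + step, eq, params)
    sm = invasion_fitness(x - step, eq, params)
    return (sp - 2.0 * s0 + sm) / (step * step)


@dataclass
class SingularPoint:
    x: float
    classification: str          # 'CSS' | 'branching' | 'repeller' | 'degenerate'
    gradient: float
    curvature: float             # d2 s / d x_mut^2 at fixed environment
    convergence_slope: float     # d(gradient)/d(x_resident); < 0 => convergent


def classify_singularity(x_star: float, params: ModelParameters,
                         other_residents: np.ndarray | list | None = None,
                         conv_step: float = CURV_STEP,
                         eq_guess: EquilibriumState | None = None) -> SingularPoint:
    """Classify a singular trait value by its second-order conditions.

    Convergence stability is measured by re-solving the ecological
    equilibrium with the focal resident displaced by ``±conv_step`` and
    differencing the selection gradient; the mutant curvature is taken in
    the singular point's own equilibrium environment.  With other
    residents present, their traits are held fixed (their birth rates
    re-equilibrate).
    """
    others = list(other_residents) if other_residents is not None else []

    def eq_at(xi: float) -> EquilibriumState:
        return solve_equilibrium([xi] + others, params, guess=eq_guess)

    eq0 = eq_at(x_star)
    grad0 = selection_gradient(float(x_star), eq0, params)
    curv = _mutant_curvature(float(x_star), eq0, params)
    gp = selection_gradient(x_star + conv_step, eq_at(x_star + conv_step), params)
    gm = selection_gradient(x_star - conv_step, eq_at(x_star - conv_step), params)
    conv = (gp - gm) / (2.0 * conv_step)

    if abs(curv) <= CURV_TOL:
        cls = "degenerate"
    elif conv < 0.0 and curv > 0.0:
        cls = "branching"
    elif conv < 0.0 and curv < 0.0:
        cls = "CSS"
    else:
        cls = "repeller"
    return SingularPoint(float(x_star), cls, grad0, curv, conv)


def find_singular_points(params: ModelParameters,
                         interval: tuple[float, float],
                         other_residents=None,
                         n_scan: int = 25,
                         xtol: float = 1e-4,
                         classify: bool = True) -> list[SingularPoint]:
    """Locate singular strategies of a (focal-resident) fitness landscape.

    Scans the selection gradient of a monomorphic resident (plus optional
    fixed co-residents) on a grid over ``interval``, brackets its sign
    changes and bisects each bracket.
    """
    others = list(other_residents) if other_residents is not None else []
    xs = np.linspace(interval[0], interval[1], n_scan)

    def grad_at(xi: float) -> float:
        eq = solve_equilibrium([xi] + others, params)
        return selection_gradient(float(xi), eq, params)

    grads = [grad_at(x) for x in xs]
    points: list[SingularPoint] = []
    for a, b, ga, gb in zip(xs[:-1], xs[1:], grads[:-1], grads[1:]):
        if ga == 0.0:
            points.append((a, ga))
            continue
        if ga * gb < 0.0:
            lo, hi, glo = a, b, ga
            while hi - lo > xtol:
                mid = 0.5 * (lo + hi)
                gm = grad_at(mid)
                if glo * gm <= 0.0:
                    hi = mid
                else:
                    lo, glo = mid, gm
            points.append((0.5 * (lo + hi), grad_at(0.5 * (lo + hi))))
    out = []
    for x_star, g in points:
        if classify:
            out.append(classify_singularity(x_star, params, others))
        else:
            out.append(SingularPoint(float(x_star), "unclassified", g,
                                     math.nan, math.nan))
    return out


# ---------------------------------------------------------------------------
# trait substitution dynamics
# ---------------------------------------------------------------------------

@dataclass
class EvoTrajectory:
    """Record of a trait-substitution run."""

    times: list[float] = field(default_factory=list)
    traits: list[np.ndarray] = field(default_factory=list)
    branching_events: list[tuple[float, float]] = field(default_factory=list)
    extinction_events: list[tuple[float, float]] = field(default_factory=list)
    final_coalition: np.ndarray | None = None
    final_equilibrium: EquilibriumState | None = None
    converged: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t, xs in zip(self.times, self.traits):
            for i, x in enumerate(xs):
                rows.append({"time": t, "species": i, "x": x})
        return pd.DataFrame(rows)

    @property
    def n_final_species(self) -> int:
        return 0 if self.final_coalition is None else len(self.final_coalition)


def count_species(traits, min_separation: float = EPS_BRANCH) -> int:
    """Number of distinct species: traits further apart than the offset used
    at branching events count separately."""
    xs = np.sort(np.atleast_1d(np.asarray(traits, dtype=float)))
    if len(xs) == 0:
        return 0
    return 1 + int(np.sum(np.diff(xs) > min_separation))


def evolve_traits(
    initial_traits,
    params: ModelParameters,
    initial_state: EquilibriumState | dict | None = None,
    step_scale: float = 1.0,
    max_dx: float = 0.05,
    max_steps: int = 600,
    max_species: int = 8,
    allow_branching: bool = True,
    grad_tol: float = GRAD_TOL,
    record_every: int = 1,
) -> EvoTrajectory:
    """Deterministic trait-substitution dynamics of the resident coalition.

    Each evolutionary step moves every resident along its selection
    gradient (``dx = step_scale * gradient`` capped at ``max_dx``),
    re-solves the ecological equilibrium, removes residents that lose
    viability, and — when a resident has converged onto a branching point
    — replaces it by two daughters offset by ``±EPS_BRANCH``.  Evolutionary
    time is in units of substitution steps (the canonical-equation rate
    constants are absorbed into the time scale).
    """
    traits = np.sort(np.atleast_1d(np.asarray(initial_traits, dtype=float)))
    traj = EvoTrajectory()
    eq = solve_equilibrium(traits, params, guess=initial_state)
    t = 0.0
    eta = np.full(len(traits), step_scale)   # per-resident step, damped on
    last_sign = np.zeros(len(traits))        # gradient sign flips (overshoot)

    for step_idx in range(max_steps):
        # prune extinct residents
        alive = eq.coalition.b > 0
        if not alive.all():
            for x_dead in traits[~alive]:
                traj.extinction_events.append((t, float(x_dead)))
            traits = traits[alive]
            eta, last_sign = eta[alive], last_sign[alive]
            if len(traits) == 0:
                traj.final_coalition = traits
                traj.final_equilibrium = eq
                return traj
            eq = solve_equilibrium(traits, params, guess=eq)

        grads = np.array([selection_gradient(i, eq, params)
                          for i in range(len(traits))])
        curvs = {}
        if step_idx % record_every == 0:
            traj.times.append(t)
            traj.traits.append(traits.copy())

        # branching / convergence test for residents with a vanished gradient
        at_singular = np.abs(grads) < grad_tol
        branched = False
        if at_singular.any():
            for i in np.flatnonzero(at_singular):
                curvs[i] = _mutant_curvature(traits[i], eq, params)
            if allow_branching and len(traits) < max_species:
                for i in sorted(curvs, key=lambda k: -curvs[k]):
                    if curvs[i] > CURV_TOL:
                        x0 = traits[i]
                        cand = np.sort(np.concatenate([
                            np.delete(traits, i),
                            [x0 - EPS_BRANCH, x0 + EPS_BRANCH],
                        ]))
                        try:
                            eq_cand = solve_equilibrium(cand, params, guess=eq)
                        except EquilibriumError:
                            continue  # daughters cannot coexist yet
                        traj.branching_events.append((t, float(x0)))
                        traits, eq = cand, eq_cand
                        eta = np.full(len(traits), step_scale)
                        last_sign = np.zeros(len(traits))
                        branched = True
                        break
            if not branched and at_singular.all() and all(
                c < CURV_TOL for c in curvs.values()
            ):
                traj.converged = True
                break

        if branched:
            t += 1.0
            continue

        # damp residents whose gradient flipped sign (overshoot of a
        # convergence-stable point); gently re-grow the step otherwise
        signs = np.sign(grads)
        flipped = (signs * last_sign) < 0
        eta[flipped] *= 0.4
        eta[~flipped] = np.minimum(eta[~flipped] * 1.2, step_scale)
        last_sign = signs

        dx = np.clip(eta * grads, -max_dx, max_dx)
        dx[at_singular] = 0.0
        order = np.argsort(traits + dx)
        new_traits = (traits + dx)[order]
        eta, last_sign = eta[order], last_sign[order]
        # merge residents that have collapsed onto each other
        keep = np.concatenate([[True], np.diff(new_traits) > 1e-3])
        new_traits = new_traits[keep]
        eta, last_sign = eta[keep], last_sign[keep]
        try:
            eq_new = solve_equilibrium(new_traits, params, guess=eq)
        except EquilibriumError:
            # halve the step once before giving up on this move
            new_traits = np.sort(traits + 0.5 * dx)[keep]
            eq_new = solve_equilibrium(new_traits, params, guess=eq)
        traits, eq = new_traits, eq_new
        t += 1.0

    traj.times.append(t)
    traj.traits.append(traits.copy())
    traj.final_coalition = traits
    traj.final_equilibrium = eq
    return traj


# ---------------------------------------------------------------------------
# branching-distance calibration (no diet shift)
# ---------------------------------------------------------------------------

def _attractor_is_branching(params: ModelParameters,
                            x_start: float | None = None) -> bool:
    """Evolve a monomorphic resident to its attractor and classify it."""
    theta = params.theta
    center = 0.5 * (theta[1] + theta[-1])
    if x_start is None:
        x_start = center + 0.2 * params.peak_spacing
    traj = evolve_traits([x_start], params, allow_branching=False,
                         max_steps=400)
    x_star = float(traj.final_coalition[0])
    sp = classify_singularity(x_star, params)
    return sp.classification == "branching"


def branching_distance_threshold(
    params: ModelParameters | None = None,
    d_range: tuple[float, float] = (1.0, 6.0),
    tol: float = 0.05,
    n_scan: int = 6,
    criterion: str = "radiation",
) -> tuple[float, float]:
    """Window of feeding-curve spacings for which an adaptive radiation occurs.

    With no ontogenetic diet shift (``m_shift = 0``) individuals feed on
    the specific-resource array for life.  The spacing between adjacent
    feeding-curve optima is varied and the evolutionary outcome of a
    monomorphic ancestor is probed; the returned interval brackets the
    spacings that pass the chosen criterion, each endpoint located by
    bisection to ``tol``.  Criteria:

    * ``'radiation'`` (default) — the trait-substitution cascade splits
      the ancestor into one specialist per resource (all optima
      colonized), the condition the feeding-curve geometry is calibrated
      for;
    * ``'branching'`` — the monomorphic evolutionary attractor classifies
      as a branching point (at least one diversification event).

    Raises ``ValueError`` if no spacing in the scan range qualifies.
    """
    base = params or ModelParameters()
    base = base.with_(m_shift=0.0, tau_s=math.inf, tau_c=1.0)

    def probe(d: float) -> bool:
        p = base.with_(peak_spacing=d)
        if criterion == "branching":
            return _attractor_is_branching(p)
        start = 0.5 * (p.theta[1] + p.theta[-1]) + 0.2 * d
        traj = evolve_traits([start], p, max_steps=700)
        return len(traj.final_coalition) >= p.n_resources

    ds = np.linspace(d_range[0], d_range[1], n_scan)
    flags = [probe(d) for d in ds]
    if not any(flags):
        raise ValueError(f"no branching for spacings in {d_range}; scan={flags}")

    first = int(np.argmax(flags))
    last = len(flags) - 1 - int(np.argmax(flags[::-1]))

    def bisect(d_false: float, d_true: float) -> float:
        while abs(d_true - d_false) > tol:
            mid = 0.5 * (d_false + d_true)
            if probe(mid):
                d_true = mid
            else:
                d_false = mid
        return 0.5 * (d_false + d_true)

    d_min = d_range[0] if first == 0 else bisect(ds[first - 1], ds[first])
    d_max = d_range[1] if last == len(ds) - 1 else bisect(ds[last + 1], ds[last])
    return (d_min, d_max)


# ---------------------------------------------------------------------------
# two-parameter species-count grids
# ---------------------------------------------------------------------------

def species_count_grid(
    params: ModelParameters,
    axis1: tuple[str, np.ndarray],
    axis2: tuple[str, np.ndarray],
    x_ancestor: float = 1.0,
    evolve_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Final species count over a parameter grid, from both ecological states.

    For every grid cell the trait-substitution dynamics are run twice:
    once from the small-individual-dominated and once from the
    large-individual-dominated stable ecological state of the ancestral
    monomorphic resident (when only one stable state exists both runs
    coincide).  A cell is flagged eco-evolutionarily bistable when the two
    final species counts differ.
    """
    from .ecology import find_stable_equilibria, set_parameter

    name1, vals1 = axis1
    name2, vals2 = axis2
    kw = dict(max_steps=400)
    kw.update(evolve_kwargs or {})
    rows = []
    for v1 in np.atleast_1d(vals1):
        for v2 in np.atleast_1d(vals2):
            p = set_parameter(set_parameter(params, name1, float(v1)),
                              name2, float(v2))
            cell = {name1: float(v1), name2: float(v2)}
            try:
                eqs = find_stable_equilibria([x_ancestor], p, classify=False)
                viable = [e for e in eqs if np.any(e.coalition.b > 0)]
                if not viable:
                    cell.update(count_small_start=0, count_large_start=0,
                                bistable=False, error="")
                    rows.append(cell)
                    continue
                # order states by their standing large-consumer biomass
                def large_bio(e):
                    return sum(bi * lh.standing_large for bi, lh in
                               zip(e.coalition.b, e.life_histories))
                viable.sort(key=large_bio)
                counts = []
                for eq0 in (viable[0], viable[-1]):
                    traj = evolve_traits([x_ancestor], p, initial_state=eq0, **kw)
                    counts.append(count_species(traj.final_coalition))
                cell.update(count_small_start=counts[0],
                            count_large_start=counts[1],
                            bistable=counts[0] != counts[1], error="")
            except Exception as exc:  # record, keep the grid going
                cell.update(count_small_start=-1, count_large_start=-1,
                            bistable=False, error=type(exc).__name__)
            rows.append(cell)
    return pd.DataFrame(rows)
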