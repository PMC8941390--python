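"""Individual-level bioenergetics of the size-structured consumer.

Individuals are characterized by body mass ``m`` (g) and a heritable niche
trait ``x``.  Small individuals (``m < m_shift``) feed on a single shared
resource; at the ontogenetic diet shift they gain access to an array of
species-specific resources, each with a Gaussian trait-matching attack-rate
profile.  Food intake saturates (type-II), assimilated energy covers
maintenance first, the surplus is routed to somatic growth in juveniles and
to egg production in adults.  All rates are per day, masses in g, resource
densities in g m^-3.

The closure (maximum intake, maintenance, assimilation, background
mortality) follows the standard cross-species fish bioenergetics used in
size-spectrum / physiologically structured models: maximum intake
``h m^n`` and maintenance ``k m^p`` with ``n = p = 3/4``, so the critical
feeding level ``f_c = k / (alpha h)`` is size independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ModelParameters",
    "ResourceEnvironment",
    "SHARED",
    "attack_coefficient",
    "attack_vector",
    "diet_weight",
    "diet_weight_matrix",
    "encounter_rate",
    "encounter_rates",
    "feeding_level",
    "intake_rate",
    "net_energy_rate",
    "growth_rate",
    "fecundity_rate",
    "mortality_rate",
    "consumption_rates",
]

#: index of the shared resource in every length-(1 + n_resources) vector
SHARED = 0

_SHIFT_MODES = ("discrete", "gradual", "broadening")


@dataclass(frozen=True)
class ModelParameters:
    """All ecological constants of the model.

    Resource vectors are ordered ``(shared, specific_1, ..., specific_n)``.
    ``tau`` entries may be ``inf`` which disables the trait dependence of
    the attack rate on that resource (used for the shared resource when
    there is no developmental trade-off).
    """

    # life-history masses (g)
    m_b: float = 0.05
    m_mat: float = 30.0
    m_shift: float = 5.0

    # attack rate: a(m, x) = A(x) * m**q
    q: float = 0.8
    A_max: float = 3.0  # m^3 g^-q day^-1

    # niche axis
    theta_s: float = 0.0
    theta_1: float = 1.0
    peak_spacing: float = 2.5
    n_resources: int = 6
    tau_s: float = math.inf  # inf: no juvenile trade-off; 20: weak trade-off
    tau_c: float = 1.0

    # resources: semi-chemostat dR/dt = delta (R_max - R) - grazing
    delta: float = 0.1  # day^-1
    R_s_max: float = 2.0  # g m^-3 (Fig-like scenarios override)
    R_c_max: float | Sequence[float] = 1.0  # scalar or per specific resource

    # diet-shift geometry
    shift_mode: str = "discrete"
    shift_steepness: float = 10.0  # log-mass logistic steepness (gradual mode)

    # bioenergetic closure (reconstructed cross-species fish values, per day)
    h: float = 85.0 / 365.0  # max-intake coefficient, g^(1-n) day^-1
    n_intake: float = 0.75
    alpha: float = 0.6  # assimilation efficiency
    k_maint: float = 10.0 / 365.0  # maintenance coefficient, g^(1-p) day^-1
    p_met: float = 0.75
    eps_egg: float = 0.1  # efficiency of converting surplus into egg mass
    mu0: float = 2.6 / 365.0  # background mortality coeff, g^(1-n) day^-1
    mort_exp: float = -0.25  # mass exponent of background mortality
    xi_starv: float = 1.0  # starvation mortality per relative energy deficit

    def __post_init__(self) -> None:
        if self.shift_mode not in _SHIFT_MODES:
            raise ValueError(f"shift_mode must be one of {_SHIFT_MODES}")
        for name in ("m_b", "m_mat", "A_max", "delta", "R_s_max", "h",
                     "k_maint", "eps_egg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.m_shift < 0:
            raise ValueError("m_shift must be >= 0")
        if self.tau_s <= 0 or self.tau_c <= 0:
            raise ValueError("niche widths must be positive (or inf)")
        if np.any(np.asarray(self.R_c_max, dtype=float) <= 0):
            raise ValueError("R_c_max must be positive")

    # ---- derived vectors -------------------------------------------------

    @property
    def theta(self) -> np.ndarray:
        """Optimal niche values, shared first then the specific resources."""
        peaks = self.theta_1 + self.peak_spacing * np.arange(self.n_resources)
        return np.concatenate(([self.theta_s], peaks))

    @property
    def tau(self) -> np.ndarray:
        return np.concatenate(
            ([self.tau_s], np.full(self.n_resources, self.tau_c))
        )

    @property
    def R_max(self) -> np.ndarray:
        rc = np.broadcast_to(
            np.asarray(self.R_c_max, dtype=float), (self.n_resources,)
        )
        return np.concatenate(([self.R_s_max], rc))

    @property
    def f_crit(self) -> float:
        """Critical feeding level (intake exactly covers maintenance).

        Only size independent when ``p_met == n_intake`` (the default).
        """
        return self.k_maint / (self.alpha * self.h)

    def with_(self, **kwargs) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class ResourceEnvironment:
    """Densities of the shared and the species-specific resources (g m^-3)."""

    R_s: float
    R: np.ndarray  # specific resources, shape (n_resources,)

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        if self.R_s < 0 or np.any(self.R < 0):
            raise ValueError("resource densities must be non-negative")

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate(([self.R_s], self.R))

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "ResourceEnvironment":
        v = np.asarray(v, dtype=float)
        return cls(R_s=float(v[SHARED]), R=v[SHARED + 1:])

    @classmethod
    def pristine(cls, params: ModelParameters) -> "ResourceEnvironment":
        """Consumer-free equilibrium: every resource at its maximum."""
        return cls.from_vector(params.R_max)


# ---------------------------------------------------------------------------
# attack rates and diet weights
# ---------------------------------------------------------------------------

def attack_coefficient(x: float, j: int, params: ModelParameters) -> float:
    """Trait-dependent attack-rate coefficient on resource ``j``.

    Gaussian in the distance between the niche trait and the resource
    optimum; equals ``A_max`` exactly at the optimum and for resources with
    infinite niche width.
    """
    nr = params.n_resources
    if not (0 <= j <= nr):
        raise IndexError(f"resource index {j} out of range 0..{nr}")
    tau = params.tau[j]
    if math.isinf(tau):
        return params.A_max
    d = x - params.theta[j]
    return params.A_max * math.exp(-(d * d) / (2.0 * tau * tau))


def attack_vector(x, params: ModelParameters) -> np.ndarray:
    """Attack coefficients on all resources; vectorized over ``x``.

    Returns shape ``(..., 1 + n_resources)`` for array-valued ``x``.
    """
    x = np.asarray(x, dtype=float)
    d = x[..., None] - params.theta
    tau = params.tau
    with np.errstate(over="ignore"):
        out = params.A_max * np.exp(-(d * d) / (2.0 * tau * tau))
    out = np.where(np.isinf(tau), params.A_max, out)
    return out


def diet_weight(m: float, j: int, params: ModelParameters) -> float:
    """Access weight of an individual of mass ``m`` on resource ``j`` in [0, 1].

    This is an access mask, not a preference distribution: in the discrete
    mode small individuals see only the shared resource and large ones only
    the specific resources; in the broadening mode large individuals keep
    the shared resource; in the gradual mode access shifts smoothly
    (logistic in log mass centred on ``m_shift``).
    """
    nr = params.n_resources
    if not (0 <= j <= nr):
        raise IndexError(f"resource index {j} out of range 0..{nr}")
    w = diet_weight_matrix(np.asarray([m]), params)[0]
    return float(w[j])


def diet_weight_matrix(m, params: ModelParameters) -> np.ndarray:
    """Diet weights for masses ``m``; shape ``(..., 1 + n_resources)``."""
    m = np.asarray(m, dtype=float)
    mode = params.shift_mode
    if params.m_shift <= 0.0:
        shared = np.zeros_like(m) if mode != "broadening" else np.ones_like(m)
        specific = np.ones_like(m)
    elif mode == "gradual":
        z = params.shift_steepness * np.log(m / params.m_shift)
        specific = 1.0 / (1.0 + np.exp(-z))
        shared = 1.0 - specific
    else:
        large = m >= params.m_shift
        specific = np.where(large, 1.0, 0.0)
        if mode == "broadening":
            shared = np.ones_like(m)
        else:  # discrete
            shared = np.where(large, 0.0, 1.0)
    out = np.empty(m.shape + (1 + params.n_resources,))
    out[..., SHARED] = shared
    out[..., SHARED + 1:] = specific[..., None]
    return out


# ---------------------------------------------------------------------------
# feeding, energetics
# ---------------------------------------------------------------------------

def _env_vector(env) -> np.ndarray:
    v = env.vector if isinstance(env, ResourceEnvironment) else np.asarray(env, float)
    if np.any(v < 0):
        raise ValueError("resource densities must be non-negative")
    return v


def encounter_rates(m, x, env, params: ModelParameters) -> np.ndarray:
    """Per-resource encountered food mass flux (g day^-1), shape (..., 1+n)."""
    v = _env_vector(env)
    m = np.asarray(m, dtype=float)
    w = diet_weight_matrix(m, params)
    a = attack_vector(x, params)
    return w * a * (m[..., None] ** params.q) * v


def encounter_rate(m, x, env, params: ModelParameters):
    """Total encountered food mass flux over all accessible resources."""
    return encounter_rates(m, x, env, params).sum(axis=-1)


def feeding_level(m, x, env, params: ModelParameters):
    """Realized intake as a fraction of maximum intake, in [0, 1]."""
    e = encounter_rate(m, x, env, params)
    imax = params.h * np.asarray(m, dtype=float) ** params.n_intake
    return e / (e + imax)


def intake_rate(m, x, env, params: ModelParameters):
    """Ingested food mass flux ``f * h * m^n`` (g day^-1)."""
    e = encounter_rate(m, x, env, params)
    imax = params.h * np.asarray(m, dtype=float) ** params.n_intake
    return e * imax / (e + imax)


def net_energy_rate(m, x, env, params: ModelParameters):
    """Assimilated intake minus maintenance (g day^-1); may be negative."""
    m = np.asarray(m, dtype=float)
    return (
        params.alpha * intake_rate(m, x, env, params)
        - params.k_maint * m ** params.p_met
    )


def growth_rate(m, x, env, params: ModelParameters):
    """Somatic growth dm/dt (g day^-1).

    Juveniles route all net energy to growth; adults have determinate
    growth (all surplus to reproduction).  Growth is floored at zero —
    energy deficits raise mortality instead of shrinking the body.
    """
    m = np.asarray(m, dtype=float)
    net = np.maximum(net_energy_rate(m, x, env, params), 0.0)
    return np.where(m < params.m_mat, net, 0.0)


def fecundity_rate(m, x, env, params: ModelParameters):
    """Offspring production rate (offspring day^-1); zero for juveniles."""
    m = np.asarray(m, dtype=float)
    net = np.maximum(net_energy_rate(m, x, env, params), 0.0)
    return np.where(m >= params.m_mat, params.eps_egg * net / params.m_b, 0.0)


def mortality_rate(m, x, env, params: ModelParameters):
    """Background size-dependent mortality plus starvation mortality (day^-1)."""
    m = np.asarray(m, dtype=float)
    mu = params.mu0 * m ** params.mort_exp
    deficit = -net_energy_rate(m, x, env, params)
    starv = params.xi_starv * np.maximum(deficit, 0.0) / m
    return mu + starv


def consumption_rates(m, x, env, params: ModelParameters) -> np.ndarray:
    """Biomass removed from each resource (g day^-1), shape (..., 1+n).

    Total ingestion is apportioned over resources by encounter share, so
    the per-resource removals sum to the (saturating) intake rate.
    """
    e_j = encounter_rates(m, x, env, params)
    m = np.asarray(m, dtype=float)
    imax = params.h * m ** params.n_intake
    etot = e_j.sum(axis=-1)
    return e_j * (imax / (etot + imax))[..., None]
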