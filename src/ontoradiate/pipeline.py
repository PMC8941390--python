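"""Scenario orchestration, canonical configurations and fixtures.

Each figure-style experiment of the model is packaged as a
:class:`Scenario`: a named engine (equilibrium solve, parameter
continuation, adaptive-dynamics evolution, species-count grid or IBM run)
plus its full parameterization.  Scenarios serialize to YAML, run through
:func:`run_scenario`, and write tabular CSV output together with a JSON
manifest (config, seed, package and library versions) that makes any run
repeatable bit for bit.

Every canonical scenario exists at two resolutions from one template: the
``'full'`` scale uses publication-style problem sizes, the ``'test'``
scale coarser grids, smaller volumes and shorter horizons so that the
whole battery runs on a desk machine.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ecology import (
    bistability_window,
    continue_in_parameter,
    find_stable_equilibria,
    growth_curve,
    integrate_life_history,
    set_parameter,
    solve_equilibrium,
)
from .adaptive_dynamics import evolve_traits, species_count_grid
from .ibm import GeneticParameters, IBMConfig, run_ibm
from .model_core import ModelParameters

__all__ = [
    "Scenario",
    "build_fixture",
    "run_scenario",
    "canonical_scenarios",
    "scenario",
]

log = logging.getLogger("ontoradiate")

ENGINES = ("equilibrium", "continuation", "ad-evolve", "ad-grid", "ibm")


@dataclass
class Scenario:
    """A named, fully serializable model experiment."""

    name: str
    engine: str
    params: ModelParameters = field(default_factory=ModelParameters)
    genetics: GeneticParameters | None = None
    options: dict = field(default_factory=dict)
    seeds: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.engine not in ENGINES:
            raise ValueError(f"engine must be one of {ENGINES}")
        if self.engine == "ibm" and not self.seeds:
            raise ValueError("stochastic scenarios require an explicit seed list")

    # ---- (de)serialization ------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "engine": self.engine,
            "params": dataclasses.asdict(self.params),
            "options": _plain(self.options),
            "seeds": list(self.seeds),
        }
        if self.genetics is not None:
            d["genetics"] = dataclasses.asdict(self.genetics)
        for k, v in d["params"].items():
            if isinstance(v, float) and math.isinf(v):
                d["params"][k] = "inf"
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        pd_ = dict(d["params"])
        for k, v in pd_.items():
            if v == "inf":
                pd_[k] = math.inf
        gen = GeneticParameters(**d["genetics"]) if "genetics" in d else None
        return cls(name=d["name"], engine=d["engine"],
                   params=ModelParameters(**pd_), genetics=gen,
                   options=dict(d.get("options", {})),
                   seeds=list(d.get("seeds", [])))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "Scenario":
        return cls.from_dict(yaml.safe_load(text))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# canonical scenarios
# ---------------------------------------------------------------------------

def scenario(name: str, scale: str = "test") -> Scenario:
    """Build one of the canonical scenarios (``scale`` 'test' or 'full')."""
    builders = canonical_scenarios()
    if name not in builders:
        raise KeyError(f"unknown scenario {name!r}; have {sorted(builders)}")
    return builders[name](scale)


def canonical_scenarios() -> dict:
    """Scenario templates for the headline experiments.

    Supply rates follow the study conditions: ``delta R_s,max`` of
    0.025 g m^-3 day^-1 for the low-productivity and 0.2 for the
    high-productivity environment, a diet shift at 5 g, birth mass 0.05 g
    (0.5 mg for the initial-composition scenarios, which use a weak
    juvenile trade-off, ``tau_s = 20``, and supply 0.6).
    """

    def low_high(scale, supply):
        p = set_parameter(ModelParameters(), "supply_s", supply)
        steps = 400 if scale == "test" else 1500
        return Scenario(
            name=f"radiation-{'low' if supply < 0.1 else 'high'}",
            engine="ad-evolve", params=p,
            options={"initial_traits": [0.0], "max_steps": steps},
        )

    def fig_low(scale):
        return low_high(scale, 0.025)

    def fig_high(scale):
        return low_high(scale, 0.2)

    def fig_bistability(scale):
        p = ModelParameters()
        n = 200 if scale == "test" else 500
        return Scenario(
            name="supply-continuation", engine="continuation", params=p,
            options={"traits": [1.0], "parameter": "supply_s",
                     "range": [0.02, 0.3], "max_points": n},
        )

    def fig_growth(scale):
        p = set_parameter(ModelParameters(), "supply_s", 0.2)
        return Scenario(
            name="hybrid-growth", engine="equilibrium", params=p,
            options={"traits": [1.57, 4.87], "growth_traits": [1.57, 3.29, 4.87]},
        )

    def fig_grid(scale):
        p = ModelParameters(tau_s=20.0)
        if scale == "test":
            ratios, shifts = [0.3, 1.0, 2.5], [0.5, 5.0]
        else:
            ratios = list(np.round(np.linspace(0.2, 3.0, 8), 3))
            shifts = [0.2, 1.0, 5.0, 15.0]
        return Scenario(
            name="species-count-grid", engine="ad-grid", params=p,
            options={"axis1": ["productivity_ratio", ratios],
                     "axis2": ["m_shift", shifts]},
        )

    def fig_ibm(scale):
        p = set_parameter(ModelParameters(), "supply_s", 0.2)
        if scale == "test":
            gen = GeneticParameters(V=4000.0, sigma=0.1, F_x=8, F_a=8)
            t_max = 80000.0
        else:
            gen = GeneticParameters(V=1e3, sigma=0.01)
            t_max = 2e6
        return Scenario(
            name="ibm-high-supply", engine="ibm", params=p, genetics=gen,
            options={"x0": 0.0, "t_max": t_max, "record_every": 1000.0},
            seeds=[1],
        )

    def fig_initial_composition(scale):
        p = set_parameter(
            ModelParameters(m_b=5e-4, tau_s=20.0), "supply_s", 0.6)
        if scale == "test":
            gen = GeneticParameters(V=2000.0, sigma=0.1)
            t_max = 40000.0
        else:
            gen = GeneticParameters(V=1e3, sigma=0.01)
            t_max = 2e6
        return Scenario(
            name="initial-composition", engine="ibm", params=p, genetics=gen,
            options={"x0": 3.0, "t_max": t_max, "record_every": 1000.0,
                     "profiles": ["small", "large"]},
            seeds=[1],
        )

    return {
        "radiation-low": fig_low,
        "radiation-high": fig_high,
        "supply-continuation": fig_bistability,
        "hybrid-growth": fig_growth,
        "species-count-grid": fig_grid,
        "ibm-high-supply": fig_ibm,
        "initial-composition": fig_initial_composition,
    }


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def build_fixture(kind: str, seed: int):
    """Deterministic synthetic fixtures for tests and examples.

    * ``'random-params'`` — a valid random :class:`ModelParameters` draw;
    * ``'small-ibm-state'`` — a small founded IBM state plus its config;
    * ``'mating-log'`` — a synthetic mating log with known ground-truth
      reproductive isolation (returns ``(records, edges, ri_true)``);
    * ``'growth-env'`` — an environment giving a known constant feeding
      level (returns ``(env, params, f_target)``).
    """
    rng = np.random.default_rng(seed)
    if kind == "random-params":
        return ModelParameters(
            m_b=float(rng.uniform(0.01, 0.2)),
            m_shift=float(rng.uniform(1.0, 10.0)),
            m_mat=float(rng.uniform(20.0, 60.0)),
            A_max=float(rng.uniform(1.0, 5.0)),
            R_s_max=float(rng.uniform(0.5, 4.0)),
            R_c_max=float(rng.uniform(0.5, 2.0)),
            peak_spacing=float(rng.uniform(2.0, 3.0)),
            tau_s=math.inf if rng.random() < 0.5 else 20.0,
        )
    if kind == "small-ibm-state":
        from .ibm import initial_state
        cfg = IBMConfig(
            params=set_parameter(ModelParameters(), "supply_s", 0.2),
            genetics=GeneticParameters(V=200.0),
            n0=80, t_max=100.0,
        )
        return cfg, initial_state(cfg, seed)
    if kind == "mating-log":
        # two clusters at x = 0 and x = 5; a configured fraction of
        # between-cluster matings with equal participant frequencies
        n = 400
        frac_between = float(rng.choice([0.0, 0.25, 0.5]))
        records = []
        for i in range(n):
            between = i < frac_between * n
            xm = 0.0 if i % 2 == 0 else 5.0
            xf = (5.0 - xm) if between else xm
            records.append((float(i), 2 * i, 2 * i + 1, xm, xf))
        ri_true = 1.0 - frac_between / 0.5
        return records, [2.5], ri_true
    if kind == "growth-env":
        params = ModelParameters()
        # choose the shared-resource density so a newborn's feeding level
        # sits exactly at the critical level: zero growth by construction
        m = params.m_b
        fc = params.f_crit
        rs = fc / (1.0 - fc) * params.h * m ** (params.n_intake - params.q) \
            / params.A_max
        env = np.concatenate(([rs], np.zeros(params.n_resources)))
        return env, params, fc
    raise KeyError(f"unknown fixture kind {kind!r}")


# ---------------------------------------------------------------------------
# execution
# ---------------------------------------------------------------------------

def run_scenario(scen: Scenario, outdir: str | Path,
                 seed: int | None = None) -> dict:
    """Dispatch a scenario to its engine and write CSV output + manifest.

    Returns the manifest dictionary (also written as ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    opts = dict(scen.options)
    written: list[str] = []
    log.info("running scenario %s (engine=%s)", scen.name, scen.engine)

    try:
        if scen.engine == "equilibrium":
            traits = opts.get("traits", [1.0])
            eq = solve_equilibrium(traits, scen.params)
            rows = [{"x": x, "b": b} for x, b in
                    zip(eq.coalition.traits, eq.coalition.b)]
            pd.DataFrame(rows).to_csv(outdir / "coalition.csv", index=False)
            env = pd.DataFrame({"resource": range(len(eq.env.vector)),
                                "density": eq.env.vector})
            env.to_csv(outdir / "environment.csv", index=False)
            written += ["coalition.csv", "environment.csv"]
            for x in opts.get("growth_traits", []):
                gc = growth_curve(x, eq.env, scen.params)
                fn = f"growth_x{x:g}.csv"
                gc.to_csv(outdir / fn, index=False)
                written.append(fn)
        elif scen.engine == "continuation":
            br = continue_in_parameter(
                opts["traits"], scen.params, opts["parameter"],
                tuple(opts["range"]), max_points=opts.get("max_points", 200),
                classify=opts.get("classify", "simulate"),
            )
            br.points.to_csv(outdir / "branch.csv", index=False)
            written.append("branch.csv")
            win = bistability_window(br)
            opts["_bistability_window"] = list(win) if win else None
        elif scen.engine == "ad-evolve":
            traj = evolve_traits(opts.get("initial_traits", [0.0]), scen.params,
                                 max_steps=opts.get("max_steps", 400))
            traj.to_frame().to_csv(outdir / "trajectory.csv", index=False)
            pd.DataFrame({"x": traj.final_coalition}).to_csv(
                outdir / "final_coalition.csv", index=False)
            written += ["trajectory.csv", "final_coalition.csv"]
        elif scen.engine == "ad-grid":
            a1 = (opts["axis1"][0], np.asarray(opts["axis1"][1], dtype=float))
            a2 = (opts["axis2"][0], np.asarray(opts["axis2"][1], dtype=float))
            grid = species_count_grid(scen.params, a1, a2,
                                      x_ancestor=opts.get("x_ancestor", 1.0))
            grid.to_csv(outdir / "grid.csv", index=False)
            written.append("grid.csv")
        elif scen.engine == "ibm":
            seeds = [seed] if seed is not None else scen.seeds
            profiles = opts.get("profiles", [opts.get("init_profile", "juvenile")])
            for sd in seeds:
                for prof in profiles:
                    cfg = IBMConfig(
                        params=scen.params, genetics=scen.genetics,
                        x0=opts.get("x0", 0.0), n0=opts.get("n0", 600),
                        init_profile=prof,
                        t_max=opts.get("t_max", 20000.0),
                        record_every=opts.get("record_every", 500.0),
                    )
                    res = run_ibm(cfg, sd)
                    tag = f"seed{sd}" + (f"_{prof}" if len(profiles) > 1 else "")
                    res.snapshots.to_csv(outdir / f"snapshots_{tag}.csv",
                                         index=False)
                    res.series.to_csv(outdir / f"series_{tag}.csv", index=False)
                    mat = pd.DataFrame(res.mating_records,
                                       columns=["time", "mother", "father",
                                                "x_mother", "x_father"])
                    mat.to_csv(outdir / f"matings_{tag}.csv", index=False)
                    written += [f"snapshots_{tag}.csv", f"series_{tag}.csv",
                                f"matings_{tag}.csv"]
    except Exception as exc:
        raise RuntimeError(f"scenario {scen.name!r} failed in engine "
                           f"{scen.engine!r}: {exc}") from exc

    manifest = {
        "scenario": scen.to_dict(),
        "config_hash": scen.config_hash(),
        "seed": seed,
        "outputs": written,
        "versions": {"ontoradiate": __version__,
                     "numpy": np.__version__, "pandas": pd.__version__},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
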