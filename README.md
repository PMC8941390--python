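# ontoradiate

Eco-evolutionary simulation of **adaptive radiation under ontogenetic diet
shifts** in a size-structured consumer–resource model.

Most animals change diet as they grow.  This package models a consumer in
which every individual starts life feeding on one *shared* resource and,
on reaching a body mass `m_shift`, gains access to an array of six
*species-specific* resources that reward specialization of a heritable
niche trait `x`: the attack-rate coefficient on resource `j` is

    A_j(x) = A_max · exp( −(x − θ_j)² / (2 τ_j²) ),   a_j(m, x) = A_j(x) · m^q,

with optima `θ_1..θ_6` spaced 2.5 trait units apart (width τ = 1) and
semi-chemostat resource renewal `dR_j/dt = δ(R_j,max − R_j) − grazing`.
Growth, reproduction and mortality follow a standard fish bioenergetic
budget (type-II intake `f·h·m^n`, maintenance `k·m^p`, determinate growth
at `m_mat`); the question the model answers is when competition among
*small* individuals for the shared resource chokes off the recruitment of
*large* individuals and with it the disruptive selection needed for an
adaptive radiation — despite abundant ecological opportunity.

Three engines share the same individual-level rates:

* **`ecology`** — equilibria of the physiologically structured population
  model: life-history quadratures (`R0`, survival, lifetime resource
  consumption), a quasi-Newton equilibrium solver, parameter continuation
  with fold detection (ecological bistability between stunted
  small-dominated and large-dominated population states), and
  perturb-and-simulate stability classification on a cohort
  discretization.
* **`adaptive_dynamics`** — invasion fitness `s = ln R0(x_mut | E_res)`,
  selection gradients, singular-strategy classification (CSS / branching
  point / repeller), deterministic trait-substitution dynamics with
  evolutionary branching, the branching window of feeding-curve spacings,
  and two-parameter species-count grids with eco-evolutionary bistability.
* **`ibm`** — a stochastic individual-based model with additive diploid
  multi-locus genetics for the niche trait and for an evolvable
  self-matching assortative-mating trait `a ∈ [−1, 1]`, free
  recombination, Gaussian mutation, explicit mate choice and
  bit-reproducible seeding.

`model_core` holds the bioenergetic closures, `pipeline` the canonical
scenario configurations, the synthetic fixture generator, batch execution
with JSON run manifests, and a CLI (`ontoradiate run|evolve|continue|
singular|fixtures`).

## Worked example

Evolve an ancestral monomorphic species (niche trait `x = 0`) under low
and high supply of the shared resource:

```python
from ontoradiate import ModelParameters
from ontoradiate.ecology import set_parameter
from ontoradiate.adaptive_dynamics import evolve_traits

for supply in (0.025, 0.2):                       # δ·R_s,max, g m⁻³ day⁻¹
    p = set_parameter(ModelParameters(), "supply_s", supply)
    traj = evolve_traits([0.0], p, max_steps=900)
    print(supply, traj.final_coalition.round(2))
```

prints

```
0.025 [1.25]
0.2   [ 1.14  3.49  6.    8.5  11.01 13.36]
```

Under low supply the lineage merely walks to the nearest optimum
(θ₁ = 1) and stays monomorphic: juveniles grow so slowly on the scarce
shared resource that few individuals recruit to the large size classes,
specific-resource competition stays weak, and there is no disruptive
selection.  Under high supply recruitment is strong, the specific
resources are depleted, and the lineage branches repeatedly until all six
optima carry a specialist — an adaptive radiation.  The same contrast can
be run with sexual, genetically explicit populations:

```python
from ontoradiate.ibm import IBMConfig, GeneticParameters, run_ibm

cfg = IBMConfig(params=p, genetics=GeneticParameters(V=1200, sigma=0.05,
                                                     F_x=4, F_a=1,
                                                     sigma_mate=0.5),
                x0=0.0, t_max=220_000)
res = run_ibm(cfg, seed=1)
print(res.series[["time", "n_clusters", "mean_a", "RI"]].tail(3))
```

which ends, after a dimorphic random-mating phase whose hybrid offspring
starve at the diet shift, with six phenotype clusters, a mean
assortative-mating trait around 0.5 and a reproductive-isolation index
around 0.85 (0 = random mating, 1 = complete isolation).

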