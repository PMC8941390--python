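# Methods

## The model

`ontoradiate` implements a size-structured consumer–resource model of
adaptive radiation under an ontogenetic diet shift.  A consumer species is
characterized by its niche trait `x` (and a mass at maturation `m_mat`);
individuals are characterized by their body mass `m`.  Everybody is born
at mass `m_b` feeding on one *shared* resource `R_s`; on reaching `m_shift`
individuals switch (discretely, by default) to an array of
*species-specific* resources `R_1..R_6` whose use requires trait
specialization: the attack-rate coefficient on resource `j` is Gaussian in
the trait,

    A_j(x) = A_max exp( -(x - theta_j)^2 / (2 tau_j^2) ),

with optima `theta_j` spaced `2.5` trait units apart and width `tau = 1`.
The shared resource either requires no specialization (`tau_s = inf`) or
trades off weakly against late-life specialization (`tau_s = 20`).  The
size-specific attack rate is `A_j(x) m^q`.  Resources renew by
semi-chemostat dynamics `dR_j/dt = delta (R_j,max - R_j) - grazing`; every
figure-style scenario quotes the shared supply rate as the product
`delta R_s,max` (g m^-3 day^-1).

Individual energetics follow the standard cross-species fish
bioenergetics of size-spectrum and physiologically structured models:
type-II intake with maximum `h m^n`, assimilation efficiency `alpha`,
maintenance `k m^p` with `p = n = 3/4` (so the critical feeding level
`f_c = k/(alpha h) ~ 0.2` is size independent), juveniles routing all net
energy to growth, adults (determinate growth at `m_mat`) routing all of
it to eggs of mass `m_b` with efficiency `eps_egg`.  Mortality is a
background power law `mu0 m^(n-1)` plus a starvation term proportional to
the relative energy deficit; growth is floored at zero (deficits kill,
they do not shrink).

### Parameter table (defaults)

| symbol | meaning | default | units |
|---|---|---|---|
| `m_b` | mass at birth | 0.05 | g |
| `m_shift` | mass at diet shift | 5 | g |
| `m_mat` | mass at maturation | 30 | g |
| `q` | attack-rate exponent | 0.8 | – |
| `A_max` | maximum attack coefficient | 3.0 | m^3 g^-q d^-1 |
| `h` | max-intake coefficient | 85/365 | g^(1-n) d^-1 |
| `n`, `p` | intake / maintenance exponents | 0.75 | – |
| `alpha` | assimilation efficiency | 0.6 | – |
| `k` | maintenance coefficient | 10/365 | g^(1-p) d^-1 |
| `eps_egg` | egg-production efficiency | 0.1 | – |
| `mu0` | background mortality coefficient | 2.6/365 | g^(1-n) d^-1 |
| `xi_starv` | starvation mortality factor | 1.0 | – |
| `delta` | resource turnover | 0.1 | d^-1 |
| `R_c,max` | specific-resource maximum | 1.0 | g m^-3 |
| `theta_s`, `theta_1` | shared / first optimum | 0, 1 | trait |
| spacing, `tau`, `tau_s` | peak geometry | 2.5, 1, inf (or 20) | trait |

`h`, `k`, `alpha`, `n`, `p`, `q` are the published cross-species fish
values converted to days.  `A_max`, `mu0`, `m_mat`, `delta` and `R_c,max`
are *reconstruction calibrations*: the primary literature for this model
family reports supply rates only as `delta R_s,max` products and does not
pin these constants, so they were fixed once, by requiring the model to
reproduce the qualitative structure the model family is known for — a
fold pair in the shared-supply rate separating a stable
stunted/small-dominated population state from a stable large-dominated
state (with the unstable saddle between them), radiation into all six
specialists at spacing 2.5 with no diet shift, and no radiation at low
shared supply.  With the literature default `mu0 = 0.84 yr^-1 g^0.25` and
`m_mat = 100 g` the small-dominated equilibrium is oscillatorily unstable
(slow juvenile-delay limit cycles); the calibrated `mu0` and the smaller
`m_mat` damp those cycles while preserving the fold bistability.

## Deterministic ecology (PSPM equilibria)

At equilibrium every resident experiences a constant environment, so its
life history collapses to quadratures along mass: age-at-mass `t(m)`,
survival `ln S(m) = -int mu/g dm`, lifetime per-resource consumption
`C_j = int c_j S / g dm`, with the adult stage closed analytically.
Quadrature is composite Simpson on a log-mass grid (385 points per diet
segment, the shift an exact segment boundary); against an adaptive
time-domain integration of the same cohort ODEs the lifetime reproductive
number `R0` agrees to better than 1e-6 relative.  If net energy turns
non-positive anywhere before maturation the individual stalls there —
it keeps consuming and dying but never matures (`R0 = 0`).  This
starvation cliff makes `R0` *discontinuous* in the environment, which is
the numerically delicate feature of the model; the equilibrium solver
therefore multi-starts from a deterministic list of environment guesses
that includes "juvenile-bottleneck" states with the shared resource just
above the newborn's critical density.

Equilibria solve `{ln R0_i = 0} ∪ {delta(R_max - R) = sum_i b_i C_i}` for
log-resources and birth rates with a quasi-Newton method (`hybr`);
branches in any parameter are traced by predictor–corrector continuation
that pins the fastest-moving log coordinate each step (this rounds fold
points where the parameter itself stalls), recording fold locations and
the small-/large-consumer standing biomasses.  Stability is classified by
discretizing an equilibrium into ~120 cohorts, perturbing numbers by a
few percent, and simulating the full cohort dynamics (transformed-Euler
growth, exact exponential survival, positivity-preserving semi-implicit
resource update): return to the equilibrium's neighbourhood is `stable`,
departure to a different attractor `unstable`.  Within a fold-delimited
branch segment stability cannot change except at the folds, so one
simulation per segment suffices.

## Adaptive dynamics

Invasion fitness is `s(x_mut) = ln R0(x_mut | E_resident)`; gradients are
central differences (step 1e-4), mutant curvature a second difference
(step 0.05), and convergence stability the derivative of the gradient
under resident displacement (equilibrium re-solved).  The trait
substitution sequence moves every resident by `eta * gradient` (capped at
0.05 trait units) with per-resident step damping on gradient sign flips;
a resident whose gradient vanishes with positive mutant curvature is
replaced by daughters at `±0.05`.  Evolutionary time is in substitution
steps — the canonical-equation rate constants are absorbed into the time
unit, so trajectories match real time only up to monotone rescaling.
The engine contains no random number generator; runs are exactly
reproducible from their configuration.

The *branching window* of feeding-curve spacings (no diet shift,
`tau = 1`) is located by bisection (resolution 0.05) under two criteria:
`'radiation'` — the cascade colonizes all six resources (the condition
the feeding-curve geometry is chosen for) — giving approximately
(1.94, 3.79) at the default closure, and `'branching'` — the monomorphic
attractor is a branching point — giving approximately (0.5, 4.17).  The
known reference window for this geometry is (1.9, 4.2); the default
closure reproduces its lower endpoint under the first criterion and its
upper endpoint (within ~2%) under the second, but no closure we found
within the reconstructed bioenergetic framework matches both endpoints
under a single criterion.  The acceptance battery reports both.

## Individual-based model

The IBM shares the individual-level rates exactly (scaled by the volume
`V`) and adds diploid additive genetics: the niche trait is the *sum* of
its `2 F_x` allelic values, the assortative-mating trait `a in [-1, 1]`
the *mean* of its `2 F_a` values.  Free recombination; each transmitted
allele mutates with probability `nu = 0.1` by a Gaussian kernel
(`sigma = 0.01` by default; a-alleles clamped).  A spawning female whose
energy buffer covers at least one egg (`m_b/eps_egg`) picks a father
among the currently mature individuals with self-matching weights
`exp(-a^2 (x_f - x_m)^2 / (2 sigma_mate^2))` (uniform at `a = 0`;
disassortative with a small uniform floor for `a < 0`; only the female's
`a` is expressed; selfing excluded).  The event order — feeding/growth,
resource update, mortality, spawning — is fixed for reproducibility, and
a single PCG64 generator seeds every random decision: identical
(config, seed) pairs give bit-identical output.

Species are operationalized as gap clusters of the mature niche traits
(split at gaps > 0.5 = tau/2).  Reproductive isolation over a window of
matings is `RI = 1 - p_obs/p_exp`, with `p_obs` the observed
between-cluster mating fraction and `p_exp = 1 - sum f_k^2` the random
expectation from the partner cluster frequencies, clipped to [0, 1].
This estimator is a documented package definition — the reference
estimator behind the published values (0.97/0.96/0.9) is not stated — so
only qualitative agreement is claimed.

### Scaled scenarios

Full-fidelity IBM runs (V = 1e3 m^3, sigma = 0.01, 8+8 loci, multi-year
horizons) take far longer than a desk session, so the packaged `'test'`
scale accelerates evolution while preserving the mechanism: smaller
volume (V ≈ 1.2e3), fewer loci (F_x = 4, F_a = 1), a larger mutation
kernel (sigma = 0.05) and a narrower mate-choice width (sigma_mate =
0.5).  These raise the mutational variance supplied per generation and
the effectiveness of moderate choosiness; they do not alter the ecology.
What a passing scaled run shows is that the documented eco-evolutionary
sequence — directional evolution, ecologically maintained dimorphism
under random mating, developmentally doomed hybrids, selection for and
rise of assortative mating, and finally reproductively isolated clusters
— unfolds mechanistically; it does not validate the real-time rates of
any real system.

### A note on the starving-hybrid snapshot

In the deterministic *dimorphic* equilibrium (two residents, no hybrids)
the middle resource is grazed only through the residents' Gaussian
tails, so it is necessarily *less* depleted than the flanking ones and a
rare intermediate phenotype is fitter there, not less fit — in any
parameterization of this model family.  The famous mid-radiation
starving-hybrid configuration instead requires the hybrid swarm itself
to depress the middle resource, which only the IBM (with gene flow
continuously regenerating hybrids) produces.  The package therefore
evaluates hybrid viability in the resource environment realized by the
IBM during its dimorphic random-mating phase.

## The synthetic fixture generator

`pipeline.build_fixture` produces: random valid parameter sets (property
tests), small founded IBM states, synthetic mating logs with known
ground-truth RI (clustered partners with a prescribed between-cluster
mating fraction), and environments with analytically known growth
(feeding level pinned at the critical level, hence zero growth).  Tests
use these in place of any external data; nothing in the package reads
data from disk.

## Numerical choices and limitations

* Quadrature 385 points/segment; equilibrium tolerances: |ln R0| < 1e-7
  scaled balance < 1e-7 (achieved residuals are typically < 1e-10);
  continuation corrector tolerance 1e-7; bisection resolutions 0.05
  (spacing window) and 1e-4 (singular points).
* The survival cutoff for time-domain truncation is 1e-12; the mass-domain
  quadrature needs no cutoff and resolves survivals to double-precision
  underflow, far below the ~1e-8 maturation probabilities of doomed
  hybrids.
* Stagnation detection is grid-based: a growth sign change wholly between
  adjacent log-mass grid points could be missed (narrower than ~1% in
  mass); none of the packaged scenarios is near that regime.
* The cohort stability classifier inherits discretization bias of order a
  few percent in the resource densities; its thresholds (return within
  half the initial deviation, or an absolute log-distance of 0.02) are
  config values.
* Eco-evolutionary time scales are model-internal: days for the ecology,
  substitution steps for adaptive dynamics.
* Initial-composition dependence in the IBM: the founding population is
  specified by a mass profile (`'small'`/`'large'` = log-uniform below /
  above `m_shift`) plus a head count.  At volumes of order 10^3 m^3 the
  demographic fluctuations and the crude initial *densities* dominate
  which ecological basin the population lands in, so the
  small-vs-large-start contrast is reliable deterministically (the
  two stable equilibrium branches, from continuation) but only
  qualitative in the stochastic simulation unless the founding state is
  loaded from a deterministic equilibrium.
* Limit cycles: parts of parameter space outside the calibrated defaults
  show slow juvenile-delay cycles around the small-dominated state; the
  stability classifier then reports `unstable` even though a
  small-dominated *attractor* (the cycle) persists nearby.
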