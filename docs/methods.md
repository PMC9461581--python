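# Methods

`patchforage` models the departure of a cohesive foraging group from a
depleting resource patch as a set of coupled evidence-accumulation
processes, and provides the numerical machinery to simulate the model,
evaluate strategy efficiency, and identify model parameters and the
mode of social communication from departure-time data.

## Model

Each of `N` agents carries a scalar belief `x_i(t)` (its motivation to
keep foraging), starting at 0 and evolving by the Euler--Maruyama SDE

    dx_i = [ mu(t) + c_i(t) ] dt + sqrt(2B) dW_i,
    mu(t) = rho * exp(-Lambda(t)) - alpha,
    Lambda(t) = (1/tau) * ∫_0^t  N_active(s) ds,

with independent Wiener processes `W_i` and one shared diffusion scale
`B`. The patch starts at energy density `rho` and depletes with
timescale `tau` per still-foraging agent, so the shared drift falls
from `rho - alpha` toward `-alpha`; `alpha` is the constant cost rate
of foraging and travel. Agent `i` commits to leaving at the first time
`x_i <= theta_i` with `theta_i < 0` (an increment--decrement strategy:
early food encounters push the belief up, away from the threshold).
Decided beliefs are clamped at their thresholds. The group is cohesive:
it departs at `T_N = max_i T_i`, so early deciders wait.

A note on the depletion exponent: writing the density as
`rho * e^{-N_active(t) * t / tau}` would make it jump at each decision
time. We use the integrated form `rho * e^{-Lambda(t)}` throughout,
which keeps the density continuous and is the only form consistent with
the telescoping group-reward expression below.

Two coupling modes transfer information between agents:

* **Diffusive** — continuous attraction to the others'
  distance-to-threshold: `c_i = kappa_i * sum_{j != i} ((x_j - theta_j)
  - (x_i - theta_i))`. Decided neighbours (distance 0) pull the
  undecided toward their own thresholds. Units of `kappa_i`: 1/time.
* **Pulsatile** — communication only at decisions: when any agent
  decides, every undecided agent `i` jumps down by `kappa_i` (belief
  units). A jump past threshold triggers a decision at the same
  instant, recursively (a cascade), producing exactly simultaneous
  departures with positive probability — a discrete atom in the
  departure-time law.

`mode="none"` switches coupling off. With `kappa = 0`, all three modes
produce byte-identical output at matched seeds (same noise stream).

### Limiting cases (two symmetric agents)

* **NC** (`kappa = 0`): i.i.d. beliefs given the shared drift; group
  time is the max of the two passage times.
* **D_inf** (`kappa -> inf`, diffusive): the half-difference
  `x_- = (x1 - x2)/2` is an Ornstein--Uhlenbeck process. Deriving its
  dynamics from the coupled SDEs gives relaxation rate `2*kappa` and

      Var[x_-](t) = B/(4 kappa) * (1 - e^{-4 kappa t}),

  which vanishes as `kappa -> inf`: both beliefs collapse onto their
  average, whose SDE carries noise `sqrt(B) dW` — *half* the diffusion
  scale of an individual. The group time is this single passage time.
* **P_inf** (spanning pulses): the first decider triggers everyone, so
  the group time is the min of N i.i.d. passage times,
  `f_min = N f S^{N-1}`.

Note that a pulse of size `|theta|` does *not* guarantee simultaneity:
beliefs rise above 0 while the patch is rich, so the survivor's
distance to threshold can exceed `|theta|`. The P_inf regime is reached
for `kappa` well above the belief excursion (tests use `kappa = 50`).

## Reward rate

While `k` agents forage the patch depletes at rate `k/tau`, so the
group's total intake up to `T_N` telescopes over the ordered decision
times and equals `rho*tau*(1 - e^{-Lambda(T_N)})`, bounded by the patch
content `rho*tau`. Strategy efficiency is the reward rate

    RR = (<r_N> - alpha * (T_I + <T>)) / (T_I + <T>),

with `<.>` the means over bouts (ratio of means — the long-run rate
over repeated bouts), `T_I` the inter-patch travel time, and `<T>` the
mean *group* time `T_N` (the cohesion constraint is what makes early
deciders' waiting costly). Strategy sweeps are plain grid searches with
common random numbers (one root seed shared by every cell), which makes
arg-max comparisons stable; optimal-threshold curves are smoothed with
a length-3 centered moving average. Exact ties in partner optimization
break toward the smaller `|theta_2|`, then the smaller `kappa_2`.

## First-passage machinery

The 1D Fokker--Planck equation with absorbing boundary at `theta` and
reflecting truncation at `x_max` is discretized in conservation form
with Scharfetter--Gummel (exponentially fitted) fluxes on a uniform
grid and stepped with a Crank--Nicolson theta-scheme; a few backward-
Euler startup steps smooth the point-mass initial condition
(Rannacher smoothing). Interior + absorbed mass balances to machine
precision each step; the first-passage density is the flux through
`theta`. `x_max` is set adaptively from the noise-free belief excursion
plus four diffusion lengths accumulated up to the noise-free crossing
time. An optional refined early time window (default: the first 0.8
time units at 1/16 of the base step) resolves near-threshold initial
transients, which absorb on the scale `theta^2/(2B)`. Against the
inverse-Gaussian closed form (constant drift), the solver's sup-norm
error is ~1% of the density peak at the default resolution and shrinks
under refinement.

Known limit: for priors with `|theta|` near 0.1 *and* `B` near 4
jointly, the absorption scale (~10^-3 time units) falls below even the
refined step; likelihoods at that extreme corner carry O(10%)
normalization error. This is the least informative corner of the prior
and does not affect the reported medians.

## Pair likelihoods

For a two-agent bout the data are the ordered pair `(T1, T2)` plus a
simultaneity flag. The joint law decomposes exactly across the first
decision for the uncoupled and pulsatile classes (agents are
independent before `T1`):

* first-decider density `2 f(t1) S(t1)` under the two-agent drift;
* the survivor's conditional interior density (a solver snapshot at
  `t1`) is propagated under the one-agent drift (with the depletion
  already incurred) to give the conditional density of `T2`;
* pulsatile only: at `T1` the survivor's density is shifted by `kappa`
  toward the threshold; the shifted-out mass is the atom
  `P(T2 = T1 | T1)`.

Likelihood tables precompute the conditional propagation from ~20
quantile nodes of the first-decider distribution and interpolate
log-densities bilinearly; tables depend only on (class, parameters,
environment), never on the data, so one LRU cache serves every fit.

The diffusive class is genuinely two-dimensional before the first
decision, so its likelihood is simulation-based: a fixed-seed bank of
simulated bouts at the queried parameters, binned in `(t1, gap)`
coordinates (`gap = t2 - t1`; strong coupling concentrates the gap near
0, so gap-resolved, data-driven bin ranges are essential), smoothed
with a Silverman rule-of-thumb Gaussian kernel with reflecting
boundaries, and floored at 1e-12 so likelihood products stay finite
(with a 3x-wider-bandwidth fallback in sparsely sampled regions). One
fixed seed per parameter query makes the likelihood a deterministic
function of the parameters. The two exact backends and the simulation
backend agree at `kappa = 0` to within the histogram's estimation
error.

Mixed atom/continuous likelihoods across classes are made
commensurable by scoring each observation as a resolution-`Delta` bin
(`Delta` defaults to the generating Euler step): continuous coordinates
contribute `density * Delta` each, a tie contributes `atom_mass *
Delta`. The factor is constant within a class — MAP estimates are
unaffected — and calibrates Bayes factors between classes. Exact
simultaneity is genuinely diagnostic of pulsatile coupling under this
convention, so datasets containing ties are identified as pulsatile
with near-certainty; identification hardness for the pulsatile class
concentrates in its weak-coupling, tie-free regime.

## Inference

Priors are uniform boxes: `theta in [-5, -0.1]`, `kappa in [0.1, 6]`,
`B in [0.1, 4]`; the uncoupled class fits `(theta, B)` only. The
environment `(rho, tau, alpha)` is treated as known during fitting
(defaults `2, 5, 1`). MAP estimation is a coarse grid search over the
box (10x8 for the uncoupled class, 8x6x6 otherwise) followed by one
local refinement pass spanning one coarse cell (5 points per axis;
4 for pulsatile, 3 for the simulation-backed diffusive class, whose
density noise does not reward finer resolution). Everything is
deterministic given the dataset and the likelihood seed.

Marginal likelihoods are simple Monte Carlo averages of the dataset
likelihood over prior draws (log-sum-exp stabilized), with a reported
standard error; log Bayes factors are their differences, antisymmetric
by construction and exactly zero for identical classes. The confusion
experiment scores every dataset of a candidate class against one
fixed, seed-derived 96-sample prior bank (common random numbers across
datasets — each estimate remains a valid simple MC average, and the
likelihood tables are built once per bank). Classification takes the
arg-max marginal with ties broken in the fixed order none < diffusive
< pulsatile.

## Synthetic data and what the tests show

All datasets are generated by the package's own simulator: Euler steps
of 0.005 time units (0.001 for strong-coupling checks, where stability
needs `kappa * dt << 1`), horizon 200-300 time units (the drift tends
to `-alpha`, so crossing is almost sure; an undecided agent at the
horizon raises an error rather than censoring silently), one
independent RNG stream per bout spawned from a root seed. Decision
times are recorded at step resolution — no Brownian-bridge sub-step
correction — so departure-time means carry an O(dt) discretization
bias, bounded in the dt-refinement test.

The generator emulates the model exactly; it does not emulate features
of real foraging data (measurement noise on departure times, missing
bouts, per-bout environmental variation, more than two foragers in the
inference pipeline). Passing tests therefore demonstrate internal
consistency of simulator, solver, reward accounting, and inference
machinery under the model's own assumptions — not field validity.

Reference problem sizes, chosen as desk-scale versions of the original
figure-quality experiments: 10^4 bouts per Monte Carlo check; parameter
recovery with 20 prior draws per class at n = 50 and 500 pairs;
identification with 30 draws per class at n = 50 pairs and 96-sample
marginals. `scripts/acceptance.py` runs the same pipeline at further
reduced sizes (8-12 draws, 4000-8000 bouts) to fit a single-CPU run.

## Known limitations

- Likelihoods and inference support two-agent groups; the simulator
  and reward accounting handle any N.
- The diffusive likelihood's histogram resolution puts a floor
  (~0.2-0.3 relative error) under its parameter recovery that more
  data cannot remove; the exact-propagation classes keep improving
  with n.
- The reflecting truncation of the solver domain biases extreme
  right-tail passage times slightly; quantified by the captured-mass
  diagnostic on every density.
- No sub-step threshold interpolation; no 2D PDE solver for the
  diffusive pair (the simulation backend stands in); no mean-field
  approximations for large groups.
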