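# patchforage

Stochastic models of **social patch-foraging decisions**: how a
cohesive group of foragers, each accumulating noisy evidence about a
depleting food patch, decides when to leave — and how the way they
share information (continuously, or only at the moment of decision)
shapes the group's foraging efficiency and can be identified from
departure-time data.

The package is for behavioral ecologists and modellers working with
drift-diffusion descriptions of patch-leaving: it provides the coupled
simulator, the first-passage numerics, reward-rate strategy
evaluation, and the Bayesian fitting/identification pipeline in one
importable library with a thin command-line interface.

## Model

Each of `N` agents holds a belief `x_i(t)` evolving as a drift-
diffusion process with shared depletion drift and threshold stopping:

```
dx_i = [ rho e^{-Λ(t)} - alpha + coupling_i ] dt + sqrt(2B) dW_i,
x_i(0) = 0,   agent i decides when x_i hits theta_i < 0,
Λ(t) = (1/tau) ∫_0^t (number still foraging) ds .
```

The group is cohesive and departs at `T_N = max_i T_i`. Two coupling
modes: **diffusive** (`kappa_i Σ_j [(x_j - theta_j) - (x_i - theta_i)]`,
continuous belief sharing) and **pulsatile** (an instantaneous jump of
size `kappa_i` toward threshold whenever another agent decides —
possibly triggering exactly simultaneous departures). Efficiency is the
reward rate `RR = (<r_N> - alpha (T_I + <T>)) / (T_I + <T>)` over a
patch visit plus travel time `T_I`. Parameters `(theta, kappa, B)` and
the coupling class itself are recovered from departure-time pairs by
MAP estimation and Bayes factors.

See `docs/methods.md` for the numerical methods (Fokker–Planck
first-passage solver, exact-propagation and simulation-based
likelihoods) and design choices.

## Worked example

Recover the parameters of an uncoupled pair from 300 simulated bouts
(`examples/fit_parameters.py`):

```python
from patchforage import (GroupModel, PriorBox, SimulationSettings,
                         dataset_pairs, map_estimate, relative_error,
                         simulate_dataset)

model = GroupModel.symmetric("none", 2, theta=-1.5, kappa=0.0, noise_scale=1.0)
df = simulate_dataset(model, SimulationSettings(dt=0.005, t_max=300.0,
                                                n_trials=300, seed=23))
fit = map_estimate(dataset_pairs(df), "none", PriorBox(), data_resolution=0.005)
```

which prints

```
truth:    theta=-1.50  B=1.00
estimate: theta=-1.46  B=0.94  (log posterior -4575.3, 105 evaluations)
mean absolute relative error: 0.045
```

`theta` is the departure threshold (how much evidence of depletion an
agent needs before quitting) and `B` the belief noise; the estimate
lands within the refined grid resolution of the generating values.

Comparing the limiting group strategies on the same patch
(`examples/limiting_cases.py`, `rho=2, tau=5, alpha=1, theta=-1, B=1`):

```
mean group departure time:  NC 7.34   D_inf 4.54   P_inf 1.88
```

No coupling (NC) departs at the max of two independent passage times;
perfect diffusive coupling (D_inf) averages the beliefs and halves the
effective noise; perfect pulsatile coupling (P_inf) departs at the
min. Coupling removes the waiting time of early deciders, which is why
it raises the reward rate once the threshold is tuned.

Other examples: `simulate_group.py` (one bout with belief
trajectories), `reward_sweep.py` (RR over a strategy grid),
`model_identification.py` (Bayes-factor classification).

## Command line

```bash
patchforage simulate --config config.yaml --output bouts.tsv
patchforage fit bouts.tsv --model-class pulsatile
patchforage experiment model_confusion --scale 0.1 --seed 1
```

Datasets are TSV tables (`trial, agent, decision_time, decision_rank,
simultaneous`) with a YAML sidecar carrying the generating model, seed
and config hash.

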