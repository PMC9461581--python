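"""Identify the coupling mode of a simulated group from departure times.

Simulates 50 bouts of a pulsatile pair, then compares the three model
classes by log Bayes factors (marginal likelihoods over the uniform
prior, simple Monte Carlo). Exactly simultaneous departures are the
pulsatile model's signature: they carry a discrete probability atom
that the continuous classes cannot produce.
"""

from patchforage import (
    GroupModel,
    PriorBox,
    SimulationSettings,
    dataset_pairs,
    log_bayes_factor,
    simulate_dataset,
)

model = GroupModel.symmetric("pulsatile", 2, theta=-1.5, kappa=2.5, noise_scale=1.0)
df = simulate_dataset(model, SimulationSettings(dt=0.005, t_max=300.0,
                                                n_trials=50, seed=31))
pairs = dataset_pairs(df)
ties = int(pairs[2].sum())
print(f"dataset: 50 pairs, {ties} exactly simultaneous departures")

prior = PriorBox()
for other in ("none", "diffusive"):
    bf = log_bayes_factor(pairs, "pulsatile", other, prior, seed=5,
                          n_prior_samples=48)
    verdict = "pulsatile" if bf > 0 else other
    print(f"log BF(pulsatile vs {other}) = {bf:+.1f}  -> evidence for {verdict}")
# Positive log Bayes factors favor the first (true) class; the margin
# over 'none' is usually larger than over 'diffusive', which can mimic
# near-synchronous departures but never exact ties.
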