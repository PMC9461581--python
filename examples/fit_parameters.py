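"""Recover model parameters from synthetic departure-time pairs.

Simulates 300 bouts of an uncoupled pair at known (theta, B), then
maximizes the posterior over the uniform prior box by grid search with
one refinement pass. The likelihood propagates the survivor's belief
density across the first decision with a Fokker--Planck solver.
"""

from patchforage import (
    GroupModel,
    PriorBox,
    SimulationSettings,
    dataset_pairs,
    map_estimate,
    relative_error,
    simulate_dataset,
)

truth = {"theta": -1.5, "b": 1.0}
model = GroupModel.symmetric("none", 2, truth["theta"], 0.0, truth["b"])
df = simulate_dataset(model, SimulationSettings(dt=0.005, t_max=300.0,
                                                n_trials=300, seed=23))
fit = map_estimate(dataset_pairs(df), "none", PriorBox(),
                   data_resolution=0.005)

print(f"truth:    theta={truth['theta']:.2f}  B={truth['b']:.2f}")
print(f"estimate: theta={fit.theta:.2f}  B={fit.noise_scale:.2f}  "
      f"(log posterior {fit.log_posterior:.1f}, {fit.n_evaluations} evaluations)")
print(f"mean absolute relative error: "
      f"{relative_error(fit.estimate, truth, 'none'):.3f}")
# With 300 pairs the MAP estimate typically lands within the refined
# grid resolution of the generating parameters.
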