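"""Choose a preservation model (HPP / NHPP / TPP) for simulated occurrences.

The data here carry a 5x jump in preservation rate at 246 Ma, so the
time-variable Poisson process (TPP, one rate per stage-like bin) should win
the AIC-style comparison, and its per-bin rates should recover the truth.
"""

import numpy as np

from paleodiv.preservation import select_preservation_model
from paleodiv.synthetic import (SimulationConfig, simulate_bd,
                                simulate_preservation)

config = SimulationConfig(
    t_start=254.0, t_end=237.0,
    lambda_episodes=[(254.0, 237.0, 0.2)],
    mu_episodes=[(254.0, 237.0, 0.1)],
    q_bins=[(254.0, 246.0, 0.4), (246.0, 237.0, 2.0)],  # 5x shift at 246 Ma
    n_seed_lineages=30, rng_seed=3)
history = simulate_bd(config)
occs = simulate_preservation(history, config)
mask = np.array([o.size > 0 for o in occs])
sampled = [o for o in occs if o.size]

edges = np.array([254.0, 250.0, 246.0, 242.0, 237.0])
best, scores, models = select_preservation_model(
    history.ts[mask], history.te[mask], sampled, bin_edges=edges)

print("model scores (lower is better):")
for kind, s in sorted(scores.items(), key=lambda kv: kv[1]):
    print(f"  {kind:4s} {s:10.1f}")
print(f"selected: {best}")
print("\nTPP per-bin preservation rates (true: 0.4, 0.4, 2.0, 2.0):")
print(np.round(models["TPP"].q, 2))
# The TPP wins because the between-bin rate difference dwarfs its extra
# parameters; its per-bin estimates track the generating rates.
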