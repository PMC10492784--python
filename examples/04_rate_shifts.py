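"""Two-step Bayesian rate estimation with reversible-jump shift detection.

Step 1 samples preservation-corrected origination/extinction times (Ts, Te)
per genus beyond its oldest/youngest fossil; step 2 runs rjMCMC over
piecewise-constant λ(t) and μ(t) on those times.  The data carry a 5x
extinction spike at 246–244 Ma which the μ trajectory should localize.
"""

import numpy as np

from paleodiv.bd import TaxonTimes, rjmcmc_rates, sample_times
from paleodiv.mcmcutil import McmcRun
from paleodiv.preservation import PreservationModel
from paleodiv.synthetic import (SimulationConfig, simulate_bd,
                                simulate_preservation)

config = SimulationConfig(
    t_start=254.0, t_end=237.0,
    lambda_episodes=[(254.0, 237.0, 0.2)],
    mu_episodes=[(254.0, 246.0, 0.1), (246.0, 244.0, 0.5), (244.0, 237.0, 0.1)],
    q_bins=[(254.0, 237.0, 1.0)],
    n_seed_lineages=40, rng_seed=11)
history = simulate_bd(config)
occs = simulate_preservation(history, config)
mask = np.array([o.size > 0 for o in occs])
sampled = [o for o in occs if o.size]

posterior = sample_times(sampled, PreservationModel("HPP", [1.0]), (0.2, 0.1),
                         (254.0, 237.0), McmcRun(iterations=2000, rng_seed=1),
                         extant=~history.extinct[mask])
print(f"sampled genera: {len(sampled)}; preservation q "
      f"posterior mean {posterior.q_samples.mean():.2f} (true 1.0)")

# analyse inside a buffered window: the simulation's standing diversity at
# 254 Ma would otherwise masquerade as an origination burst at the old edge
lam, mu = rjmcmc_rates(posterior.times, (252.0, 237.0),
                       McmcRun(iterations=40000, rng_seed=2))
print("\n age    lambda_mean   mu_mean   mu_95%HPD")
for i in range(0, len(lam.grid), 2):
    print(f"{lam.grid[i]:6.1f}   {lam.mean[i]:8.3f}   {mu.mean[i]:8.3f}"
          f"   ({mu.hpd_lo[i]:.3f}, {mu.hpd_hi[i]:.3f})")
shifts = np.concatenate([s for s in mu.shift_ages if s.size])
print(f"\nposterior mean mu-shift age: {shifts.mean():.1f} Ma "
      f"(true spike 246-244 Ma)")
# mu(t) should sit near 0.1 outside the spike and rise sharply inside it;
# the posterior shift ages cluster at the spike boundaries.
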