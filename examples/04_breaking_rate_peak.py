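"""Breaking-event statistics across the transition.

Counts breaking events per 1000-step window while sweeping the individual
payoff: the rate peaks right at the critical threshold, where groups keep
forming and dissolving.
"""

import numpy as np

from spingroups import SimConfig, critical_threshold, density_curve, \
    pi_grid_default

base = SimConfig(n_agents=200, group_size=10, vec_len=3, seed=23,
                 replicates=5)
curve = density_curve(pi_grid_default(step=0.1), base)

peak = curve.pi_i[np.argmax(curve.breaks_mean.to_numpy())]
print(curve[["pi_i", "rho_mean", "breaks_mean"]].to_string(index=False))
print(f"\nbreaking rate peaks at pi_i = {peak}")
print(f"density half-max threshold at pi_hat = {critical_threshold(curve)}")
print("Deep in the group phase groups are stable (few breaks); deep in the")
print("individual phase few groups exist to break; the churn is maximal at")
print("the phase boundary, so the peak marks the critical threshold.")
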