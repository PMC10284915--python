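"""Simulate one participant and inspect the ground truth.

Generates a resting-state and a hypercapnic BOLD run driven by the same
hidden CVR/BAT fields, then prints what the simulator knows and the
downstream estimators will try to recover.
"""

import numpy as np

from hemomap import SimulationConfig, simulate_subject

config = SimulationConfig(grid_shape=(32, 40, 12), n_timepoints=150, seed=7)
subject = simulate_subject(config)
truth = subject.truth
brain = truth.brain_mask

print(f"grid {config.grid_shape}, {config.n_timepoints} frames at "
      f"TR {config.tr} s")
print(f"brain voxels: {brain.sum()}, cerebellum: "
      f"{truth.cerebellum_mask.sum()}, atlas regions: "
      f"{len(np.unique(truth.atlas.values)) - 1}")
print(f"true CVR  (%/mmHg): {truth.cvr_true.values[brain].mean():.3f} +/- "
      f"{truth.cvr_true.values[brain].std():.3f}")
print(f"true BAT  (s):      {truth.bat_true.values[brain].mean():.2f} +/- "
      f"{truth.bat_true.values[brain].std():.2f}")

tc = subject.rest_bold.values[tuple(np.argwhere(brain)[0])]
print(f"one voxel's resting signal: mean {tc.mean():.1f} a.u., "
      f"fluctuation {100 * tc.std() / tc.mean():.2f} % of baseline")
print(f"resting EtCO2: {subject.rest_etco2.values.mean():.1f} mmHg, "
      f"SD {subject.rest_etco2.values.std():.2f} mmHg")
print(f"hypercapnic EtCO2 range: {subject.hc_etco2.values.min():.0f}-"
      f"{subject.hc_etco2.values.max():.0f} mmHg")
# The fluctuation percentage is CVR x EtCO2 variability: ~0.25 %/mmHg x
# ~1.5 mmHg plus thermal noise — the weak natural contrast the resting-state
# method works with.
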