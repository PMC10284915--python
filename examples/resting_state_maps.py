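"""Global-regression resting-state (GRRS) mapping and truth recovery.

Runs the classical estimation chain on a noiseless simulated subject — GLM
against the cerebellar reference for the CVR coefficient maps, exhaustive
+/-9 s lag search for BAT — and compares the estimates with the simulator's
hidden truth.
"""

import numpy as np

from hemomap import SimulationConfig, run_grrs, simulate_subject, zscore_map

config = SimulationConfig(grid_shape=(32, 40, 12), n_timepoints=150,
                          seed=11).noiseless()
subject = simulate_subject(config)
truth = subject.truth
brain = truth.brain_mask

out = run_grrs(subject.rest_bold, truth.cerebellum_mask, brain,
               subject.rest_motion)

truth_z = zscore_map(truth.cvr_true, brain)
cvr_cc = np.corrcoef(out.cvr_z.values[brain], truth_z.values[brain])[0, 1]
bat_err = np.abs(out.bat_seconds.values[brain] - truth.bat_true.values[brain])

print(f"CVR-Z spatial correlation with truth: {cvr_cc:.4f}")
print(f"BAT error: median {np.median(bat_err) * 1000:.0f} ms, "
      f"within 0.2 s for {100 * (bat_err <= 0.2).mean():.1f} % of voxels")
print(f"BAT range: [{out.bat_seconds.values[brain].min():.1f}, "
      f"{out.bat_seconds.values[brain].max():.1f}] s "
      "(bounded by the +/-9 s search window)")
# Without noise the estimators invert the forward model almost exactly:
# correlation ~0.99+ and sub-grid-step BAT errors. Under realistic noise the
# same maps degrade substantially — that gap is what the network closes.
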