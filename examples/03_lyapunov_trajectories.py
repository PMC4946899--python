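"""Ecological dynamics ascend the community fitness F.

Three trajectories of a 63-species world (N=6), each started from random
log-uniform abundances. Whatever the start, F increases monotonically,
the mean substrate availability falls as the community learns to deplete
all substrates, and every run lands on the same survivor set.
"""

import numpy as np

from metapart.experiments import early_coupling, run_trajectories

report = run_trajectories(n_traj=3, n_substrates=6, eps=1e-3, seed=7)

for i, (traj, trace) in enumerate(zip(report.trajectories, report.traces)):
    dF_min = float(np.diff(traj.F_values).min())
    print(
        f"run {i}: F {traj.F_values[0]:+.4f} -> {traj.F_values[-1]:+.6f} "
        f"(min step {dF_min:+.1e}), "
        f"mean availability {trace['mean_availability'].iloc[0]:.3f} -> "
        f"{trace['mean_availability'].iloc[-1]:.3f}, "
        f"survivors = {sorted(g.label for g in traj.final.support())}"
    )
    print(f"        early F-<f> coupling (Spearman) = {early_coupling(trace):+.2f}")

print(f"all runs share one final survivor set: {report.common_support}")
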