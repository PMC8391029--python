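#!/usr/bin/env python
"""Localize water labels by permutation reduction and quantify the effect.

Runs the exact-assignment reduction on a toy solvated system and reports the
assignment cost and the per-label positional spread before/after — the
reduction is what makes per-molecule entropy bookkeeping meaningful.
Writes results/permutation_summary.csv.
"""

import numpy as np
import pandas as pd

import hydroshell as hs

system = hs.gen_toy_solvated("point_probe", n_frames=150, seed=3, box=3.0,
                             density=15.0)
traj = system.solvent
reduced, record = hs.permute_trajectory(traj, reference_frame=0)


def label_spread(t):
    """Mean per-label positional standard deviation (nm)."""
    return float(np.mean(np.std(t.positions, axis=0)))


summary = pd.DataFrame({
    "metric": ["n_molecules", "n_frames", "mean_assignment_cost_nm2",
               "label_spread_before_nm", "label_spread_after_nm"],
    "value": [traj.n_molecules, traj.n_frames, record.costs.mean(),
              label_spread(traj), label_spread(reduced)],
})
summary.to_csv("results/permutation_summary.csv", index=False)
print(summary.to_string(index=False))
print("\nLabels are localized: the per-label spread drops by "
      f"{label_spread(traj) / label_spread(reduced):.1f}x, while each "
      "frame's multiset of molecular states is untouched.")
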