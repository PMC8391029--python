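#!/usr/bin/env python
"""Shell-resolved solvent entropy on a structured synthetic ensemble.

Builds a correlated Gaussian solvent (one coupled pair and one coupled
triple among otherwise independent molecules), runs the third-order
mutual-information expansion with k = 1 neighbors, and assembles the
inner-shell entropy S_internal - I/2.  The exact joint entropy of the
generator serves as the reference.  Writes results/shell_entropy.json.
"""

import json

import numpy as np

import hydroshell as hs
from hydroshell.entropy import mie_total, shell_entropy
from hydroshell.system import ShellAssignment

N_MOL, N_FRAMES = 6, 6000
traj, ref = hs.gen_gaussian_cloud(
    N_MOL, N_FRAMES, seed=4, sigma=0.05, box=3.0,
    correlated_pairs=[(0, 1, 0.8)], coupled_triples=[(2, 3, 4, 0.5)])

pairs = [(0, 1), (2, 3), (2, 4), (3, 4)]
terms = hs.compute_entropy_terms(traj, pairs=pairs, triples=[(2, 3, 4)])
shells = ShellAssignment(order=np.arange(N_MOL), n_analysis=N_MOL, n_inner=4)
se = shell_entropy(terms, shells)

total = mie_total(terms, range(N_MOL))
rot_parts = (sum(terms.S1_rot.values()) - sum(terms.I_tr_self.values())
             - sum(terms.I2_rot.values()) + sum(terms.I3_rot.values())
             - sum(terms.I2_transrot.values()))
out = {
    "n_molecules": N_MOL, "n_frames": N_FRAMES,
    "S1_trans_sum_nats": sum(terms.S1_trans.values()),
    "I2_trans_sum_nats": sum(terms.I2_trans.values()),
    "I3_trans_sum_nats": sum(terms.I3_trans.values()),
    "mie_total_nats": total,
    "mie_trans_part_nats": total - rot_parts,
    "analytic_trans_joint_nats": ref.joint_entropy(range(N_MOL)),
    "S_internal_nats": se.S_internal,
    "I_cross_nats": se.I_cross,
    "S_shell_nats": se.S_shell,
    "minus_TS_shell_kJ_per_mol": terms.minus_TS(se.S_shell),
}
with open("results/shell_entropy.json", "w") as fh:
    json.dump(out, fh, indent=2)
for key, val in out.items():
    print(f"{key}: {val:.4f}" if isinstance(val, float) else f"{key}: {val}")
err = out["mie_trans_part_nats"] - out["analytic_trans_joint_nats"]
print(f"\nThird-order expansion vs exact joint entropy (translational): "
      f"{err:+.3f} nats — truncation is exact here because no dependence "
      "spans more than three molecules.")
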