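"""Permutation reduction of identical solvent molecules.

Physically identical molecules may be relabeled per frame without changing
any observable; choosing, for every frame, the labeling that minimizes the
total squared displacement of the locator sites from a reference frame
localizes each label in space.  This exploits the Gibbs N! permutation
symmetry and is a prerequisite for per-molecule entropy and energy
bookkeeping.

The assignment problem is solved exactly (Hungarian-class algorithm) on the
minimum-image squared-distance matrix between locator sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as _iter_permutations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .system import SolventTrajectory, minimum_image


@dataclass
class PermutationRecord:
    """Per-frame optimal permutations and their costs.

    ``perms[f][i]`` is the original molecule index assigned to label ``i`` in
    frame ``f``; ``costs[f]`` is the attained sum of squared minimum-image
    locator displacements (nm^2) from the reference frame.
    """

    perms: np.ndarray          # (n_frames, n_molecules) int
    costs: np.ndarray          # (n_frames,)
    reference_frame: int

    def __post_init__(self) -> None:
        n = self.perms.shape[1]
        for f, p in enumerate(self.perms):
            if sorted(p.tolist()) != list(range(n)):
                raise ValueError(f"frame {f}: permutation is not a bijection")
        if np.any(self.costs < 0):
            raise ValueError("assignment costs must be non-negative")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "frame": np.arange(len(self.costs)),
            "cost_nm2": self.costs,
            "permutation": [_cycle_notation(p) for p in self.perms],
        })


def _cycle_notation(perm: np.ndarray) -> str:
    seen = np.zeros(len(perm), dtype=bool)
    cycles = []
    for start in range(len(perm)):
        if seen[start]:
            continue
        cyc = [start]
        seen[start] = True
        j = int(perm[start])
        while j != start:
            cyc.append(j)
            seen[j] = True
            j = int(perm[j])
        if len(cyc) > 1:
            cycles.append("(" + " ".join(map(str, cyc)) + ")")
    return "".join(cycles) or "()"


def _cost_matrix(frame_pos: np.ndarray, ref_pos: np.ndarray,
                 box: np.ndarray) -> np.ndarray:
    """Squared minimum-image distances, rows = reference labels, columns =
    frame molecules."""
    delta = minimum_image(frame_pos[None, :, :] - ref_pos[:, None, :], box)
    return np.einsum("ijk,ijk->ij", delta, delta)


def permute_trajectory(traj: SolventTrajectory, reference_frame: int = 0,
                       ) -> tuple[SolventTrajectory, PermutationRecord]:
    """Relabel molecules in every frame to minimize the summed squared
    minimum-image displacement of locator sites from ``reference_frame``.

    All sites and the orientation of a molecule move together with its label;
    each frame's content as a multiset of molecule states is unchanged.
    """
    n_frames, n_mol = traj.positions.shape[:2]
    if not 0 <= reference_frame < n_frames:
        raise ValueError(f"reference frame {reference_frame} out of range")
    ref = traj.positions[reference_frame]

    perms = np.empty((n_frames, n_mol), dtype=int)
    costs = np.empty(n_frames)
    new_pos = np.empty_like(traj.positions)
    new_quat = np.empty_like(traj.quaternions)
    for f in range(n_frames):
        cost = _cost_matrix(traj.positions[f], ref, traj.box[f])
        rows, cols = linear_sum_assignment(cost)
        perm = cols[np.argsort(rows)]
        perms[f] = perm
        costs[f] = cost[np.arange(n_mol), perm].sum()
        new_pos[f] = traj.positions[f][perm]
        new_quat[f] = traj.quaternions[f][perm]

    reduced = SolventTrajectory(new_pos, new_quat, traj.box.copy(),
                                traj.frame_interval, traj.sites)
    return reduced, PermutationRecord(perms, costs, reference_frame)


def brute_force_permute(frame_pos: np.ndarray, ref_pos: np.ndarray,
                        box: np.ndarray) -> tuple[np.ndarray, float]:
    """Exhaustive-minimum assignment over all N! permutations (test oracle).

    Guarded at N <= 8; returns (permutation, cost) with the same convention
    as :func:`permute_trajectory`.
    """
    n = len(frame_pos)
    if n > 8:
        raise ValueError("brute force guarded at N <= 8")
    cost = _cost_matrix(np.asarray(frame_pos, float), np.asarray(ref_pos, float),
                        np.asarray(box, float))
    best_perm, best_cost = None, np.inf
    for p in _iter_permutations(range(n)):
        c = cost[np.arange(n), list(p)].sum()
        if c < best_cost:
            best_cost, best_perm = c, np.array(p, dtype=int)
    return best_perm, float(best_cost)
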