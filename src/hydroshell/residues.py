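"""Per-residue local solvation thermodynamics, surface convexity, and
hydrophobicity correlations.

A water molecule belongs to a residue in a frame when its locator lies
within 0.4 nm of any atom of that residue (minimal atom distance); waters
near several residues count for each.  The local interaction energy,
entropy contribution and free energy of a residue are visitation-weighted
means of the bulk-referenced per-molecule ledger values over all assigned
water-frame observations (the pV term is neglected, being small and state
independent).

The convexity of the protein-water surface at a residue is

    c = N_d / ((4/3 pi d^3 - V_res) n_W),

with N_d the frame-averaged number of waters within d = 1 nm of the residue
center, V_res the residue's own volume and n_W the bulk water number
density; c = 1 marks a fully exposed residue and c = 0 a buried one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .maps import PerMoleculeLedger
from .synthetic import BULK_WATER_DENSITY
from .system import SolvatedSystem, minimum_image

ASSIGN_CUTOFF_NM = 0.4
CONVEXITY_RADIUS_NM = 1.0


# --------------------------------------------------------------------------
# water-to-residue assignment
# --------------------------------------------------------------------------

def assign_waters(system: SolvatedSystem, cutoff: float = ASSIGN_CUTOFF_NM,
                  molecules: np.ndarray | None = None,
                  mode: str = "multi") -> dict[int, dict[int, int]]:
    """Per-residue water visitation counts over the trajectory.

    Returns ``{residue_id: {molecule: n_frames_assigned}}``.  With
    ``mode='multi'`` (default) a water within ``cutoff`` of several residues
    counts for each; ``mode='nearest'`` assigns it only to the closest one.
    """
    if mode not in ("multi", "nearest"):
        raise ValueError("mode must be 'multi' or 'nearest'")
    traj = system.solvent
    mols = (np.arange(traj.n_molecules) if molecules is None
            else np.asarray(molecules, dtype=int))
    res_ids = [r.residue_id for r in system.solute.residues]
    res_atoms = {rid: system.solute.residue_atom_indices(rid) for rid in res_ids}
    counts: dict[int, dict[int, int]] = {rid: {} for rid in res_ids}

    for f in range(traj.n_frames):
        solute_xyz = system.solute.frame_positions(f)
        wat = traj.positions[f][mols]
        box = traj.box[f]
        dmin = np.full((len(res_ids), len(mols)), np.inf)
        for r_i, rid in enumerate(res_ids):
            atoms = solute_xyz[res_atoms[rid]]
            delta = minimum_image(wat[:, None, :] - atoms[None], box)
            dmin[r_i] = np.linalg.norm(delta, axis=-1).min(axis=1)
        if mode == "multi":
            hits = dmin <= cutoff
        else:
            nearest = np.argmin(dmin, axis=0)
            hits = np.zeros_like(dmin, dtype=bool)
            ok = dmin[nearest, np.arange(len(mols))] <= cutoff
            hits[nearest[ok], np.nonzero(ok)[0]] = True
        for r_i, rid in enumerate(res_ids):
            for m in mols[hits[r_i]]:
                counts[rid][int(m)] = counts[rid].get(int(m), 0) + 1
    return counts


# --------------------------------------------------------------------------
# per-residue thermodynamics
# --------------------------------------------------------------------------

@dataclass
class ResidueContribution:
    residue_id: int
    name: str
    polarity: str
    dU: float                  # kJ/mol per nearby water, bulk-referenced
    minus_TdS: float
    dF: float
    n_waters: float            # mean assigned waters per frame
    convexity: float | None = None
    hydrophobicity: float | None = None
    defined: bool = True


_ENTROPY_CHANNELS = ("S1_trans", "S1_rot", "S2_trans", "S2_rot", "transrot")


def residue_thermodynamics(system: SolvatedSystem,
                           assignment: dict[int, dict[int, int]],
                           ledger: PerMoleculeLedger,
                           ) -> list[ResidueContribution]:
    """Visitation-weighted mean ledger values per residue.

    The ledger is expected to be bulk-referenced; waters without ledger
    entries (outside the analysis set) are ignored.  Residues with no
    assigned ledger-covered waters are flagged undefined (NaN values).
    """
    n_frames = system.solvent.n_frames
    out: list[ResidueContribution] = []
    for res in system.solute.residues:
        visits = assignment.get(res.residue_id, {})
        w = {m: n for m, n in visits.items()
             if m in ledger.channels["dF"]}
        total = sum(w.values())
        if total == 0:
            out.append(ResidueContribution(res.residue_id, res.name, res.polarity,
                                           np.nan, np.nan, np.nan, 0.0,
                                           defined=False))
            continue

        def wmean(channels: tuple[str, ...]) -> float:
            acc = 0.0
            for m, n in w.items():
                acc += n * sum(ledger.channels[c].get(m, 0.0) for c in channels)
            return acc / total

        du = wmean(("U_PS", "U_SS"))
        mts = wmean(_ENTROPY_CHANNELS)
        out.append(ResidueContribution(
            res.residue_id, res.name, res.polarity, du, mts, du + mts,
            n_waters=sum(visits.values()) / n_frames))
    return out


# --------------------------------------------------------------------------
# convexity
# --------------------------------------------------------------------------

def residue_volume(system: SolvatedSystem, residue_id: int,
                   overlap_correction: bool = False) -> float:
    """Residue volume (nm^3) as the sum of atomic van-der-Waals sphere
    volumes; with ``overlap_correction`` a Monte-Carlo union volume is used
    instead (pairwise sphere overlaps are otherwise double counted)."""
    atoms = system.solute.residue_atom_indices(residue_id)
    radii = np.array([system.solute.atoms[i].vdw_radius for i in atoms])
    if not overlap_correction:
        return float(np.sum(4.0 / 3.0 * np.pi * radii ** 3))
    pos = system.solute.frame_positions(0)[atoms]
    if np.all(radii == 0):
        return 0.0
    lo = (pos - radii[:, None]).min(axis=0)
    hi = (pos + radii[:, None]).max(axis=0)
    rng = np.random.default_rng(0)
    pts = rng.uniform(lo, hi, size=(200_000, 3))
    d = np.linalg.norm(pts[:, None, :] - pos[None], axis=-1)
    inside = np.any(d <= radii[None, :], axis=1)
    return float(inside.mean() * np.prod(hi - lo))


def convexity(system: SolvatedSystem, residue_id: int,
              d: float = CONVEXITY_RADIUS_NM,
              n_w: float = BULK_WATER_DENSITY,
              overlap_correction: bool = False) -> float:
    """Convexity c = N_d / ((4/3 pi d^3 - V_res) n_W) of one residue.

    N_d is the frame-averaged number of water locators within ``d`` of the
    residue's heavy-atom center of geometry (minimum image); V_res the
    residue volume.  Raises if V_res fills the whole reference sphere.
    """
    if d <= 0 or n_w <= 0:
        raise ValueError("d and n_w must be positive")
    sphere = 4.0 / 3.0 * np.pi * d ** 3
    v_res = residue_volume(system, residue_id, overlap_correction)
    if v_res >= sphere:
        raise ValueError(f"residue volume {v_res:.3f} nm^3 fills the "
                         f"reference sphere ({sphere:.3f} nm^3)")
    atoms = system.solute.residue_atom_indices(residue_id)
    heavy = [i for i in atoms if system.solute.atoms[i].element != "H"] or list(atoms)
    traj = system.solvent
    n_d = 0.0
    for f in range(traj.n_frames):
        center = system.solute.frame_positions(f)[heavy].mean(axis=0)
        delta = minimum_image(traj.positions[f] - center[None], traj.box[f])
        n_d += np.count_nonzero(np.linalg.norm(delta, axis=-1) <= d)
    n_d /= traj.n_frames
    return float(n_d / ((sphere - v_res) * n_w))


# --------------------------------------------------------------------------
# hydrophobicity scale
# --------------------------------------------------------------------------

def load_hydrophobicity_scale(path=None) -> dict[str, float]:
    """Residue-name -> hydrophobicity index from a two-column CSV
    (residue,index; '#' comments allowed).  Without ``path`` the bundled
    *synthetic placeholder* scale ships; swap in an empirical scale for real
    analyses."""
    import pandas as pd

    if path is None:
        from importlib.resources import files

        path = files("hydroshell.data") / "hydrophobicity_synthetic.csv"
    with open(path) as fh:
        df = pd.read_csv(fh, comment="#")
    return dict(zip(df["residue"].astype(str), df["index"].astype(float)))


# --------------------------------------------------------------------------
# correlation
# --------------------------------------------------------------------------

def correlate(values_x, values_y) -> float:
    """Pearson product-moment correlation with listwise exclusion of
    non-finite pairs; returns NaN (with a warning) on zero variance."""
    x = np.asarray(values_x, dtype=float)
    y = np.asarray(values_y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 finite pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance: correlation undefined")
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)
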