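"""Domain types and I/O for solvated systems.

Conventions
-----------
* Lengths in nm, times in ps, charges in e, energies in kJ mol^-1.
* Quaternions are stored scalar-first ``(w, x, y, z)`` and unit-normalized.
  The water body frame has z along the dipole bisector of H-O-H and x along
  the in-plane H-H direction; the quaternion rotates body-frame vectors into
  the lab frame.
* A molecule's "locator" site (the oxygen for water) defines its position for
  shell ranking, voxel visitation and permutation reduction.
* Boxes are rectangular and periodic; distances use the minimum-image
  convention.  Internal indexing is 0-based; residue ids are 1-based.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation


# --------------------------------------------------------------------------
# parameter and structure types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NonbondedParams:
    """Per-site nonbonded parameters: mass (amu), charge (e), LJ sigma (nm),
    LJ epsilon (kJ mol^-1)."""

    mass: float
    charge: float
    lj_sigma: float
    lj_epsilon: float

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"mass must be positive, got {self.mass}")
        if self.lj_sigma < 0 or self.lj_epsilon < 0:
            raise ValueError("LJ sigma and epsilon must be non-negative")


@dataclass(frozen=True)
class Site:
    """A solvent interaction site: name, body-frame offset from the locator
    (nm), and nonbonded parameters."""

    name: str
    offset: tuple[float, float, float]
    params: NonbondedParams


# TIP3P-like 3-site water used by the synthetic generators and as the default
# solvent species.  O-H 0.09572 nm, H-O-H 104.52 deg; dipole bisector along +z.
_OH = 0.09572
_HALF_ANGLE = np.deg2rad(104.52 / 2.0)

WATER_SITES: tuple[Site, ...] = (
    Site("OW", (0.0, 0.0, 0.0),
         NonbondedParams(15.9994, -0.834, 0.31506, 0.63639)),
    Site("HW1", (float(_OH * np.sin(_HALF_ANGLE)), 0.0, float(_OH * np.cos(_HALF_ANGLE))),
         NonbondedParams(1.008, 0.417, 0.0, 0.0)),
    Site("HW2", (float(-_OH * np.sin(_HALF_ANGLE)), 0.0, float(_OH * np.cos(_HALF_ANGLE))),
         NonbondedParams(1.008, 0.417, 0.0, 0.0)),
)


@dataclass
class Residue:
    residue_id: int          # 1-based
    name: str
    polarity: str = "apolar"  # charged | polar | apolar

    def __post_init__(self) -> None:
        if self.polarity not in ("charged", "polar", "apolar"):
            raise ValueError(f"unknown polarity class {self.polarity!r}")


@dataclass
class SoluteAtom:
    name: str
    element: str
    residue_id: int
    residue_name: str
    vdw_radius: float
    params: NonbondedParams


@dataclass
class SoluteStructure:
    """Solute atoms with per-frame (or static, n_frames == 1) positions."""

    positions: np.ndarray          # (n_frames or 1, n_atoms, 3)
    atoms: list[SoluteAtom]
    residues: list[Residue]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim == 2:
            self.positions = self.positions[None]
        if self.positions.shape[1] != len(self.atoms):
            raise ValueError("positions second axis must match atom count")
        ids = sorted({r.residue_id for r in self.residues})
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError("residue ids must be contiguous from 1")
        known = {r.residue_id for r in self.residues}
        for a in self.atoms:
            if a.residue_id not in known:
                raise ValueError(f"atom {a.name} maps to unknown residue {a.residue_id}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def frame_positions(self, frame: int) -> np.ndarray:
        """Atom positions for ``frame`` (static structures broadcast)."""
        return self.positions[min(frame, self.positions.shape[0] - 1)]

    def residue_atom_indices(self, residue_id: int) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms)
                         if a.residue_id == residue_id], dtype=int)


# --------------------------------------------------------------------------
# solvent trajectory
# --------------------------------------------------------------------------

@dataclass
class SolventTrajectory:
    """Localized solvent molecules over a trajectory.

    ``positions`` holds the locator site (n_frames, n_molecules, 3);
    ``quaternions`` the body-to-lab orientation (n_frames, n_molecules, 4),
    scalar first.  All molecules are chemically identical with the shared
    site table ``sites`` (first entry is the locator).
    """

    positions: np.ndarray
    quaternions: np.ndarray
    box: np.ndarray                      # (n_frames, 3)
    frame_interval: float = 10.0         # ps
    sites: tuple[Site, ...] = WATER_SITES

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.quaternions = np.asarray(self.quaternions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.box.ndim == 1:
            self.box = np.tile(self.box, (self.positions.shape[0], 1))
        if self.positions.shape[:2] != self.quaternions.shape[:2]:
            raise ValueError("positions and quaternions must agree on (frames, molecules)")
        norms = np.linalg.norm(self.quaternions, axis=-1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("quaternions must be unit within 1e-6")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_molecules(self) -> int:
        return self.positions.shape[1]

    def wrapped_positions(self) -> np.ndarray:
        """Locator positions wrapped into [0, box) per frame."""
        return np.mod(self.positions, self.box[:, None, :])

    def site_positions(self, frame: int) -> np.ndarray:
        """All site positions for one frame, shape (n_molecules, n_sites, 3)."""
        offsets = np.array([s.offset for s in self.sites])           # (S, 3)
        rot = Rotation.from_quat(self.quaternions[frame][:, [1, 2, 3, 0]])
        mats = rot.as_matrix()                                       # (M, 3, 3)
        lab_offsets = np.einsum("mij,sj->msi", mats, offsets)
        return self.positions[frame][:, None, :] + lab_offsets

    def subset(self, molecule_indices: Sequence[int]) -> "SolventTrajectory":
        idx = np.asarray(molecule_indices, dtype=int)
        return SolventTrajectory(self.positions[:, idx], self.quaternions[:, idx],
                                 self.box.copy(), self.frame_interval, self.sites)


@dataclass
class SolvatedSystem:
    solute: SoluteStructure
    solvent: SolventTrajectory


# --------------------------------------------------------------------------
# geometry helpers
# --------------------------------------------------------------------------

def minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement for a rectangular periodic box.

    ``delta`` is (..., 3); ``box`` broadcasts against it.
    """
    delta = np.asarray(delta, dtype=float)
    box = np.asarray(box, dtype=float)
    return delta - box * np.round(delta / box)


def minimum_image_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    return np.linalg.norm(minimum_image(a - b, box), axis=-1)


# --------------------------------------------------------------------------
# shell assignment
# --------------------------------------------------------------------------

@dataclass
class ShellAssignment:
    """Solvent molecules ordered by trajectory-average minimal distance to the
    solute; the closest ``n_analysis`` form the analysis set and the closest
    ``n_inner`` the inner solvation shell."""

    order: np.ndarray        # permutation of all solvent indices, closest first
    n_analysis: int
    n_inner: int
    mean_distances: np.ndarray = field(default=None)  # aligned with `order`

    def __post_init__(self) -> None:
        order = np.asarray(self.order, dtype=int)
        if sorted(order.tolist()) != list(range(order.size)):
            raise ValueError("order must be a permutation of all solvent indices")
        if self.n_inner > self.n_analysis:
            raise ValueError("n_inner may not exceed n_analysis")
        self.order = order

    @property
    def analysis_set(self) -> np.ndarray:
        return self.order[: self.n_analysis]

    @property
    def inner_shell(self) -> np.ndarray:
        return self.order[: self.n_inner]

    @property
    def outer_analysis(self) -> np.ndarray:
        """Analysis-set molecules outside the inner shell."""
        return self.order[self.n_inner: self.n_analysis]


def rank_shells(system: SolvatedSystem, n_analysis: int = 4000,
                n_inner: int = 1000) -> ShellAssignment:
    """Order solvent molecules by trajectory-average minimal distance from the
    locator site to any solute atom (minimum image); ties break by molecule
    index.  ``n_analysis``/``n_inner`` larger than the molecule count are
    clamped with a warning.
    """
    if n_inner > n_analysis:
        raise ValueError(f"n_inner ({n_inner}) exceeds n_analysis ({n_analysis})")
    traj = system.solvent
    n_mol = traj.n_molecules
    if n_analysis > n_mol:
        warnings.warn(f"n_analysis={n_analysis} exceeds molecule count {n_mol}; clamping")
        n_analysis = n_mol
    n_inner = min(n_inner, n_analysis)

    dist_sum = np.zeros(n_mol)
    for f in range(traj.n_frames):
        solute_xyz = system.solute.frame_positions(f)                # (A, 3)
        delta = traj.positions[f][:, None, :] - solute_xyz[None]     # (M, A, 3)
        d = np.linalg.norm(minimum_image(delta, traj.box[f]), axis=-1)
        dist_sum += d.min(axis=1)
    mean_d = dist_sum / traj.n_frames
    order = np.argsort(mean_d, kind="stable")  # stable -> lower index wins ties
    return ShellAssignment(order=order, n_analysis=n_analysis, n_inner=n_inner,
                           mean_distances=mean_d[order])


# --------------------------------------------------------------------------
# parameter table I/O
# --------------------------------------------------------------------------

def read_params_table(path: str | Path) -> pd.DataFrame:
    """Read the nonbonded parameter CSV (columns: name, type, mass, charge,
    sigma, epsilon, vdw_radius), indexed by atom name."""
    df = pd.read_csv(path)
    required = {"name", "type", "mass", "charge", "sigma", "epsilon", "vdw_radius"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"parameter table missing columns: {sorted(missing)}")
    return df.set_index("name")


def params_for(df: pd.DataFrame, atom_name: str) -> NonbondedParams:
    if atom_name not in df.index:
        raise KeyError(f"no nonbonded parameters for atom type {atom_name!r}")
    row = df.loc[atom_name]
    return NonbondedParams(float(row["mass"]), float(row["charge"]),
                           float(row["sigma"]), float(row["epsilon"]))


# --------------------------------------------------------------------------
# plain-text trajectory dialect
# --------------------------------------------------------------------------
#
# frame header:  "frame <index> time <ps> box <bx> <by> <bz>"
# site line:     "<molecule_id> <site_name> <x> <y> <z> [<qw> <qx> <qy> <qz>]"
# The quaternion is carried on the locator (first) site line of each molecule.

def write_text_trajectory(traj: SolventTrajectory, path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            t = f * traj.frame_interval
            bx, by, bz = traj.box[f]
            fh.write(f"frame {f} time {t:.4f} box {bx:.6f} {by:.6f} {bz:.6f}\n")
            sites = traj.site_positions(f)
            for m in range(traj.n_molecules):
                for s, site in enumerate(traj.sites):
                    x, y, z = sites[m, s]
                    line = f"{m} {site.name} {x:.7f} {y:.7f} {z:.7f}"
                    if s == 0:
                        q = traj.quaternions[f, m]
                        line += " " + " ".join(f"{v:.8f}" for v in q)
                    fh.write(line + "\n")


def read_text_trajectory(path: str | Path,
                         sites: tuple[Site, ...] = WATER_SITES) -> SolventTrajectory:
    frames_pos: list[np.ndarray] = []
    frames_quat: list[np.ndarray] = []
    boxes: list[np.ndarray] = []
    times: list[float] = []
    cur_pos: dict[int, np.ndarray] = {}
    cur_quat: dict[int, np.ndarray] = {}

    def flush() -> None:
        if not cur_pos:
            return
        ids = sorted(cur_pos)
        frames_pos.append(np.array([cur_pos[i] for i in ids]))
        frames_quat.append(np.array([cur_quat.get(i, np.array([1.0, 0, 0, 0]))
                                     for i in ids]))
        cur_pos.clear()
        cur_quat.clear()

    with open(path) as fh:
        for raw in fh:
            tok = raw.split()
            if not tok:
                continue
            if tok[0] == "frame":
                flush()
                times.append(float(tok[3]))
                boxes.append(np.array([float(v) for v in tok[5:8]]))
                continue
            mol = int(tok[0])
            name = tok[1]
            xyz = np.array([float(v) for v in tok[2:5]])
            if mol not in cur_pos:          # first (locator) site of molecule
                cur_pos[mol] = xyz
            if name == sites[0].name and len(tok) >= 9:
                q = np.array([float(v) for v in tok[5:9]])
                cur_quat[mol] = q / np.linalg.norm(q)
    flush()

    counts = {p.shape[0] for p in frames_pos}
    if len(counts) != 1:
        raise ValueError(f"molecule count varies across frames: {sorted(counts)}")
    interval = times[1] - times[0] if len(times) > 1 else 10.0
    return SolventTrajectory(np.array(frames_pos), np.array(frames_quat),
                             np.array(boxes), interval, sites)


# --------------------------------------------------------------------------
# full-system reader
# --------------------------------------------------------------------------

_WATER_RESNAMES = {"SOL", "WAT", "HOH", "TIP3", "TIP", "SPC"}
_TEXT_SUFFIXES = {".txt", ".dat", ".frames"}


def orientation_from_water_sites(o: np.ndarray, h1: np.ndarray,
                                 h2: np.ndarray) -> np.ndarray:
    """Body-to-lab quaternion(s) (w, x, y, z) from O/H1/H2 positions.

    z = normalized H-O-H bisector, x = in-plane H1-H2 direction, y = z cross x.
    Accepts arrays shaped (..., 3).
    """
    b1 = h1 - o
    b2 = h2 - o
    z = b1 + b2
    z = z / np.linalg.norm(z, axis=-1, keepdims=True)
    x = b1 - b2
    x = x - np.sum(x * z, axis=-1, keepdims=True) * z
    x = x / np.linalg.norm(x, axis=-1, keepdims=True)
    y = np.cross(z, x)
    mats = np.stack([x, y, z], axis=-1)      # columns are body axes in lab frame
    q = Rotation.from_matrix(mats.reshape(-1, 3, 3)).as_quat()  # (x, y, z, w)
    q = q[:, [3, 0, 1, 2]]
    return q.reshape(o.shape[:-1] + (4,))


def read_system(structure_path: str | Path, trajectory_path: str | Path,
                params_path: str | Path) -> SolvatedSystem:
    """Read a solvated system: structure (PDB/GRO), solvent trajectory
    (XTC/DCD/TRR via MDAnalysis, or the plain-text dialect), and a nonbonded
    parameter CSV.

    Solvent residues are recognized by name (SOL/WAT/HOH/TIP3/SPC); water
    orientations are derived from the O/H/H site geometry when the trajectory
    does not carry quaternions.
    """
    params = read_params_table(params_path)
    structure_path = Path(structure_path)
    trajectory_path = Path(trajectory_path)

    import MDAnalysis as mda  # heavy import kept local

    uni = mda.Universe(str(structure_path))
    solvent_sel = uni.residues[np.isin(uni.residues.resnames, list(_WATER_RESNAMES))]
    solute_atoms_grp = uni.atoms - solvent_sel.atoms

    atoms: list[SoluteAtom] = []
    res_map: dict[int, Residue] = {}
    rid = 0
    last_resindex = None
    for a in solute_atoms_grp:
        if a.resindex != last_resindex:
            rid += 1
            last_resindex = a.resindex
            res_map[rid] = Residue(rid, str(a.resname), _polarity_of(str(a.resname)))
        row = params_for(params, str(a.name))
        vdw = float(params.loc[str(a.name)]["vdw_radius"])
        atoms.append(SoluteAtom(str(a.name), str(a.element) if hasattr(a, "element")
                                else str(a.name)[0], rid, str(a.resname), vdw, row))
    solute = SoluteStructure(solute_atoms_grp.positions[None] / 10.0, atoms,
                             list(res_map.values()))

    if trajectory_path.suffix.lower() in _TEXT_SUFFIXES:
        solvent = read_text_trajectory(trajectory_path)
        n_struct = len(solvent_sel)
        if n_struct and solvent.n_molecules != n_struct:
            raise ValueError(
                f"solvent molecule count mismatch: structure has {n_struct}, "
                f"trajectory has {solvent.n_molecules}")
        return SolvatedSystem(solute, solvent)

    traj_uni = mda.Universe(str(structure_path), str(trajectory_path))
    if len(traj_uni.atoms) != len(uni.atoms):
        raise ValueError(
            f"atom count mismatch: structure has {len(uni.atoms)} atoms, "
            f"trajectory frames have {len(traj_uni.atoms)}")
    wat = traj_uni.residues[np.isin(traj_uni.residues.resnames, list(_WATER_RESNAMES))]
    n_mol = len(wat)
    pos, quat, box = [], [], []
    for _ in traj_uni.trajectory:
        xyz = wat.atoms.positions.reshape(n_mol, -1, 3) / 10.0   # Angstrom -> nm
        pos.append(xyz[:, 0].copy())
        quat.append(orientation_from_water_sites(xyz[:, 0], xyz[:, 1], xyz[:, 2]))
        box.append(traj_uni.dimensions[:3] / 10.0)
    dt = traj_uni.trajectory.dt if traj_uni.trajectory.dt else 10.0
    solvent = SolventTrajectory(np.array(pos), np.array(quat), np.array(box), dt)
    return SolvatedSystem(solute, solvent)


_CHARGED = {"ARG", "LYS", "ASP", "GLU", "HIS"}
_POLAR = {"SER", "THR", "ASN", "GLN", "TYR", "CYS", "TRP"}


def _polarity_of(resname: str) -> str:
    if resname in _CHARGED:
        return "charged"
    if resname in _POLAR:
        return "polar"
    return "apolar"
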