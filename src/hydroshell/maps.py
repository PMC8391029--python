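"""Per-molecule thermodynamic ledgers and visitation-weighted voxel maps.

Multi-body terms are split equally between the molecules involved (half of
each pair term, a third of each triple term), removing the double/triple
counting inherent in pair sums.  Each molecule's scalar contribution is then
spread over space by accumulating, on a regular grid spanning the box, the
visitation-weighted average

    value(v) = sum_i n_iv c_i / sum_i n_iv,

where n_iv counts how often molecule i's locator visited voxel v.  Because
the trajectory is permutation-reduced, each voxel is visited by only a few
localized molecules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import KB, T_REF
from .entropy import EntropyTerms
from .enthalpy import EnergyDecomposition
from .system import SolventTrajectory

DEFAULT_GRID = 129

CHANNELS = ("S1_trans", "S1_rot", "S2_trans", "S2_rot", "transrot",
            "U_PS", "U_SS", "dF")


@dataclass
class PerMoleculeLedger:
    """Per-molecule scalar contributions per channel, kJ mol^-1 (entropies as
    -T*S).  ``channels[name][mol]``; pair terms carry half to each partner,
    triple terms a third, so each channel's sum over molecules equals the
    channel total."""

    channels: dict[str, dict[int, float]]
    T: float = T_REF

    def channel_total(self, name: str) -> float:
        return float(sum(self.channels[name].values()))

    def molecules(self) -> list[int]:
        out: set[int] = set()
        for ch in self.channels.values():
            out.update(ch)
        return sorted(out)

    def bulk_referenced(self, bulk_means: dict[str, float]) -> "PerMoleculeLedger":
        """Subtract a per-molecule bulk mean from every entry of each channel
        (channels absent from ``bulk_means`` pass through unchanged)."""
        out = {name: {m: v - bulk_means.get(name, 0.0) for m, v in ch.items()}
               for name, ch in self.channels.items()}
        return PerMoleculeLedger(out, self.T)


def split_terms(entropy_terms: EntropyTerms | None,
                energy_decomp: EnergyDecomposition | None,
                T: float = T_REF) -> PerMoleculeLedger:
    """Build the per-molecule ledger from entropy terms and/or an energy
    decomposition.

    Entropy channels are converted to -T*S contributions: single-molecule
    terms wholly to their molecule; each pair MI half to each partner; each
    triple interaction-information a third to each member, with the signs
    they carry in the expansion (-I2, +I3, -I_tr).  Energy channels take
    U_PS wholly, U_SS as the half-shared inner-inner part plus half of each
    inner-outer coupling.  ``dF`` is the sum of all channels present.
    """
    ch: dict[str, dict[int, float]] = {name: {} for name in CHANNELS}

    def add(name: str, mol: int, value: float) -> None:
        ch[name][mol] = ch[name].get(mol, 0.0) + value

    if entropy_terms is not None:
        to_f = -T * KB  # nats -> -T*S in kJ/mol
        for i, s in entropy_terms.S1_trans.items():
            add("S1_trans", i, to_f * s)
        for i, s in entropy_terms.S1_rot.items():
            add("S1_rot", i, to_f * s)
        for i, s in entropy_terms.I_tr_self.items():
            add("transrot", i, to_f * (-s))
        for (i, j), v in entropy_terms.I2_trans.items():
            add("S2_trans", i, to_f * (-v) / 2)
            add("S2_trans", j, to_f * (-v) / 2)
        for (i, j), v in entropy_terms.I2_rot.items():
            add("S2_rot", i, to_f * (-v) / 2)
            add("S2_rot", j, to_f * (-v) / 2)
        for (i, j), v in entropy_terms.I2_transrot.items():
            add("transrot", i, to_f * (-v) / 2)
            add("transrot", j, to_f * (-v) / 2)
        for tri, v in entropy_terms.I3_trans.items():
            for m in tri:
                add("S2_trans", m, to_f * v / 3)
        for tri, v in entropy_terms.I3_rot.items():
            for m in tri:
                add("S2_rot", m, to_f * v / 3)

    if energy_decomp is not None:
        for i, v in energy_decomp.U_PS.items():
            add("U_PS", i, v)
        for i, v in energy_decomp.U_SS_inner.items():
            add("U_SS", i, v)
        for i, v in energy_decomp.U_inner_outer.items():
            add("U_SS", i, v / 2)

    mols = sorted(set().union(*[set(c) for c in ch.values() if c]) or set())
    for m in mols:
        ch["dF"][m] = sum(ch[name].get(m, 0.0) for name in CHANNELS
                          if name != "dF")
    return PerMoleculeLedger(ch, T)


# --------------------------------------------------------------------------
# voxel grid
# --------------------------------------------------------------------------

@dataclass
class VoxelGrid:
    """Visitation-weighted scalar field on a regular grid spanning the box.

    ``values`` is defined only where ``counts > 0``; empty voxels hold NaN.
    """

    values: np.ndarray       # (nx, ny, nz)
    counts: np.ndarray       # (nx, ny, nz) int
    origin: np.ndarray       # (3,) nm
    spacing: np.ndarray      # (3,) nm

    def __post_init__(self) -> None:
        if np.any(self.spacing <= 0):
            raise ValueError("grid spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def accumulate_grid(traj: SolventTrajectory, ledger: PerMoleculeLedger,
                    channel: str, n_voxels: int = DEFAULT_GRID) -> VoxelGrid:
    """Accumulate one ledger channel on an ``n_voxels``^3 grid spanning the
    (first-frame) box.  Locators are wrapped by minimum image into the box,
    never dropped."""
    values = ledger.channels[channel]
    mols = np.array(sorted(values), dtype=int)
    if mols.size == 0:
        raise ValueError(f"channel {channel!r} has no molecules")
    c = np.array([values[m] for m in mols])

    box = traj.box[0]
    spacing = box / n_voxels
    pos = np.mod(traj.positions[:, mols, :], box[None, None, :])
    idx = np.floor(pos / spacing).astype(int)
    np.clip(idx, 0, n_voxels - 1, out=idx)
    flat = (idx[..., 0] * n_voxels + idx[..., 1]) * n_voxels + idx[..., 2]

    counts = np.zeros(n_voxels ** 3, dtype=np.int64)
    sums = np.zeros(n_voxels ** 3)
    np.add.at(counts, flat.ravel(), 1)
    np.add.at(sums, flat.ravel(),
              np.broadcast_to(c[None, :], flat.shape).ravel())
    with np.errstate(invalid="ignore"):
        vals = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    shape = (n_voxels,) * 3
    return VoxelGrid(vals.reshape(shape), counts.reshape(shape),
                     origin=np.zeros(3), spacing=spacing)


# --------------------------------------------------------------------------
# OpenDX scalar-field I/O
# --------------------------------------------------------------------------

_DX_SENTINEL = 9999.0


def write_map(grid: VoxelGrid, path) -> None:
    """Write an OpenDX scalar field; empty voxels are written as the sentinel
    value recorded in the header comment."""
    nx, ny, nz = grid.shape
    vals = np.where(np.isnan(grid.values), _DX_SENTINEL, grid.values)
    with open(path, "w") as fh:
        fh.write("# visitation-weighted thermodynamic map (kJ/mol)\n")
        fh.write(f"# empty voxels written as sentinel {_DX_SENTINEL}\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin {:.6f} {:.6f} {:.6f}\n".format(*grid.origin))
        fh.write(f"delta {grid.spacing[0]:.6f} 0 0\n")
        fh.write(f"delta 0 {grid.spacing[1]:.6f} 0\n")
        fh.write(f"delta 0 0 {grid.spacing[2]:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items {vals.size} "
                 "data follows\n")
        flat = vals.ravel()
        for start in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.9g}" for v in flat[start:start + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "field" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')


def read_map(path) -> VoxelGrid:
    """Read a scalar field written by :func:`write_map` (sentinel -> NaN)."""
    shape = None
    origin = np.zeros(3)
    deltas: list[float] = []
    data: list[float] = []
    reading = False
    n_items = 0
    with open(path) as fh:
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            if reading and len(data) < n_items:
                try:
                    data.extend(float(t) for t in tok)
                    continue
                except ValueError:
                    reading = False
            if tok[0] == "#":
                continue
            if tok[:4] == ["object", "1", "class", "gridpositions"]:
                shape = tuple(int(t) for t in tok[5:8])
            elif tok[0] == "origin":
                origin = np.array([float(t) for t in tok[1:4]])
            elif tok[0] == "delta":
                deltas.append(max(float(t) for t in tok[1:4]))
            elif tok[0] == "object" and "array" in tok:
                n_items = int(tok[tok.index("items") + 1])
                reading = True
    if shape is None or len(data) < n_items:
        raise ValueError("malformed map file")
    vals = np.array(data[:n_items]).reshape(shape)
    nanvals = np.where(vals == _DX_SENTINEL, np.nan, vals)
    counts = (~np.isnan(nanvals)).astype(np.int64)
    return VoxelGrid(nanvals, counts, origin, np.array(deltas))
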