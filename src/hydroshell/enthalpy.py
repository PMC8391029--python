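"""Pairwise interaction-energy decomposition and the pV work term.

Energies are recomputed from per-site partial charges and Lennard-Jones
parameters with Lorentz-Berthelot combination:

    U(r) = 4 eps [(sig/r)^12 - (sig/r)^6] 1[r <= r_LJ]  +  f q_a q_b / r,

with a hard 2 nm Lennard-Jones cutoff and bare minimum-image Coulomb (no
lattice summation) — this is an analysis engine operating on stored
configurations, not a simulation engine.  For every inner-shell water
molecule the interaction energies with the solute (U_PS), with the other
inner-shell molecules (U_SS_inner, half-shared per pair) and with the outer
solvent (U_inner_outer) are averaged over frames.  Enthalpy H = U + pV with
pV = p <V>.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import BAR_NM3_TO_KJ_PER_MOL, COULOMB_FACTOR
from .system import (
    NonbondedParams,
    ShellAssignment,
    SolvatedSystem,
    minimum_image,
)

LJ_CUTOFF_NM = 2.0


def pair_interaction_energy(params_a: NonbondedParams, params_b: NonbondedParams,
                            r: float | np.ndarray,
                            lj_cutoff: float = LJ_CUTOFF_NM) -> float | np.ndarray:
    """Site-site nonbonded energy (kJ mol^-1) at separation r (nm).

    Lorentz-Berthelot: sigma arithmetic mean, epsilon geometric mean.
    Lennard-Jones hard-truncated at ``lj_cutoff``; Coulomb evaluated at all
    distances.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    sig = 0.5 * (params_a.lj_sigma + params_b.lj_sigma)
    eps = np.sqrt(params_a.lj_epsilon * params_b.lj_epsilon)
    u = np.zeros_like(r)
    if eps > 0 and sig > 0:
        sr6 = (sig / r) ** 6
        u = np.where(r <= lj_cutoff, 4.0 * eps * (sr6 ** 2 - sr6), 0.0)
    u = u + COULOMB_FACTOR * params_a.charge * params_b.charge / r
    return float(u) if u.ndim == 0 else u


@dataclass
class SiteGroup:
    """Flat per-site arrays with a group (molecule) index for energy sums."""

    positions: np.ndarray      # (n_sites, 3)
    charge: np.ndarray
    sigma: np.ndarray
    epsilon: np.ndarray
    group: np.ndarray          # (n_sites,) int, group id per site
    n_groups: int

    @classmethod
    def from_molecules(cls, site_pos: np.ndarray,
                       prm: list[NonbondedParams]) -> "SiteGroup":
        """Molecules sharing one site table: site_pos (M, S, 3)."""
        m, s = site_pos.shape[:2]
        return cls(site_pos.reshape(m * s, 3),
                   np.tile([p.charge for p in prm], m),
                   np.tile([p.lj_sigma for p in prm], m),
                   np.tile([p.lj_epsilon for p in prm], m),
                   np.repeat(np.arange(m), s), m)

    @classmethod
    def from_atoms(cls, pos: np.ndarray, prm: list[NonbondedParams],
                   single_group: bool = False) -> "SiteGroup":
        """Heterogeneous atoms, each its own group (or one collective group)."""
        n = pos.shape[0]
        group = np.zeros(n, dtype=int) if single_group else np.arange(n)
        return cls(np.asarray(pos, dtype=float),
                   np.array([p.charge for p in prm]),
                   np.array([p.lj_sigma for p in prm]),
                   np.array([p.lj_epsilon for p in prm]),
                   group, 1 if single_group else n)


def _group_pair_energy(a: SiteGroup, b: SiteGroup, box: np.ndarray,
                       lj_cutoff: float) -> np.ndarray:
    """(n_groups_a, n_groups_b) matrix of summed site-site pair energies.

    Self site pairs (identical coordinates) are excluded; intra-group pairs
    are included only when a and b are distinct objects covering different
    sites, so callers zero the diagonal for self-interactions.
    """
    delta = minimum_image(a.positions[:, None, :] - b.positions[None, :, :], box)
    r = np.linalg.norm(delta, axis=-1)
    same = r < 1e-12
    r = np.where(same, 1.0, r)

    sig = 0.5 * (a.sigma[:, None] + b.sigma[None, :])
    eps = np.sqrt(a.epsilon[:, None] * b.epsilon[None, :])
    sr6 = np.where(sig > 0, (sig / r) ** 6, 0.0)
    u = np.where(r <= lj_cutoff, 4.0 * eps * (sr6 ** 2 - sr6), 0.0)
    u += COULOMB_FACTOR * a.charge[:, None] * b.charge[None, :] / r
    u[same] = 0.0

    out = np.zeros((a.n_groups, b.n_groups))
    flat = a.group[:, None] * b.n_groups + b.group[None, :]
    np.add.at(out.reshape(-1), flat.ravel(), u.ravel())
    return out


@dataclass
class EnergyDecomposition:
    """Per-molecule and total interaction energies (kJ mol^-1), with the
    per-frame series retained for error analysis.

    ``U_SS_inner`` assigns half of each inner-inner pair energy to each
    partner, so its sum equals the full inner-inner energy with every pair
    counted once.  ``U_inner_outer`` holds the full coupling of each inner
    molecule to the outer solvent.
    """

    inner_molecules: np.ndarray                       # molecule indices
    U_PS: dict[int, float]
    U_SS_inner: dict[int, float]
    U_inner_outer: dict[int, float]
    U_PP: float
    pV: float
    per_frame: dict[str, np.ndarray] = field(default_factory=dict)
    U_PP_bonded: float | None = None

    @property
    def U_PS_total(self) -> float:
        return float(sum(self.U_PS.values()))

    @property
    def U_SS_total(self) -> float:
        """Inner-inner (once per pair) plus inner-outer coupling."""
        return float(sum(self.U_SS_inner.values())
                     + sum(self.U_inner_outer.values()))

    @property
    def U_PP_full(self) -> float:
        return self.U_PP + (self.U_PP_bonded or 0.0)

    @property
    def H(self) -> float:
        return self.U_PP_full + self.U_PS_total + self.U_SS_total + self.pV

    def components(self) -> dict[str, float]:
        return {"U_PP": self.U_PP_full, "U_PS": self.U_PS_total,
                "U_SS": self.U_SS_total, "pV": self.pV, "H": self.H}


def pv_term(volumes: np.ndarray, pressure: float = 1.0) -> float:
    """p <V> in kJ mol^-1 from a per-frame volume series (nm^3) at a pressure
    in bar."""
    volumes = np.asarray(volumes, dtype=float)
    if volumes.size == 0:
        raise ValueError("empty volume series")
    if np.any(volumes <= 0):
        raise ValueError("volumes must be positive")
    return float(pressure * volumes.mean() * BAR_NM3_TO_KJ_PER_MOL)


def decompose_enthalpy(system: SolvatedSystem, shells: ShellAssignment,
                       pressure: float = 1.0, lj_cutoff: float = LJ_CUTOFF_NM,
                       bonded_energy: np.ndarray | None = None,
                       ) -> EnergyDecomposition:
    """Trajectory-averaged interaction-energy decomposition.

    For each inner-shell molecule: U_PS with all solute atoms, U_SS_inner
    with the other inner molecules (half per pair), U_inner_outer with every
    molecule outside the inner shell.  U_PP is the solute-internal nonbonded
    pair energy (all distinct atom pairs); a per-frame externally computed
    bonded series may be added verbatim via ``bonded_energy``.
    """
    traj = system.solvent
    inner = np.asarray(shells.inner_shell, dtype=int)
    outer = np.setdiff1d(np.arange(traj.n_molecules), inner)
    n_frames = traj.n_frames
    if bonded_energy is not None:
        bonded_energy = np.asarray(bonded_energy, dtype=float)
        if bonded_energy.shape[0] != n_frames:
            raise ValueError("bonded energy series must have one entry per frame")

    solute_prm = [a.params for a in system.solute.atoms]
    site_prm = [s.params for s in traj.sites]

    ups = np.zeros((n_frames, len(inner)))
    uss_in = np.zeros((n_frames, len(inner)))
    uio = np.zeros((n_frames, len(inner)))
    upp = np.zeros(n_frames)
    for f in range(n_frames):
        box = traj.box[f]
        solute_xyz = system.solute.frame_positions(f)
        sites = traj.site_positions(f)                             # (M, S, 3)
        inner_grp = SiteGroup.from_molecules(sites[inner], site_prm)
        solute_one = SiteGroup.from_atoms(solute_xyz, solute_prm, single_group=True)

        ups[f] = _group_pair_energy(inner_grp, solute_one, box, lj_cutoff)[:, 0]

        m_ss = _group_pair_energy(inner_grp, inner_grp, box, lj_cutoff)
        np.fill_diagonal(m_ss, 0.0)
        uss_in[f] = 0.5 * m_ss.sum(axis=1)

        if outer.size:
            outer_grp = SiteGroup.from_molecules(sites[outer], site_prm)
            uio[f] = _group_pair_energy(inner_grp, outer_grp, box,
                                        lj_cutoff).sum(axis=1)

        if system.solute.n_atoms > 1:
            solute_atoms = SiteGroup.from_atoms(solute_xyz, solute_prm)
            m_pp = _group_pair_energy(solute_atoms, solute_atoms, box, lj_cutoff)
            np.fill_diagonal(m_pp, 0.0)
            upp[f] = 0.5 * m_pp.sum()

    volumes = np.prod(traj.box, axis=1)
    return EnergyDecomposition(
        inner_molecules=inner,
        U_PS={int(m): float(v) for m, v in zip(inner, ups.mean(axis=0))},
        U_SS_inner={int(m): float(v) for m, v in zip(inner, uss_in.mean(axis=0))},
        U_inner_outer={int(m): float(v) for m, v in zip(inner, uio.mean(axis=0))},
        U_PP=float(upp.mean()),
        pV=pv_term(volumes, pressure),
        per_frame={"U_PS": ups.sum(axis=1), "U_SS_inner": uss_in.sum(axis=1),
                   "U_inner_outer": uio.sum(axis=1), "U_PP": upp,
                   "volume": volumes},
        U_PP_bonded=(float(bonded_energy.mean()) if bonded_energy is not None
                     else None),
    )


def energy_difference(decomp_a: "EnergyDecomposition | dict[str, float]",
                      decomp_b: "EnergyDecomposition | dict[str, float]",
                      ) -> dict[str, float]:
    """Per-component differences mean(B) - mean(A).

    When assembling a folding budget, A is the native fold and B the
    molten-globule-like state, so positive values destabilize B.
    """
    comp_a = decomp_a.components() if hasattr(decomp_a, "components") else dict(decomp_a)
    comp_b = decomp_b.components() if hasattr(decomp_b, "components") else dict(decomp_b)
    if set(comp_a) != set(comp_b):
        raise ValueError(f"component mismatch: {sorted(set(comp_a) ^ set(comp_b))}")
    return {key: comp_b[key] - comp_a[key] for key in comp_a}
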