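"""Synthetic solvent ensembles with known statistical structure.

These generators stand in for molecular-dynamics sampling: they produce
:class:`~hydroshell.system.SolventTrajectory` objects whose entropies, mutual
informations and energies are known in closed form (attached as analytic
references), so every downstream estimator can be validated without running
a simulation.

All generators are seed-deterministic; the seed is mandatory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .system import (
    NonbondedParams,
    Residue,
    SoluteAtom,
    SoluteStructure,
    SolvatedSystem,
    SolventTrajectory,
)

TWO_PI_E = 2.0 * np.pi * np.e

#: TIP3P-like bulk water number density, nm^-3.
BULK_WATER_DENSITY = 33.4


# --------------------------------------------------------------------------
# specification record
# --------------------------------------------------------------------------

@dataclass
class EnsembleSpec:
    """Declarative description of a synthetic ensemble.

    ``kind`` selects the generator; ``params`` carries its keyword arguments.
    """

    kind: str
    n_molecules: int
    n_frames: int
    seed: int
    params: dict = field(default_factory=dict)

    _KINDS = ("ideal_gas", "gaussian_cloud", "orientation_ensemble",
              "coupled_transrot", "toy_solvated")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown ensemble kind {self.kind!r}")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def generate(spec: EnsembleSpec):
    """Dispatch an :class:`EnsembleSpec` to its generator."""
    fn = {
        "ideal_gas": gen_ideal_gas,
        "gaussian_cloud": gen_gaussian_cloud,
        "orientation_ensemble": gen_orientation_ensemble,
        "coupled_transrot": gen_coupled_transrot,
        "toy_solvated": gen_toy_solvated,
    }[spec.kind]
    if spec.kind == "toy_solvated":
        return fn(n_frames=spec.n_frames, seed=spec.seed, **spec.params)
    return fn(n_molecules=spec.n_molecules, n_frames=spec.n_frames,
              seed=spec.seed, **spec.params)


# --------------------------------------------------------------------------
# quaternion sampling
# --------------------------------------------------------------------------

def random_unit_quaternions(rng: np.random.Generator, shape: tuple) -> np.ndarray:
    """Haar-uniform unit quaternions (w, x, y, z) of the given leading shape."""
    q = rng.normal(size=shape + (4,))
    q /= np.linalg.norm(q, axis=-1, keepdims=True)
    return q


def wobble_quaternions(rng: np.random.Generator, shape: tuple,
                       sigma_rot: float) -> np.ndarray:
    """Small-angle Gaussian orientation noise about the identity: rotation
    vectors with independent per-axis std ``sigma_rot`` (rad)."""
    rv = rng.normal(scale=sigma_rot, size=shape + (3,))
    q = Rotation.from_rotvec(rv.reshape(-1, 3)).as_quat()  # (x, y, z, w)
    return q[:, [3, 0, 1, 2]].reshape(shape + (4,))


# --------------------------------------------------------------------------
# ideal gas (bulk reference emulator)
# --------------------------------------------------------------------------

def gen_ideal_gas(n_molecules: int, n_frames: int, box: float | Sequence[float],
                  seed: int, frame_interval: float = 10.0) -> SolventTrajectory:
    """Positions i.i.d. uniform in the box, orientations Haar-uniform."""
    if n_frames < 1:
        raise ValueError("n_frames must be at least 1")
    box = np.broadcast_to(np.asarray(box, dtype=float), (3,)).copy()
    if np.any(box <= 0):
        raise ValueError("box must be positive")
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.0, box, size=(n_frames, n_molecules, 3))
    quat = random_unit_quaternions(rng, (n_frames, n_molecules))
    return SolventTrajectory(pos, quat, np.tile(box, (n_frames, 1)), frame_interval)


# --------------------------------------------------------------------------
# correlated Gaussian clouds (oracle for translational entropy / MI)
# --------------------------------------------------------------------------

@dataclass
class GaussianReference:
    """Exact differential entropies for a per-axis jointly Gaussian ensemble.

    ``axis_cov`` holds one (M, M) covariance matrix per Cartesian axis
    (correlations couple matched axes only, so the three axes are independent
    blocks).  All entropies are in nats, positions in nm.
    """

    axis_cov: list[np.ndarray]

    def joint_entropy(self, indices: Sequence[int]) -> float:
        idx = np.asarray(indices, dtype=int)
        s = 0.0
        for cov in self.axis_cov:
            sub = cov[np.ix_(idx, idx)]
            sign, logdet = np.linalg.slogdet(TWO_PI_E * sub)
            if sign <= 0:
                raise ValueError("covariance block not positive definite")
            s += 0.5 * logdet
        return s

    def entropy_single(self, i: int) -> float:
        return self.joint_entropy([i])

    def mi_pair(self, i: int, j: int) -> float:
        return (self.entropy_single(i) + self.entropy_single(j)
                - self.joint_entropy([i, j]))

    def interaction_info(self, i: int, j: int, k: int) -> float:
        """Co-information I3 = S_i + S_j + S_k - S_ij - S_ik - S_jk + S_ijk,
        the third-order term of the mutual-information expansion
        S_ijk = sum S1 - sum I2 + I3."""
        s1 = sum(self.entropy_single(m) for m in (i, j, k))
        s2 = (self.joint_entropy([i, j]) + self.joint_entropy([i, k])
              + self.joint_entropy([j, k]))
        return s1 - s2 + self.joint_entropy([i, j, k])


def gen_gaussian_cloud(n_molecules: int, n_frames: int, seed: int,
                       sigma: float | Sequence[float] = 0.1,
                       means: np.ndarray | None = None,
                       box: float | Sequence[float] = 10.0,
                       correlated_pairs: Sequence[tuple[int, int, float]] = (),
                       coupled_triples: Sequence[tuple[int, int, int, float]] = (),
                       frame_interval: float = 10.0,
                       ) -> tuple[SolventTrajectory, GaussianReference]:
    """Per-molecule Gaussian position fluctuations with optional inter-molecule
    correlation on matched Cartesian axes.

    ``correlated_pairs`` entries (i, j, rho) impose correlation rho between
    molecules i and j on each axis; ``coupled_triples`` (i, j, k, rho) impose
    pairwise equicorrelation rho within the triple.  Orientations are
    Haar-uniform and independent of positions.

    Returns the trajectory and a :class:`GaussianReference` carrying the exact
    entropies, e.g. S1 = 3/2 ln(2 pi e sigma^2) and
    I_pair = -(3/2) ln(1 - rho^2).
    """
    box = np.broadcast_to(np.asarray(box, dtype=float), (3,)).copy()
    sig = np.broadcast_to(np.asarray(sigma, dtype=float), (n_molecules,)).copy()
    if means is None:
        # default: molecules on a cubic lattice centered in the box
        n_side = int(np.ceil(n_molecules ** (1 / 3)))
        grid = np.stack(np.meshgrid(*[np.arange(n_side)] * 3, indexing="ij"),
                        axis=-1).reshape(-1, 3)[:n_molecules]
        spacing = box / max(n_side, 1)
        means = (grid + 0.5) * spacing
    means = np.asarray(means, dtype=float)

    corr = np.eye(n_molecules)
    for i, j, rho in correlated_pairs:
        if not abs(rho) < 1:
            raise ValueError("|rho| must be < 1")
        corr[i, j] = corr[j, i] = rho
    for i, j, k, rho in coupled_triples:
        for a, b in ((i, j), (i, k), (j, k)):
            corr[a, b] = corr[b, a] = rho
    cov = corr * np.outer(sig, sig)
    # one covariance block per axis; identical structure on x, y, z
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as err:
        raise ValueError("covariance is not positive definite") from err

    rng = np.random.default_rng(seed)
    z = rng.standard_normal(size=(3, n_frames, n_molecules))
    fluct = np.einsum("mk,afk->afm", chol, z)          # (3, F, M)
    pos = means[None] + np.moveaxis(fluct, 0, -1)      # (F, M, 3)
    quat = random_unit_quaternions(rng, (n_frames, n_molecules))
    traj = SolventTrajectory(pos, quat, np.tile(box, (n_frames, 1)), frame_interval)
    return traj, GaussianReference(axis_cov=[cov, cov, cov])


# --------------------------------------------------------------------------
# orientation ensembles (oracle for rotational entropy)
# --------------------------------------------------------------------------

@dataclass
class OrientationReference:
    """Exact rotational entropy (nats) under the geodesic-angle metric with
    the uniform distribution normalized to ln(8 pi^2)."""

    entropy: float
    uniform: bool
    sigma_rot: float | None = None


def gen_orientation_ensemble(n_molecules: int, n_frames: int, seed: int,
                             sigma_rot: float | None = None,
                             box: float | Sequence[float] = 5.0,
                             frame_interval: float = 10.0,
                             ) -> tuple[SolventTrajectory, OrientationReference]:
    """Orientation ensembles: Haar-uniform (``sigma_rot=None``) or a
    small-angle Gaussian wobble about identity with per-axis std ``sigma_rot``
    (rad; tangent-space entropy valid for sigma_rot <~ 0.2 rad).

    Positions are i.i.d. uniform in the box and carry no structure.
    """
    box = np.broadcast_to(np.asarray(box, dtype=float), (3,)).copy()
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.0, box, size=(n_frames, n_molecules, 3))
    if sigma_rot is None:
        quat = random_unit_quaternions(rng, (n_frames, n_molecules))
        ref = OrientationReference(entropy=float(np.log(8 * np.pi ** 2)), uniform=True)
    else:
        if sigma_rot < 0:
            raise ValueError("sigma_rot must be non-negative")
        quat = wobble_quaternions(rng, (n_frames, n_molecules), sigma_rot)
        ref = OrientationReference(
            entropy=1.5 * float(np.log(TWO_PI_E * sigma_rot ** 2)),
            uniform=False, sigma_rot=sigma_rot)
    return (SolventTrajectory(pos, quat, np.tile(box, (n_frames, 1)), frame_interval),
            ref)


# --------------------------------------------------------------------------
# coupled translation-rotation ensembles
# --------------------------------------------------------------------------

@dataclass
class TransRotReference:
    """Exact per-molecule translation-rotation mutual information (nats)."""

    mi: float
    sigma_t: float
    sigma_r: float
    rho_tr: float
    n_coupled_axes: int


def gen_coupled_transrot(n_molecules: int, n_frames: int, seed: int,
                         sigma_t: float = 0.05, sigma_r: float = 0.05,
                         rho_tr: float = 0.0, n_coupled_axes: int = 1,
                         box: float | Sequence[float] = 5.0,
                         frame_interval: float = 10.0,
                         ) -> tuple[SolventTrajectory, TransRotReference]:
    """Per-molecule 6-D Gaussian over (position, tangent rotation vector) with
    cross-correlation ``rho_tr`` between matched position/rotation axes on the
    first ``n_coupled_axes`` axes.

    The analytic MI is I = -(n_coupled_axes/2) ln(1 - rho_tr^2), the Gaussian
    closed form; valid as a rotational statement in the small-angle regime
    (sigma_r <~ 0.2 rad).
    """
    if not abs(rho_tr) < 1:
        raise ValueError("|rho_tr| must be < 1")
    if not 0 <= n_coupled_axes <= 3:
        raise ValueError("n_coupled_axes must be in 0..3")
    box = np.broadcast_to(np.asarray(box, dtype=float), (3,)).copy()
    rng = np.random.default_rng(seed)

    # sample (t_axis, r_axis) pairs; coupling only within matched axes
    n_side = int(np.ceil(n_molecules ** (1 / 3)))
    grid = np.stack(np.meshgrid(*[np.arange(n_side)] * 3, indexing="ij"),
                    axis=-1).reshape(-1, 3)[:n_molecules]
    means = (grid + 0.5) * (box / max(n_side, 1))

    pos = np.empty((n_frames, n_molecules, 3))
    rv = np.empty((n_frames, n_molecules, 3))
    for ax in range(3):
        z1 = rng.standard_normal((n_frames, n_molecules))
        z2 = rng.standard_normal((n_frames, n_molecules))
        t = z1
        rho = rho_tr if ax < n_coupled_axes else 0.0
        r = rho * z1 + np.sqrt(1 - rho ** 2) * z2
        pos[..., ax] = means[None, :, ax] + sigma_t * t
        rv[..., ax] = sigma_r * r
    quat = Rotation.from_rotvec(rv.reshape(-1, 3)).as_quat()[:, [3, 0, 1, 2]]
    quat = quat.reshape(n_frames, n_molecules, 4)
    mi = -0.5 * n_coupled_axes * float(np.log(1 - rho_tr ** 2))
    traj = SolventTrajectory(pos, quat, np.tile(box, (n_frames, 1)), frame_interval)
    return traj, TransRotReference(mi, sigma_t, sigma_r, rho_tr, n_coupled_axes)


# --------------------------------------------------------------------------
# toy solvated systems (fixtures for residue / convexity analyses)
# --------------------------------------------------------------------------

_PROBE_PARAMS = NonbondedParams(12.0, 0.0, 0.0, 0.0)
_SHELL_PARAMS = NonbondedParams(12.0, 0.0, 0.34, 0.36)


def _solid_sphere_atoms(center: np.ndarray, radius: float, spacing: float,
                        vdw: float, residue_id: int, residue_name: str,
                        ) -> tuple[np.ndarray, list[SoluteAtom]]:
    n = int(np.ceil(radius / spacing))
    axes = np.arange(-n, n + 1) * spacing
    grid = np.stack(np.meshgrid(axes, axes, axes, indexing="ij"), -1).reshape(-1, 3)
    grid = grid[np.linalg.norm(grid, axis=1) <= radius]
    atoms = [SoluteAtom("C", "C", residue_id, residue_name, vdw, _SHELL_PARAMS)
             for _ in range(len(grid))]
    return grid + center, atoms


def gen_toy_solvated(shape: str, n_frames: int, seed: int,
                     box: float | Sequence[float] = 6.0,
                     density: float = BULK_WATER_DENSITY,
                     sphere_radius: float = 1.5,
                     cavity_radius: float = 1.2,
                     atom_spacing: float = 0.25,
                     frame_interval: float = 10.0) -> SolvatedSystem:
    """Toy solutes with labeled residues, solvated by uniform ideal water.

    Shapes
    ------
    ``point_probe``
        A single zero-volume, zero-radius probe atom at the box center;
        water fills the whole box.  Its convexity is 1 by construction.
    ``sphere``
        A solid sphere of atoms (radius ``sphere_radius``) with residue 1 a
        zero-volume probe at the center and residue 2 the body; water is
        excluded from the sphere.  The central residue's 1 nm surroundings are
        fully occupied by solute, so its convexity is 0.
    ``hemisphere_cavity``
        A planar wall (lower half of the box) with a hemispherical pocket of
        radius ``cavity_radius`` carved into it; residue 1 is a probe at the
        pocket center on the wall surface.  Roughly half the probe's d-sphere
        is accessible to water.
    ``groove``
        A planar wall with a rectangular channel; residue 1 sits at the
        channel floor.

    Water molecules are placed independently each frame, uniformly at number
    density ``density`` (nm^-3) over the region the shape does not exclude;
    orientations are Haar-uniform.  Placement is by rejection sampling against
    the *geometric* shape, so exclusion is exact.
    """
    box = np.broadcast_to(np.asarray(box, dtype=float), (3,)).copy()
    rng = np.random.default_rng(seed)
    center = box / 2.0
    vol_box = float(np.prod(box))

    if shape == "point_probe":
        positions = center[None]
        atoms = [SoluteAtom("P", "P", 1, "PRB", 0.0, _PROBE_PARAMS)]
        residues = [Residue(1, "PRB", "apolar")]
        def excluded(p: np.ndarray) -> np.ndarray:
            return np.zeros(len(p), dtype=bool)
    elif shape == "sphere":
        if sphere_radius * 2 >= min(box):
            raise ValueError("sphere does not fit in box")
        body_pos, body_atoms = _solid_sphere_atoms(center, sphere_radius,
                                                   atom_spacing, 0.15, 2, "BOD")
        positions = np.vstack([center[None], body_pos])
        atoms = [SoluteAtom("P", "P", 1, "PRB", 0.0, _PROBE_PARAMS)] + body_atoms
        residues = [Residue(1, "PRB", "apolar"), Residue(2, "BOD", "apolar")]
        def excluded(p: np.ndarray) -> np.ndarray:
            return np.linalg.norm(p - center, axis=1) <= sphere_radius
    elif shape == "hemisphere_cavity":
        z_wall = center[2]
        # wall atoms on a grid below z_wall, skipping the pocket
        n = np.floor(box / atom_spacing).astype(int)
        axes = [((np.arange(k) + 0.5) * s) for k, s in zip(n, box / n)]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), -1).reshape(-1, 3)
        grid = grid[grid[:, 2] <= z_wall]
        pocket_center = np.array([center[0], center[1], z_wall])
        grid = grid[np.linalg.norm(grid - pocket_center, axis=1) > cavity_radius]
        atoms = [SoluteAtom("P", "P", 1, "PRB", 0.0, _PROBE_PARAMS)]
        atoms += [SoluteAtom("C", "C", 2, "WAL", 0.15, _SHELL_PARAMS)
                  for _ in range(len(grid))]
        positions = np.vstack([pocket_center[None], grid])
        residues = [Residue(1, "PRB", "apolar"), Residue(2, "WAL", "apolar")]
        def excluded(p: np.ndarray) -> np.ndarray:
            below = p[:, 2] <= z_wall
            in_pocket = np.linalg.norm(p - pocket_center, axis=1) <= cavity_radius
            return below & ~in_pocket
    elif shape == "groove":
        z_wall = center[2]
        half_width = 0.5
        n = np.floor(box / atom_spacing).astype(int)
        axes = [((np.arange(k) + 0.5) * s) for k, s in zip(n, box / n)]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), -1).reshape(-1, 3)
        grid = grid[grid[:, 2] <= z_wall]
        in_channel = (np.abs(grid[:, 0] - center[0]) <= half_width) & \
                     (grid[:, 2] > z_wall - 1.0)
        grid = grid[~in_channel]
        floor = np.array([center[0], center[1], z_wall - 1.0])
        atoms = [SoluteAtom("P", "P", 1, "PRB", 0.0, _PROBE_PARAMS)]
        atoms += [SoluteAtom("C", "C", 2, "WAL", 0.15, _SHELL_PARAMS)
                  for _ in range(len(grid))]
        positions = np.vstack([floor[None], grid])
        residues = [Residue(1, "PRB", "apolar"), Residue(2, "WAL", "apolar")]
        def excluded(p: np.ndarray) -> np.ndarray:
            below = p[:, 2] <= z_wall
            in_ch = (np.abs(p[:, 0] - center[0]) <= half_width) & \
                    (p[:, 2] > z_wall - 1.0)
            return below & ~in_ch
    else:
        raise ValueError(f"unknown toy shape {shape!r}")

    # constant molecule count chosen from the accessible volume
    probe = rng.uniform(0.0, box, size=(20000, 3))
    frac_free = 1.0 - float(np.mean(excluded(probe)))
    n_water = int(round(density * vol_box * frac_free))
    if n_water < 1:
        raise ValueError("density incompatible with box: no room for water")

    pos = np.empty((n_frames, n_water, 3))
    for f in range(n_frames):
        placed = 0
        while placed < n_water:
            cand = rng.uniform(0.0, box, size=(max(2 * (n_water - placed), 64), 3))
            cand = cand[~excluded(cand)]
            take = min(len(cand), n_water - placed)
            pos[f, placed:placed + take] = cand[:take]
            placed += take
    quat = random_unit_quaternions(rng, (n_frames, n_water))
    solvent = SolventTrajectory(pos, quat, np.tile(box, (n_frames, 1)),
                                frame_interval)
    solute = SoluteStructure(positions[None], atoms, residues)
    return SolvatedSystem(solute, solvent)
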