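"""Protein entropy, error estimation, the folding free-energy budget and
denaturation-temperature extrapolation.

Sign convention: differences are molten-globule minus native fold
(dG = G_m - G_f), so positive values favor the native fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from .constants import AMU_SI, EULER_E, HBAR_SI, KB, KB_SI, T_REF


# --------------------------------------------------------------------------
# Schlitter quasi-harmonic protein entropy
# --------------------------------------------------------------------------

def superpose_frames(positions: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Mass-weighted least-squares rigid fit of every frame onto the first:
    removes center-of-mass translation and net rotation."""
    pos = np.asarray(positions, dtype=float)
    masses = np.asarray(masses, dtype=float)
    w = masses / masses.sum()
    ref = pos[0] - (w[:, None] * pos[0]).sum(axis=0)
    out = np.empty_like(pos)
    out[0] = ref
    for f in range(1, len(pos)):
        x = pos[f] - (w[:, None] * pos[f]).sum(axis=0)
        rot, _ = Rotation.align_vectors(ref, x, weights=masses)
        out[f] = rot.apply(x)
    return out


def schlitter_entropy(positions: np.ndarray, masses: np.ndarray,
                      T: float = T_REF, fit: bool = True,
                      ) -> tuple[float, float]:
    """Schlitter's quasi-harmonic entropy upper bound from a positional
    covariance.

        S = (k_B/2) ln det[ 1 + (k_B T e^2 / hbar^2) M^(1/2) C M^(1/2) ]

    with C the covariance (nm^2) of the superposed coordinates, M the
    diagonal mass matrix (amu) and e Euler's number.  Zero eigenvalues
    (rigid-fit null space, static coordinates) contribute ln 1 = 0.

    Returns ``(S, -T*S)`` in (kJ mol^-1 K^-1, kJ mol^-1).
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim == 2:
        pos = pos[:, :, None]        # (F, A) 1-D coordinates -> (F, A, 1)
    n_frames, n_atoms, n_dim = pos.shape
    masses = np.asarray(masses, dtype=float)
    if masses.shape != (n_atoms,):
        raise ValueError("one mass per atom required")
    if n_frames <= 3 * n_atoms:
        warnings.warn(f"only {n_frames} frames for {3 * n_atoms} degrees of "
                      "freedom; covariance may be rank deficient")
    if fit and n_dim == 3 and n_atoms >= 3:
        pos = superpose_frames(pos, masses)

    flat = pos.reshape(n_frames, n_atoms * n_dim)
    flat = flat - flat.mean(axis=0, keepdims=True)
    cov = flat.T @ flat / n_frames                    # nm^2
    m = np.repeat(masses, n_dim)
    msqrt = np.sqrt(m)
    mat = msqrt[:, None] * cov * msqrt[None, :]       # amu nm^2

    # (k_B T e^2 / hbar^2) in 1/(amu nm^2)
    alpha = KB_SI * T * EULER_E ** 2 / HBAR_SI ** 2 * AMU_SI * 1e-18
    eig = np.linalg.eigvalsh(mat)
    eig = np.clip(eig, 0.0, None)
    s = 0.5 * KB * float(np.sum(np.log1p(alpha * eig)))
    return s, -T * s


def schlitter_closed_form(sigma2: float, mass: float, T: float = T_REF) -> float:
    """Closed-form Schlitter entropy (kJ mol^-1 K^-1) of a single 1-D
    coordinate with positional variance ``sigma2`` (nm^2) and mass (amu) —
    the analytic value the sampled estimate converges to."""
    alpha = KB_SI * T * EULER_E ** 2 / HBAR_SI ** 2 * AMU_SI * 1e-18
    return 0.5 * KB * float(np.log1p(alpha * mass * sigma2))


# --------------------------------------------------------------------------
# error estimation
# --------------------------------------------------------------------------

@dataclass
class ErrorTable:
    """Per-molecule spreads and replicate-level errors (kJ mol^-1).

    ``per_molecule_sd``: standard deviation over bulk-phase molecules per
    channel — the assumption is that shell molecules are subject to the same
    spread as bulk ones.  ``difference_error``: error of a state difference,
    sqrt(SEM_A^2 + SEM_B^2) with SEM = SD/sqrt(n_replicas).
    """

    per_molecule_sd: dict[str, float] = field(default_factory=dict)
    replicate_sd: dict[str, tuple[float, float]] = field(default_factory=dict)
    difference_error: dict[str, float] = field(default_factory=dict)


def estimate_errors(bulk_values: dict[str, np.ndarray] | None = None,
                    replicates_a: dict[str, np.ndarray] | None = None,
                    replicates_b: dict[str, np.ndarray] | None = None,
                    ) -> ErrorTable:
    """Estimate per-molecule and replicate errors.

    ``bulk_values``: channel -> per-molecule values of bulk-phase molecules.
    ``replicates_a``/``replicates_b``: channel -> per-replica totals of the
    two states; both must be present (with >= 2 replicas) for difference
    errors.
    """
    table = ErrorTable()
    if bulk_values:
        for name, vals in bulk_values.items():
            table.per_molecule_sd[name] = float(np.std(np.asarray(vals, float),
                                                       ddof=1))
    if replicates_a and replicates_b:
        for name in replicates_a:
            if name not in replicates_b:
                raise ValueError(f"channel {name!r} missing from state B")
            a = np.asarray(replicates_a[name], dtype=float)
            b = np.asarray(replicates_b[name], dtype=float)
            if a.size < 2 or b.size < 2:
                continue  # single replicate: difference error undefined
            sd_a, sd_b = float(np.std(a, ddof=1)), float(np.std(b, ddof=1))
            table.replicate_sd[name] = (sd_a, sd_b)
            table.difference_error[name] = float(
                np.sqrt(sd_a ** 2 / a.size + sd_b ** 2 / b.size))
    return table


# --------------------------------------------------------------------------
# free-energy budget
# --------------------------------------------------------------------------

ENTHALPY_COMPONENTS = ("U_PP", "U_PS", "U_SS", "pV")
ENTROPY_COMPONENTS = ("minus_TS_P", "minus_TS1_trans", "minus_TS1_rot",
                      "minus_TS2_trans", "minus_TS2_rot", "minus_TS_transrot")
SOLVENT_ENTROPY_COMPONENTS = ENTROPY_COMPONENTS[1:]
MULTIBODY_COMPONENTS = ("minus_TS2_trans", "minus_TS2_rot", "minus_TS_transrot")


@dataclass
class FreeEnergyBudget:
    """The folding free-energy ledger (kJ mol^-1), differences molten minus
    native; positive favors the native fold.

    Identities hold exactly by construction:
    dH = dU_PP + dU_PS + dU_SS + p_dV and dG = dH + sum of -T dS terms.
    """

    deltas: dict[str, float]
    errors: dict[str, float] = field(default_factory=dict)

    @property
    def dH(self) -> float:
        return float(sum(self.deltas[c] for c in ENTHALPY_COMPONENTS))

    @property
    def solvent_entropy_total(self) -> float:
        return float(sum(self.deltas[c] for c in SOLVENT_ENTROPY_COMPONENTS))

    @property
    def multibody_subtotal(self) -> float:
        return float(sum(self.deltas[c] for c in MULTIBODY_COMPONENTS))

    @property
    def dG(self) -> float:
        return float(self.dH + sum(self.deltas[c] for c in ENTROPY_COMPONENTS))

    def summary(self) -> dict[str, float]:
        out = dict(self.deltas)
        out["dH"] = self.dH
        out["solvent_entropy_total"] = self.solvent_entropy_total
        out["multibody_subtotal"] = self.multibody_subtotal
        out["dG"] = self.dG
        return out


def assemble_budget(native: dict[str, np.ndarray | float],
                    molten: dict[str, np.ndarray | float]) -> FreeEnergyBudget:
    """Assemble the budget from per-state components.

    Each entry may be a scalar or a per-replica array; differences are
    mean(molten) - mean(native) and errors combine replica SEMs in
    quadrature.  Every component in ``ENTHALPY_COMPONENTS`` and
    ``ENTROPY_COMPONENTS`` must be present in both states.
    """
    required = ENTHALPY_COMPONENTS + ENTROPY_COMPONENTS
    for name in required:
        for label, state in (("native", native), ("molten", molten)):
            if name not in state:
                raise KeyError(f"missing component {name!r} in {label} state")
    deltas: dict[str, float] = {}
    reps_a: dict[str, np.ndarray] = {}
    reps_b: dict[str, np.ndarray] = {}
    for name in required:
        a = np.atleast_1d(np.asarray(native[name], dtype=float))
        b = np.atleast_1d(np.asarray(molten[name], dtype=float))
        deltas[name] = float(b.mean() - a.mean())
        reps_a[name], reps_b[name] = a, b
    errors = estimate_errors(replicates_a=reps_a,
                             replicates_b=reps_b).difference_error
    return FreeEnergyBudget(deltas, errors)


# --------------------------------------------------------------------------
# Gibbs-Helmholtz denaturation temperatures
# --------------------------------------------------------------------------

@dataclass
class DenaturationParams:
    """Gibbs-Helmholtz inputs anchored at T0: dH0 (kJ/mol), dS0 (kJ/mol/K),
    constant heat-capacity difference dCp (kJ/mol/K; protein-typical range
    5-15)."""

    dH0: float
    dS0: float
    dCp: float
    T0: float = T_REF

    def __post_init__(self) -> None:
        if self.dCp <= 0:
            raise ValueError("dCp must be positive")

    def dG(self, T: np.ndarray | float) -> np.ndarray | float:
        """dG(T) = dH0 + dCp (T - T0) - T [dS0 + dCp ln(T/T0)]."""
        T = np.asarray(T, dtype=float)
        out = (self.dH0 + self.dCp * (T - self.T0)
               - T * (self.dS0 + self.dCp * np.log(T / self.T0)))
        return float(out) if out.ndim == 0 else out


@dataclass
class DenaturationResult:
    T_cold: float | None       # K; None if no root in bracket
    T_hot: float | None

    @property
    def t_cold_celsius(self) -> float | None:
        return None if self.T_cold is None else self.T_cold - 273.15

    @property
    def t_hot_celsius(self) -> float | None:
        return None if self.T_hot is None else self.T_hot - 273.15


def denaturation_temperatures(params: DenaturationParams,
                              bracket: tuple[float, float] = (150.0, 450.0),
                              ) -> DenaturationResult:
    """Cold and heat denaturation temperatures: the roots of dG(T) = 0 below
    and above T0, found by bracketed root search.

    Requires dG(T0) > 0 (the folded state must be stable at the anchor);
    a missing sign change in a bracket yields None for that side rather than
    an error.
    """
    lo, hi = bracket
    if not lo < params.T0 < hi:
        raise ValueError("bracket must contain T0")
    if params.dG(params.T0) <= 0:
        raise ValueError("dG(T0) must be positive (folded state stable)")

    def root(a: float, b: float) -> float | None:
        fa, fb = params.dG(a), params.dG(b)
        if fa * fb > 0:
            return None
        return float(brentq(params.dG, a, b, xtol=1e-10))

    t0 = params.T0
    return DenaturationResult(T_cold=root(lo, t0 * (1 - 1e-9)),
                              T_hot=root(t0 * (1 + 1e-9), hi))
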