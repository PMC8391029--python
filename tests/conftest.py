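"""Shared fixtures: small synthetic systems generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

import hydroshell as hs


@pytest.fixture(scope="session")
def water_box():
    """8-molecule, 5-frame ideal-gas water box (locator + orientations)."""
    return hs.gen_ideal_gas(n_molecules=8, n_frames=5, box=2.5, seed=42)


@pytest.fixture(scope="session")
def probe_system():
    """Point probe in uniform water, modest size for geometry tests."""
    return hs.gen_toy_solvated("point_probe", n_frames=50, seed=7, box=3.0,
                               density=10.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_static_system(solute_pos, solvent_pos, box=10.0, charges=None,
                       vdw=0.15):
    """Hand-built single-frame system with zero-volume placeholder params."""
    from hydroshell.system import (NonbondedParams, Residue, SoluteAtom,
                                   SoluteStructure, SolvatedSystem,
                                   SolventTrajectory, WATER_SITES)

    solute_pos = np.atleast_2d(np.asarray(solute_pos, dtype=float))
    charges = charges if charges is not None else [0.0] * len(solute_pos)
    atoms = [SoluteAtom(f"A{i}", "C", 1, "RES", vdw,
                        NonbondedParams(12.0, q, 0.3, 0.2))
             for i, q in enumerate(charges)]
    solute = SoluteStructure(solute_pos[None], atoms, [Residue(1, "RES")])
    solvent_pos = np.asarray(solvent_pos, dtype=float)
    if solvent_pos.ndim == 2:
        solvent_pos = solvent_pos[None]
    n_f, n_m = solvent_pos.shape[:2]
    quat = np.zeros((n_f, n_m, 4))
    quat[..., 0] = 1.0
    solvent = SolventTrajectory(solvent_pos, quat, np.full((n_f, 3), box),
                                sites=WATER_SITES)
    return SolvatedSystem(solute, solvent)
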