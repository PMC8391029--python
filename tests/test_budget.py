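"""Schlitter entropy, error estimation, budget identities and the
Gibbs-Helmholtz denaturation extrapolation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydroshell.budget import (
    DenaturationParams,
    assemble_budget,
    denaturation_temperatures,
    estimate_errors,
    schlitter_closed_form,
    schlitter_entropy,
)


class TestSchlitter:
    def test_harmonic_ensemble_matches_closed_form(self):
        """Classical harmonic coordinate with variance kT/(m w^2): the
        sampled Schlitter estimate converges to the closed-form value at the
        analytic variance."""
        rng = np.random.default_rng(60)
        sigma, mass = 0.02, 12.0
        x = rng.normal(scale=sigma, size=(40_000, 1))
        s, _ = schlitter_entropy(x, np.array([mass]), fit=False)
        assert s == pytest.approx(schlitter_closed_form(sigma ** 2, mass),
                                  rel=0.02)

    def test_zero_variance_zero_entropy(self):
        s, mts = schlitter_entropy(np.zeros((50, 1)), np.array([10.0]),
                                   fit=False)
        assert s == 0.0 and mts == 0.0

    def test_monotone_in_variance(self):
        rng = np.random.default_rng(61)
        values = []
        for sigma in (0.01, 0.02, 0.04):
            x = rng.normal(scale=sigma, size=(20_000, 1))
            values.append(schlitter_entropy(x, np.array([12.0]), fit=False)[0])
        assert values[0] < values[1] < values[2]

    def test_upper_bound_property(self):
        """The Schlitter value bounds the classical harmonic-oscillator
        entropy S_cl = kB (1 - ln(hbar w / kB T)) from above."""
        from hydroshell.constants import AMU_SI, HBAR_SI, KB, KB_SI, T_REF

        mass, sigma = 12.0, 0.02
        omega = np.sqrt(KB_SI * T_REF / (mass * AMU_SI * (sigma * 1e-9) ** 2))
        x_over = HBAR_SI * omega / (KB_SI * T_REF)
        s_classical = KB * (1.0 - np.log(x_over))
        assert schlitter_closed_form(sigma ** 2, mass) >= s_classical

    def test_rigid_fit_removes_global_motion(self):
        """A rigid body tumbling without internal motion has zero entropy
        after superposition."""
        rng = np.random.default_rng(62)
        from scipy.spatial.transform import Rotation

        body = rng.uniform(-0.3, 0.3, size=(5, 3))
        frames = np.stack([Rotation.random(random_state=int(i)).apply(body)
                           + rng.uniform(-1, 1, 3) for i in range(40)])
        s, _ = schlitter_entropy(frames, np.full(5, 12.0), fit=True)
        assert s == pytest.approx(0.0, abs=1e-6)


class TestEstimateErrors:
    def test_constant_values_zero_sd(self):
        t = estimate_errors(bulk_values={"U_SS": np.full(100, 3.0)})
        assert t.per_molecule_sd["U_SS"] == 0.0

    def test_known_sigma_recovered(self):
        """Bulk spread of 1.05 kJ/mol recovered within 5% at 1e4 molecules."""
        vals = np.random.default_rng(63).normal(0.0, 1.05, size=10_000)
        t = estimate_errors(bulk_values={"U_SS": vals})
        assert t.per_molecule_sd["U_SS"] == pytest.approx(1.05, rel=0.05)

    def test_replicate_difference_error_formula(self):
        a = {"X": np.array([10.0, 12.0])}
        b = {"X": np.array([20.0, 22.0])}
        t = estimate_errors(replicates_a=a, replicates_b=b)
        # SD = sqrt(2) each, SEM = 1, difference error = sqrt(2)
        assert t.difference_error["X"] == pytest.approx(np.sqrt(2.0), rel=1e-12)

    def test_spread_scaling(self):
        rng = np.random.default_rng(64)
        a = {"X": rng.normal(size=8)}
        b = {"X": rng.normal(size=8)}
        t1 = estimate_errors(replicates_a=a, replicates_b=b)
        t2 = estimate_errors(replicates_a={"X": 2 * a["X"]},
                             replicates_b={"X": 2 * b["X"]})
        assert t2.difference_error["X"] == pytest.approx(
            2 * t1.difference_error["X"], rel=1e-12)

    def test_single_replicate_no_difference_error(self):
        t = estimate_errors(replicates_a={"X": np.array([1.0])},
                            replicates_b={"X": np.array([2.0])})
        assert "X" not in t.difference_error


def _zero_components():
    from hydroshell.budget import ENTHALPY_COMPONENTS, ENTROPY_COMPONENTS

    return {name: 0.0 for name in ENTHALPY_COMPONENTS + ENTROPY_COMPONENTS}


class TestAssembleBudget:
    def test_all_zero_gives_zero_dG(self):
        b = assemble_budget(_zero_components(), _zero_components())
        assert b.dG == 0.0 and b.dH == 0.0

    def test_missing_component_named(self):
        bad = _zero_components()
        del bad["U_SS"]
        with pytest.raises(KeyError, match="U_SS"):
            assemble_budget(bad, _zero_components())

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e3, 1e3, allow_nan=False), min_size=10,
                    max_size=10))
    def test_identities_hold_exactly(self, vals):
        """dH and dG are exact sums of their components for arbitrary
        inputs."""
        from hydroshell.budget import ENTHALPY_COMPONENTS, ENTROPY_COMPONENTS

        names = ENTHALPY_COMPONENTS + ENTROPY_COMPONENTS
        molten = dict(zip(names, vals))
        b = assemble_budget(_zero_components(), molten)
        assert b.dH == sum(molten[c] for c in ENTHALPY_COMPONENTS)
        assert b.dG == b.dH + sum(molten[c] for c in ENTROPY_COMPONENTS)


class TestDenaturation:
    def _params(self, dCp=15.0):
        return DenaturationParams(dH0=228.0, dS0=(673.0 - 498.0) / 300.0,
                                  dCp=dCp)

    def test_roots_match_grid_scan(self):
        """Bracketed roots agree with a fine grid scan of sign changes to
        0.01 K."""
        p = self._params()
        res = denaturation_temperatures(p)
        grid = np.arange(150.0, 450.0, 0.005)
        sign = np.sign(p.dG(grid))
        flips = np.nonzero(np.diff(sign))[0]
        roots = [(grid[i] + grid[i + 1]) / 2 for i in flips]
        assert len(roots) == 2
        assert res.T_cold == pytest.approx(roots[0], abs=0.01)
        assert res.T_hot == pytest.approx(roots[1], abs=0.01)

    def test_large_dcp_roots_approach_anchor(self):
        wide = denaturation_temperatures(self._params(dCp=10.0))
        narrow = denaturation_temperatures(self._params(dCp=100.0))
        assert wide.T_cold < narrow.T_cold < 300.0
        assert 300.0 < narrow.T_hot < wide.T_hot

    def test_unstable_anchor_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            denaturation_temperatures(DenaturationParams(10.0, 1.0, 15.0))

    def test_missing_root_reported_not_raised(self):
        # tiny dCp: no cold root above 150 K
        res = denaturation_temperatures(
            DenaturationParams(dH0=228.0, dS0=175.0 / 300.0, dCp=1.0))
        assert res.T_cold is None
        assert res.T_hot is None or res.T_hot > 300.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(50.0, 500.0), st.floats(0.05, 1.2), st.floats(5.0, 15.0))
    def test_random_triples_agree_with_scan(self, dh, ds, dcp):
        """Root finder agrees with the grid-scan oracle whenever roots
        exist."""
        p = DenaturationParams(dh, ds, dcp)
        if p.dG(300.0) <= 0:
            return
        res = denaturation_temperatures(p)
        grid = np.arange(150.0, 450.0, 0.01)
        flips = np.nonzero(np.diff(np.sign(p.dG(grid))))[0]
        roots = [(grid[i] + grid[i + 1]) / 2 for i in flips]
        found = [t for t in (res.T_cold, res.T_hot) if t is not None]
        assert len(found) == len(roots)
        for t, r in zip(sorted(found), roots):
            assert t == pytest.approx(r, abs=0.02)
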