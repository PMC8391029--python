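"""Pairwise energies, the decomposition, and conservation properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hydroshell as hs
from hydroshell.system import NonbondedParams

NEUTRAL = NonbondedParams(10.0, 0.0, 0.3, 0.5)
PLUS = NonbondedParams(10.0, 1.0, 0.0, 0.0)
MINUS = NonbondedParams(10.0, -1.0, 0.0, 0.0)


class TestPairEnergy:
    def test_lj_minimum_is_minus_epsilon(self):
        r_min = 2.0 ** (1 / 6) * 0.3
        assert hs.pair_interaction_energy(NEUTRAL, NEUTRAL, r_min) == \
            pytest.approx(-0.5, rel=1e-12)

    def test_coulomb_unit_charges(self):
        """+e and -e at 0.5 nm: f q1 q2 / r = -277.8709 kJ/mol."""
        u = hs.pair_interaction_energy(PLUS, MINUS, 0.5)
        assert u == pytest.approx(-277.870916, abs=1e-4)

    def test_lj_cutoff_at_2nm(self):
        assert hs.pair_interaction_energy(NEUTRAL, NEUTRAL, 2.5) == 0.0
        assert hs.pair_interaction_energy(NEUTRAL, NEUTRAL, 1.9) != 0.0

    def test_symmetry(self):
        a = NonbondedParams(10.0, 0.3, 0.31, 0.4)
        b = NonbondedParams(10.0, -0.2, 0.25, 0.7)
        assert hs.pair_interaction_energy(a, b, 0.4) == \
            hs.pair_interaction_energy(b, a, 0.4)

    def test_zero_distance_rejected(self):
        with pytest.raises(ValueError):
            hs.pair_interaction_energy(NEUTRAL, NEUTRAL, 0.0)

    def test_lorentz_berthelot(self):
        a = NonbondedParams(1.0, 0.0, 0.2, 0.4)
        b = NonbondedParams(1.0, 0.0, 0.4, 0.9)
        # combined sigma 0.3, eps 0.6; minimum at 2^(1/6)*0.3 is -0.6
        assert hs.pair_interaction_energy(a, b, 2.0 ** (1 / 6) * 0.3) == \
            pytest.approx(-0.6, rel=1e-12)


class TestPvTerm:
    def test_unit_conversion(self):
        assert hs.pv_term(np.full(10, 343.0)) == pytest.approx(20.656, abs=1e-3)

    def test_linear_in_volume(self):
        v = np.array([100.0, 200.0])
        assert hs.pv_term(2 * v) == pytest.approx(2 * hs.pv_term(v), rel=1e-12)

    def test_invalid_series_rejected(self):
        with pytest.raises(ValueError):
            hs.pv_term(np.array([]))
        with pytest.raises(ValueError):
            hs.pv_term(np.array([0.0]))


def _water_system(water_pos, solute_pos=((5.0, 5.0, 5.0),), charges=None,
                  box=10.0):
    from conftest import make_static_system

    return make_static_system(np.asarray(solute_pos, float),
                              np.asarray(water_pos, float), box=box,
                              charges=charges)


class TestDecomposition:
    def test_hand_summed_static_frame(self):
        """1 solute atom, 2 inner + 1 outer water on a line: components
        equal manually summed site-site pair energies."""
        sys_ = _water_system([[5.5, 5.0, 5.0], [6.0, 5.0, 5.0],
                              [7.0, 5.0, 5.0]], charges=[0.5])
        shells = hs.rank_shells(sys_, n_analysis=3, n_inner=2)
        d = hs.decompose_enthalpy(sys_, shells)

        from hydroshell.enthalpy import SiteGroup, _group_pair_energy
        site_prm = [s.params for s in sys_.solvent.sites]
        sites = sys_.solvent.site_positions(0)
        box = sys_.solvent.box[0]
        solute = SiteGroup.from_atoms(sys_.solute.frame_positions(0),
                                      [a.params for a in sys_.solute.atoms],
                                      single_group=True)
        inner = SiteGroup.from_molecules(sites[:2], site_prm)
        outer = SiteGroup.from_molecules(sites[2:], site_prm)
        ups = _group_pair_energy(inner, solute, box, 2.0)[:, 0]
        uss = _group_pair_energy(inner, inner, box, 2.0)
        np.fill_diagonal(uss, 0.0)
        uio = _group_pair_energy(inner, outer, box, 2.0)

        np.testing.assert_allclose([d.U_PS[0], d.U_PS[1]], ups, rtol=1e-12)
        np.testing.assert_allclose([d.U_SS_inner[0], d.U_SS_inner[1]],
                                   0.5 * uss.sum(axis=1), rtol=1e-12)
        np.testing.assert_allclose([d.U_inner_outer[0], d.U_inner_outer[1]],
                                   uio.sum(axis=1), rtol=1e-12)

    def test_all_zero_params_give_zero(self):
        sys_ = _water_system([[5.5, 5, 5], [6.5, 5, 5]])
        # neutralize water sites
        from hydroshell.system import Site
        zero = NonbondedParams(1.0, 0.0, 0.0, 0.0)
        sys_.solvent.sites = tuple(Site(s.name, s.offset, zero)
                                   for s in sys_.solvent.sites)
        shells = hs.rank_shells(sys_, n_analysis=2, n_inner=2)
        d = hs.decompose_enthalpy(sys_, shells)
        assert d.U_PS_total == 0.0 and d.U_SS_total == 0.0

    def test_conservation_on_random_system(self, rng):
        """Reassembled components equal the direct total of all pair
        energies involving inner molecules and the solute, to 1e-9."""
        wat = rng.uniform(2.0, 8.0, size=(6, 3))
        sys_ = _water_system(wat, solute_pos=[[5, 5, 5], [5.4, 5, 5]],
                             charges=[0.3, -0.3])
        shells = hs.rank_shells(sys_, n_analysis=6, n_inner=4)
        d = hs.decompose_enthalpy(sys_, shells)

        from hydroshell.enthalpy import SiteGroup, _group_pair_energy
        sites = sys_.solvent.site_positions(0)
        site_prm = [s.params for s in sys_.solvent.sites]
        box = sys_.solvent.box[0]
        inner_idx = shells.inner_shell
        outer_idx = np.setdiff1d(np.arange(6), inner_idx)
        solute = SiteGroup.from_atoms(sys_.solute.frame_positions(0),
                                      [a.params for a in sys_.solute.atoms],
                                      single_group=True)
        inner = SiteGroup.from_molecules(sites[inner_idx], site_prm)
        outer = SiteGroup.from_molecules(sites[outer_idx], site_prm)
        m_ss = _group_pair_energy(inner, inner, box, 2.0)
        np.fill_diagonal(m_ss, 0.0)
        direct = (_group_pair_energy(inner, solute, box, 2.0).sum()
                  + 0.5 * m_ss.sum()
                  + _group_pair_energy(inner, outer, box, 2.0).sum())
        reassembled = d.U_PS_total + d.U_SS_total
        assert reassembled == pytest.approx(direct, rel=1e-9)

    def test_fixed_relabeling_invariance(self, rng):
        """A fixed global relabeling of the molecules permutes the
        per-molecule terms but leaves every total unchanged."""
        wat = rng.uniform(2.0, 8.0, size=(3, 5, 3))
        sys_ = _water_system(wat, charges=[0.2])
        shells = hs.rank_shells(sys_, n_analysis=5, n_inner=3)
        d1 = hs.decompose_enthalpy(sys_, shells)

        import copy
        perm = np.array([3, 0, 4, 1, 2])
        sys2 = copy.deepcopy(sys_)
        sys2.solvent = sys_.solvent.subset(perm)
        shells2 = hs.rank_shells(sys2, n_analysis=5, n_inner=3)
        d2 = hs.decompose_enthalpy(sys2, shells2)
        assert d1.H == pytest.approx(d2.H, rel=1e-9)
        inv = np.argsort(perm)
        for old, val in d1.U_PS.items():
            assert d2.U_PS[int(inv[old])] == pytest.approx(val, rel=1e-9)


class TestEnergyDifference:
    def test_zero_for_identical(self):
        a = {"U_PS": 1.0, "U_SS": 2.0}
        assert hs.energy_difference(a, a) == {"U_PS": 0.0, "U_SS": 0.0}

    def test_shift_propagates(self):
        a = {"U_PS": 1.0}
        b = {"U_PS": 6.0}
        assert hs.energy_difference(a, b)["U_PS"] == pytest.approx(5.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(-1e3, 1e3), st.floats(-1e3, 1e3))
    def test_antisymmetric(self, x, y):
        a, b = {"U_PS": x}, {"U_PS": y}
        assert hs.energy_difference(a, b)["U_PS"] == \
            -hs.energy_difference(b, a)["U_PS"]

    def test_component_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            hs.energy_difference({"U_PS": 1.0}, {"U_SS": 1.0})
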