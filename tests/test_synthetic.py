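"""Synthetic generators: determinism, symmetry and analytic references.

The analytic reference values attached by the generators are themselves
validated against independent numerical oracles (direct estimation, closed
forms, Monte-Carlo volume integration).
"""

import numpy as np
import pytest

import hydroshell as hs
from hydroshell.entropy import knn_entropy, mutual_information, rotational_entropy
from hydroshell.synthetic import EnsembleSpec, generate

TWO_PI_E = 2 * np.pi * np.e


class TestDeterminism:
    @pytest.mark.parametrize("kind,params", [
        ("ideal_gas", {"box": 3.0}),
        ("gaussian_cloud", {"sigma": 0.1}),
        ("orientation_ensemble", {"sigma_rot": 0.1}),
        ("coupled_transrot", {"rho_tr": 0.5}),
    ])
    def test_same_seed_identical(self, kind, params):
        spec = EnsembleSpec(kind, n_molecules=4, n_frames=50, seed=9,
                            params=params)
        a, b = generate(spec), generate(spec)
        ta = a[0] if isinstance(a, tuple) else a
        tb = b[0] if isinstance(b, tuple) else b
        np.testing.assert_array_equal(ta.positions, tb.positions)
        np.testing.assert_array_equal(ta.quaternions, tb.quaternions)

    def test_seed_mandatory(self):
        with pytest.raises(TypeError):
            hs.gen_ideal_gas(n_molecules=2, n_frames=2, box=1.0)


class TestIdealGas:
    def test_mean_position_is_box_center(self):
        traj = hs.gen_ideal_gas(n_molecules=20, n_frames=2000, box=2.0, seed=3)
        mean = traj.positions.reshape(-1, 3).mean(axis=0)
        np.testing.assert_allclose(mean, [1.0, 1.0, 1.0], atol=0.02)

    def test_positions_pairwise_independent(self):
        """Empirical MI between two molecules of an ideal gas is zero within
        estimator noise."""
        traj = hs.gen_ideal_gas(n_molecules=2, n_frames=20000, box=1.0, seed=4)
        mi = mutual_information(traj.positions[:, 0], traj.positions[:, 1])
        assert abs(mi) < 0.03

    def test_no_frames_rejected(self):
        with pytest.raises(ValueError):
            hs.gen_ideal_gas(n_molecules=2, n_frames=0, box=1.0, seed=1)


class TestGaussianCloud:
    def test_single_molecule_closed_form(self):
        _, ref = hs.gen_gaussian_cloud(3, 100, seed=5, sigma=0.1)
        expected = 0.5 * np.log(TWO_PI_E ** 3 * 0.1 ** 6)
        assert ref.entropy_single(0) == pytest.approx(expected, rel=1e-12)

    def test_pair_mi_closed_form(self):
        """rho = 0.9 on matched axes: I = -3/2 ln(1 - 0.81) = 2.4911 nats."""
        _, ref = hs.gen_gaussian_cloud(2, 100, seed=5, sigma=0.1,
                                       correlated_pairs=[(0, 1, 0.9)])
        assert ref.mi_pair(0, 1) == pytest.approx(2.4910968, abs=1e-6)

    def test_uncorrelated_mi_zero(self):
        _, ref = hs.gen_gaussian_cloud(2, 100, seed=5, sigma=0.1)
        assert ref.mi_pair(0, 1) == pytest.approx(0.0, abs=1e-12)

    def test_samples_match_reference(self):
        """The estimator recovers the attached analytic S1 and pair MI."""
        traj, ref = hs.gen_gaussian_cloud(2, 40000, seed=6, sigma=0.08,
                                          correlated_pairs=[(0, 1, 0.8)])
        s1 = knn_entropy(traj.positions[:, 0])
        assert s1 == pytest.approx(ref.entropy_single(0), abs=0.03)
        mi = mutual_information(traj.positions[:, 0], traj.positions[:, 1])
        assert mi == pytest.approx(ref.mi_pair(0, 1), rel=0.05)

    def test_non_positive_definite_rejected(self):
        with pytest.raises(ValueError):
            hs.gen_gaussian_cloud(3, 10, seed=1, sigma=0.1,
                                  coupled_triples=[(0, 1, 2, -0.9)])


class TestOrientationEnsemble:
    def test_uniform_minus_reference_zero(self):
        traj, ref = hs.gen_orientation_ensemble(1, 50000, seed=8)
        est = rotational_entropy(traj.quaternions[:, 0])
        assert est - ref.entropy == pytest.approx(0.0, abs=0.03)

    def test_wobble_tangent_closed_form(self):
        """sigma_rot = 0.05 rad: entropy matches 3/2 ln(2 pi e sigma^2)
        within 2%."""
        traj, ref = hs.gen_orientation_ensemble(1, 100000, seed=9,
                                                sigma_rot=0.05)
        est = rotational_entropy(traj.quaternions[:, 0])
        assert est == pytest.approx(ref.entropy, rel=0.02)

    def test_halving_sigma_drops_entropy_3ln2(self):
        t1, _ = hs.gen_orientation_ensemble(1, 60000, seed=10, sigma_rot=0.1)
        t2, _ = hs.gen_orientation_ensemble(1, 60000, seed=11, sigma_rot=0.05)
        drop = (rotational_entropy(t1.quaternions[:, 0])
                - rotational_entropy(t2.quaternions[:, 0]))
        assert drop == pytest.approx(3 * np.log(2), abs=0.05)


class TestCoupledTransRot:
    def test_zero_coupling_zero_mi(self):
        _, ref = hs.gen_coupled_transrot(1, 100, seed=1, rho_tr=0.0)
        assert ref.mi == 0.0

    def test_closed_form_attached(self):
        _, ref = hs.gen_coupled_transrot(1, 100, seed=1, rho_tr=0.8)
        assert ref.mi == pytest.approx(-0.5 * np.log(0.36), rel=1e-12)

    def test_mi_monotone_in_coupling(self):
        estimates = []
        for rho in (0.3, 0.6, 0.9):
            traj, _ = hs.gen_coupled_transrot(1, 15000, seed=12, rho_tr=rho)
            estimates.append(mutual_information(traj.positions[:, 0],
                                                traj.quaternions[:, 0]))
        assert estimates[0] < estimates[1] < estimates[2]

    def test_invalid_coupling_rejected(self):
        with pytest.raises(ValueError):
            hs.gen_coupled_transrot(1, 10, seed=1, rho_tr=1.2)


class TestToySolvated:
    def test_point_probe_fully_wet(self, probe_system):
        """Every voxel of the probe's surroundings is accessible: convexity
        close to 1 downstream."""
        assert hs.convexity(probe_system, 1, n_w=10.0) == pytest.approx(1.0,
                                                                        abs=0.05)

    def test_buried_center_has_no_water_within_1nm(self):
        sys_ = hs.gen_toy_solvated("sphere", n_frames=10, seed=2, box=6.0,
                                   density=10.0)
        center = sys_.solute.frame_positions(0)[0]
        d = np.linalg.norm(sys_.solvent.positions - center, axis=-1)
        assert d.min() > 1.0

    def test_cavity_water_fraction_matches_mc_volume(self):
        """Frame-averaged water count within d of the pocket probe agrees
        with a Monte-Carlo integral of the accessible volume."""
        sys_ = hs.gen_toy_solvated("hemisphere_cavity", n_frames=200, seed=3,
                                   box=5.0, density=12.0, cavity_radius=0.0)
        probe = sys_.solute.frame_positions(0)[0]
        d = np.linalg.norm(sys_.solvent.positions - probe[None, None], axis=-1)
        n_d = (d <= 1.0).sum() / sys_.solvent.n_frames

        rng = np.random.default_rng(0)
        pts = probe + rng.uniform(-1, 1, size=(200000, 3))
        pts = pts[np.linalg.norm(pts - probe, axis=1) <= 1.0]
        frac_wet = np.mean(pts[:, 2] > probe[2])   # plain wall: upper half
        expected = 12.0 * 4.0 / 3.0 * np.pi * frac_wet
        assert n_d == pytest.approx(expected, rel=0.05)

    def test_density_incompatible_rejected(self):
        with pytest.raises(ValueError, match="density"):
            hs.gen_toy_solvated("point_probe", n_frames=1, seed=1, box=1.0,
                                density=1e-6)
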