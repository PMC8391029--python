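"""k-NN entropy estimators, mutual information, and the expansion machinery.

Oracle values are closed forms: Gaussian entropy (1/2) ln((2 pi e)^d det S),
uniform-box entropy ln V, Haar rotation entropy ln(8 pi^2), Gaussian MI
-(d/2) ln(1 - rho^2).
"""

import numpy as np
import pytest

import hydroshell as hs
from hydroshell.entropy import (
    EntropyTerms,
    EuclideanChannel,
    joint_knn_entropy,
    knn_entropy,
    mie_total,
    mutual_information,
    rotational_entropy,
    shell_entropy,
)
from hydroshell.system import ShellAssignment

TWO_PI_E = 2 * np.pi * np.e


class TestKnnEntropy:
    def test_gaussian_1d(self):
        x = np.random.default_rng(0).normal(size=(100_000, 1))
        assert knn_entropy(x) == pytest.approx(0.5 * np.log(TWO_PI_E), abs=0.02)

    def test_uniform_cube_periodic(self):
        x = np.random.default_rng(1).uniform(size=(100_000, 3))
        assert knn_entropy(x, boxsize=1.0) == pytest.approx(0.0, abs=0.02)

    def test_deterministic(self):
        x = np.random.default_rng(2).normal(size=(5000, 3))
        assert knn_entropy(x) == knn_entropy(x)

    def test_error_decreases_with_n(self):
        """Mean absolute error against the closed form shrinks with sample
        size (averaged over replicates to beat estimator variance)."""
        exact = 1.5 * np.log(TWO_PI_E)
        errs = []
        for n in (1000, 10_000, 100_000):
            reps = [abs(knn_entropy(
                np.random.default_rng(100 * n + r).normal(size=(n, 3))) - exact)
                for r in range(3)]
            errs.append(np.mean(reps))
        assert errs[0] > errs[2]
        assert errs[2] < 0.02 * abs(exact)

    def test_duplicates_jittered(self):
        x = np.zeros((50, 3))
        x[:25] = 1.0
        s = knn_entropy(x)      # duplicate-heavy input survives via jitter
        assert np.isfinite(s)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            knn_entropy(np.zeros((5, 3)))


class TestRotationalEntropy:
    def test_uniform_haar_volume(self):
        from hydroshell.synthetic import random_unit_quaternions

        q = random_unit_quaternions(np.random.default_rng(3), (100_000,))
        assert rotational_entropy(q) == pytest.approx(np.log(8 * np.pi ** 2),
                                                      abs=0.03)

    def test_wobble_tangent_form(self):
        from hydroshell.synthetic import wobble_quaternions

        q = wobble_quaternions(np.random.default_rng(4), (100_000,), 0.05)
        expected = 1.5 * np.log(TWO_PI_E * 0.05 ** 2)
        assert rotational_entropy(q) == pytest.approx(expected, rel=0.02)

    def test_difference_of_two_uniform_ensembles_zero(self):
        from hydroshell.synthetic import random_unit_quaternions

        qa = random_unit_quaternions(np.random.default_rng(5), (40_000,))
        qb = random_unit_quaternions(np.random.default_rng(6), (40_000,))
        assert rotational_entropy(qa) - rotational_entropy(qb) == pytest.approx(
            0.0, abs=0.05)

    def test_non_unit_quaternion_rejected(self):
        q = np.full((100, 4), 0.9)
        with pytest.raises(ValueError, match="unit"):
            rotational_entropy(q)


class TestMutualInformation:
    def test_independent_gaussians_zero(self):
        rng = np.random.default_rng(7)
        mi = mutual_information(rng.normal(size=(50_000, 3)),
                                rng.normal(size=(50_000, 3)))
        assert mi == pytest.approx(0.0, abs=0.02)

    @pytest.mark.parametrize("rho", [0.5, 0.9])
    def test_gaussian_pair_closed_form(self, rho):
        rng = np.random.default_rng(int(rho * 10))
        n = 50_000
        z1, z2 = rng.standard_normal((2, n, 3))
        mi = mutual_information(0.1 * z1,
                                0.1 * (rho * z1 + np.sqrt(1 - rho ** 2) * z2))
        assert mi == pytest.approx(-1.5 * np.log(1 - rho ** 2), rel=0.03)

    def test_monotone_in_correlation(self):
        rng = np.random.default_rng(8)
        n = 20_000
        z1, z2 = rng.standard_normal((2, n, 3))
        mis = [mutual_information(z1, rho * z1 + np.sqrt(1 - rho ** 2) * z2)
               for rho in (0.5, 0.9)]
        assert mis[0] < mis[1]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            mutual_information(np.zeros((100, 3)), np.zeros((50, 3)))


class TestCorrelationLists:
    def _static_traj(self, positions, box=10.0):
        pos = np.tile(np.asarray(positions, dtype=float)[None], (2, 1, 1))
        quat = np.zeros(pos.shape[:2] + (4,))
        quat[..., 0] = 1.0
        return hs.SolventTrajectory(pos, quat, np.full((2, 3), box))

    def test_pair_within_cutoff(self):
        traj = self._static_traj([[0, 0, 0], [0.9, 0, 0]])
        pairs, triples = hs.build_correlation_lists(traj)
        assert pairs == [(0, 1)] and triples == []

    def test_triple_within_cutoff(self):
        a = 0.3
        pts = [[0, 0, 0], [a, 0, 0], [a / 2, a * np.sqrt(3) / 2, 0]]
        pairs, triples = hs.build_correlation_lists(self._static_traj(pts))
        assert len(pairs) == 3 and triples == [(0, 1, 2)]

    def test_beyond_cutoff_excluded(self):
        traj = self._static_traj([[0, 0, 0], [1.1, 0, 0]])
        pairs, _ = hs.build_correlation_lists(traj)
        assert pairs == []


class TestMieTotal:
    def test_independent_molecules_sum_of_singles(self):
        terms = EntropyTerms(S1_trans={0: 1.0, 1: 2.0}, S1_rot={0: 0.5, 1: 0.5})
        assert mie_total(terms, [0, 1]) == pytest.approx(4.0)

    def test_pair_telescopes_to_joint_estimate(self):
        """For two jointly Gaussian molecules the third-order expansion
        equals the direct 6-D joint estimate by construction."""
        traj, _ = hs.gen_gaussian_cloud(2, 6000, seed=20, sigma=0.06,
                                        correlated_pairs=[(0, 1, 0.7)])
        x0, x1 = traj.positions[:, 0], traj.positions[:, 1]
        s0, s1 = knn_entropy(x0), knn_entropy(x1)
        i2 = s0 + s1 - joint_knn_entropy([EuclideanChannel(x0),
                                          EuclideanChannel(x1)])
        mie_trans = s0 + s1 - i2
        direct = joint_knn_entropy([EuclideanChannel(x0), EuclideanChannel(x1)])
        assert mie_trans == pytest.approx(direct, rel=1e-12)

    def test_triple_group_matches_analytic_joint(self):
        """Third-order expansion of a 3-molecule coupled Gaussian group
        agrees with the exact joint entropy within estimator noise."""
        traj, ref = hs.gen_gaussian_cloud(3, 8000, seed=21, sigma=0.05,
                                          coupled_triples=[(0, 1, 2, 0.5)])
        pairs = [(0, 1), (0, 2), (1, 2)]
        terms = hs.compute_entropy_terms(traj, pairs=pairs,
                                         triples=[(0, 1, 2)],
                                         include_pair_transrot=False)
        mie = mie_total(terms, [0, 1, 2])
        # subtract the (independent) rotational and self trans-rot parts
        rot_and_self = (sum(terms.S1_rot.values())
                        - sum(terms.I_tr_self.values())
                        - sum(terms.I2_rot.values())
                        + sum(terms.I3_rot.values()))
        assert mie - rot_and_self == pytest.approx(
            ref.joint_entropy([0, 1, 2]), abs=0.25)

    def test_missing_pair_term_raises(self):
        terms = EntropyTerms(S1_trans={0: 1.0, 1: 1.0}, S1_rot={0: 0.0, 1: 0.0},
                             pairs=[(0, 1)])
        with pytest.raises(KeyError, match="pair"):
            mie_total(terms, [0, 1])

    def test_label_invariance(self):
        """Applying a fixed relabeling to all molecules leaves the expansion
        total unchanged."""
        traj, _ = hs.gen_gaussian_cloud(3, 3000, seed=22, sigma=0.05,
                                        correlated_pairs=[(0, 1, 0.6)])
        perm = np.array([2, 0, 1])
        traj_p = hs.SolventTrajectory(traj.positions[:, perm],
                                      traj.quaternions[:, perm],
                                      traj.box.copy())
        pairs = [(0, 1), (0, 2), (1, 2)]
        t_a = hs.compute_entropy_terms(traj, pairs=pairs, triples=[])
        t_b = hs.compute_entropy_terms(traj_p, pairs=pairs, triples=[])
        assert mie_total(t_a, [0, 1, 2]) == pytest.approx(
            mie_total(t_b, [0, 1, 2]), abs=1e-9)


class TestShellEntropy:
    def _shells(self, n, n_inner):
        return ShellAssignment(order=np.arange(n), n_analysis=n, n_inner=n_inner)

    def test_formula(self):
        terms = EntropyTerms(S1_trans={0: 5.0, 1: 6.0}, S1_rot={0: 0.0, 1: 0.0},
                             I2_trans={(0, 1): 4.0}, I2_rot={(0, 1): 0.0},
                             pairs=[(0, 1)])
        se = shell_entropy(terms, self._shells(2, 1))
        assert se.S_internal == pytest.approx(5.0)
        assert se.I_cross == pytest.approx(4.0)
        assert se.S_shell == pytest.approx(3.0)

    def test_no_cross_terms(self):
        terms = EntropyTerms(S1_trans={0: 5.0}, S1_rot={0: 1.0})
        se = shell_entropy(terms, self._shells(1, 1))
        assert se.S_shell == se.S_internal

    def test_cross_gaussian_pair_hand_computed(self):
        """Two-group system with one cross pair of known Gaussian MI."""
        rho = 0.8
        traj, ref = hs.gen_gaussian_cloud(2, 20_000, seed=23, sigma=0.05,
                                          correlated_pairs=[(0, 1, rho)])
        terms = hs.compute_entropy_terms(traj, pairs=[(0, 1)], triples=[],
                                         include_pair_transrot=False)
        se = shell_entropy(terms, self._shells(2, 1))
        expected_cross = (terms.I2_trans[(0, 1)] + terms.I2_rot[(0, 1)])
        assert se.I_cross == pytest.approx(expected_cross, rel=1e-12)
        # and the trans part of the cross MI matches the closed form
        assert terms.I2_trans[(0, 1)] == pytest.approx(
            -1.5 * np.log(1 - rho ** 2), rel=0.08)
        assert se.S_shell == pytest.approx(se.S_internal - se.I_cross / 2,
                                           rel=1e-15)
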