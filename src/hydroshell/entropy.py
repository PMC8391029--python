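"""Nonparametric solvent entropy via k-nearest-neighbor estimation and a
third-order mutual-information expansion (MIE).

Estimator
---------
All terms use the Kozachenko-Leonenko estimator with k = 1 at every
expansion order,

    S_hat = psi(N) - psi(k) + (1/N) sum_i ln V(eps_i),

where eps_i is the distance from sample i to its k-th nearest neighbor and
V(eps) the volume of the metric ball of radius eps.  For a d-dimensional
Euclidean channel V(eps) = c_d eps^d with c_d the unit-ball volume; for the
rotation group the metric is the geodesic angle with the quaternion double
cover collapsed, d(q, q') = 2 arccos|<q, q'>|, and the Haar ball volume is
V(eps) = 8 pi (eps - sin eps), normalized so the uniform distribution attains
ln(8 pi^2).

Joint (pair/triple and translation-rotation) spaces use the product metric
max_c d_c/s_c over channels, whose ball volume is the product of the channel
ball volumes at radii s_c eps; the per-channel commensuration scales s_c are
taken as mean pairwise distances on a fixed leading subsample.

Expansion
---------
For a member set M with listed pairs P and triples T,

    S = sum_{i in M} (S1_trans + S1_rot)
        - sum_{(i,j) in P} (I2_trans + I2_rot)
        + sum_{(i,j,k) in T} (I3_trans + I3_rot)
        - sum_{i in M} I_tr_self - sum_{(i,j) in P} I2_transrot,

with I3 the interaction information S_i+S_j+S_k-S_ij-S_ik-S_jk+S_ijk (so the
identity S_ijk = sum S1 - sum I2 + I3 holds exactly for an isolated triple);
all translation-rotation coupling terms enter as correlations with negative
sign.  The inner-shell entropy is S_internal - I_cross/2, where I_cross sums
every term straddling the inner/outer boundary with its expansion sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma, gammaln

from .constants import KB, T_REF
from .system import ShellAssignment, SolventTrajectory, minimum_image

_JITTER = 1e-9
_JITTER_SEED = 20210602


# --------------------------------------------------------------------------
# metric channels
# --------------------------------------------------------------------------

class EuclideanChannel:
    """A d-dimensional Euclidean coordinate block of N samples."""

    kind = "euclidean"

    def __init__(self, samples: np.ndarray):
        x = np.ascontiguousarray(np.atleast_2d(samples), dtype=float)
        if x.ndim != 2:
            raise ValueError("samples must be (N, d)")
        self.x = x
        self._sq = np.einsum("ij,ij->i", x, x)

    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def dim(self) -> int:
        return self.x.shape[1]

    def block_sq_distances(self, start: int, stop: int) -> np.ndarray:
        """Squared distances from samples[start:stop] to all samples, (m, N).

        float32 BLAS: a ~1e-7 relative error on neighbor distances is far
        below the statistical error of the estimator.
        """
        x32 = self._x32
        g = x32[start:stop] @ x32.T
        d2 = self._sq32[start:stop, None] + self._sq32[None, :] - 2.0 * g
        np.maximum(d2, 0.0, out=d2)
        return d2

    @property
    def _x32(self) -> np.ndarray:
        if not hasattr(self, "_x32_cache"):
            self._x32_cache = self.x.astype(np.float32)
            self._sq32 = np.einsum("ij,ij->i", self._x32_cache, self._x32_cache)
        return self._x32_cache

    def block_distances(self, start: int, stop: int) -> np.ndarray:
        return np.sqrt(self.block_sq_distances(start, stop).astype(float))

    def log_ball_volume(self, eps: np.ndarray) -> np.ndarray:
        d = self.dim
        log_cd = (d / 2) * np.log(np.pi) - gammaln(d / 2 + 1)
        return log_cd + d * np.log(eps)

    def jitter(self, rng: np.random.Generator) -> "EuclideanChannel":
        return EuclideanChannel(self.x + rng.normal(scale=_JITTER, size=self.x.shape))


class RotationChannel:
    """Unit quaternions (w, x, y, z) under the geodesic angle metric with the
    double cover collapsed."""

    kind = "rotation"

    def __init__(self, quaternions: np.ndarray):
        q = np.ascontiguousarray(np.atleast_2d(quaternions), dtype=float)
        if q.shape[-1] != 4:
            raise ValueError("quaternions must be (N, 4)")
        norms = np.linalg.norm(q, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("quaternions must be unit within 1e-6")
        self.q = q / norms[:, None]

    @property
    def n(self) -> int:
        return self.q.shape[0]

    def block_sq_distances(self, start: int, stop: int) -> np.ndarray:
        """Squared chordal double-cover distances e^2 = 2 - 2|<q, q'>|.

        The chordal metric e = min(|q - q'|, |q + q'|) = 2 sin(theta/4) is a
        monotone transform of the geodesic angle theta, so neighbor ranks are
        identical; ``log_ball_volume`` converts back to the Haar volume.
        """
        q32 = self._q32
        dot = np.abs(q32[start:stop] @ q32.T)
        d2 = 2.0 - 2.0 * dot
        np.maximum(d2, 0.0, out=d2)
        return d2

    @property
    def _q32(self) -> np.ndarray:
        if not hasattr(self, "_q32_cache"):
            self._q32_cache = self.q.astype(np.float32)
        return self._q32_cache

    def block_distances(self, start: int, stop: int) -> np.ndarray:
        return np.sqrt(self.block_sq_distances(start, stop).astype(float))

    def log_ball_volume(self, eps: np.ndarray) -> np.ndarray:
        """Haar volume of the chordal ball of radius eps (via the geodesic
        angle theta = 4 arcsin(eps/2))."""
        e = np.clip(np.asarray(eps, dtype=float), 0.0, 2.0 - 1e-15)
        theta = 4.0 * np.arcsin(np.minimum(e / 2.0, 1.0))
        theta = np.minimum(theta, np.pi)
        small = theta < 1e-4
        body = np.where(small, theta ** 3 / 6.0 * (1.0 - theta ** 2 / 20.0),
                        theta - np.sin(theta))
        return np.log(8.0 * np.pi) + np.log(body)

    def jitter(self, rng: np.random.Generator) -> "RotationChannel":
        from scipy.spatial.transform import Rotation

        rv = rng.normal(scale=_JITTER, size=(self.n, 3))
        dq = Rotation.from_rotvec(rv)
        base = Rotation.from_quat(self.q[:, [1, 2, 3, 0]])
        out = (dq * base).as_quat()[:, [3, 0, 1, 2]]
        return RotationChannel(out)


Channel = EuclideanChannel | RotationChannel


def as_channel(samples: np.ndarray, kind: str = "auto") -> Channel:
    """Wrap raw samples: (N, 4) unit rows become a rotation channel under
    ``kind='auto'``; anything else is Euclidean."""
    samples = np.asarray(samples, dtype=float)
    if kind == "rotation":
        return RotationChannel(samples)
    if kind == "euclidean":
        return EuclideanChannel(samples)
    if (samples.ndim == 2 and samples.shape[1] == 4
            and np.allclose(np.linalg.norm(samples, axis=1), 1.0, atol=1e-6)):
        return RotationChannel(samples)
    return EuclideanChannel(samples)


# --------------------------------------------------------------------------
# single-channel estimators
# --------------------------------------------------------------------------

def _kl_from_log_volumes(log_vols: np.ndarray, n: int, k: int) -> float:
    return float(digamma(n) - digamma(k) + log_vols.mean())


def knn_entropy(samples: np.ndarray, k: int = 1,
                boxsize: float | np.ndarray | None = None) -> float:
    """Kozachenko-Leonenko differential entropy (nats) of Euclidean samples.

    ``boxsize`` switches to the minimum-image (toroidal) metric of a periodic
    rectangular box, the natural metric for solvent coordinates; it also
    removes the hard-boundary bias for distributions supported on the whole
    box.  Exact-duplicate samples are perturbed once by a seeded 1e-9 jitter;
    if duplicates survive the perturbation an error is raised.
    """
    ch = EuclideanChannel(samples)
    if ch.n < 10:
        raise ValueError(f"need at least 10 samples, got {ch.n}")
    if k < 1 or k >= ch.n:
        raise ValueError("require 1 <= k < N")
    x = ch.x if boxsize is None else np.mod(ch.x, boxsize)
    eps = _kdtree_kth_distance(x, k, boxsize)
    if np.any(eps == 0.0):
        rng = np.random.default_rng(_JITTER_SEED)
        ch = ch.jitter(rng)
        x = ch.x if boxsize is None else np.mod(ch.x, boxsize)
        eps = _kdtree_kth_distance(x, k, boxsize)
        if np.any(eps == 0.0):
            raise ValueError("duplicate samples persist after jitter")
    return _kl_from_log_volumes(ch.log_ball_volume(eps), ch.n, k)


def _kdtree_kth_distance(x: np.ndarray, k: int,
                         boxsize: float | np.ndarray | None = None) -> np.ndarray:
    tree = cKDTree(x, boxsize=boxsize)
    dist, _ = tree.query(x, k=k + 1)
    return dist[:, k]


def rotational_entropy(quaternions: np.ndarray, k: int = 1) -> float:
    """k-NN entropy (nats) of orientations under the collapsed-double-cover
    geodesic metric; the uniform distribution attains ln(8 pi^2).

    Nearest neighbors are found exactly with a KD-tree over the doubled point
    set {+-q}: the sign-minimized chordal distance e = min(|q-q'|, |q+q'|) is
    monotone in the geodesic angle theta = 4 arcsin(e/2), and e <= sqrt(2)
    while each antipodal self-image sits at distance 2, so it never shadows a
    true neighbor.
    """
    ch = RotationChannel(quaternions)
    if ch.n < 10:
        raise ValueError(f"need at least 10 samples, got {ch.n}")
    if k < 1 or k >= ch.n:
        raise ValueError("require 1 <= k < N")
    e = _rotation_kth_chordal(ch.q, k)
    if np.any(e == 0.0):
        rng = np.random.default_rng(_JITTER_SEED)
        ch = ch.jitter(rng)
        e = _rotation_kth_chordal(ch.q, k)
        if np.any(e == 0.0):
            raise ValueError("duplicate orientations persist after jitter")
    return _kl_from_log_volumes(ch.log_ball_volume(e), ch.n, k)


def _rotation_kth_chordal(q: np.ndarray, k: int) -> np.ndarray:
    doubled = np.vstack([q, -q])
    tree = cKDTree(doubled)
    dist, _ = tree.query(q, k=k + 1)
    return dist[:, k]


# --------------------------------------------------------------------------
# product-metric joint estimator
# --------------------------------------------------------------------------

def _channel_scale(ch: Channel, m: int = 256) -> float:
    """Commensuration scale: mean pairwise distance among the first
    min(N, m) samples (deterministic)."""
    mm = min(ch.n, m)
    d = ch.block_distances(0, mm)[:, :mm]
    iu = np.triu_indices(mm, k=1)
    s = float(d[iu].mean()) if iu[0].size else 1.0
    return s if s > 0 else 1.0


def joint_knn_entropy(channels: list[Channel], k: int = 1,
                      scales: list[float] | None = None) -> float:
    """KL entropy (nats) of the product space of several channels under the
    scaled max metric, by chunked exact brute-force neighbor search."""
    n = channels[0].n
    if any(ch.n != n for ch in channels):
        raise ValueError("all channels must have the same sample count")
    if n < 10:
        raise ValueError(f"need at least 10 samples, got {n}")
    if scales is None:
        scales = [_channel_scale(ch) for ch in channels]

    eps = _product_kth_distance(channels, scales, k)
    if np.any(eps == 0.0):
        rng = np.random.default_rng(_JITTER_SEED)
        channels = [ch.jitter(rng) for ch in channels]
        eps = _product_kth_distance(channels, scales, k)
        if np.any(eps == 0.0):
            raise ValueError("duplicate joint samples persist after jitter")

    log_vol = np.zeros(n)
    for ch, s in zip(channels, scales):
        log_vol += ch.log_ball_volume(s * eps)
    return _kl_from_log_volumes(log_vol, n, k)


def _product_kth_distance(channels: list[Channel], scales: list[float],
                          k: int) -> np.ndarray:
    if all(ch.kind == "euclidean" for ch in channels):
        return _euclidean_product_kth(channels, scales, k)
    return _product_kth_brute(channels, scales, k)


def _euclidean_product_kth(channels: list[EuclideanChannel],
                           scales: list[float], k: int) -> np.ndarray:
    """Exact k-th neighbor under max_c d_c/s_c for Euclidean channels via
    KD-tree candidate refinement: the L2 norm on the concatenated scaled
    coordinates brackets the channel-max metric within a factor sqrt(C),
    so the true neighbor is certified to lie among the L2 candidates once
    the candidate list extends past sqrt(C) times the k-th refined distance.
    """
    n = channels[0].n
    xs = np.hstack([ch.x / s for ch, s in zip(channels, scales)])
    tree = cKDTree(xs)
    root_c = np.sqrt(len(channels))
    todo = np.arange(n)
    eps = np.empty(n)
    m = max(16, 2 * (k + 1))
    while todo.size:
        m = min(m, n)
        d_l2, idx = tree.query(xs[todo], k=m)
        dmax = np.zeros_like(d_l2)
        for ch, s in zip(channels, scales):
            diff = ch.x[todo][:, None, :] - ch.x[idx]
            np.maximum(dmax, np.linalg.norm(diff, axis=-1) / s, out=dmax)
        dmax[idx == todo[:, None]] = np.inf
        dmax.sort(axis=1)
        r_k = dmax[:, k - 1]
        certified = (d_l2[:, m - 1] >= root_c * r_k) | (m == n)
        eps[todo[certified]] = r_k[certified]
        todo = todo[~certified]
        m *= 4
    return eps


def _product_kth_brute(channels: list[Channel], scales: list[float],
                       k: int) -> np.ndarray:
    """k-th neighbor distance under max_c d_c/s_c, chunked exact brute force
    on squared-distance surrogates (max of squares = square of max)."""
    n = channels[0].n
    eps = np.empty(n)
    chunk = max(16, int(24_000_000 // max(n, 1)))
    inv_s2 = np.array([1.0 / s ** 2 for s in scales], dtype=np.float32)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        dmax: np.ndarray | None = None
        for ch, w in zip(channels, inv_s2):
            d2 = ch.block_sq_distances(start, stop)
            d2 *= w
            dmax = d2 if dmax is None else np.maximum(dmax, d2, out=dmax)
        rows = np.arange(stop - start)
        dmax[rows, np.arange(start, stop)] = np.inf
        eps[start:stop] = np.partition(dmax, k - 1, axis=1)[:, k - 1]
    return np.sqrt(eps)


def mutual_information(samples_x: np.ndarray, samples_y: np.ndarray,
                       k: int = 1, kind_x: str = "auto", kind_y: str = "auto",
                       estimator: str = "radius_matched") -> float:
    """I(X; Y) = S(X) + S(Y) - S(X, Y) in nats, each entropy via the k-NN
    estimator in the appropriate metric (translational, rotational or mixed).

    With ``estimator='radius_matched'`` (default) the two marginal entropies
    are evaluated at the joint-space neighbor radii via neighbor counts,

        S_hat(X) = psi(N) - <psi(n_x + 1)> + <ln V_x(s_x eps)>,

    which cancels the leading bias shared with the joint estimate and reduces
    to the Kraskov-Stoegbauer-Grassberger form
    I = psi(k) + psi(N) - <psi(n_x + 1) + psi(n_y + 1)>.
    ``estimator='kl'`` uses three independent Kozachenko-Leonenko estimates;
    it is the form used inside the expansion machinery, where exact
    telescoping against joint entropies matters more than absolute bias.
    """
    cx = as_channel(samples_x, kind_x)
    cy = as_channel(samples_y, kind_y)
    if cx.n != cy.n:
        raise ValueError(f"sample count mismatch: {cx.n} vs {cy.n}")
    if estimator == "kl":
        sx = _single_channel_entropy(cx, k)
        sy = _single_channel_entropy(cy, k)
        sxy = joint_knn_entropy([cx, cy], k)
        return sx + sy - sxy
    if estimator != "radius_matched":
        raise ValueError(f"unknown estimator {estimator!r}")

    n = cx.n
    if n < 10:
        raise ValueError(f"need at least 10 samples, got {n}")
    scales = [_channel_scale(cx), _channel_scale(cy)]
    eps = _product_kth_distance([cx, cy], scales, k)
    if np.any(eps == 0.0):
        rng = np.random.default_rng(_JITTER_SEED)
        cx, cy = cx.jitter(rng), cy.jitter(rng)
        eps = _product_kth_distance([cx, cy], scales, k)
        if np.any(eps == 0.0):
            raise ValueError("duplicate joint samples persist after jitter")
    counts = [_strict_ball_counts(ch, s * eps) for ch, s in zip((cx, cy), scales)]
    return float(digamma(k) + digamma(n)
                 - np.mean(digamma(counts[0] + 1) + digamma(counts[1] + 1)))


def _strict_ball_counts(ch: Channel, radii: np.ndarray) -> np.ndarray:
    """Number of other samples strictly within ``radii`` of each sample,
    under the channel metric."""
    r = radii * (1.0 - 1e-10)
    if ch.kind == "rotation":
        tree = cKDTree(np.vstack([ch.q, -ch.q]))
        # chordal radius <= sqrt(2) guarantees at most one sign per neighbor
        counts = tree.query_ball_point(ch.q, np.minimum(r, np.sqrt(2.0)),
                                       return_length=True)
    else:
        tree = cKDTree(ch.x)
        counts = tree.query_ball_point(ch.x, r, return_length=True)
    return np.maximum(np.asarray(counts) - 1, 0)  # exclude self


def _single_channel_entropy(ch: Channel, k: int) -> float:
    if ch.kind == "rotation":
        return rotational_entropy(ch.q, k)
    return knn_entropy(ch.x, k)


# --------------------------------------------------------------------------
# localized coordinates
# --------------------------------------------------------------------------

def localized_positions(traj: SolventTrajectory) -> np.ndarray:
    """Unwrap locator positions around each molecule's first-frame anchor by
    minimum image, so a localized molecule's samples form one compact cloud
    even when it sits on a periodic boundary."""
    anchor = traj.positions[0]
    return anchor[None] + minimum_image(traj.positions - anchor[None],
                                        traj.box[:, None, :])


# --------------------------------------------------------------------------
# correlation lists and term containers
# --------------------------------------------------------------------------

def build_correlation_lists(traj: SolventTrajectory,
                            shells: ShellAssignment | None = None,
                            pair_cutoff: float = 1.0,
                            triple_cutoff: float = 0.33,
                            ) -> tuple[list[tuple[int, int]],
                                       list[tuple[int, int, int]]]:
    """Pairs of analysis-set molecules whose trajectory-average minimum-image
    locator distance is within ``pair_cutoff`` (nm), and triples whose three
    average distances are all within ``triple_cutoff``."""
    members = (np.arange(traj.n_molecules) if shells is None
               else np.sort(shells.analysis_set))
    pos = traj.positions[:, members]
    n = len(members)
    dist_sum = np.zeros((n, n))
    for f in range(traj.n_frames):
        delta = pos[f][:, None, :] - pos[f][None, :, :]
        dist_sum += np.linalg.norm(minimum_image(delta, traj.box[f]), axis=-1)
    mean_d = dist_sum / traj.n_frames

    pairs = [(int(members[a]), int(members[b]))
             for a, b in zip(*np.nonzero(np.triu(mean_d <= pair_cutoff, k=1)))]
    close = mean_d <= triple_cutoff
    triples = [(int(members[a]), int(members[b]), int(members[c]))
               for a, b, c in combinations(range(n), 3)
               if close[a, b] and close[a, c] and close[b, c]]
    return pairs, triples


@dataclass
class EntropyTerms:
    """All terms of the third-order expansion, in nats.

    Pair keys are sorted 2-tuples, triple keys sorted 3-tuples of molecule
    indices.  ``I2_transrot`` holds the symmetrized cross term
    I(x_i; q_j) + I(x_j; q_i); ``I_tr_self`` the per-molecule I(x_i; q_i).
    ``T`` (K) converts entropies to -T*S free-energy contributions.
    """

    S1_trans: dict[int, float] = field(default_factory=dict)
    S1_rot: dict[int, float] = field(default_factory=dict)
    I_tr_self: dict[int, float] = field(default_factory=dict)
    I2_trans: dict[tuple[int, int], float] = field(default_factory=dict)
    I2_rot: dict[tuple[int, int], float] = field(default_factory=dict)
    I2_transrot: dict[tuple[int, int], float] = field(default_factory=dict)
    I3_trans: dict[tuple[int, int, int], float] = field(default_factory=dict)
    I3_rot: dict[tuple[int, int, int], float] = field(default_factory=dict)
    pairs: list[tuple[int, int]] = field(default_factory=list)
    triples: list[tuple[int, int, int]] = field(default_factory=list)
    T: float = T_REF

    def minus_TS(self, nats: float) -> float:
        """Convert an entropy in nats to -T*S in kJ mol^-1 at this T."""
        return -self.T * KB * nats


def compute_entropy_terms(traj: SolventTrajectory,
                          shells: ShellAssignment | None = None,
                          pairs: list[tuple[int, int]] | None = None,
                          triples: list[tuple[int, int, int]] | None = None,
                          k: int = 1,
                          include_pair_transrot: bool = True,
                          T: float = T_REF) -> EntropyTerms:
    """Estimate every term of the third-order expansion for the analysis set
    of a (permutation-reduced) trajectory."""
    members = (list(range(traj.n_molecules)) if shells is None
               else [int(i) for i in shells.analysis_set])
    if pairs is None or triples is None:
        p, t = build_correlation_lists(traj, shells)
        pairs = p if pairs is None else pairs
        triples = t if triples is None else triples
    pairs = [tuple(sorted(p)) for p in pairs]
    triples = [tuple(sorted(t)) for t in triples]

    pos = localized_positions(traj)
    tchan = {i: EuclideanChannel(pos[:, i]) for i in members}
    rchan = {i: RotationChannel(traj.quaternions[:, i]) for i in members}

    terms = EntropyTerms(pairs=pairs, triples=triples, T=T)
    for i in members:
        terms.S1_trans[i] = knn_entropy(tchan[i].x, k)
        terms.S1_rot[i] = rotational_entropy(rchan[i].q, k)
        terms.I_tr_self[i] = (terms.S1_trans[i] + terms.S1_rot[i]
                              - joint_knn_entropy([tchan[i], rchan[i]], k))

    joint_cache: dict[tuple, float] = {}

    def joint(keys: tuple[tuple[str, int], ...]) -> float:
        if keys not in joint_cache:
            chans: list[Channel] = [tchan[i] if kind == "t" else rchan[i]
                                    for kind, i in keys]
            joint_cache[keys] = joint_knn_entropy(chans, k)
        return joint_cache[keys]

    for i, j in pairs:
        terms.I2_trans[(i, j)] = (terms.S1_trans[i] + terms.S1_trans[j]
                                  - joint((("t", i), ("t", j))))
        terms.I2_rot[(i, j)] = (terms.S1_rot[i] + terms.S1_rot[j]
                                - joint((("r", i), ("r", j))))
        if include_pair_transrot:
            cross_ij = (terms.S1_trans[i] + terms.S1_rot[j]
                        - joint((("t", i), ("r", j))))
            cross_ji = (terms.S1_trans[j] + terms.S1_rot[i]
                        - joint((("t", j), ("r", i))))
            terms.I2_transrot[(i, j)] = cross_ij + cross_ji

    for i, j, kk in triples:
        for chan, s1, i3 in (("t", terms.S1_trans, terms.I3_trans),
                             ("r", terms.S1_rot, terms.I3_rot)):
            s_pairs = (joint(((chan, i), (chan, j)))
                       + joint(((chan, i), (chan, kk)))
                       + joint(((chan, j), (chan, kk))))
            s_triple = joint(((chan, i), (chan, j), (chan, kk)))
            i3[(i, j, kk)] = (s1[i] + s1[j] + s1[kk]) - s_pairs + s_triple
    return terms


# --------------------------------------------------------------------------
# expansion totals
# --------------------------------------------------------------------------

def mie_total(terms: EntropyTerms, member_set) -> float:
    """Third-order expansion total (nats) restricted to ``member_set``."""
    members = set(int(i) for i in member_set)
    for i in members:
        if i not in terms.S1_trans or i not in terms.S1_rot:
            raise KeyError(f"missing single-molecule terms for molecule {i}")
    s = sum(terms.S1_trans[i] + terms.S1_rot[i] for i in members)
    s -= sum(terms.I_tr_self.get(i, 0.0) for i in members)
    for p in terms.pairs:
        if set(p) <= members:
            if p not in terms.I2_trans or p not in terms.I2_rot:
                raise KeyError(f"missing pair terms for {p}")
            s -= terms.I2_trans[p] + terms.I2_rot[p]
            s -= terms.I2_transrot.get(p, 0.0)
    for t in terms.triples:
        if set(t) <= members:
            if t not in terms.I3_trans or t not in terms.I3_rot:
                raise KeyError(f"missing triple terms for {t}")
            s += terms.I3_trans[t] + terms.I3_rot[t]
    return float(s)


@dataclass
class ShellEntropy:
    """Inner-shell entropy ledger: S_shell = S_internal - I_cross/2 with
    I_cross the signed sum of all expansion terms straddling the boundary."""

    S_internal: float
    I_cross: float

    @property
    def S_shell(self) -> float:
        return self.S_internal - self.I_cross / 2.0


def shell_entropy(terms: EntropyTerms, shells: ShellAssignment) -> ShellEntropy:
    """Assemble the inner-shell entropy from computed terms.

    Cross terms (one molecule inside the inner shell, one outside but in the
    analysis set) are summed with the sign they carry in the expansion: +I2
    and +I_tr for pair correlations, -I3 for triples, so that
    S_inner+outer = S_internal + S_external - (cross contribution) and the
    shell keeps half of the shared correlation entropy.
    """
    inner = set(int(i) for i in shells.inner_shell)
    i_cross = 0.0
    for p in terms.pairs:
        n_in = sum(1 for m in p if m in inner)
        if n_in == 1:
            i_cross += terms.I2_trans[p] + terms.I2_rot[p]
            i_cross += terms.I2_transrot.get(p, 0.0)
    for t in terms.triples:
        n_in = sum(1 for m in t if m in inner)
        if 0 < n_in < 3:
            i_cross -= terms.I3_trans[t] + terms.I3_rot[t]
    return ShellEntropy(S_internal=mie_total(terms, inner), I_cross=i_cross)
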