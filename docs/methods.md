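# Methods

This note documents the models, estimators, numerical choices and
limitations of `hydroshell`, in the spirit of a statistical-software methods
section. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Units, conventions, constants

Lengths in nm, energies in kJ mol⁻¹, charges in elementary charges, masses
in amu, temperatures in K. Entropies are carried in nats internally and
reported as −TS in kJ mol⁻¹ via k_B = 0.0083145 kJ mol⁻¹ K⁻¹ at
T = 300 K. The Coulomb prefactor is f = 138.935458 kJ mol⁻¹ nm e⁻²;
1 bar·nm³ = 0.0602214076 kJ mol⁻¹. Boxes are rectangular and periodic;
distances use the minimum-image convention. Internal indexing is 0-based;
residue ids are 1-based. State differences are
Δ = (unfolded-like) − (folded), so positive values favor the folded state.

Molecule position means the locator site (the water oxygen). Orientations
are unit quaternions (scalar first) for the body frame with z along the
H–O–H bisector and x along the in-plane H–H direction; the paperless choice
of locator and body frame is a package convention, as is fixing shell
membership once from trajectory-average distances rather than per frame
(required for per-molecule bookkeeping after permutation reduction).

## Permutation reduction

Identical solvent molecules are relabeled in every frame to minimize
Σᵢ‖x_{π(i)} − x_i^ref‖² (minimum image, locator sites) against a reference
frame (default: first). The assignment is solved exactly with a
Hungarian-class algorithm (`scipy.optimize.linear_sum_assignment`); an
exhaustive N ≤ 8 oracle ships for tests. The approximate gradient methods
used at MD scale are out of scope — at the problem sizes this package
targets, exactness is affordable and removes a tuning dimension. All sites
and the orientation of a molecule move with its label, so each frame's
multiset of molecular states is untouched: per-frame totals (energies) are
invariant, while per-label series become localized and therefore meaningful.

## Entropy estimation

Every entropy uses the Kozachenko–Leonenko estimator with k = 1 at all
expansion orders,

    S_hat = psi(N) − psi(k) + (1/N) Σ ln V(ε_i),

with ε_i the distance to the k-th neighbor and V(ε) the metric ball volume.

* **Translational channels** are Euclidean; V(ε) = c_d ε^d. An optional
  toroidal (periodic-box) metric is available and is the natural choice for
  distributions supported on the whole box — it also removes the
  hard-boundary bias of the estimator. Localized molecule clouds are
  unwrapped around their first-frame anchor before estimation so a molecule
  sitting on a box face is one compact cloud.
* **Rotational channels** use the geodesic angle with the quaternion double
  cover collapsed, θ = 2 arccos|⟨q,q′⟩|, normalized so the uniform
  distribution attains ln 8π²; the Haar ball volume is 8π(θ − sin θ).
  Neighbor searches run on a KD-tree over the doubled point set {±q}: the
  sign-minimized chordal distance e = 2 sin(θ/4) is a monotone transform of
  θ, and e ≤ √2 while each antipodal self-image sits at distance 2, so the
  search is exact. For ε < 10⁻⁴ the ball volume uses the series
  θ³/6·(1 − θ²/20) to avoid cancellation.
* **Joint spaces** (pairs, triples, translation–rotation) use the product
  metric max_c d_c/s_c over channels, whose ball volume factorizes into the
  per-channel volumes at radii s_c ε. The commensuration scales s_c are the
  mean pairwise distances on a fixed leading subsample (≤ 256 samples) —
  deterministic, and only an efficiency choice: the estimator is consistent
  for any fixed scales. Rotation channels enter joints through the chordal
  metric (monotone in θ, so ranks are unchanged; volumes are converted
  back through θ(e)). Neighbor search is exact: KD-tree candidate
  refinement in the concatenated space for all-Euclidean joints (the L2
  norm brackets the channel-max metric within √C), chunked brute force with
  BLAS squared-distance surrogates otherwise (float32 matrices; the ~1e−7
  relative distance error is far below estimator noise).
* **Degenerate samples**: exact duplicates are perturbed once by a seeded
  1e−9 jitter; surviving duplicates raise.

`mutual_information` defaults to radius-matched marginal estimates: the two
marginal entropies are evaluated at the joint-space neighbor radii via
neighbor counts, which cancels the leading bias shared with the joint term
and reduces algebraically to the Kraskov–Stögbauer–Grassberger form
I = ψ(k) + ψ(N) − ⟨ψ(n_x+1) + ψ(n_y+1)⟩. The plain three-estimate KL
difference remains available (`estimator="kl"`) and is what the expansion
machinery uses internally, because there the exact telescoping of pair and
triple terms against joint entropies matters more than absolute bias — and
in the shell analysis all terms enter as differences against a bulk
reference, where shared bias cancels anyway.

### Mutual-information expansion

For the analysis set (default: 4000 closest molecules), pair terms are
collected for molecules within 1.0 nm trajectory-average distance and
triples within 0.33 nm. The third-order total over a member set M is

    S = Σ S1_trans + Σ S1_rot − Σ I2_trans − Σ I2_rot + Σ I3_trans
        + Σ I3_rot − Σ I_tr_self − Σ I2_transrot,

with I3 the interaction information (S_i+S_j+S_k − S_ij−S_ik−S_jk+S_ijk),
so S_ijk = ΣS1 − ΣI2 + I3 holds identically for an isolated triple.
Translation–rotation coupling is computed both per molecule (self term) and
for listed pairs (symmetrized cross term I(x_i;q_j)+I(x_j;q_i)); both are
reported separately and both enter the expansion with negative sign, since
the reference analysis aggregates them as one channel without specifying
the split. Higher-order correlations are neglected.

The inner-shell entropy (default: closest 1000 molecules) is
S_internal − I/2, where S_internal is the expansion total over inner
molecules and I sums every term straddling the boundary *with its expansion
sign* (+I2, +I_tr, −I3): the shell keeps half of the shared correlation
entropy. The identity S_shell = S_internal − I/2 is exact by construction.

## Enthalpy decomposition

Interaction energies are recomputed from per-site charges and LJ parameters:
U(r) = 4ε[(σ/r)¹² − (σ/r)⁶]·1[r ≤ 2 nm] + f q_a q_b/r, Lorentz–Berthelot
combination, bare minimum-image Coulomb with no lattice summation. This is
an analysis engine operating on stored configurations; the missing
long-range electrostatics is a documented limitation, acceptable because
budget quantities are state differences of like systems. Per inner-shell
molecule the engine accumulates U_PS (all solute atoms), U_SS_inner (half
of each inner–inner pair) and U_inner_outer (full coupling to all non-inner
solvent). U_PP is the all-distinct-pairs solute nonbonded energy (no bonded
exclusions — toy solutes have no bonds); an externally computed bonded
series can be added verbatim, and without it U_PP is labeled
nonbonded-only. H = U + p⟨V⟩ at 1 bar.

## Spatial maps

Each pair term contributes half to each partner, each triple term a third —
removing the double/triple counting — and single-molecule terms map wholly;
entropies convert to −TS. Ledger values are bulk-referenced *before* voxel
accumulation (per-molecule differences against the bulk-reference mean);
referencing after averaging would weight molecules by visitation instead.
The grid (default 129³) spans the box; each voxel holds the
visitation-weighted mean of the localized molecules that visited it, and
Σ_v value·count = Σ_i c_i·n_frames holds to rounding. Output is OpenDX
scalar fields with empty voxels written as a sentinel recorded in the
header (the writer is a small self-contained implementation of the
scalar-field subset of the format).

## Residue analysis and convexity

A water belongs to a residue in a frame when its locator is within 0.4 nm
of any atom of the residue; waters near several residues count for each
(an exclusive nearest-residue mode exists). Per-residue ΔU, −TΔS and
ΔF = ΔU + (−TΔS) are visitation-weighted means over water–frame
observations of the bulk-referenced ledger; pV is neglected (small and
state-independent). Residues with no assigned waters are flagged undefined.

Convexity: c = N_d / ((4/3 πd³ − V_res) n_W) with d = 1 nm. The reference
sphere is centered at the residue's heavy-atom center of geometry (the
formula's spherical volume implies *some* center; this is the package's
choice), N_d is a per-frame average, and V_res sums atomic van-der-Waals
sphere volumes (a Monte-Carlo union-volume option corrects pairwise
overlaps). n_W defaults to 33.4 nm⁻³, a TIP3P-like bulk density, which is
also the toy-solute generator default. Pearson correlations against a
hydrophobicity scale use listwise exclusion; the bundled scale is a clearly
labeled synthetic placeholder (the empirical scale a study would use is a
drop-in CSV).

## Protein entropy and the budget

Schlitter's upper bound S = ½k_B ln det[1 + (k_B T e²/ħ²) M^½ Σ M^½] is
evaluated from the mass-weighted positional covariance after a
mass-weighted least-squares rigid fit to the first frame (removing external
motion; the fit is this package's choice). Zero eigenvalues contribute
ln 1 = 0. A warning is raised when n_frames ≤ 3N.

Per-molecule errors are standard deviations over bulk-phase molecules
(shell molecules are assumed subject to the same spread); state differences
carry √(SEM_A² + SEM_B²) with SEM = SD/√n_replicas — the replicate-error
combination is this package's definition, chosen as the standard
independent-replica form. Budget identities (ΔH as the sum of its four
components, ΔG as ΔH plus all −TΔS terms) hold exactly by construction.

Denaturation temperatures solve ΔG(T) = ΔH₀ + ΔC_P(T−T₀) −
T[ΔS₀ + ΔC_P ln(T/T₀)] = 0 by bracketed Brent iteration on (150 K, T₀) and
(T₀, 450 K), anchored at T₀ = 300 K with constant ΔC_P — the standard
Gibbs–Helmholtz form, documented as this package's definition of the
extrapolation. ΔG(T₀) ≤ 0 is a precondition error; a missing sign change in
a bracket is reported as "no denaturation in range", not an exception.

## Synthetic data: what it emulates and what it does not

The generators produce localized water-like ensembles with *known* answers:
Gaussian position clouds with correlations on matched Cartesian axes only
(so every MI is a product of 1-D closed forms), small-angle tangent-space
orientation ensembles (the only rotational regime with a closed-form
entropy; valid σ_rot ≲ 0.2 rad), Haar-uniform references, 6-D Gaussians
with translation–rotation cross-correlation, and geometric toy solutes
(probe, sphere, wall/pocket, groove) with exact shape-based water
exclusion. They are seed-deterministic.

They do **not** emulate real water structure: no radial distribution
functions, hydrogen bonding, force-field-consistent sampling, or coupling
between the energy scale and the configurational statistics. Passing tests
therefore demonstrate the correctness of the estimators, bookkeeping and
arithmetic — not force-field fidelity. The headline magnitudes of a real
protein study require microsecond MD ensembles that are deliberately out of
scope; the published Crambin budget numbers enter only as *inputs* to the
exact-arithmetic and extrapolation checks.

## Problem sizes

The test and analysis scales were chosen so each estimator operates in its
asymptotic regime at desk scale: single-channel oracle checks at N = 10⁵
samples; joint/MI oracle checks at N = 2–5·10⁴ (translation–rotation MI
averaged over three replicate ensembles); expansion and null-difference
suites with 5–8 molecules × 2500–8000 frames and 4 replicas per state;
convexity with ~1000 independently resampled frames at bulk density. The
acceptance script uses 1000 frames for the exposed-probe convexity and 40
for the buried-residue case (exact zero).

## Known limitations

* k = 1 KL estimates have the largest variance in the k-NN family; the
  reference analysis prescribes k = 1, and tests average replicates where
  variance would otherwise dominate.
* Bare-Coulomb analysis energies are not comparable to Ewald-based MD
  energies in absolute terms.
* The MIE truncation is exact only when dependence is confined to groups of
  ≤ 3 molecules (as in the synthetic fixtures); for real water it is an
  approximation whose error is not bounded here.
* Schlitter entropy is an upper bound and, for the unfolded-like state of a
  real protein, misses conformational multiplicity beyond the sampled
  basin (a k_B T ln(100…1000) ≈ 11–17 kJ mol⁻¹ scale correction discussed
  in the literature; reported as a constant range, never computed here).
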