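# Methods

## The harmonic network

The anisotropic network model treats the coarse-grained structure as beads
joined by Hookean springs.  For beads i, j at equilibrium separation
s⁰_ij ≤ r_c the potential contributes ½·γ(s⁰_ij)·(s_ij − s⁰_ij)²; both the
connectivity and the spring constants are frozen at the equilibrium
geometry, so the analytic Hessian assembled by `build_hessian` is exactly
the second derivative of `anm_potential` (the test suite verifies this by
central differences on random small bead sets, both force-constant laws,
to 1e-6 relative).

The off-diagonal 3×3 super-element of a connected pair is
−(γ_ij/s⁰²)·**d**·**d**ᵀ with **d** the equilibrium displacement vector;
diagonal super-elements enforce zero block row sums (translational
invariance).  Eigenvalues are therefore non-negative, with a six-dimensional
rigid-body null space for any connected geometry (five for collinear
degenerate cases).  `solve_modes` verifies the null space against the
analytic rigid translation/rotation basis (subspace overlap ≥ 0.99) before
dropping it; more near-zero modes than the rigid rank means the network is
disconnected and is reported as such rather than silently analyzed.

Parameters, with defaults and rationale:

| parameter | default | meaning |
|---|---|---|
| cutoff r_c | 9 Å | spring truncation; the scan optimum for CG2 networks of CUG duplexes; scanned over 5–15 Å by `scan_parameters` |
| γ law | exponential | γ(r) = γ₀·exp(−(r − r₀)/ℓ), hard-truncated at r_c |
| γ₀ | 12 (arbitrary units) | contact weight at r₀; only ratios matter for mode shapes |
| r₀ | 3.0 Å | heavy-atom contact distance |
| decay length ℓ | 4.6 Å | chosen so γ(25 Å) ≈ 0.1 — the weighting effectively vanishes by 25 Å |
| scheme | CG2 (P, C2', C4, N3) | backbone probes plus base-edge probes, so base-pair breathing is visible to the network |

Eigenvector signs are fixed (largest-magnitude component positive) for
reproducible output; all comparison metrics use absolute values, so the
convention is cosmetic.  A dense symmetric eigensolver is used throughout:
the systems of interest are a few hundred beads, where sparse machinery
buys nothing.

## Ensemble analysis

PCA uses the covariance of mean-centred 3N coordinate vectors with divisor
m−1 (fractions are divisor-invariant; the absolute σᵢ are sample
variances).  `align_ensemble` iterates superposition onto the evolving
mean until the mean moves < 1e-6 Å RMSD (max 100 iterations); the
converged ensemble has each conformer optimally posed with respect to the
mean, which is exactly the property the projection identities rely on
(projecting an ensemble onto its own principal modes reproduces the
variance spectrum).  Cross-ensemble projections superpose each foreign
conformer onto the mode set's reference mean first, so rigid-body offsets
cannot masquerade as deformation.

Essential dynamics analysis is PCA applied to n equally distributed
snapshots (default 2000): indices round(k·(L−1)/(n−1)), which always
includes the first and last frame.  A trajectory shorter than n is taken
whole with a warning rather than an error.

Collectivity follows the exponential-entropy definition on per-bead
(3-component) squared displacements with the natural logarithm and the
convention 0·log 0 = 0; it is exactly 1 for a uniform mode and 1/N for a
single-bead mode.

## Conformer generation

`sample_conformers` displaces the reference along k selected modes with
amplitudes c_k ~ Normal(0, s²/λ_k) — equipartition weighting, so the
softest mode receives the largest excursions.  The global scale s is set
in closed form so the root-mean-square RMSD from the reference equals the
requested target (default 2 Å); the mean of the RMSD distribution has no
clean closed form for unequal mode variances, and the rms convention keeps
the calibration exact.  A deterministic uniform-grid rule with matching
per-mode variances is available for systematic sweeps.  No excluded-volume
or stereochemistry screening is applied: the generator works in the linear
regime the harmonic model itself assumes.

## U-U pair geometry

Types I–VI are assigned from two measurements:

* **Hydrogen bonds** (0/1/2): candidates are N3(a)→O2/O4(b) and
  N3(b)→O2/O4(a); a candidate passes on heavy-atom distance ≤ 3.5 Å, plus
  an N3–H···O angle ≥ 135° when an imino hydrogen is present (crystal
  models without hydrogens are judged on distance alone — the cpptraj-style
  defaults, both configurable).  Each donor contributes at most one bond.
* **Inclination**: the local helix axis ĥ runs between the C1'–C1'
  midpoints of the flanking canonical pairs; the groove axis is ĝ = ĥ × l̂
  (l̂ the pair's C1'→C1' long axis), with its sign fixed so the flanking
  pairs' base centroids project negative.  The displacement of the uracil
  base-centroid midpoint along ĝ, measured relative to the same quantity
  on the ideal builder geometry, is labelled major above +0.5 Å, minor
  below −0.5 Å, and "none" inside the dead zone.  The dead zone is this
  package's operationalization of "inclined" — the crystallographic
  literature uses the word without a quantitative criterion.

The (bond count, inclination) pairs map to types via the standard table
(2,minor)→I, (1,minor)→II, (0,none)→III, (1,major)→IV, (2,major)→V,
(0,major)→VI.  Three combinations fall outside the table; they are mapped
to the nearest type for their bond count — (2,none) and (1,none) resolve
toward major or minor by the displacement sign, (0,minor) resolves to
III — and flagged `atypical` so downstream statistics can exclude them.

Conformation clustering across trajectory frames uses average linkage on
pairwise RMSDs of the pair's heavy atoms, computed after superposing each
frame on the flanking canonical pairs so that internal pair motion, not
global drift, drives the distances.  Merging stops when the smallest
inter-cluster average distance exceeds the threshold (default 3.0 Å);
the suite checks the result against a brute-force O(m³) agglomeration.

## The synthetic duplex builder

`build_aform_duplex` emulates the geometric features the analyses consume,
not RNA chemistry.  Bases are planar regular polygons (bond length
1.38 Å) carrying the exocyclic O2/O4/N4/O6/N2/N6 acceptors and donors;
base-pair orientations are solved numerically so canonical pairs meet
their Watson–Crick contacts at 2.9 Å with C1'–C1' = 10.4 Å, and U·U pairs
adopt the stretched wobble (one N3···O4 bond at 2.9 Å, the symmetric
second contact opened to 4.6 Å).  Pairs stack under the A-form transform:
twist 32.7°/step, rise 2.81 Å, x-displacement −4.4 Å along the groove
axis, inclination 19° — fiber-diffraction canon, all overridable.  The
atom dictionary is reduced (backbone probes P, C1', C2', C4' only; no O5'/
O3' chain chemistry, no hydrogens): sufficient for the coarse-graining
schemes, superposition, and U-U typing, and documented as non-chemical
geometry.  With the default x-displacement the C1'-midpoint helix radius
is 4.4 Å, so successive pair midpoints are √((2·4.4·sin 16.35°)² + 2.81²)
≈ 3.75 Å apart in space while the axial rise stays exactly 2.81 Å.

`perturb_uu` re-poses one U-U pair to a target type by replacing the two
uracil bases with the pair-frame template of the target's bond count and
then translating both bases together along ĝ until the inclination
displacement equals the label's value (0 / ±1.5 Å).  The common
translation preserves all intra-pair distances, so the two measurements
are controlled independently; the frame's orientation is taken from the
flanking canonical pairs, which the perturbation never touches, making the
operation idempotent.

`GenerativeModel` draws conformers reference + Σ z_k√σ_k·d_k + isotropic
noise.  `from_fractions` converts prescribed top-k PCA percentages into
mode variances by spreading the residual variance evenly over the
remaining 3N−k directions and subtracting that floor from the top modes,
so the expected sample fractions hit the prescription; total variance
defaults to 1 Å² per bead, a typical crystal-ensemble fluctuation scale.
Seeds are explicit arguments everywhere; nothing touches global random
state.

## What the synthetic conditions do and do not show

The generators reproduce the statistical structure the analyses assume —
low-rank Gaussian variation about a reference, prescribed variance splits
(the 43.2/22.9/13.9 % split used in tests mirrors a crystal-fragment
ensemble), stationary snapshot streams with optional slow drift — but not
anharmonicity, conformational substates, solvent-mediated interactions or
crystal-packing artifacts.  Passing tests therefore demonstrate that the
estimators and metrics are implemented correctly and recover known ground
truth at the stated sample sizes; they do not certify how well a harmonic
network describes real CUG-repeat dynamics, which is precisely the
scientific question the pipeline is built to pose against experimental
ensembles.

One consequence of the idealized geometry is worth flagging: a straight
A-form duplex has two nearly equivalent bending planes, so network modes 2
and 3 are near-degenerate (eigenvalues within ~4 % for the CG2/9 Å
(CUG)₃ network).  PCA on any finite ensemble generated from such a pair
recovers the *plane* but mixes the individual vectors; recovery checks
therefore assert per-mode identity only for the non-degenerate softest
mode and use cumulative/subspace overlaps for the degenerate pair.  Real
crystal fragments are less symmetric and do not sit at this edge case.

## Problem sizes and numerical choices

The test and acceptance runs use the 18-nt (CUG)₃ duplex (70 CG2 beads,
204 internal modes), ensembles of 2000 conformers, trajectories of ~1200
frames, and 20-frame clustering mixtures — sizes at which every stage
completes in seconds while keeping sampling error well inside the asserted
tolerances.  Rigid-body identification uses a relative eigenvalue
threshold of 1e-8; superposition convergence 1e-6 Å; mode-vector
renormalization warns above 1e-6 deviation from unit norm; scan ties break
toward the smaller cutoff (the sparser, cheaper model).  PDB coordinates
round-trip to the format's 1e-3 Å precision.

## Known limitations

* The builder's backbone probes are positioned by fixed offsets, not by
  sugar-phosphate chemistry; torsion-level realism is out of scope.
* Water-mediated hydrogen bonds, ions and solvent effects are invisible to
  both the network model and the U-U typing (snapshots are assumed
  solvent-stripped).
* mmCIF input, protein chains and secondary-structure prediction are not
  supported; trajectories enter as multi-model PDB only.
* The network model itself is harmonic: it cannot cross barriers between
  U-U substates, which is exactly where trajectory-based analysis takes
  over.
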