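# Methods

`radcurve` quantifies forearm posture and active pronation ability from the
morphology of the radius, using two complementary signals: the outline shape
of the proximal radial head (analyzed with sliding semi-landmark geometric
morphometrics) and the angle of curvature of the shaft (a three-point angle
metric).  Straight radii that cannot cross the ulna sit near 90°, and
sprawling taxa carry flattened, reniform radial heads; curved radii and
rounded, elongate radial heads mark parasagittal taxa with mammalian-style
pronation.  This note records the models, the numerical choices, and what the
synthetic data do and do not establish.

## Outline convention and input data

Each specimen is a closed 2D outline of the radial head: one fixed landmark
(index 0, digitized at the middle of the ulnar articular surface — the only
point with clear homology across mammals, squamates and archosaurs) followed
by 20 sliding semi-landmarks, traversed clockwise.  "Clockwise" is enforced as
negative shoelace signed area in y-up Cartesian coordinates (the digitizer
convention, not image row/column); counter-clockwise inputs are reversed with
a warning.  `resample_outline` spaces the semi-landmarks equally by cumulative
arc length along the input polyline, keeping the start vertex exact.
Right-side specimens are mirrored (x ↦ −x) at load time so downstream
rotation-only superimposition never needs reflections.  TPS files are parsed
with `LM=`, `ID=`, `IMAGE=` and `SCALE=` keys; `SCALE` multiplies coordinates
on read and is never re-emitted, so write→read round-trips are exact.

## Partial Procrustes superimposition

Every configuration is centered at the origin and scaled to centroid size 1
(the square root of the summed squared distances of the landmarks from their
centroid); partial superimposition keeps centroid size fixed at 1 rather than
letting scale re-optimize during rotation.  The optimal rotation of b onto a
is the closed-form 2D orthogonal fit θ = atan2(Σ(a_y b_x − a_x b_y), Σ a·b),
rotation only.  The partial Procrustes distance is the root sum of squared
coordinate differences after rotation, computed as the norm of the rotated
difference rather than via √(2 − 2cosφ), which loses half the working
precision for near-identical shapes.

GPA iterates: align all specimens to the current consensus, recompute the
consensus as the re-normalized coordinate-wise mean, stop when the RMS
consensus change drops below `tol = 1e-8` (`max_iter = 100`; non-convergence
returns a flagged result with a warning).  The output is canonicalized by
rotating everything so the consensus fixed landmark lies on the +x axis; this
makes results invariant, not merely equivariant, under common similarity
transforms of the raw data.  At convergence the aligned mean is proportional
to the consensus (equal up to the mean's centroid size, which is slightly
below 1 whenever shapes scatter).

A note on a small-dispersion identity: for two specimens, the distance of
each to the consensus equals half their pairwise distance only asymptotically
(2 sin(φ/2) vs sin φ on the pre-shape sphere, agreeing to O(φ³)); the test
suite exercises it at pairwise distance ~1e-3 where it holds to 1e-9.

## Sliding semi-landmarks by minimum bending energy

Semi-landmarks carry no point-to-point homology along the curve, so their
tangential position is treated as a nuisance parameter.  Tangent directions
are cyclic central differences on the specimen's current closed outline (the
fixed landmark participates as a neighbor but never slides).  With U the
block tangent matrix and B the bending energy matrix at the consensus, the
sliding amounts t minimize (y + Ut − c)ᵀ(B ⊗ I₂)(y + Ut − c); the objective
is exactly quadratic, so a single linear solve reaches the tangent-space
optimum (ridge ε = 1e-10 fallback if the normal equations are singular).
Slid configurations are re-normalized to centroid size 1.  The schedule is 3
outer cycles of slide → re-GPA, then a final GPA; each pass logs total
bending energy before/after and is asserted non-increasing.  Sliding follows
the specimen's own tangents (re-projected each cycle) rather than the
consensus tangents.

## Thin-plate spline warps and ordination

The bending energy matrix uses the Bookstein kernel U(r) = r² ln r² with
U(0) = 0: L = [[K, Q], [Qᵀ, 0]], Q = [1 | x | y], and B is the upper-left
k×k block of L⁻¹, symmetrized.  The alternative kernel r² ln r halves every
eigenvalue but leaves warp directions — and hence all scores up to a scalar —
unchanged.  B annihilates the affine fields (1, x, y per coordinate), giving
exactly k − 3 positive eigenvalues; their eigenvectors (ascending eigenvalue,
large-scale warps first) are the principal warps.

Partial warp scores project the Procrustes residuals onto each principal
warp separately in x and y (2(k−3) columns; 36 for the 21-point convention).
The uniform (affine) component is included by default as two extra columns,
computed against an orthonormal basis of the affine deformation space at the
consensus with the similarity fields (scaling (x, y) and rotation (−y, x))
projected out; a switch excludes it, since whether the original ordinations
included the uniform term is not recorded.

The relative warp analysis is the α = 0 (equal-weight) variant: an ordinary
PCA via eigendecomposition of the covariance of the column-centered score
matrix.  Because the warp basis is orthonormal, the non-uniform score PCA is
identical to a PCA of the residuals projected off the affine-plus-similarity
subspace — the package tests this equivalence directly.  Axis signs are fixed
by making each loading's largest-magnitude entry positive, so output is
reproducible across eigensolvers.  Axis significance is read against the
broken-stick expectation E(p_k) = (1/S) Σ_{i=k..S} 1/i.  `shape_along_axis`
maps loadings back through the warp/uniform bases to draw axis-extreme
outlines; it is linear in the score and returns the consensus at 0.

## Group tests

Goodall's F compares between- to within-group Procrustes sums of squares:

    F = [d²(x̄_a, x̄_b) / (1/n_a + 1/n_b)] /
        [(Σ d²(a_i, x̄_a) + Σ d²(b_j, x̄_b)) / (n_a + n_b − 2)]

with d the partial Procrustes distance and group means the re-normalized
coordinate-wise means after joint superimposition of the two groups.  Zero
within-group variation with distinct means returns +inf with a warning.
Significance comes from label permutations with the superimposition held
fixed; semi-landmark data have fewer free degrees of freedom than variables,
so parametric F reference distributions are avoided entirely.  The p
estimator counts the observed statistic in numerator and denominator
(p ≥ 1/(n_perm + 1)); when the number of distinct label splits is ≤ 10 000
the test switches to exhaustive enumeration (ties detected with a relative
1e-9 tolerance so analytically equal complement splits count).  Default
n_permutations = 1999.

Pairwise batteries re-superimpose each pair in isolation — matching the
behavior of the classic two-group tools — with a `global_superimposition`
flag for sensitivity analysis; singleton groups are skipped with a warning.
The shared significance level is base alpha (default 0.05) divided by the
number of pairs: 0.002 for 6 groups, 0.0018 for 8, 0.0011 for 10.

Angle comparisons use a tie-corrected (midrank) Kruskal–Wallis omnibus H and
mean-rank multiple comparisons: pair (i, j) is flagged when
|R̄_i − R̄_j| > z_{1−α′/2} √(N(N+1)/12 (1/n_i + 1/n_j)) with α′ shared across
pairs Bonferroni-style.  The reported per-pair p is the exact two-sided
rank-sum probability when the pair is small enough to enumerate, else the
normal approximation above; the significance decision always follows the
mean-rank criterion.

## Phylogenetic signal

Blomberg's K uses the Brownian tip covariance V (shared root-to-MRCA path
lengths): K = (MSE₀/MSE) / [(tr V − n/Σ V⁻¹) / (n − 1)], with MSE₀ the tip
variance about the phylogenetically weighted mean and MSE the GLS error.
K ≈ 1 under Brownian motion; phylogenetically unstructured traits give K
well below 1.  p-values come from tip-shuffling permutations (999 by
default, seeded).  For a score matrix the package reports per-axis K and p
plus a variance-weighted summary K whose p comes from shuffling tip labels
jointly across axes — one deliberate reading of "signal in a score matrix";
a single scalar K for a whole matrix has no canonical definition, and the
package does not attempt one.  The implementation agrees with the standard R
implementation (phytools::phylosig) to 12 decimals on shared fixtures.

## Synthetic data: what it emulates and what it does not

`generate_outlines` draws groups of 21-point outlines around archetype
shapes: `rounded` (elongate/rounded head, the parasagittal morphology) and
`reniform` (compressed, kidney-shaped head, the sprawling morphology), both
checked in as fixtures built from smooth parametric curves — deliberately not
traced from published figures.  Group mean offsets apply a smooth radial
bulge centered opposite the fixed landmark, scaled by root-finding so the
partial Procrustes distance between group means equals the requested δ
(default 0.08); specimens add isotropic Gaussian landmark noise in the raw
frame (default σ = 0.02, a digitization-error model) plus a random similarity
transform standing in for camera pose and magnification.  Default n = 20 per
group.  `generate_angles` draws per-group angles from Gaussians truncated to
(0, 180): sprawled mean 90° (the straight-radius anchor), parasagittal mean
75°, sd 5° — the 75/5 values are simulation settings chosen to give a curved
group clearly separated at moderate n, not measurements.
`generate_tree_and_traits` simulates pure-birth (Yule, rate 1) ultrametric
trees and evolves traits by Brownian motion along branches, or draws white
noise for the no-signal control.  All generators are pure functions of their
parameters and a seed.

The synthetic model is isotropic and independent across landmarks; real
outlines have correlated, anisotropic variation, taphonomic distortion and
digitization drift along the curve.  Passing tests therefore establish the
correctness and calibration of the machinery (exact null behavior,
parameter recovery, power at large offsets), not biological effect sizes.

Because the plug-in distance between estimated group means is inflated by
sampling noise (E d̂² = δ² + tr cov(x̄_a) + tr cov(x̄_b), about +0.009 under
the default generator), `estimate_group_offset` subtracts the within-group
SS/(n(n−1)) estimate of each trace and clips at zero; parameter-recovery
checks use this estimator.

## Numerical choices and degenerate inputs

* Convergence: GPA tol 1e-8 RMS, max 100 iterations; sliding 3 cycles.
* Duplicate landmarks make the TPS system singular and are rejected naming
  the offending pair; all-coincident configurations cannot be scaled and are
  rejected as degenerate.
* Exhaustive permutation switch at ≤ 10 000 splits; permutation p-values are
  bit-reproducible given (seed, n_permutations).
* Angle of curvature: interior angle at the proximal radial-head vertex via
  atan2(|cross|, dot) — orientation- and mirror-invariant, exact at 90° for
  perpendicular constructions.  The two published descriptions of the distal
  point ("lateral" in the text, "medial" in the figure caption) share the
  same vertex, which is all the computation uses.  `classify_curvature` uses
  a closed interval |angle − 90| ≤ tolerance with tolerance an explicit
  parameter (default 0); it is a reporting utility and never feeds the
  statistics.
* Problem sizes in the test and acceptance runs (e.g. 200-replicate
  calibrations at n = 5–20 per group, 64-tip trees) were chosen as the
  smallest sizes at which the binomial/simulation error bands are meaningful.

## Known limitations

* 2D outlines only; no 3D TPS, no asymmetry decomposition, no resistant-fit
  superimposition, and full (scale-varying) Procrustes is out of scope.
* The relative warp analysis offers only α = 0; the bending-energy-weighted
  variants are not implemented.
* Reproducing per-specimen published angles requires the original recorded
  tables; the three-point metric cannot be re-derived from outlines alone.
* The sliding criterion is minimum bending energy only; Procrustes-distance
  sliding is not offered.
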