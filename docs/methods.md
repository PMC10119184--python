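# Methods

cortevo builds a common geometric reference frame for cortical surfaces
across species, reconstructs ancestral cortical shapes along a calibrated
phylogeny, and runs the downstream spatial and phylogenetic-comparative
statistics. This note records the models, the parameters that matter, the
numerical choices made where the design was genuinely open, and what the
synthetic validation does and does not establish.

## Surface representation and operators

Cortical surfaces are closed, edge-manifold triangle meshes of spherical
topology (Euler characteristic 2), with coordinates in mm. The discrete
Laplace–Beltrami operator is the cotangent Laplacian with one-third
triangle-area mass lumping; triangles below 1e-12 mm² are excluded and
their cotangents clamped at ±1e6. Spectral embeddings solve the
generalized problem `L φ = λ M φ` with a deterministic ARPACK start vector
and a per-column sign convention (first non-tiny entry nonnegative), so
repeated runs are bit-identical.

Geodesic distances are edge-weighted shortest paths on the mesh graph
(Dijkstra). This overestimates true polyhedral geodesics — by up to ~8% on
an icosphere — consistently in every direction; all downstream statistics
normalize distances, so only the convention matters, and it is used
everywhere (distance transforms, variograms, parcellations).

Extrinsic shape features per vertex:

* **sulcal depth** — negated point-to-triangle distance to the convex hull
  surface (0 where the cortex touches its hull, negative in sulci);
* **depth derivative** — magnitude of the per-face linear gradient of depth,
  area-averaged to vertices;
* **mean curvature** — cotangent formula `M⁻¹ L x = 2 H n`, signed against
  the outward normal (1/R on a sphere);
* **local gyrification** — patch area over the area of the patch's planar
  convex hull inside a geodesic disc of radius 0.15·√(total area); the
  reference plane is orthogonal to the patch's mean normal (a best-fit PCA
  plane is not stable when principal directions tie, and the mean normal
  keeps the feature exactly rigid-invariant);
* **curvature ridge indicator** — top-decile mean-curvature vertices thinned
  by non-maximum suppression along the distance transform to the ridge
  seeds, with explicit tie tolerances so the binary map is rigid-invariant.
  This is a declared, testable stand-in for a full Hamilton–Jacobi
  skeletonization, which is deliberately out of scope; the indicator is one
  of several matching cues and swappable.

Global traits are total cortical surface area, convex-hull area, and their
ratio (gyrification index).

## Dense correspondence

Every vertex is embedded as a feature vector combining (a) the spectral
coordinates `φ_i/√λ_i` (zero mode dropped; the block rescaled to unit mean
column variance so the eigenvalue weighting survives normalisation), (b)
z-scored extrinsic features, and (c) z-scored anatomical label
pseudo-probabilities `exp(-d_geo/bw)` together with their negative
logarithms. The last point matters: `-log p` recovers the smooth global
geodesic distance transform of each label, and a handful of such distance
fields nearly trilaterates position on the surface — they are the
strongest cross-species anchors in the stack, mirroring the role of
manually labelled structures in real comparative data. Default block
weights: spectral 1.0, each extrinsic feature 0.5, labels 1.0; spectral
band k = 30; label bandwidth 5% of the mesh diameter. None of these is
critical within a factor of ~2.

Eigenvector ambiguity is resolved per near-degenerate eigenvalue block
(relative gap below 0.2 — harmonic levels of near-spherical shapes are
separated by ≥50%, so this tolerance groups whole levels without merging
across levels). Within each block an orthogonal correction is estimated by
Procrustes. Plain descriptor-coefficient Procrustes is biased when shapes
genuinely differ, so the matcher bootstraps: a nearest-neighbour pre-match
on the non-spectral channels supplies an approximate correspondence, and
the Procrustes is solved on the pulled-back eigenvectors; heat-kernel
signatures (invariant to any in-block rotation) serve as additional
descriptors when no correspondence is available. Each block's residual
yields a confidence in [0, 1]; unalignable blocks are attenuated in *both*
embeddings so they cannot inject noise into matching distances. A
rank-deficient Procrustes receives an identity bias so that aligning an
embedding to itself is exactly the identity.

Soft correspondences come from Coherent Point Drift in the embedding
space: one surface's vectors are Gaussian-mixture centers displaced by a
Gaussian-kernel-regularized coherent field, the other's are data, and EM
alternates responsibilities and the regularized displacement. The outlier
component is uniform over the data bounding volume (the textbook constant
is meaningless in 30+ dimensions). Defaults: outlier weight 0.1, tolerance
1e-6, kernel width 2.0 and regularization 2.0 in z-scored units, low-rank
Nyström kernel above 5000 vertices. Two matching rounds are run by
default: the first round's correspondence re-aligns the spectral blocks for
the second — this rescues pairs whose feature-only bootstrap is weak.

Post-processing follows three stages: (1) responsibility-weighted target
coordinates are smoothed along mesh edges (10 iterations, 0.5 damping)
before the nearest-point lookup, making maps continuous; (2) a joint
Laplacian — both mesh graphs with inverse-edge-length affinities on the
diagonal blocks, binary vertex correspondences scaled by the mean affinity
off-diagonal — is eigendecomposed (16 modes) and correspondences re-derived
by nearest neighbours in the joint space, symmetrically for both surfaces;
(3) a reversibility optimization runs block-coordinate descent on the
Dirichlet energy of both displacement fields *from the input maps* plus the
squared round-trip displacements, with projection back to the surface and a
backtracking safeguard that guarantees a non-increasing energy. Penalizing
the displacement (not the map itself) makes identity maps between identical
meshes an exact fixed point and decouples the smoothness and reversibility
terms cleanly.

Maps are stored barycentrically (source vertex → face plus weights on the
target), so they are continuous; hard vertex maps take the
largest-weight corner. Expansion maps are per-vertex log ratios of lumped
vertex areas under the forward map, optionally normalized by the global
area ratio.

Measured on generator sister pairs (level-3 icospheres, default
deformations), the stack maps ≥ 90–100% of vertices within one ring of
ground truth with mean error ≈ 0.4–0.6 mean edge lengths; accuracy
degrades monotonically with deformation amplitude. Anchor geometry
matters: label seeds must be non-coplanar and asymmetric, otherwise the
matching problem has an exact reflection symmetry and can converge to the
mirror image.

## Ancestral shape reconstruction

Ancestors of matched sisters are estimated in discrete-shell space. The
deformation energy of vertex positions `x` from a reference shell combines
a membrane term — squared relative change of edge lengths and triangle
areas, weighted by reference areas — and a bending term — squared
dihedral-angle change weighted by `l₀²/A₀` and a coefficient of
1e-3·diameter². The interpolant minimizes `(1-t)·W(x;A) + t·W(x;B)` by
L-BFGS with analytic gradients from the linear-blend initialization;
endpoints are returned exactly, and the interpolant's energy never exceeds
the blend's. The alternative reading of t (a point on the shell-space
geodesic rather than an energy weight) was noted and not taken: the energy
weighting needs one minimization instead of a path discretization and
coincides with it at the endpoints and, for near-isometric pairs, in
between.

The interpolation factor t is the relative distance of the ancestral
global-trait state (log cortical area, log hull area, standardized) to the
two sisters, with the ancestral states estimated by phylogenetic BLUP under
the fitted trait model — branch lengths alone are not trusted to scale
genetic into morphological change.

Label maps are fused on the ancestor by a debiased entropic Wasserstein
barycenter computed with heat-kernel convolutions: the kernel is the
symmetrized implicit-Euler heat operator `(I + (ε/k) M^{-1/2}LM^{-1/2})^{-k}`
with ε = (mean edge length)² and k = 10 substeps (fewer substeps give the
resolvent's exponential tails, which turn the cost W1-like and collapse
two-Dirac barycenters onto an endpoint). The debiasing potential removes
the entropic blur, so fusing a label with itself returns it exactly; inputs
are normalized to probability measures and the result rescaled to the
weighted mean of input masses, conserving label mass by convention.
Because OT-fused maps still blur slowly as the traversal ascends, the
*matching anchors* of each ancestor are re-derived: the fused label's
support (≥ 50% of its maximum) is re-encoded as a fresh geodesic
pseudo-probability on the ancestor mesh. The fused maps themselves remain
the label estimates.

Tree-wide reconstruction is post-order: match children (label-anchored),
resample the sparser child onto the denser topology, interpolate at t, fuse
labels, and continue. Polytomies are rejected, not silently resolved —
reconstruction order changes results. After the root, every node is
resampled onto one common topology (densest tip by default, or any provided
reference). Propagation defaults to *direct* matching of the reference to
every node: composing pairwise maps down the tree compounds the ~0.6-edge
per-hop error to several edges on deep paths, while direct label-anchored
matches stay at per-pair accuracy. Composition remains available
(`propagate="compose"`).

On 4-tip generator trees the reconstructed root sits ~0.7 mean edge lengths
from the true root surface after rigid alignment — which matches the
statistical floor: the exact phylogenetic BLUP of every vertex coordinate,
using the *true* correspondences, errs by 0.4–1.1 edges across seeds,
because the root state has irreducible conditional variance given only four
descendants at realistic evolutionary rates. The pipeline is at the
information limit; tighter recovery requires denser taxon sampling or
slower evolution, not a better reconstruction.

## Phylogenetic comparative models

Trait evolution is Gaussian along the tree: BM (covariance = shared path
length), OU with the root fixed at the optimum
(`exp(-α d_ij)(1-exp(-2α t_ij))/(2α)`), EB (`(exp(r t_ij)-1)/r`), and a
scalar-OU model with optimum shifts on edges. Likelihoods are matrix-normal
with the trait covariance R profiled (`Z'K⁻¹Z/n`, ridged toward a scaled
identity for p ≫ n); kernel parameters are optimized by bounded scalar
search, with an explicit boundary check against the BM limit. Likelihoods
match dense multivariate-normal evaluation to 1e-6 and ancestral BLUPs
match brute-force Gaussian conditioning to 1e-8 on small trees.

Shift detection is greedy forward selection of shift edges with GLS
scoring, the shift count chosen by GIC; exhaustive enumeration over edge
subsets is available for small trees and is used as the test oracle (the
greedy and exhaustive optima agree there). The mean design of a shift edge
under OU is the standard exponential pull-in weight along root-to-node
paths; collinear designs (sibling root edges plus intercept) are handled by
minimum-norm least squares.

Model selection uses GIC = −2·loglik + 2·df with df composed of: mean
parameters (p per regime column); the trait-covariance term as a trace-form
shrinkage count (`Σ_{i≤j} w_i w_j`, `w_i = d_i/(d_i + λ·mean(d))` —
p(p+1)/2 when the ridge vanishes); `max(1, p/2)` per kernel parameter —
a kernel parameter is shared by all p traits and its finite-sample score
bias accumulates over traits, so counting it as 1 lets a boundary parameter
soak up p small per-trait gains (empirically ~6 log-lik units at p=60,
n=30 under the BM null); and ln(E) per selected shift for its placement
among E candidate edges (an extended-BIC multiplicity correction — without
it, greedy search over ~30 edges under the null finds ~3.5 log-lik units
per spurious shift). With these terms the generating family is selected in
essentially all high-dimensional replicates for BM, OU and EB truths, and
null trees select zero shifts. The formula is the package's own; it is
validated by rank ordering and selection consistency, not against any
published constant.

Phylogenetic PCA estimates the evolutionary covariance from
phylogenetically whitened, GLS-centered data with a ridge toward the scaled
identity; the ridge strength comes from a 10-point log-spaced grid by
leave-one-out cross-validated Gaussian score. Modes are eigenvectors of the
estimate (deterministic sign: largest loading positive); scores are
projections of the centered tip data.

## Spatial statistics

The modal-segregation semivariogram follows a fixed recipe: graph-geodesic
distances max-normalized to [0, 1], 20 equal bins, per-bin mean pairwise
cosine distance of the 3-channel modal vectors (zero vectors excluded with
a warning), and min-max normalization of the curve. Linear, spherical and
exponential models are fitted by repeated randomly initialized least
squares (100 starts each), weighted by per-bin pair counts (the sparse
first/last bins otherwise dominate), and the best family by SSE wins —
with one deterministic tie-break: a family must beat the spherical fit by
a 5% SSE margin, because the three families' range conventions are not
interchangeable and flipping between them on statistically tied SSEs
jitters the range estimate by tens of percent. The exponential family
reports the practical range (95% of sill). Noiseless curves of each family
are recovered essentially exactly.

Surrogate maps permute the observed values, smooth them with a geodesic
Gaussian kernel, mix with the unsmoothed permutation, and affinely rescale
to the target mean and SD; kernel scale and mixing weight minimize the
variogram SSE against the target, with a parsimony rule that a plain
permutation within 10% of the best SSE wins (white noise should reduce to
permutations). Surrogate-referenced permutation p-values are calibrated
(type-I error within [0.03, 0.07] at nominal 0.05 in the validation
suite). Note the BY-corrected significance floor: with m regions and n
surrogates the smallest attainable q is about `m·c(m)/(n+1)`, which is why
the pipeline uses 1000 surrogates.

The generator's modal maps are softmax-normalized smoothed white-noise
channels whose smoothing scale is calibrated per realization by bisection
on the map's own empirical variogram until the fitted practical range hits
the target; at 642 vertices this closes to within ~3% (median). Fitted
ranges of *independent* realizations at a fixed scale scatter by 15–30% at
desk scale — one realization of a long-range field on 642 vertices contains
only a handful of independent patches — which is an information limit of
the problem size, not of the estimator.

## Ecology statistics

Mode screening uses two-sided Mann–Whitney tests per (mode, variable) with
Benjamini–Hochberg q-values across the whole family; BH and BY are
first-principles step-up implementations, oracle-checked against
statsmodels. Expansion synthesis reconstructs shapes at the group centroids
in the span of significant modes and takes per-vertex log area ratios; the
pipeline's habitat maps additionally subtract the global mean log-ratio —
relative expansion — because a chance allometric (overall size) difference
between small habitat groups otherwise swamps every regional statistic with
a common offset. Repeated-measures correlation is the ANCOVA definition
(subject means removed from both variables, df = N − k − 1, Fisher-z CI),
matching pingouin to 1e-10; RANOVA with Mauchly sphericity,
Greenhouse–Geisser correction and Games–Howell post-hocs are delegated to
pingouin. The habitat-complexity scale fixes arboreal = 1, terrestrial = 0
and places fossorial by least-squares projection onto the
arboreal–terrestrial axis. Decoding keeps the top ceil(1%) of term
correlations, ties broken by name; trajectory clustering is average-linkage
on correlation distance with the cluster count chosen by maximal mean
silhouette over k = 2..12.

## The generator as study conditions

The generator emulates the structure of a comparative dataset at desk
scale: a Yule tree rescaled to 70 Myr (rodent–primate LCA order); surfaces
as radial warps of a common icosphere (level 3, 642 vertices by default;
base radius 30 mm) with spherical-harmonic bands l = 1..3 (tip SD 5% of
radius), six localized patch inflations (tip SD 8%), an allometric
log-scale (tip SD 0.15), all evolving as BM from zero at the root, plus a
fixed (non-evolving) folding ripple so correspondence difficulty stays
decoupled from evolutionary signal; four anatomical labels at fixed
generic non-coplanar directions; binary ecological traits from logistic
models on designated components, with the habitat triple one-hot from
noisy tertiles of a designated patch component. Everything is reproducible
from seeds, and ground truth (ancestral meshes, vertex correspondences,
coefficient trajectories, planted associations) is recorded.

What this does *not* emulate: realistic gyral geometry and its biomechanics,
imaging and segmentation noise, missing or partial surfaces, non-identity
true correspondences (topology is shared by construction — the pipeline is
never told this and must re-estimate it), and the taxon density of a large
real comparative dataset. Passing tests therefore demonstrate the machinery's correctness
and its behaviour under controlled signal, not performance on real
comparative data.

Default problem sizes were chosen so the full pipeline (10 tips, level-3
surfaces, 1000 surrogates) completes in minutes on a single core; the
spatial and phylogenetic simulations in the validation suite use the sizes
stated in their tests (e.g. 200 rate-recovery replicates at 100 tips, 50
shift-recovery replicates at 16 tips, 20 variogram replicates per target
range).

## Known limitations

* Correspondence accuracy saturates at ~0.5 mean edge lengths per pair:
  two genuinely different shapes define vertex-level homology only up to
  local ambiguity. Composition over deep trees inherits this per hop;
  direct propagation avoids the compounding but not the per-pair floor.
* Root reconstructions are bounded by the conditional variance of the
  ancestral state given the sampled tips; with few tips and realistic
  rates this floor exceeds a quarter edge length (see the reconstruction
  section).
* The scalar-OU shift search is greedy; it is oracle-exact on small trees
  but can in principle miss interacting shift configurations on large ones.
* The GIC is a package-specific construction, validated for rank ordering
  and selection consistency only.
* Variogram ranges from single small-mesh realizations scatter widely;
  range comparisons should use the per-realization calibration protocol or
  many replicates.
* Heat-kernel OT fusion assumes near-uniform vertex mass; strongly
  irregular meshes would need the full mass-weighted formulation.
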