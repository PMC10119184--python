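# cortevo

Phylogenetic comparative analysis of cortical surface geometry.

Comparative neuroscience needs a common spatial reference frame before the
cortices of different species can be compared point by point — but across
mammals there are no shared landmarks, cortical areas appear, vanish and
move, and sizes span orders of magnitude. cortevo builds that frame and the
analyses on top of it:

* **Dense cross-species correspondence** — every vertex is embedded by the
  spectral coordinates of the cotangent Laplace–Beltrami operator
  (`L φ = λ M φ`, scaled `φ_i/√λ_i`) combined with extrinsic folding
  descriptors (sulcal depth, curvature, local gyrification) and anatomical
  label pseudo-probabilities `exp(-d_geo/bw)`; surfaces are matched by
  Coherent Point Drift (an EM fit of a coherently displaced Gaussian
  mixture) and refined through edge smoothing, a joint-Laplacian embedding
  and a smoothness + reversibility optimization.
* **Ancestral shape reconstruction** — matched sister shapes are averaged in
  the space of discrete shells, minimizing
  `(1-t)·W(x; A) + t·W(x; B)` with membrane (edge/area strain) and bending
  (dihedral) terms; the factor `t` comes from phylogenetic ancestral states
  of the global traits (log cortical area, log hull area), and label maps
  are merged with heat-kernel Wasserstein barycenters. Iterated to the root
  of the tree, then everything is resampled onto one common topology.
* **Trait-evolution models** — BM, OU, early-burst and scalar-OU with
  automatically detected optimum shifts, fitted by phylogenetic GLS;
  model selection by a Generalized Information Criterion valid for
  ridge-penalized p ≫ n fits; ancestral states by BLUP; L2-regularized
  phylogenetic PCA.
* **Spatial statistics** — 20-bin cosine-distance semivariograms of modal
  specificity with linear/spherical/exponential fits (sill and range), and
  spatial-autocorrelation-matched surrogate maps for permutation inference.
* **Ecology associations** — rank-sum mode screening with BH/BY FDR,
  expansion-map synthesis, surrogate-referenced parcel tests,
  repeated-measures correlation along a habitat-complexity ordering, term
  decoding and trajectory clustering.

A ground-truth generator (`cortevo.synth`) produces complete synthetic
datasets — calibrated trees, surfaces evolving as Brownian deformations of
an icosphere, modal maps with a controlled spatial range, ecology tables
with planted effects — and records the true ancestors, correspondences and
associations, so every stage is validated against known truth.

## Worked example

`examples/01_match_surfaces.py` generates two sister species (deformed
icospheres, 642 vertices, 70 Myr apart) and recovers their vertex
correspondence:

```
$ python examples/01_match_surfaces.py
vertices matched within one ring of truth: 100.0%
mean map error: 0.16 mean edge lengths
```

Both surfaces are warps of one icosphere, so vertex i of one truly
corresponds to vertex i of the other; the stack re-estimates that map from
geometry and label fields alone, and here places every vertex within one
ring of the true target, with a mean residual of about a sixth of an edge
length.

The other examples reconstruct ancestors along a 4-tip tree
(`02_reconstruct_ancestors.py`), fit variograms and surrogates
(`03_variogram_and_surrogates.py`), fit and select trait-evolution models
(`04_phylo_models.py`), and run the full pipeline
(`05_full_pipeline.py`). The pipeline is also available as one call:

```python
from cortevo.pipeline import PipelineConfig, run_pipeline
manifest = run_pipeline(PipelineConfig(out_dir="run", seed=1))
```

which simulates a dataset, matches and reconstructs all ancestors, fits
the evolutionary models and pPCA, fits modal variograms, and runs the
ecology statistics, writing meshes, tables and a reproducibility manifest
into the run directory.

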