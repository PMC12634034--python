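# Methods

## Model and assumptions

`ksrv` infers RNA velocity for spatial transcriptomics spots that measure
only total expression, by transferring spliced/unspliced abundance from a
reference scRNA-seq dataset of the same tissue. The method assumes:

* the two modalities share a common set of gene identifiers (exact string
  match after whitespace stripping; no alias resolution), and the biological
  state space sampled by the reference covers the states present in the
  tissue — spots are expressed as convex combinations of reference cells,
  so states absent from the reference cannot be imputed;
* splicing kinetics follow the two-stage linear ODE
  `du/dt = α − β·u`, `ds/dt = β·u − γ·s` with gene-wise constant rates.
  Only the ratio γ/β is identifiable from (u, s) snapshots, so β is scaled
  to 1 and the reported γ is the degradation/splicing ratio;
* cells at extreme spliced abundance sit near the steady-state line
  u = γ·s (the standard steady-state velocity model). Transient genes that
  never approach equilibrium violate this and get biased γ.

### Integration

Each modality is library-size normalized (per-observation scaling to the
dataset's median total count, layers scaled by the same factor so u:s ratios
are preserved), log1p-transformed, and embedded by kernel PCA on the shared
gene panel: the RBF kernel `exp(−γ_k‖x−x′‖²)` with γ_k = 1/n_shared_genes
(the conventional default), double-centered before the eigendecomposition
(without centering the leading eigenvector only encodes the kernel row
means). Kernel components live in modality-specific sample spaces, so each
component is given a gene-space surrogate direction — the unit-normalized
back-projection Xᵀα of its dual vector; gene space is the only coordinate
system the two modalities share. With a linear kernel these surrogates are
exactly the classical PCA loadings and the whole stage reproduces
PCA-based principal-vector alignment, which serves as the stage's oracle in
the tests.

Alignment takes the SVD of the loading cross-product PᵀQ; the singular
values are the cosine similarities of the aligned direction pairs (exactly
the cosines of principal angles when columns are orthonormal, as in the
linear case; values are clipped to [0, 1] otherwise). Pairs with similarity
above the threshold (default 0.3) are retained and both column-mean-centered
expression matrices are projected onto the reference-side aligned basis.
Per-component signs are fixed (largest-magnitude loading entry positive) so
results are deterministic across linear-algebra backends.

### Imputation

Each spot takes its k = 50 nearest reference cells by cosine distance in the
aligned space (ties by ascending reference index). Weights
`a_ij = 1 − d_ij/Σd`, `a*_ij = a_ij/(k−1)` are non-negative for k ≥ 2 and
sum to one per spot as an algebraic identity; all-zero-distance
neighborhoods take uniform weights (the continuity limit), and k = 1 is the
trivial weight 1 (needed for exact self-recovery). Imputation covers **all**
reference genes, not only the shared panel — the panel anchors the latent
space, the transfer is what makes unmeasured genes available. Label scores
sum the weights per cell type; ties resolve to the lexicographically
smallest type.

### Velocity

γ per gene is the zero-intercept least-squares slope of u on s restricted to
the bottom+top `quantile` (default 0.05) of s. Genes with fewer than 10
nonzero spliced values, zero spliced variance, or a non-positive slope are
masked invalid with zero velocity. The transition graph uses 30
expression-space neighbors (PCA-reduced to 30 dimensions above 500 genes;
deterministic full SVD), edge weight ∝ exp(cos(v_i, S_j − S_i)/σ) with
σ = 0.05, restricted to positive cosines; zero-velocity observations get
uniform outgoing rows. The 2-D projection is the transition-expected
displacement minus the uniform expectation over the same neighborhood, with
unit-normalized displacement vectors (so dense and sparse regions
contribute comparably); tissue coordinates are the intended embedding. A
pseudotime substitute orders observations by diffusion arrival from a root
(default: minimal incoming transition mass), min-max normalized per weakly
connected component — a deliberately simple stand-in for model-based latent
time, adequate for ordering but not for absolute timing.

### Evaluation and spatiotemporal analytics

The similarity score between velocity fields is `Σ β_i·CS_i` with β the
normalized reference-field magnitudes — ground-truth weighting, so that
large true movements dominate; a flag switches to estimated-field weighting
for sensitivity analysis. Zero vectors contribute cosine 0. The score is
computed as `Σ(M·CS)/ΣM`, which keeps the self-comparison identity exact in
floating point.

Distance analytics use the Euclidean distance from a configurable origin
(default (0, 0), the literal definition; `centroid` is available because
real tissues rarely place a meaningful origin at the coordinate zero).
Pseudotime is divided into ten equal-width bins (left-closed, last bin
closed); per bin the population variance (1/n, not the n−1 estimator) and
linear-interpolation 10th/90th percentiles of distance are computed, bins
with fewer than two observations are dropped, and cubic polynomials of the
bin-median times are fitted by least squares.

ω per cell type minimizes `Σ(ωT + (1−ω)D − Y)²` in closed form
(`ω* = Σ(T−D)(Y−D)/Σ(T−D)²`, clipped to [0, 1]), with T, D and Y each
min-max rescaled to [0, 1] beforehand — the linear combination mixes
incommensurable units otherwise. Y is the mean of strictly positive entries
of each spot's (normalized) expression row. A type where T and D coincide
everywhere has no identifiable ω and is reported missing rather than
defaulted.

## Parameter defaults

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| similarity threshold | 0.3 | cosine | retention cut for aligned components |
| k (neighbors) | 50 | cells | transfer neighborhood size |
| kernel γ_k | 1/n_genes | 1/expr² | conventional RBF width |
| n_components | min(50, n_obs−1) | — | standard single-cell latent size |
| steady-state quantile | 0.05 | fraction | extreme-abundance anchor set |
| graph neighbors | 30 | cells | velocity-graph kNN |
| σ (softmax scale) | 0.05 | cosine | transition sharpness |
| n_bins | 10 | — | pseudotime intervals |
| origin | (0, 0) | coords | distance reference point |

## Synthetic data generator

The generator is the package's test bed: per gene it draws α ∈ [2, 8],
γ ∈ [0.3, 1.5], β = 1 and one switch time ∈ [0.4, 0.8] (fractions of the
trajectory); cells get uniform pseudotimes on [0, 1] mapped to ODE time
t·t_max with t_max = 20, so induction phases reach their fixed point even
for slow genes. u(t), s(t) come from the exact closed-form ODE solution
(induction from the origin, then repression from the switch state; the
γ = β case uses the analytic limit), verified against a fine-step numerical
integrator. Gaussian noise (sd 0.1) is added and clipped at zero; the true
velocity β·u − γ·s is recorded pre-noise. The default paired regime — 500
reference cells × 200 genes, 300 spots on a random 60-gene panel, three
time-tercile cell types, spot x-coordinate tracking time (sd 0.05) — is the
benchmark configuration used by the end-to-end tests; these sizes keep the
full suite in seconds on one core while leaving every stage's signal
clearly above its acceptance margin.

What the simulator does **not** emulate: negative-binomial count noise and
dropout, batch effects beyond what separate draws induce, doublets,
spatially structured gene programs independent of pseudotime, or
multi-lineage branching. Passing tests therefore demonstrate correctness of
the algorithms under the stated kinetic model, not robustness to the full
noise structure of real Visium/MERFISH data.

## Numerical conventions

* Eigenvalues below max·1e-9 are treated as zero; kernels are symmetrized
  before `eigh`; similarity singular values clipped to [0, 1] at 1e-12.
* Neighbor ties → ascending reference index; label ties → lexicographic;
  pseudotime ties → arrival mass, then index. No operation permutes
  observation order.
* Matrices are stored sparse below 50% density; every operation accepts
  both layouts.
* All randomness flows from a single seeded generator per simulation; the
  pipeline itself is deterministic given its inputs, and metrics JSON is
  rendered with sorted keys and fixed precision so repeated runs are
  byte-identical.

## Limitations

* The steady-state estimator is the only velocity mode; dynamical-model
  fitting (EM over latent time) is out of scope, so genes far from
  equilibrium get biased γ.
* Kernel components have no exact pre-image; the gene-space surrogate
  loadings used for alignment are an approximation that is exact only in
  the linear-kernel case.
* Spots are treated as single cells; no deconvolution of multi-cell spots.
* The diffusion pseudotime substitute orders states along the transition
  graph; it is not calibrated biological time.
* 2-D projection can fabricate arrows pointing at whatever neighbors exist
  in the embedding — a known artifact of all velocity embedding projections,
  mitigated but not removed by the uniform-expectation correction.
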