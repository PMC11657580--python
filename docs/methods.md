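# Methods

## Model

A shape collection `S` is a set of closed orientable triangle meshes, one
per subject and side. Each surface carries the regularized isophotic metric

    g_ω = I + ω·III,   ω ≥ 0,

with `I` the first fundamental form and `III` the third (the pullback of
the round metric under the Gauss map). `III` measures normal variation —
extrinsic curvature — so ω interpolates between purely intrinsic geometry
(ω = 0) and a metric that also sees how the surface bends in space. Since
`III` is scale-invariant while `I` scales quadratically, ω is parameterized
as ω = α·ℓ² with ℓ the bounding-box diagonal, making α dimensionless.

Correspondence between surfaces is functional: a map `F : X_M → X_N`
between truncated Laplace–Beltrami eigenspaces, encoded by a matrix `C`
acting on basis coefficients. Pointwise maps induce functional maps by
pullback and are recovered from them by nearest neighbors in the spectral
embedding; ZoomOut alternates the two conversions while growing the basis
dimension by one per step. Over the collection, a functional-map network is
built on all pairs, pruned to the symmetrized k-nearest-neighbor graph
under the 2-cycle consistency score `|C_NM C_MN − I|_F` with the smallest k
that keeps the graph connected, and a consistent latent basis (CLB) is
computed as the minimizer of `Σ_edges |C_MN Y_M − Y_N|²_F` under the
stacked orthonormality constraint — the smallest eigenvectors of the
network's quadratic form. Consistent ZoomOut alternates this latent-basis
computation with a per-edge refinement through the latent embedding while
growing dimensions on a fixed schedule.

Shape differences are Gram matrices of two inner products evaluated on the
latent functions realized on each mesh: the area-based L² product and the
conformal (Dirichlet) product on zero-mean functions, both with respect to
g_ω. Equality of the first across a correspondence characterizes locally
area-preserving maps, of the second conformal maps; both together,
isometry. The SPD matrices are linearized Log-Euclideanly (matrix
logarithm, lower-triangle vectorization, unit 2-norm) as node features, and
Log-Euclidean distances between them drive an RBF similarity kernel with
median bandwidth. The population graph multiplies that kernel by a binary
phenotype gate (sex and ApoE genotype must coincide, and one subject must
be among the 30 nearest neighbors of the other). A three-layer Chebyshev
GCN (order K = 2, hidden widths 64/64, ReLU, dropout, softmax output)
classifies all nodes transductively, trained with cross-entropy on the
labeled nodes only; performance is the mean over repeated stratified 70/30
Monte Carlo splits with full retraining per draw.

## Discretizations and numerical choices

**Isophotic operators.** Every vertex `v` with unit normal `n(v)` is lifted
to `(v, √ω·n(v)) ∈ R⁶`; the pullback metric of this embedding is exactly
`I + ω·III`. Edge lengths between lifted vertices feed the intrinsic
cotangent formula (law of cosines for the angles, Heron for areas), so the
construction degenerates bit-for-bit to the standard weighted cotangent
scheme at ω = 0, and all triangle inequalities hold automatically because
lifted lengths are genuine Euclidean distances. Mass is barycentric-lumped
(area/3 per corner): diagonal and unconditionally positive definite.
Normals are area-weighted vertex normals. Degenerate (zero-metric-area)
faces raise; a nonpositive cotangent denominator (not reachable through the
lift, kept as a guard) is clamped to zero with a warning.

**Eigenbasis.** Generalized eigenpairs `W φ = λ A φ` by shift-invert
Lanczos (shift −10⁻³), re-orthonormalized in the mass inner product via a
Cholesky correction, eigenvalues ascending, sign fixed by making the first
entry of significant magnitude (> 10⁻⁸ of the column max) positive.
Eigenvalues in (−10⁻⁸·λ_max, 0) are clamped to zero. The eigenbasis is
always computed at ω = 0; ω enters only the descriptor-stage inner
products. This keeps α sweeps cheap (maps and latent bases are reused) and
reflects that the correspondence machinery operates on the standard
cotangent operator.

**Landmarks and registration.** Landmark initialization rigidly aligns the
second mesh to the first — PCA pre-alignment over the four
sign-disambiguated proper rotations plus the identity, selected by
nearest-neighbor residual, followed by rigid coherent point drift (EM with
closed-form rigid M-step, 40 iterations) on farthest-point subsamples of
300 points; plain ICP is the fallback. Landmarks are farthest-point samples
on the first mesh paired with nearest aligned vertices. The functional map
is the ridge-regularized (λ = 10⁻⁸) least-squares fit of landmark basis
rows. Rigid registration is intrinsically ambiguous for shapes with
extrinsic (near-)symmetries: the mirror alignment of two mirror-isometric
shapes is the better rigid fit, and maps built on it pass every pairwise
consistency check (the flip is an involution). For collections constructed
or acquired in a common coordinate frame the registration method `"none"`
trusts the given pose; the sphere-dome experiments use it, cohort pipelines
default to CPD.

**ZoomOut and Consistent ZoomOut.** Pointwise conversion uses exact
brute-force nearest neighbors below 5000 vertices (ties to the smallest
index) and a k-d tree above. Consistent ZoomOut starts from the leading
`8×8` blocks, performs 20 steps growing the spectral dimension by 1 and a
real-valued latent accumulator by 7/10 per step (instantiated size =
floor of the accumulator, with a 10⁻⁹ guard against float drift), ending at
spectral dimension 28 and latent dimension 22. The output records the
residual of a latent basis computed at the same final dimensions from the
unrefined maps (`init_residual`); the refined residual never exceeds it.
Residuals at different latent sizes are not comparable (the objective grows
with the number of columns), which is why the baseline is evaluated at
matched dimensions.

**Descriptors.** Latent functions are realized on the mesh (`F = Φ Y`),
the conformal descriptor first projects them to zero mean against the
ω-density. Gram matrices are symmetrized and floored spectrally at
ε = 10⁻⁸ relative to max(1, λ_max) so the matrix logarithm is defined (the
conformal Gram is only semidefinite: constants lie in the kernel). An
exactly zero logarithm yields the zero feature vector (the unit-norm rule
is undefined there and an identity descriptor carries no information).
Multi-descriptor and multi-side features concatenate per-block unit-norm
vectors without re-normalization; pairwise distances combine per-block
Log-Euclidean distances as the Frobenius distance of the block-diagonal
logarithms (root sum of squares). The similarity kernel uses these raw
Log-Euclidean distances, not the normalized feature vectors.

**GCN.** A self-contained dense implementation: Chebyshev polynomials of
the rescaled normalized Laplacian `2L/λ_max − I` by the three-term
recurrence, analytic backpropagation, Adam (lr 10⁻², weight decay 5·10⁻⁴ on
weights only, dropout 0.5 on hidden activations, 200 epochs, no early
stopping), Glorot-style initialization, all randomness from one seeded
generator. λ_max is the exact top eigenvalue of L via a dense symmetric
eigensolver — population graphs have at most a few hundred nodes, and the
exact value keeps the Chebyshev domain `[−1, 1]` tight; the common
λ_max := 2 shortcut is a config option. Zero-degree nodes use
`D^{-1/2} := 0`; an entirely empty graph takes λ_max := 1, reducing the
convolution to its self-term. The k-NN parameter of the phenotype gate is
clipped to n − 1 on cohorts smaller than the default 30. Stratified splits
take floor(fraction·class size) per class and assign remainders by largest
fractional part; undefined metric ratios (zero denominators) are reported
as NaN with a warning and excluded from summary means.

## Parameter defaults

| parameter | default | meaning |
|---|---|---|
| `k_eigen` | 42 | Laplace–Beltrami basis size per shape |
| `landmark_count` | 130 | approximate landmarks for map initialization |
| `fmap_init_dim` | 30 | initial functional-map size |
| `zoomout_steps` | 12 | pairwise spectral upsampling steps (30 → 42) |
| `clb_init_dim` / `clb_steps` | 8 / 20 | network refinement 8 → 28 dims |
| `clb_latent_step` | 7/10 | latent growth per step (final size 22) |
| `alpha` | 2⁻⁶ | blending weight ω = α·ℓ² |
| `knn` | 30 | phenotype-gate neighborhood |
| `cv_draws` / `train_fraction` | 100 / 0.7 | Monte Carlo cross-validation |
| GCN | K=2, 64/64, lr 10⁻², wd 5·10⁻⁴, dropout 0.5, 200 epochs | training |

`PipelineConfig.desk()` is the scaled configuration used for the synthetic
studies in the tests and the acceptance script, sized for meshes of a few
hundred vertices: basis 24, maps 10 → 16 (6 ZoomOut steps), 60 landmarks,
network refinement 6 → 14 with latent size 11, 25 cross-validation draws.
Problem sizes there — cohorts of n = 60 subjects, one side, ~200-vertex
meshes — are the package's own choice of desk-scale study conditions.

## What the synthetic data does and does not emulate

The cohort generator produces ellipsoidal blobs (axes 1 : 0.85 : 0.75) from
a latitude/longitude sphere template with a vertex ring snapped onto the
dome cutting plane, per-subject band-limited spherical-harmonic noise
(degrees 2–4, RMS amplitude 0.015 of the unit radius) displaced along
vertex normals, a class-dependent deformation, optional genus-1 handles
(two distant faces removed and bridged by a six-triangle tube, mimicking
segmentation artifacts), mirrored left sides with independent noise, and
ApoE genotypes whose E4 frequency is elevated in the diseased class
(association 0.5: 65% vs 30%; sex is uninformative by construction). The
`bump` effect is an inward radial atrophy with Gaussian angular profile
(std 0.55 rad) — it changes intrinsic and extrinsic geometry and emulates
localized volume loss. The `bend` effect mirrors the dome above the plane
`z = 1 − 2·effect_size`: an exact Euclidean reflection, hence an isometry
of the template — intrinsic geometry is preserved up to the noise, and only
ω > 0 descriptors can see the class difference. This is the mechanism probe
behind the α-sweep experiment.

The generator makes no attempt at anatomically realistic hippocampus
geometry, scanner noise models, or correlated left/right effects. Passing
tests therefore demonstrate that the machinery detects the geometric signal
classes it is designed for (area distortion; purely extrinsic bending)
under smooth nuisance variation and topological artifacts — not clinical
performance. Published accuracies on real cohorts are computed on
non-redistributable imaging-derived meshes and are out of reach of these
synthetic conditions by design.

## Known limitations

* Rigid registration cannot disambiguate extrinsic symmetries (see above);
  collections of near-symmetric shapes in inconsistent poses need external
  pose normalization or `registration="none"` in a shared frame.
* All-pairs map computation is O(n²) in the cohort size; no candidate-pair
  pre-filter is implemented.
* ZoomOut step counts are sometimes tuned so that the resulting pointwise
  maps realize small deformations (e.g. in terms of Green–Lagrange
  strain); no principled threshold exists, so the package exposes a mean
  edge-distortion diagnostic (`map_distortion`) rather than an automatic
  tuner.
* The GCN is dense; graphs beyond a few thousand nodes would need a sparse
  implementation.
* Descriptors assume the latent basis is meaningful on every shape; on
  shapes whose maps were pruned to few edges the latent functions can be
  poorly constrained.
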