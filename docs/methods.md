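# Methods

This note records the models, the parameter defaults and their rationale,
and the numerical conventions `gbpath` pins. Everything here is covered by
tests; `tests/test_acceptance.py` is the numerical contract.

## 1. Stain deconvolution (`stain_deconvolution`)

Brightfield IHC follows the Beer–Lambert law: transmitted intensity
`I = I0 · 10^(−OD)` per RGB channel, and optical densities of co-localized
stains add linearly. We compute

```
OD = −log10((I + eps) / (I0 + eps)),    I0 = 255, eps = 1
```

The `eps` guard bounds the OD of a fully absorbing pixel (I = 0) at
`log10(256) ≈ 2.41` instead of infinity; at 8-bit quantization, intensities
near zero are dominated by sensor noise anyway, and the guard costs at most
~0.01 OD elsewhere (the acceptance tests bound the whole-image
concentration round-trip error at 0.02).

The stain matrix `M` stacks unit-norm stain OD vectors (rows). Built-in
panels use the Ruifrok–Johnston vectors: hematoxylin (0.650, 0.704, 0.286),
eosin (0.072, 0.990, 0.105), DAB (0.268, 0.570, 0.776); a two-stain panel
is completed with the normalized cross product as the residual row.
Concentrations solve `c = OD · M⁻¹`. Negative components — physically
impossible, produced by noise off the stain plane — are clamped to zero,
and the fraction of clamped entries is reported (`clamp_rate`), because a
large clamp rate signals a wrong stain panel.

`stain_channel` min–max scales one concentration plane to [0, 1] for
thresholding, recording the constants; a constant plane maps to zeros with
a warning.

## 2. Segmentation (`segmentation`)

Otsu's threshold on an `n_bins = 256` histogram: the returned value is the
interior bin edge maximizing the between-class variance
`w0·w1·(μ0−μ1)²` over the two classes it induces. Edges, not bin centers,
so `binarize` (strictly greater-than) reproduces the class split exactly.
Exact ties break to the lowest edge (deterministic); constant images raise
`ValueError` (degenerate histogram) rather than returning an arbitrary cut
— batch callers that consider blank tiles legitimate use `segment_channel`,
which converts that error into an empty mask plus a warning.

Connected components use 4- or 8-connectivity (default 8, appropriate for
roundish nuclei); labels are renumbered 1..n in raster-scan order of each
component's first pixel so labelings are reproducible across backends.
For membrane markers segmented upstream by a CNN, body/process probability
maps are binarized at one global threshold in [0, 1] and merged by union;
objects containing no body pixel are flagged.

## 3. Feature extraction (`feature_extraction`)

Per object: area; perimeter as the 4-neighbor crack length (count of
exposed pixel edges, image borders included); radius statistics (mean, sd,
min, max of boundary-pixel distances to the centroid, where a boundary
pixel has at least one exposed 4-edge); centroid (`cx` = column, `cy` =
row, 0-based); second-central-moment ellipse. The diagonal second moments
include a `+1/12` per-pixel extent term (a pixel is a unit square, not a
point); this keeps eccentricity strictly below 1 for one-pixel-wide
objects and makes the moments of a digitized shape converge to the
continuous values. Orientation `theta = 0.5·atan2(2·μ11, μ20−μ02)` with
the y-axis taken upward, range `(−π/2, π/2]`; `major_axis = 4·√λ1`
(ellipse-equivalent). Intensity features are the mean, sd and 5%/95%
quantiles of the stain channel inside the object.

Texture uses a hand-rolled gray-level co-occurrence matrix restricted to
pixel pairs that both lie inside the object (background must not leak into
nuclear texture): the channel is quantized to 16 levels by
`clip(floor(v·16), 0, 15)`, counts for offsets (0,1) and (1,0) are
symmetrized and normalized, and contrast / correlation / energy /
homogeneity are averaged over offsets with at least one pair. A constant
object has correlation 1 by convention (perfectly self-correlated); objects
with no within-object pair at any offset get zeros and
`glcm_degenerate=True`.

## 4. Spatial statistics (`spatial_stats`)

Cellularity proxy: the mean over cells of the distance to the k-th nearest
other cell, `k = 100`. Dense tissue pulls the 100th neighbor close; the
large k makes the statistic robust to local clumping. Computed exactly via
a KD-tree (verified against the all-pairs oracle). Images with `n ≤ k`
cells get NaN plus an `insufficient_cells` flag — no silent fallback.
Staining burden: the DAB-positive to hematoxylin-positive pixel count
ratio, which normalizes marker load by cellularity and tile size; a zero
denominator is flagged.

## 5. Artifact filtering (`artifact_filter`)

A random-forest classifier (200 trees) labels objects positive/negative
for true signal from the shape + moment + intensity + texture features,
excluding positions (`cx`, `cy`): where an object sits must not determine
whether it is real. Training requires explicit `positive` / `negative`
labels (≥ 2 each); a stratified 25% holdout estimates accuracy before the
final refit on all rows. Filtering drops negatives and objects below
`min_area`, logs removals per image, never mutates features (idempotent).

## 6. Morphology phenotyping (`morphology_clustering`)

Cells are balanced by group (8,000 per group by default) to keep the
embedding and the chi-square from being dominated by the better-sampled
group, z-scored over the shape + moment features (positions excluded,
constant columns dropped with a warning), embedded by UMAP (2-D, 15
neighbors, min_dist 0.1, fixed `random_state`, hence single-threaded and
reproducible) and clustered by DBSCAN. `eps` is an explicit analysis
parameter (`suggest_eps` provides a k-distance-knee starting point);
clusters smaller than 160 cells (2% of a 8,000-cell group) are relabeled
as noise, and retained clusters are renumbered by decreasing size. The
retained-clusters × groups table is tested with an uncorrected Pearson
chi-square (general r×c contract; under the balanced design the expected
counts embody the even-split baseline); tables with an expected cell < 1
are flagged, not silently rejected.

## 7. Expression clustering (`expression_clustering`)

Samples are clustered on the signature gene subset by k-means, k chosen
from 2..10 by maximum mean silhouette width (best of 10 restarts per k,
ties to the smaller k). t-SNE (perplexity 10, PCA init, fixed seed) is
used for visualization only; clustering operates in gene space.

Validation is a permutation test: each gene's values are permuted
independently across samples — preserving every gene's marginal
distribution while destroying all gene–gene covariance — and the scrambled
matrix is re-clustered at the same k (a lightweight k-means++ Lloyd fit;
re-clustering is essential, otherwise the null ignores that k-means finds
*some* structure in any data and the test would be anti-conservative).
The statistic is `mean between-cluster − mean within-cluster` pairwise
Euclidean distance, estimated from up to 10,000 sampled pairs per class;
`p = (1 + #{null ≥ observed}) / (n_perm + 1)` (add-one rule, one-sided,
never exactly zero). Calibration under the null is pinned by test:
rejection rate at the 5% level stays within [2.5%, 7.5%].

The cluster-by-diagnosis association on a 2×2 table uses the Yates
continuity-corrected chi-square,
`χ² = Σ (max(|O−E|−0.5, 0))² / E`, df = 1, with the correction clamped at
zero for near-independent tables. The reference cohort table
[[22, 4], [5, 17]] gives χ² = 16.117216, p = 5.95e-05.

## 8. Imputation (`imputation`)

Cross-platform scale is removed by dividing every gene by a shared
housekeeping gene, per sample. Candidates are genes expressed (non-zero)
in every sample of both datasets whose variance falls in the lower 20th
percentile in *both*; the chosen gene minimizes the sum of its variance
ranks (ties lexicographic). Normalization is idempotent and cancels any
per-sample scale factor exactly.

Predictors per target gene come from Boruta: each iteration appends
permuted shadow copies of the surviving predictors (always ≥ 5 shadow
columns — a max over fewer is too weak a bar), fits a random forest on a
fresh 80% row subsample, and scores a hit for every real predictor whose
impurity importance beats the best shadow. The row subsampling matters:
a fixed noise column's spurious correlation with the target never
re-randomizes across iterations (unlike the freshly permuted shadows), so
without it lucky noise columns accumulate hits and get falsely confirmed.
Decisions are Bonferroni-corrected binomial tests (α = 0.01) against
Binomial(n_iter, ½): significantly many hits confirms, significantly few
rejects, leftovers after `max_iter = 100` are tentative. The null
false-confirmation rate is pinned ≤ 2α by test.

The imputer is a random-forest regressor (200 trees) trained on the
reference dataset; a 25% holdout estimates out-of-sample Pearson r before
the refit on all samples, models with r < 0.3 are flagged `low_quality`,
and every imputed value carries `imputed=True` so downstream tables can
distinguish measured from estimated expression.

## 9. Synthetic data (`synthetic_data`)

**Images.** Nuclei are ellipses (semi-major = drawn radius, semi-minor
shrunk by the drawn eccentricity) with uniform interior stain
concentration, drawn from configurable morphology subpopulations. All
nuclei carry hematoxylin (0.6 OD); a configurable fraction additionally
carries DAB (0.8 OD). Optional artifact objects render at 20% of the
nuclear hematoxylin OD, appear in the truth table with negative ids but
not in the label mask. Rendering follows the same Beer–Lambert model the
deconvolution inverts: concentration → OD via the stain matrix → `I =
255·10^(−OD)`, optional Gaussian OD noise, rounded to uint8. Truth pixel
counts are exact recounts of the rendered concentration rasters. With
`allow_overlap=False`, placement uses bounding-circle rejection sampling
(capped at 10,000 attempts per object, then a deterministic error) with a
2 px margin so rasterized nuclei can never become 8-adjacent — on such
tiles connected components recover the generated cell count exactly.
The generator emulates stain mixing, quantization and additive OD noise;
it does not emulate out-of-focus blur, chromatic aberration, nuclear
texture, or partial-volume edge effects.

**Expression.** Log-normal genes × samples matrices: gene baselines are
`N(2, 0.3)` in log space; signature genes (assigned round-robin to k
balanced, shuffled latent clusters) gain a log-scale effect in their
cluster; housekeeping genes have log-sd equal to the requested coefficient
of variation (for small σ, a log-normal's CV ≈ σ); imputation target genes
are sums of centered predictor log-values (optionally with an interaction
term) plus noise scaled to a prescribed population R². Defaults (109
samples, 83 signature genes, k = 3) mirror the bulk cohort setting the
pipeline targets.

## 10. Pipeline (`pipeline`, `cli`)

A single YAML config (unknown keys rejected; SHA-256 hash recorded in
every output) drives both arms. Per-stage seeds derive deterministically
from one global seed (`seed·1000 + stage_index`, mod 2³¹−1), so identical
configs reproduce identical outputs while stages stay decoupled. The
image arm writes `image_stats.csv`, `cells.csv` and `image_arm.json`;
morphology clustering is skipped (and said so in the report) when groups
cannot support the balanced subsample. The expression arm writes
`embedding.csv`, `clusters.csv` and `expression_arm.json`; the 2×2
chi-square runs only when diagnosis labels are provided and the table is
2×2, otherwise the report records why it was skipped. Any image failure
surfaces the failing image id. The `gbpath` CLI wraps each step and both
full arms.
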