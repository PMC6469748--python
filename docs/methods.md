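# Methods

This note documents the models and procedures implemented in `osteotile`,
the parameter choices that matter, what the synthetic generator does and
does not emulate, and the numerical conventions adopted where the design was
genuinely open.

## Problem setting

Post-chemotherapy osteosarcoma resections are assessed histologically by the
fraction of necrotic tumor. The pipeline operates on 1024×1024 RGB tiles cut
from H&E whole-slide images at 10× magnification and assigns each tile one
of three classes: non-tumor (NT), necrotic tumor (NEC), viable tumor (VT).
Two classification routes are provided — engineered features with classical
learners, and a small convolutional network on 128×128 sub-patches — plus
hierarchical three-class evaluation and map rendering.

## Synthetic data generator

The generator renders the three archetypes a pathologist distinguishes:

| archetype | nuclei/tile | radius (px) | appearance |
|---|---|---|---|
| NT  | 50  | 4–8  | sparse pale nuclei, near-white background |
| NEC | 150 | 3–7  | faded nuclei, low-frequency fragmentation mask, 0.6 strength, desaturation, dark debris specks |
| VT  | 400 | 5–10 | dark hematoxylin nuclei scattered around 25 cluster parents (σ = 30 px), pink background |

Nuclei are ellipses with uniform orientation and axis ratio 0.6–1; overlap
is permitted (real nuclei clump). The VT/NT density ratio of 8 exceeds the
4× separation the downstream separability property assumes. Per-channel
Gaussian noise (σ = 3–5) and a low-frequency background mottle prevent
degenerate flat fields. Everything is a pure function of `(spec, seed)`.

What the generator does **not** emulate: real chromatin texture, stromal
architecture, scanner optics and compression, stain variability between
laboratories, annotation noise. A green test on synthetic data therefore
establishes that the pipeline's machinery is correct and that it can recover
a planted, well-separated signal — not that clinical-grade accuracy would be
reached on real slides.

## Expert-guided features (8)

1. Convert to CIELAB (sRGB, D65 white point) and exclude pixels with
   a\* > δ (default δ = 64, strict comparator) — removes bone matrix, red
   blood cells and other strongly red objects. The comparator and δ are
   configurable; the source material uses ≥ and > interchangeably.
2. Otsu-threshold the grayscale intensity of the remaining pixels; darker
   (stain-dense) pixels are foreground ("blue"), the rest background
   ("red"). A constant tile is all background, with a warning.
3. Flood-fill (8-connected components of) the foreground into nuclei
   clusters; per cluster measure area, perimeter, circularity 4πA/P²,
   centroid.
4. Average the per-window centroid counts over the non-overlapping 32×32
   grid.

Features, fixed order: total_clusters, average_clusters, red_count,
red_percentage, blue_count, blue_percentage, mean_area, mean_circularity.
Empty-set means are 0 (not NaN) so feature matrices stay finite.

**Perimeter convention.** The raw count of boundary pixels overestimates
perimeter length (a rasterized disk of radius 20 would get circularity
≈ 1.24), so circularity uses the weighted chain-code perimeter estimate of
`skimage.measure.regionprops`, which yields ≈ 0.91 for that disk and keeps
circularity ≤ 1 + ε for convex shapes. The raw boundary count is retained in
`ClusterStats.boundary_pixels`. Red/blue pixel counts are taken *after* the
a\* exclusion.

## Texture features (53)

Color deconvolution follows Beer–Lambert: OD = −log₁₀(I/255) per channel,
projected by least squares onto the normalized Ruifrok–Johnston H&E basis
(H = [0.650, 0.704, 0.286], E = [0.072, 0.990, 0.105]); negative
concentrations are clipped. All texture measurements are taken on the
hematoxylin optical-density channel.

The catalog (fixed order, the module's contract):

* 13 Haralick statistics × 3 contexts (39): full-resolution H channel,
  2×-downsampled H channel, and the full-resolution channel restricted to
  the Otsu stain-dense foreground (co-occurrence pairs must have both pixels
  inside the mask).
* Gabor score (1): mean filter-response magnitude at frequency 0.08 over 4
  orientations; the image mean is subtracted first so a constant image
  scores exactly 0.
* Object statistics (6): primary object count, mean area, mean equivalent
  diameter (2·√(A/π), band 30–120 px), foreground fraction, Otsu weighted
  within-class variance, sum of fore/background histogram entropies.
* Neighbor statistics (7): mean/max/median neighbor count at boundary
  distance ≤ 5 px, percent of objects touching a neighbor, number of clumps
  (connected components of the neighbor graph), largest and mean clump size.

GLCM settings: 8 equal-width gray levels, the four distance-1 offsets (0°,
45°, 90°, 135°), symmetric, normalized, features averaged over offsets;
entropies use base-2 logarithms. Degenerate (single-entry) matrices report 0
for correlation-type features with a warning. Secondary objects are grown
from primary seeds by nearest-seed (Euclidean) assignment inside an Otsu
support mask — one secondary region per primary, regions partition the
support.

The expert and texture catalogs are disjoint by construction (no duplicated
feature semantics).

## Classical learning

Information gain G(C, X) = H(C) − Σ_x (|C_x|/|C|)·H(C|x) with base-2 entropy;
continuous features are discretized into 10 equal-frequency bins (quantile
edges). Values are bounded by H(C) ≤ log₂3 ≈ 1.585.

The registry holds exactly 13 configurations: complex trees with a split cap
of 30 or 100 and Gini or deviance (entropy) criterion (4); SVMs with
quadratic, cubic or Gaussian kernel × one-vs-one or one-vs-all multiclass
handling (6); a bagged-tree and two AdaBoost ensembles over decision-tree
bases (3). SVM features are z-scored on the training data; polynomial
kernels are (xᵀx/s + 1)^d with the standard "scale" normalization s (the
unscaled form is numerically ill-conditioned in 61 dimensions), degree 3 for
the cubic kernel, box constraint C = 1 by default. Trees consume raw
features. Fitting is delegated to scikit-learn (CART, libsvm, SAMME
AdaBoost); the surrounding arithmetic — splits, entropies, accuracies — is
native.

Stratified holdout uses the floor rule — per class, train = ⌊0.8·n⌋, the
remainder to test — which is the only rounding consistent with a published
914/230 partition of a 536/263/345 corpus. Class scores for ROC analysis:
trees/ensembles use predict_proba; one-vs-one SVMs aggregate
logistic-squashed pairwise margins into vote fractions; one-vs-all SVMs
softmax their margins. The score construction is a package choice — argmax
classification does not provide one.

## Patch CNN

Architecture (valid padding, 2×2 max pool): 128×128×3 → conv 5×5×4 →
124×124×4 → pool → 62×62×4 → conv 5×5×8 → 58 → pool → 29 → conv 3×3×16 → 27
→ pool → 13 → flatten 2704 → FC 256 (logistic) → FC 3 → softmax. Only the
first filter count (4) is pinned by the 62×62×4 reference volume; 8/16/256
are configurable defaults. Weights start N(0, 0.01) — variance 0.01, i.e.
std 0.1 — biases at 0.

Training: cross-entropy, minibatch SGD with Nesterov momentum γ = 0.9,
learning rate 10⁻³, batch 100, 20 epochs. Two conventions deserve note:

* **Reduction.** Gradients are *summed* over the minibatch (per-sample
  accumulation), the classical LeNet-era convention; with batch-mean
  averaging the stated rate is effectively 100× smaller and the network
  demonstrably cannot converge within 20 epochs even on trivially separable
  data. The implementation was verified against numerical differentiation
  (relative error ≤ 5·10⁻⁶).
* **Output head.** "Logistic regression as the activation" is read as:
  logistic sigmoid in hidden layers, multinomial logistic regression
  (softmax) at the 3-neuron output — softmax *is* the multiclass logistic
  model and yields proper probability triples.

Inputs are scaled to [0, 1] and standardized per channel with statistics
from the training set. Determinism: fixed seeds drive initialization and
shuffling; two runs with the same seed produce identical weights.

Preprocessing: the Euler number (8-connected objects minus 4-connected
enclosed background holes) of the Otsu-binarized dark-tissue image flags
background-dominated patches; patches with e ≥ −3 are kept, exactly as the
source prescribes, with threshold and direction configurable (the filter's
prose rationale and its comparator disagree; on synthetic data the printed
rule also drops some hole-rich tissue patches). L-channel normalization
rescales CIELAB lightness to mean 70, spread 12 — typical for a well-exposed
H&E scan — leaving a\*/b\* untouched; output stays float RGB to avoid
quantization. Augmentation: the 8 dihedral transforms, and per-image PCA
color shifts Q·(λ∘α) with α ~ N(1, 0.1) as printed (a switch selects the
canonical zero-centered variant); the RGB covariance is computed on
unit-scaled pixels, otherwise 8-bit eigenvalues make the shift absurd.
Augmentation is applied to training folds only, avoiding leakage.

Tile aggregation: majority vote over kept patches, ties broken by highest
mean probability, zero-patch tiles default to NT with a warning.

## Hierarchical evaluation

Each sample's probability triple collapses to s_tumor = P(NEC) + P(VT) and
s_viable = P(VT)/(P(NEC) + P(VT)) (0/0 → 0.5; the ratio form is a package
choice, configurable to raw P(VT)). The decision rule at thresholds
(t₁, t₂): NT iff s_tumor < t₁, else NEC iff s_viable < t₂, else VT. The ROC
surface collects the per-class true-positive-rate triples over a 201×201
threshold grid on empirical score quantiles (±∞ endpoints included).

VUS is computed two ways, which must agree as the grid refines: (a)
Stieltjes integration of TPR_VT over the (TPR_NT, TPR_NEC) increments, and
(b) the exact triple-counting estimator — the probability that a random
(NT, NEC, VT) triple satisfies s_tumor(NT) below *both* tumor scores and
s_viable(NEC) < s_viable(VT), each strict inequality earning half credit on
equality (the binary-AUC tie convention; a pair tied on s_tumor earns ¼ for
an NT sample tied with it). The estimator is vectorized over (NEC, VT)
pairs with sorted-search counting, O(n² log n), and is checked against O(n³)
enumeration. Limits: VUS = 1 for perfect separation, 1/6 for
label-independent scores.

## Prediction maps

Slides are cut into a non-overlapping 1024-px grid; partial edge tiles are
dropped (the featurizers assume full support). Tiles with tissue fraction
below 2% (pixels darker than gray level 235) are flagged absent and skipped.
Rendering uses exact legend colors — VT (255,0,0), NEC (0,255,0), NT
(0,0,255), absent black — at an eye-fit scale (longest edge ≤ 2048 px,
nearest-neighbor so legend colors survive), optionally alpha-blended onto
the downscaled slide. Percent necrosis divides NEC tiles by tumor tiles
(NEC + VT) only, the pathology convention; a grid without tumor cells
reports the quantity as absent rather than 0. No post-hoc smoothing of the
label grid is applied.

## Known limitations

* The synthetic archetypes are far easier than clinical tissue; reported
  synthetic accuracies are upper bounds on machinery correctness, not
  clinical performance claims.
* The 53-feature catalog is a documented reconstruction of a
  CellProfiler-style bank, not a bit-level reproduction of that tool.
* The numpy CNN is CPU-only and sized for desk-scale experiments (hundreds
  to thousands of patches), not for the ~57k-patch corpora of full studies.
* Published real-data accuracies (≈90% SVM, ≈93% CNN, AUC ≥ 0.98, VUS
  0.92–0.96) require the original annotated WSIs and are out of scope.
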