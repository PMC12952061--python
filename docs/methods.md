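# Methods

This note documents the models, numerical choices and limitations behind
`ghostcbir`. It states nothing that the test suite or
`scripts/acceptance.py` does not itself compute.

## Backbone

The feature extractor is a Ghost-style efficient CNN: a 3×3 stride-2 stem
(batch-norm, ReLU), a stack of Ghost bottlenecks, a final 1×1 expansion to
the embedding width, and global average pooling. The full-size spec follows
the published GhostNet width table and ends at 960 channels, hence a 960-d
embedding; only the stem, the block structure and the 960-d output are fixed
requirements, so the per-stage widths of the full spec are our choice of the
standard table. A two-block toy spec (≤ 24 channels, 24-d embedding) is the
default for desk-scale experiments and tests.

### Deformable convolution

Every spatial (3×3 depthwise) convolution inside the Ghost modules, and the
stride-2 downsampling conv of each reducing bottleneck, samples the input at
learned, per-position offsets. Fractional positions are resolved by
**bilinear interpolation with zeros outside the image** — the original
deformable-convolution convention, chosen because it is differentiable in
the offsets. Offsets are produced by a parallel plain 3×3 convolution with
2K² output channels per offset group (K = 3; 4 offset groups by default,
channels inside a group sharing one displacement field; maps with fewer
channels fall back to the largest divisor). The offset generator is
**zero-initialized**, so training starts from an exact standard convolution;
this also makes the zero-offset equivalence directly testable. Analytic
gradients of the sampling with respect to input, weights and offsets are
implemented by hand and verified against central finite differences
(tolerance 1e-3) — necessary because the offsets make sampling
input-dependent.

### Ghost module

A 1×1 "primary" convolution produces roughly half the output channels; a
cheap 3×3 depthwise *deformable* convolution applied to the primary output
produces the rest; the two blocks are concatenated. The cheap path consumes
the primary output (the GhostNet convention); the secondary channel count
must be a multiple of the primary count (depthwise multiplier).

### DFC attention

Runs in parallel on the bottleneck input and gates the expansion Ghost
module's output by element-wise multiplication. Pipeline: 2×2 average pool →
1×1 channel mixing → horizontal 1×5 depthwise stage → vertical 5×1 depthwise
stage → sigmoid → separable bilinear upsample back to the gated map's size.
The kernel extents (5) and the upsampling mode are our realization of the
decoupled-FC design; the attention literature fixes the stages but not these
constants. The **reduction ratio** (default 8) sets the width of the
channel-mixing stage, which we factorize as cin → max(cout/r, 1) → cout so
the ratio has a concrete parameter-count meaning inside the five-stage
pipeline.

### Bottleneck and shortcut

out = shortcut(x) + ghost₂( down( ghost₁(x) ⊙ attention(x) ) ), where `down`
(stride-2 depthwise deformable conv + batch-norm) exists only in reducing
blocks. The shortcut is the identity when shapes match; otherwise a
depthwise 3×3 (stride as the block) + 1×1 projection, each with batch-norm —
element-wise addition forces a shape-matching shortcut, and this is the
standard efficient-CNN realization. The second Ghost module is linear (no
ReLU) so the residual sum is unconstrained; ReLU is used everywhere else.

### Re-parameterization

Parallel conv branches (e.g. 3×3 + 1×1, each possibly with frozen
batch-norm) merge into one kernel by folding each branch's batch-norm into
its weights (w ← w·γ/√(σ²+ε), b ← (b−μ)·γ/√(σ²+ε)+β), zero-padding smaller
kernels to the target center, and summing weights and biases. Folding
precedes summation because the merged form presumes bare conv weights. The
merge is exact (tested at 1e-5 over random branch sets) and idempotent.

### Autodiff core

The network runs on a purpose-built reverse-mode autodiff layer over NumPy
(float64, single-threaded): grouped/rectangular conv2d via im2col,
deformable conv2d with hand-written backward, average pooling, separable
bilinear resizing, batch-norm composed from primitives, and the usual
elementwise ops. Everything is deterministic given parameters and input; all
randomness (init, dropout, shuffling, augmentation) flows through explicit
`numpy.random.Generator` objects.

## Objectives

Softmax is computed max-shifted. Cross-entropy clamps probabilities at 1e-12
inside the log (additive epsilon), far below any test tolerance, so a zero
probability at the true class yields a large finite loss. The distillation
loss is τ²·KL between temperature-softened distributions; the blend is
L = (1−α)·L_ce + α·L_kd with defaults α = 0.7, τ = 4. The KL direction
defaults to **teacher-as-target**, KL(p_t ‖ p_s) — the standard distillation
semantics — with the reversed direction available behind a switch, because
the written form of the loss is ambiguous about argument order. The teacher
is an injected callable; tests use a fixed random linear map, never a
downloaded model.

## Retrieval

Distances are computed on raw (unnormalized) embeddings: correlation
(1 − Pearson), standardized Euclidean with per-feature sample standard
deviations estimated over the gallery (ddof = 1), and Spearman distance
1 − ρ_S with tie-safe average ranks (the classical 6Σd²/(n(n²−1)) form
assumes no ties; with ties we rank-transform and take Pearson). The Spearman
*correlation* itself is not a distance, so the engine orders candidates by
1 − ρ, which preserves the similarity ordering. Degenerate (constant)
vectors under the two correlation-type metrics raise an error rather than
returning an arbitrary value; real embeddings are never constant.
Zero-variance gallery features get unit standard deviation plus a warning,
preserving dimensionality.

Per metric, the top k = 30 candidates are kept (ascending distance, ties by
gallery index). Majority voting counts, per candidate, the metrics whose set
contains it. The final list is the top n = 10 by **votes desc → mean
within-metric rank asc (absent metrics imputed rank k+1) → correlation
distance asc → gallery index asc**. Votes are the primary key; the remaining
keys are deterministic, similarity-faithful tie-breaks that make the final
ranks (needed by the rank-weighted metrics) well defined. A candidate does
not need two votes to be eligible: the list is purely top-n by votes. k and
n are config defaults, overridable.

## Evaluation metrics

AP@K carries two conventions. `as_written` divides Σ_k Prec@k·rel_k by the
number of relevant retrieved items (and returns 0 when there is none);
`as_reported` divides by K. They coincide when all K items are relevant, but
for a list with nine relevant items of ten the former gives 1.0 and the
latter 0.9 — the 0.9/0.8 worked values the package reproduces follow the
`as_reported` convention, which is therefore the default; both are exposed
rather than silently resolving the discrepancy. At chance (relevant fraction
1/C), Prec@10 sits at 1/C while both AP conventions have different, smaller
or larger baselines; the chance-level test uses Prec@10 accordingly.

CRAS uses harmonic rank weights and is reported at 4 decimal places.
Converting a mismatch at rank a into a match raises CRAS by exactly
(1/a)/W, so earlier ranks always matter more. Classification metrics are
per-class one-vs-rest precision/recall/F1, macro-averaged unweighted, with a
zero denominator yielding 0 plus a warning; accuracy is the pooled fraction
correct.

## Protocol

Preprocessing: bilinear resize to the target size (default 224 for the full
spec, 32 in the toy config), min-max scaling to [0, 255] with **floor**
rounding into uint8 (deterministic; idempotent on its own output), and
division by 255 at the network input. A constant image maps to zeros with a
warning.

Folds: patients are shuffled per class with the run seed and dealt
round-robin to k = 5 folds, so per-fold class counts are within one patient
of proportional and assignment is exactly reproducible. Validation is one of
the four remaining folds, rotating with the test fold (the protocol fixes
that splits are redefined per fold but not their sizes, so this is a
configurable default). The gallery is built from the training split only;
queries come from the held-out fold only; the driver asserts
patient-disjointness before computing any metric and aborts on violation.
Augmentation (crop to 90 % area, flips p = 0.5, brightness/contrast p = 0.2,
rotation ±50° p = 0.5, Gaussian blur p = 0.2, affine shift 0.0625 / scale
10 % / rotation ±45°) is applied independently per transform, only to
training-split records — calling the augmenter outside a training context
raises, and a spy test counts that the cross-validation driver triggers it
exactly once per training image per epoch.

## Synthetic data

The image generator emulates the *structure* of a curated T1-CE slice
collection at desk scale — not its radiological appearance: an elliptical
"head" at intensity ~90 with Gaussian noise (sd 8), one bright (~200)
class-stereotyped lesion per patient (class 0: large irregular blob, free
position; class 1: round rim-enhanced blob near the convexity; class 2:
small midline blob, center-low), jittered across that patient's slices. The
per-patient lesion is what makes slices of a patient correlated, which is
exactly what gives the patient-level split its meaning. Defaults: 3 classes
× 6 patients × 6 slices at 48×48 px. The embedding generator produces class
mean (unit direction × separation) + per-patient offset (sd 0.5) + per-slice
noise (sd 1), with query patients held out of the gallery.

Passing tests on this generator show that the pipeline recovers strong,
well-separated class structure end-to-end and that its metrics respond
correctly to separation; they do not show performance on real MRI, where
class overlap, scanner variation and lesion heterogeneity are far larger.

## Problem sizes and toy configuration

The end-to-end study trains the toy backbone on 3 × 6 × 6 = 108 synthetic
slices at 32×32, 10 epochs, batch 16, learning rate 3e-3, dropout 0.1,
flips-only augmentation — sizes chosen once as the smallest configuration in
which the 5-fold protocol is meaningful and training converges cleanly. The
full-scale defaults (learning rate 1e-4, batch 32, weight decay 1e-4,
dropout 0.3, 40 epochs, early-stopping patience 5, α = 0.7, τ = 4, offset
groups 4, reduction ratio 8) remain in `RunConfig`/`TrainConfig` for
full-size runs. Separation-sweep studies use 210 held-out queries per
separation level.

## Known limitations

* The NumPy autodiff core is written for clarity and desk-scale problems;
  it is single-threaded float64 and not suited to training the full 960-d
  backbone on a real dataset.
* The full-size per-stage width table is a conventional choice, not a
  requirement; other stage configurations are expressible via
  `BackboneSpec`.
* The voting CBIR performs exact exhaustive search; approximate
  nearest-neighbour indexing is out of scope.
* CRAS follows the predicted-label definition literally; aggregating with
  ground-truth query labels instead would measure retrieval purity, not
  classifier–retrieval agreement.
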