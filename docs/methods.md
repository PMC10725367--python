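# Methods

This note documents the models, conventions and numerical choices behind
`lesiongraph`, the reasoning where the design was genuinely open, and what
the synthetic experiments do and do not demonstrate.

## Synthetic phantoms

The generator produces image/mask/label triplets whose classes differ in
exactly the properties the ten features measure.

**Geometry.** The lesion contour is star-convex:
`r(θ) = r0 · (1 + irregularity · Σₖ aₖ sin(kθ + φₖ) + spicule spikes)`,
with harmonics k = 2…6, amplitudes ~ U(0.4, 1)/k, and spicules as narrow
Gaussian bumps in θ (width 0.04–0.09 rad, amplitude 0.25–0.45). The
harmonic mixture is shifted to be non-negative so lobes push outward: the
farthest lobe then stretches the moments-ellipse major axis faster than the
area grows, which makes mean circularity and solidity *strictly* decreasing
in the irregularity amplitude — the generator's contract with the shape
features. The base ellipse has axis ratio 0.9 (near-round, mildly
elongated); with a more elongated base, small perturbations *isotropize*
the second moments and can transiently raise circularity, breaking the
monotone response. Base radius is 0.28 of the image side; masks are kept
strictly inside the border and reduced to one 4-connected component.

**Intensity.** Lesions are hypoechoic: interior = background −
`rim_contrast`. Texture heterogeneity is a Gaussian-filtered (σ = 6 px)
white-noise field scaled to the requested standard deviation, added inside
the lesion only. Speckle is multiplicative Rayleigh noise normalized to
unit mean — the modality's characteristic noise — scaled by
`speckle_sigma` and applied to the whole image, then clipped to [0, 255].

**Class presets** (config data, not constants): benign irregularity 0.03,
0 spicules, heterogeneity 4, speckle 0.05, rim contrast 70; malignant
irregularity 0.22, 7 spicules, heterogeneity 22, speckle 0.25, rim
contrast 30. These were chosen once as plausible caricatures of the two
classes' sonographic appearance and produce clear separation in all ten
features.

**What the phantoms are not.** No beamforming, attenuation, shadowing or
depth-dependent resolution; no segmentation noise (masks are exact); no
overlap between the class distributions comparable to real cohorts.
Consequently, passing end-to-end tests demonstrates that the pipeline's
machinery is correct and that the features capture the constructed
contrasts — not that the approach reaches any particular clinical accuracy.

## Feature conventions

- Coordinates are 0-based (row, col); masks binarize at > 0; features are
  computed on the largest connected component.
- Both entropies use log base 2 with 0·log 0 := 0.
- Texture statistics (histograms and GLCM pairs) use only pixels with
  mask = 1: the zeros that the bitwise-AND ROI extraction writes outside
  the lesion would otherwise dominate every histogram.
- GLCM: G = 8 gray levels by uniform binning of [0, 255], offset distance
  D = 1, pair counts accumulated over directions {0, π/4, π/2, 3π/4} with
  both pixels inside the mask, symmetrized, normalized to sum 1. G, D and
  the brightness band width are config keys; the defaults are declared
  choices, not values inferred from data.
- GLCM correlation is reported in the variance-normalized form (covariance
  divided by the marginal standard deviations, hence in [−1, 1]); the raw
  covariance form is available via `normalized_correlation=False`. A
  single-level (zero-variance) matrix returns correlation 1 by convention.
- Circularity's d_max is the major-axis length of the moments-equivalent
  ellipse of the region.
- Solidity counts pixel centers in both numerator and denominator: the
  hull area is the number of grid centers inside the exact convex-hull
  polygon of the boundary centers. This keeps both measures on the same
  discretization footing, so convex regions score ≈ 1 and the ratio never
  exceeds 1; hull areas measured on pixel corners instead bias convex
  shapes down by ≈ half a perimeter's worth of pixels.
- The minimum-area enclosing ellipse is computed by Khachiyan's algorithm
  with away steps (linear convergence) on the convex-hull vertices of the
  boundary pixel corners, relative optimality gap 1e−6, iteration cap 1e5.
  Corner offsets (±0.5 px) make the ellipse enclose whole pixels so the
  ratio stays ≥ 1 up to discretization.
- Brightness bands are Euclidean distance-transform bands of width k = 10
  px just inside and just outside the boundary; the band must not be
  clipped by the image border for the value to be translation-invariant.

## Statistics

Welch's unequal-variance two-sample t-test is used per feature (sign
convention benign − malignant): group sizes and variances both differ
between classes, and the equal-variance form has no advantage here. Two
zero-variance groups degenerate to t = 0/±∞ by the mean difference. No
multiple-testing correction by default (per-feature reporting); a
Bonferroni option exists. Density estimates are Gaussian KDE with
Silverman bandwidth.

## Graph

Spearman correlation is computed as Pearson correlation of average ranks —
the general definition, identical to the classical rank-difference formula
when ties are absent and unbiased when they occur (quantized features can
tie). A constant feature row has undefined correlation and raises, naming
the offending row. Edges are undirected, stored once (source < target);
thresholding keeps weight ≥ τ, except τ = 1.0 which selects weight
exactly 1 within 1e−12 (an "equal to one" selection, not a bound).
Negative-weight edges survive in the unthresholded graph. Adjacency is
dense up to 2000 nodes and CSR-sparse above, with identical semantics.

The anomaly filter uses fixed correlation cut points (weak < 0.4,
strong ≥ 0.7, both config keys). Only the two anomaly predicates remove
edges — strong∧cross-class and weak∧same-class; the middle band always
passes. The predicates act on disjoint weight ranges, so removal order is
irrelevant, the operation is idempotent, and counts are conserved; a
report with all five counts is emitted alongside the filtered table.

## The classifier

**Why an in-repo network.** The model runs on a compact reverse-mode
autograd engine (`lesiongraph.nn.autograd`) written for this package: the
architecture needs only broadcasted arithmetic, matmul, reductions, a few
activations and a fused softmax-cross-entropy, and an engine of ~250 lines
keeps the whole classifier inspectable and dependency-free. Gradients are
verified against central finite differences in the test suite.

**Architecture.** `n_ffn_blocks` (default 9) skip-connected FFN blocks are
distributed as evenly as possible around `n_gcn_layers` (default 3)
graph-convolution layers, extra blocks going to the front: 9 blocks and 3
GCN layers give FFF·G·FF·G·FF·G·FF. Each block is batch-norm → dropout 0.2
→ Dense(64, ELU) → Dense(64, ELU), combined with its (projected) input.
The default combination is a depthwise convolutional LSTM cell — gate
transforms are kernel-size-1 convolutions along the feature axis, i.e.
per-feature weights — run over the length-2 sequence [skip, transformed],
whose final hidden state is the block output; the reference design names
a 1-D convolutional-recurrent combination without specifying its wiring,
so this minimal cell was chosen as the declared interpretation,
with plain concatenation as the documented alternative. The GCN layer is
`h_u ← ELU(W_n h_u + W_nei · agg N(u) + b)` with mean (degree-normalized)
neighbor aggregation by default and raw sum as an option, followed by row
L2 normalization of the embeddings ("normalized" is stated without a
formula; unit-norm rows are the standard reading). A model-level dropout
0.3 precedes the final 2-logit dense layer and softmax.

**Training.** Transductive: every forward pass sees all nodes and the full
adjacency; the loss is sparse categorical cross-entropy over mini-batches
(default 128) of *training* nodes only. Default 100 epochs, Nadam
(Dozat's Adam-with-Nesterov) at lr 0.01; Adam/Adamax/SGD are selectable.
Splits are stratified 80/10/10 by class (the reference design leaves the proportions unstated;
this default keeps train/val/test accuracies comparable). Batch-norm uses
current-pass statistics in training and exponential running estimates
(momentum 0.1) in inference. Gradients are clipped to global norm 5.0:
the recurrent combiner at lr 0.01 otherwise diverges on a minority of
seeds after reaching separation. No early stopping (fixed-epoch training).
All randomness — initialization, dropout masks, batch order, splits, folds,
tuner proposals — flows through one generator seeded from `ModelConfig.seed`,
so runs are bit-reproducible.

**Evaluation.** The confusion-matrix suite reports percentages; a metric
with a zero denominator is NaN and listed in the report's `undefined`
field, never silently zero. MCC is scaled to percent for consistency.
Five-fold CV uses stratified folds; the reported mean is the arithmetic
mean of fold accuracies. The threshold sweep reuses one split and seed
across all thresholds so rows are comparable.

**Bayesian tuning.** Gaussian-process surrogate (Matern ν = 2.5 on the
unit-box-scaled space, length-scale bounds [1e−2, 1e2]) with UCB
acquisition μ + κσ, κ = 2.0, maximized over 512 random candidates per
iteration; 5 initial random evaluations; integer dimensions (hidden units,
batch size) are rounded after acquisition. Search box: hidden 32–64, lr
0.001–0.01, batch 64–128, dropout 0.3–0.7.

## HOG baseline

The comparison arm resizes the full image (no mask) to 224×224 and
computes HOG with 16×16-pixel cells, 2×2-cell blocks at one-cell stride,
9 unsigned orientation bins and L2-Hys normalization — 13²·4·9 = 6084
dimensions; that geometry is the one consistent with the reference
descriptor length of 6084. The descriptor table then follows the identical
Spearman-graph + GNN path, unthresholded (its reference comparison
condition), sharing split and seed with the handcrafted arm.

## Problem sizes

The test suite and the acceptance script run at desk scale: phantom
cohorts of 20–100 images at 128–256 px, graphs of up to 100 nodes for
training, and a 647-row random feature table for the combinatorial
edge-count identity. These sizes were chosen so the full pipeline,
including five-fold CV, completes in a few minutes on one CPU while still
exercising every code path at the reference table dimensions where those
are self-contained.

## Known limitations

- Phantom realism as above; no claim of clinical accuracy transfers.
- The dense adjacency path materializes an n×n matrix inside the GCN even
  when edges are sparse; fine to a few thousand nodes, wasteful beyond.
- The depthwise (kernel-1) convolutional LSTM combiner is one reading of
  an under-specified design; the `concat` alternative is provided for
  ablation.
- The tuner's acquisition optimizes over random candidates, not a
  gradient-based inner loop; adequate for 4 dimensions and small budgets.
- The reference dataset description reports 467 benign images in one place and a node
  numbering implying 437 in another; the package always takes class counts
  from the cohort manifest and does not attempt to resolve the discrepancy.
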