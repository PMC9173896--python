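# Methods

This note documents the models implemented in `dermoclass`, the design
choices made where the published description of each component is
incomplete, and what the synthetic benchmark does and does not show.

## Pipeline overview

Images flow through denoise → segment → featurize → classify. A single
global seed is fanned out to per-stage seeds by a fixed counter scheme
(`stage_seed = (seed + 1000003 · stage_index) mod 2³¹`); every derived
seed is recorded in the run manifest, so one integer reproduces a run
bit for bit (the metrics JSON of a rerun is byte-identical).

## Bilateral filtering

The filter is the standard product-of-Gaussians form: spatial kernel
`exp(−‖q−p‖²/2σ_s²)`, range kernel `exp(−(F(q)−F(p))²/2σ_r²)`,
normalized per pixel over a square window. Choices:

- **Per-channel filtering.** RGB channels are filtered independently;
  joint-range variants would couple channels but the simplest faithful
  reading is per-channel.
- **Replicate padding** avoids darkening at image borders.
- **Defaults** σ_s = 2 px, σ_r = 0.1 intensity units, window half-width
  `ceil(3σ_s)` (captures >99% of the spatial kernel mass). The source
  method reports no values; these suit 64×64–256×256 dermoscopy-style
  images whose lesion/skin contrast is ≈0.3–0.5, an order of magnitude
  above σ_r, so lesion borders are preserved while noise (σ ≈ 0.02) is
  well inside the averaging range.

Output is a convex combination of neighbourhood values, which gives the
tested invariants: constant images are fixed points, output is bounded
by the neighbourhood min/max, and with σ_r → ∞ the filter degenerates
to a plain Gaussian blur of the same window.

## Fuzzy k-means segmentation

Pixels are clustered in RGB space (no spatial coordinates: the goal is
separating pigmented from healthy *intensity*, not enforcing contiguity)
by minimizing `L = Σ_j Σ_i b_ij^f ‖x_i − C_j‖²`. The published
description gives only the objective; the updates used are the exact
per-block minimizers (standard fuzzy c-means):

    b_ij = 1 / Σ_l (g_ij / g_il)^{1/(f−1)},   C_j = Σ_i b_ij^f x_i / Σ_i b_ij^f.

- **Zero distances**: a pixel coinciding with a centroid gets crisp
  membership there (the limit of the update).
- **Initialization**: seeded farthest-point sampling over distinct
  pixel values — reproducible and never coincident.
- **Defaults** k = 2, f = 2, tol = 1e−5 on |ΔL|, max 100 iterations.
- **Lesion cluster** = the one whose centroid has the lowest luminance
  (0.299R + 0.587G + 0.114B); pigmented lesions are darker than skin.
  Ties break to the lowest index. The binary mask takes each pixel's
  arg-max membership. No morphological post-processing by default.

Alternating minimization guarantees a non-increasing objective; this is
asserted (within 1e−9) on every fit, and the crisp limit f → 1⁺ is
checked against k-means started from the same centroids.

## Feature extraction

The extractor is a compact CNN implemented directly on numpy arrays:
three conv blocks (8/16/32 filters, 3×3, stride 1, ReLU, 2×2 max-pool),
global average pooling to a 32-vector, and a logistic head used only
during training. Inputs are masked (background zeroed), centred
(`2(x − 0.5)` inside the mask, so lesion pixels are roughly zero-mean)
and resized to 64×64. Features are the GAP vector; the head is
discarded after training.

Training is mini-batch SGD with momentum on binary cross-entropy.
Defaults: learning rate 0.005, momentum 0.9, batch 8, 100 epochs.
Momentum and input centring are deliberate additions: plain SGD on raw
[0,1] masked inputs sits on the symmetric plateau (loss ≈ ln 2) for
many initializations because ~80% of input pixels are zero and the
remaining values are small and one-signed; centring plus momentum makes
convergence reliable across seeds. Gradients of the conv/pool/GAP stack
are exact (verified against finite differences during development, and
the conv/pool primitives against quadruple-loop oracles in the suite).

A `nasnet_pretrained` backend name is reserved behind the same
interface for an ImageNet-pretrained NASNet adapter; it needs an
optional deep-learning runtime plus downloaded weights and is outside
the tested default path.

## Cascade-forward classifier

The network output is the sum of a direct input→output path and a
one-hidden-layer path:

    y = f_in(w·x) + f_out(b_o + v · f_h(Wx + b_h)).

Defaults: f_in = identity, f_h = f_o = logistic, 10 hidden units, one
output unit (binary task). Because y is unbounded, the classifier
applies a final logistic squash and thresholds the score at 0.5 (ties
at the threshold go to melanoma). This decision rule is the minimal
completion of the published formulation, which never states one.

Parameters flatten to a single vector in the fixed order (direct
weights, hidden weights row-major, output weights, hidden biases,
output bias) — the search space for the optimizer — and serialize as
JSON so model files are diffable.

## MRFO training

The optimizer minimizes a box-constrained fitness with N agents over T
iterations. The published material gives the three update equations but
no scheduler; the control flow used is the canonical one:

- per agent, a fair coin chooses cyclone vs chain foraging; cyclone
  uses a fresh uniform reference point (exploration) when `t/T` is
  below a fresh uniform draw, and the best-known position otherwise;
- after all agents move and are evaluated, each performs one somersault
  step and is re-evaluated;
- positions are clipped to the box; the best-ever solution is tracked
  separately (elitism), so the reported best fitness never worsens.

Two printed coefficient formulas were typographically broken in the
source and are implemented in their standard forms: α = 2r√|ln r1| and
β = 2·exp(r1(T−t+1)/T)·sin(2πr1). Defaults: N = 30, T = 100,
weight box [−5, 5] per dimension, somersault factor S = 2.

**Classifier fitness.** The fitness is the training error rate,
`100 · misclassified / total`. Because that surface is piecewise
constant, the pipeline adds a tie-break term: the mean absolute
deviation of the score from the 0/1 target, scaled by `100/n_train` so
it is strictly smaller than one misclassification step. It therefore
never trades an error for margin — it only orders weight vectors with
*equal* error counts, preferring larger decision margins. Without it,
the optimizer keeps the first zero-training-error vector it finds,
whose held-out accuracy is erratic; with it, held-out accuracy at the
default study conditions is stable. Set `margin_weight: 0` to recover
the pure error-rate fitness.

Features are z-scored with training-split statistics before
classification so the weight box is scale-appropriate.

## Evaluation protocol

Melanoma is the positive class. The stratified split sends
`round(0.7 · n_class)` of each class to training (so 250 + 250 images
give exactly 350/150). Per-class precision/recall/F-score come from the
2×2 confusion matrix; the "Average" row is the unweighted macro mean;
accuracy is orientation-invariant. Zero-denominator metrics are
reported as 0 with a warning flag. Reported percentages are rounded
half-up to two decimals only at report time; unrounded values are kept.
ROC and PR points come from a standard threshold sweep over the unique
scores (scikit-learn's implementation behind the module's interface).

## Synthetic data

Each image is a skin-tone background (constant colour plus low-amplitude
smooth cosine texture) with one darker elliptical lesion whose boundary
radius is perturbed by sinusoids: even harmonics carry the
border-irregularity amplitude, odd harmonics the asymmetry. Melanoma
images get the configured asymmetry scale, extra border amplitude and a
color-variance multiplier (≥1) on within-lesion mottling; benign images
use the base values. After rendering, the lesion radius is rescaled
(perturbation field fixed) until the mask area matches the sampled
target fraction, so the configured area range is a hard invariant.
Gaussian noise (σ = 0.02) is added everywhere and exactly
`round(0.005 · H · W)` pixel sites are set to pure black or white.

Defaults — 64×64 images, lesion area 8–25% of the frame, asymmetry 1.0,
border irregularity 0.4, color-variance multiplier 2.5 — are the study
conditions for all end-to-end tests: strong, unambiguous class effects
at desk scale. What passing shows: every stage is numerically correct,
the stages compose, and the pipeline recovers a strong class signal
from images it has never seen. What it does not show: performance on
real dermoscopy, which has hair and ruler artifacts, specular
highlights, multi-modal lesion colours, class overlap and label noise —
none of which are simulated.

## Numerical choices and degenerate inputs

- Constant images cannot be segmented (fewer distinct colours than k):
  rejected with an explicit error rather than returning an arbitrary mask.
- Non-finite images, fitnesses or configuration values are rejected at
  the boundary of each module.
- Logistic activations clip their argument at ±500 to avoid overflow;
  max-pool pads ragged edges with −∞ so no real value is invented.
- Dice of two empty masks is defined as 1.0.

## Problem sizes

End-to-end runs use 50 images per class at 64×64 (70/30 split), the
extractor trains for 100 epochs on the 70-image training split, and the
optimizer runs 30 agents for 100 iterations over the 373-dimensional
weight vector (32 features, 10 hidden units). A full pipeline run takes
roughly half a minute on one CPU core; the sphere benchmark for the
optimizer (20 agents, 200 iterations, 10 seeds) a few seconds.

## Known limitations

- The compact CNN is a desk-scale stand-in for a large pretrained
  extractor; its features are only as good as the training split.
- Error-rate fitness over a 373-dimensional box is a hard search
  problem; MRFO finds zero-training-error solutions reliably at these
  sizes, but scaling feature_dim or n_hidden up substantially would
  need larger populations/budgets.
- Fuzzy k-means on RGB alone assumes the lesion is the darkest
  coherent colour cluster; occlusions or shadows violating that
  assumption will mis-select the lesion cluster.
- The CLI's `segment` command applied to an un-denoised image inherits
  salt-and-pepper outliers; the intended order is preprocess → segment.
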