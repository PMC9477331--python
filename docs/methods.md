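# Methods

## Problem and approach

Nuclei segmentation of hematoxylin-eosin (HE) stained histology is usually
trained on hand-annotated masks, which are expensive (a single high-power
field can hold several hundred nuclei).  `nucseg` implements a fully
unsupervised alternative that exploits the staining chemistry itself:
hematoxylin renders chromatin blue-purple, eosin renders cytoplasm pink, and
unstained extra-cellular space (ECS) stays near-white.  The pipeline has four
stages:

1. **Pseudo-labels by color clustering.**  Random sub-graphs are cropped from
   each slide and their pixels clustered with k-means (k = 3) on RGB values
   normalized to [0, 1].  Clusters are named by chemistry: the brightest
   centroid is ECS; of the remaining two, the one with the larger blue-minus-
   red difference is NUCLEI, the other CYTOPLASM.  Binary nucleus label
   patches of size N×N are cut from the clustering map on a stride-N/2 grid,
   keeping only patches whose nucleus fraction lies in [0.05, 0.80] —
   near-empty and nucleus-saturated windows teach nothing about boundaries.
2. **Asymmetric samples.**  Each N×N label is paired with the 2N×2N image
   crop centered on it (padding N/2 per side).  Supervising only the central
   region widens the receptive field around the labeled area, acting as a
   cheap spatial attention: context is visible, but only the trustworthy
   center is scored.
3. **Full Mixup in HSV space.**  Training batches are augmented by blending
   pairs of patches.  Blending happens in HSV because hue — the axis that
   identifies tissue — is one channel there: saturation and value mix
   linearly with weight λ, hue mixes along the shorter circular arc (350° and
   10° must average to 0°, not 180°), and the two binary labels are unioned
   so no nucleus is lost.  Blending pale and saturated stains this way keeps
   nucleus hues tight where naive RGB averaging washes them out; the package
   asserts this as a measurable variance inequality on synthetic pairs.
4. **A gated encoder–decoder without skip connections.**  See below.

## The channel-gated network

The network maps a 2N×2N×3 patch to an N×N nucleus-probability map through a
conventional conv/pool encoder and transposed-conv decoder — but with **no**
skip concatenations.  Information crosses layers instead through a
per-channel state vector ("feature global delivery connection"):

    AP_l = spatial mean of the level's input features   (one value/channel)
    i_l  = σ(W_i · AP_l + b_i)          local-layer information, in (0,1)
    g_l  = σ(W_g · S_{l−1} + b_g)       gate on the previous level's state
    S_l  = g_l ⊙ i_l

The gate's output width follows the channel ladder: 2·C_{l−1} while encoding
(channels double per level) and C_{l−1}/2 while decoding.  The first level
has no predecessor, so S_1 = i_1 — equivalent to an all-ones gate.  Each
level applies two gated residual blocks

    F̂ = K₂ ∗ ReLU(K₁ ∗ F + b₁) + b₂
    F̃ = ReLU(F̂ ⊙ S_l + F)

so the learned residual is scaled per channel by the delivery state before
the identity addition; with S_l ≡ 0 the whole network collapses to plain
ReLU propagation, which the tests verify.  The head is a 1×1 convolution and
sigmoid at full resolution, center-cropped to N×N.  The two 3×3 kernels of a
block carry independent biases.  No batch normalization is used anywhere.

The implementation is pure numpy (im2col convolutions with hand-derived
backward passes, Adam); every layer's gradient is pinned by finite-difference
checks in the test suite, and a regression test freezes the parameter count
as a function of the architecture config.

Defaults: depth 4, base width 32, He-normal initialization (seeded), zero
biases.  The pipeline's desk-scale configuration (below) uses depth 3 and
base width 8.

## Losses and the dynamic curriculum

The per-sample loss is the mean of binary cross-entropy (predictions clamped
at 1e−7) and smoothed Dice loss (additive smoothing 1 in numerator and
denominator); the batch loss is the mean of per-sample values.  BCE supplies
dense gradients; Dice protects small nuclei from being drowned by the
background class.

Training adjusts the mixup probability p each epoch from validation feedback.
Two validation subsets are scored — the unmixed patches, and a mixed set
rebuilt every epoch from validation pairs with a per-epoch seed — each by the
mean of Jaccard similarity and Dice coefficient on thresholded (0.5)
predictions, averaged per patch.  If the unmixed subset scores higher, p
rises by Δp (the model needs more mixed exposure); if lower, p falls;
ties leave it unchanged; p is clipped to [p_min, p_max].  Training stops
when p has sat at p_max for `patience` consecutive epochs, or at the epoch
cap.  With `dynamic: false` the loop runs the full cap at constant p — the
fixed-mode reference uses p = 0.5.

Chosen constants (configurable): Δp = 0.05, p_min = 0.1, p_max = 0.9,
patience 3, Adam at 1e−3.  The mixing weight λ is drawn uniformly from
(0.3, 0.7) by default — a fixed 0.5 is available — keeping both source
populations visible in every blend.

## Inference

Whole slides are segmented by exact central tiling: reflect-pad by N/2 (plus
a bottom/right remainder so the tiling closes), slide 2N×2N windows at
stride N, and write each window's central N×N prediction into place.  Every
output pixel is produced by exactly one window (asserted at run time), so no
blending heuristics are involved; the asymmetric training makes window
centers trustworthy.  The binary mask is thresholded at 0.5 and instances
are 8-connected components.

## Evaluation

Pixel-level: F1 = 2TP/(2TP+FP+FN), IoU (= Jaccard similarity) and Dice.
Object-level: the Aggregated Jaccard Index.  Every ground-truth object G_i
is matched to the predicted object maximizing Jaccard overlap (ties to the
lowest predicted label); Σ|G_i ∩ S_j(i)| is divided by Σ|G_i ∪ S_j(i)| plus
the full area of every predicted object never selected by any G_i.  A
ground-truth object with no overlapping prediction contributes its own area
to the denominator.  A deliberately naive pixel-set enumerator
(`aji_bruteforce`) ships alongside the fast contingency-table implementation
and the two are required to agree to 1e−12 on randomized fixtures.
Dataset-level numbers are per-image means.

## Synthetic study conditions

No public dataset ships with the package; a parametric generator renders
HE-like slides with exact instance masks.  Nuclei are rotated ellipses with
hue in 220–290° (blue-purple), cytoplasm blobs in 320–350° (pink), ECS
near-white; `stain_quality` "high" draws saturated dark nuclei
(S ∈ 0.55–0.75, V ∈ 0.40–0.60) and "low" draws pale ones (S ∈ 0.25–0.40,
V ∈ 0.70–0.88), emulating well- and poorly-stained acquisitions; slides
alternate between the two regimes.  Nucleus placement is rejection-sampled
so neighbours may touch (center distance ≥ 0.75 × summed radii) without a
later ellipse cutting an earlier one in two — instances can abut, which is
the regime where AJI is discriminative, yet every label stays connected.
Gaussian sensor noise (σ = 4 intensity units) is added last.  Generation is
a pure function of its spec: identical parameters give bit-identical rasters.

The reference end-to-end study runs 20 training and 5 held-out slides of
256×256 px with 50 nuclei of radius 6–12 px each, 3 sub-graphs of 128 px per
slide, N = 48, at most 210 patches split 2:1 into train/validation, a
depth-3/base-8 network, batch 16, and at most 30 epochs — sized so the whole
study completes in minutes on one CPU core.  At seed 1 it reaches pixel
F1 ≈ 0.97 and AJI ≈ 0.61 on the held-out slides.

What the generator does **not** emulate: real chromatin texture and nucleoli,
stain gradients within a nucleus, out-of-focus blur, touching nuclei with
shared membranes, scanner color profiles, or annotation noise.  Passing the
synthetic study therefore demonstrates that the machinery is correct and the
unsupervised loop can recover a known segmentation signal — not that the
reported numbers transfer to clinical material.

## Numerical choices and degenerate inputs

- Patch normalization maps the 1st/99th per-channel percentiles of the
  patch's source sub-graph to [0, 1] (clipped).  An exactly constant channel
  degenerates to mid-gray with a warning.
- k-means uses seeded k-means++ with 4 restarts; a sub-graph with fewer
  distinct colors than k raises a diagnostic error instead of returning a
  defective map.  A blue-minus-red margin below 0.02 between the two stained
  centroids emits a warning that the nuclei/cytoplasm call is fragile.
- Class-assignment ties break deterministically by centroid index.
- Metric conventions: F1 returns 1 (with a warning) when no positives exist
  anywhere; IoU/Dice return 1 on two empty masks; AJI returns 1 (with a
  warning) when both instance maps are empty.
- One global seed fans out to per-stage seeds via SHA-256 of the stage name,
  so stages are independently reproducible and all derived seeds stay below
  2³¹.

## Known limitations

- Pseudo-labels inherit every failure of color separability: heavy stain
  batch effects, necrosis, or overlapping chromatin will mislead k-means and
  there is no human-in-the-loop correction stage.
- The numpy implementation targets clarity and CPU-scale studies, not GPU
  throughput; full-scale (400-epoch, 1000×1000-slide) training is out of
  scope.
- Instance separation relies on connected components of the binary mask;
  deeply overlapping nuclei merge into one instance.  No boundary-aware
  post-processing (watershed, seeded splitting) is included.
- Sliding-window inference assumes the slide fits in memory; there is no
  pyramidal/whole-slide-image support.
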