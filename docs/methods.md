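# Methods

`lesionkit` implements a dermoscopy skin-lesion analysis chain — contrast
enhancement, deep-saliency segmentation, wrapper feature selection by
moth-flame optimization, correlation-based feature fusion, and kernel
extreme learning machine (KELM) classification — as a library of composable
stages that runs end to end on synthetic fixtures.  This note records the
model of each stage, its assumptions, the parameters that matter, and the
design choices made where the procedure left genuine freedom.

## Contrast enhancement (`lesionkit.enhancement`)

Dermoscopic lesions occupy the dark band of the luminance histogram.  The
chain is:

1. **Histogram and lesion band.** The 256-bin histogram of the luminance
   image is split by Otsu's threshold `t`; the lesion band is `[k1, t]` with
   `k1` the lowest occupied level, and the *patch* is the set of pixels in
   band.  The darker mode is taken to be the lesion, which is the standard
   polarity for pigmented lesions.  A constant or unimodal image yields the
   full occupied range, flagged degenerate, and passes through unchanged.
2. **Variance weighting.** The global population variance σ², normalized by
   the maximum possible 8-bit variance (127.5²), acts as a bounded gain
   `w ∈ [0, 1]`: patch pixels are contrast-amplified about the patch mean
   with gain `1 + w`.  A raw multiplication of histogram counts by σ² has no
   pixel-domain meaning, so the variance enters as this normalized gain.
3. **In-patch equalization.** Classic CDF histogram equalization applied to
   the patch pixels only, mapped onto the patch's own level range (so a
   two-level patch maps to the extremes of its range and the full-image
   patch reduces to textbook equalization).
4. **Fusion.** A 50/50 convex blend of the original with the
   patch-composited image; pixels outside the patch are returned unchanged.
   A blend is bounded and symmetric, which is all the operation needs.
5. **Gain passes.** Two sequential passes; each applies candidate contrast
   gains g ∈ {1,…,5} about the image mean and keeps the candidate with the
   largest Otsu between-class variance (ties → smallest gain).  The
   between-class variance is the natural separability score for a step whose
   stated purpose is to separate lesion from background.

Color images are processed on ITU-R BT.601 luminance; each channel is then
rescaled by the per-pixel luminance ratio, keeping hue stable.  Outputs are
clipped to [0, 255]; the whole chain is deterministic, and on a constant
image it is the identity.

## Deep-saliency segmentation (`lesionkit.dss`, `lesionkit.nn`)

**Network.** A ten-layer CNN (input, conv 3×3×64 + ReLU, conv 3×3×64 + ReLU,
max-pool 2×2/2, conv 3×3×128 + ReLU, fully connected, softmax) implemented
in numpy (forward and backward as offset-slice BLAS products).  Training is
SGD with momentum, `v ← m·v − r·∇`, `w ← w + v`, with learning rate 0.001,
momentum 0.9, mini-batch 28.  The net is trained on *image-level* lesion
class labels; because fixture classes differ only through their lesions, the
class-discriminative signal is spatially confined to the lesion.

**Input standardization.** Images are resized to the input grid (desk-scale
default 64×64; 224×224 remains available) and standardized per image and per
channel.  This choice is load-bearing: after standardization the (majority)
background sits near zero and lesion pixels are large-magnitude deviations,
so third-conv-layer activation magnitude tracks lesion-ness rather than raw
brightness — even before training sharpens it.

**Saliency map.** All 128 third-conv channels are min-max normalized,
averaged, bilinearly upsampled to the input grid, and min-max normalized
again (constant channels map to zero).  The map is homogenized over SLIC
superpixels computed on the (enhanced) image — each superpixel takes its
mean saliency — then binarized at its arithmetic mean τ with strict `>`
(ties → background).  Default 200 superpixels, configurable.

**Cleanup and contour.** Holes are filled and only the largest connected
component is kept (one component, no holes, by construction).  The final
mask is the morphological Chan–Vese evolution (50 iterations, smoothing 1)
of that mask, run on the *original* image: the upsampled conv grid carries a
receptive-field halo of roughly the kernel footprint around the true
boundary, and the region-based contour removes it.  Refinement on the
original rather than the enhanced image matters for small low-contrast
lesions, whose enhanced neighborhoods are smeared into mid-tones that give
the contour no region contrast; the contour is skipped entirely when the
initial inside/outside gray means differ by less than 0.02 (a flat image
offers no evidence to move the boundary).

**Evaluation.** Pixel accuracy (%), error = 100 − accuracy (an exact
identity), and Dice = 2TP/(2TP+FP+FN), averaged unweighted over images.

## Feature extraction (`lesionkit.features`)

Class balancing cycles deterministically through six variants per original —
identity, horizontal flip, vertical flip, and the transposes of all three —
until each class reaches the target count exactly; a target above 6× the
available originals is rejected.  Features are global-average-pooled
activations of a backbone behind one interface: the built-in tiny CNN
(128-d) is the desk-scale default; `resnet101`/`densenet201` name pretrained
networks that require an optional deep-learning dependency and raise an
actionable error without it.  The interface reports whatever width a
backbone emits and hard-codes none.  Stratified splitting keeps per-class
proportions within one sample; a singleton class goes to train with a
warning.

## Wrapper selection by moth-flame optimization (`lesionkit.imfo`)

A moth's continuous position vector (clipped to [−4, 4]) is binarized into a
feature gate and scored by

    fitness = r·Error + (1 − r)·|selected|/Dim,

with Error the misclassification rate of a cubic-polynomial-kernel SVM
(one-vs-all) on a single seeded stratified 30% hold-out of the training
partition, using the gated columns only.  `r` defaults to 0.9 (fixed); a
per-evaluation-random mode exists but the fixed mode is required whenever
results are compared against enumeration.  The all-zero gate scores the
worst value 1.0 without a classifier call.  Hold-out errors are memoized per
unique gate, so with a frozen fitness an exhaustive enumeration and any
number of optimizer runs cost at most 2^Dim − 1 SVM fits in total.

Each iteration: (i) sigmoid mean-gate — gate j opens when σ(position_j)
strictly exceeds the row mean V of σ(position), recomputed every iteration
(V sits in ≈0.4–0.48 for slightly negative-centered positions); (ii)
evaluate and merge into an elitist flame set (best `n_pop` of flames ∪
moths, sorted by fitness); (iii) spiral update per dimension,
`d·e^{b·l}·cos(2πl) + F`, with `d = |F − position|`, `b = 1`, `l` uniform in
[−1, 1], and moth i paired with flame min(i, n_flames−1) under a flame count
shrinking linearly from `n_pop` to 1; (iv) entropy gate on the updated
positions — gate j opens when σ(position_j) strictly exceeds the normalized
Shannon entropy (10 bins on [0, 1], log base 10) of the row's sigmoid
histogram — evaluated as a second candidate, the better of the two gates
kept per moth.  Defaults: population 20, 100 iterations (30 at desk scale).
The recorded best-ever fitness is non-increasing by construction and the
best-ever gate is returned.

The *plain MFO* baseline disables both adaptive gates and binarizes at the
fixed threshold σ(position) > 0.5, isolating the adaptive gates as the only
difference between the two variants.  A position-weighting term
`w·F + (1−w)·F` with w annealed 0.9 → 0.4 appears in the update; with the
pairing term read as the matched flame's position it is algebraically inert
and is kept only as configuration surface.

An exhaustive oracle (guarded to ≤ 15 dimensions) enumerates every nonempty
gate under the frozen fitness, breaking ties toward the lexicographically
smallest gate; it is the reference the optimizer is tested against.

## Correlation fusion (`lesionkit.fusion`)

The narrower of the two selected matrices is padded to the wider one's
width; each padded entry of sample i is the normalized Shannon entropy of
that sample's original feature row (zero-padding available).  Columns are
paired positionally; every pair whose Pearson correlation meets the
threshold (default 0.5, configurable) contributes *both* columns to the
fused matrix, ordered by descending ρ with ties to the lower index — which
is why the fused width k3 (always even) can exceed either input width.
Correlation of a constant column is defined as 0.  Padding columns
participate in the correlation like any other column.  An empty retention
set produces an explicit warning (callers fall back to concatenation).  When
fusion is fitted on a training partition, the recorded (i, j, ρ) pairs are
re-applied verbatim to assemble the test partition.

## KELM (`lesionkit.kelm`)

With one-hot targets T and kernel Gram matrix Ω of the training rows, the
output weights solve `(I/C + Ω)β = T`; a test point scores as
`K(x, X_train)·β` with arg-max decision (ties → earlier class).  The system
is solved through the eigendecomposition of Ω; when the ridge 1/C falls
below the eigenvalue round-off floor (very large C on a rank-deficient
kernel), noise-level directions are dropped, which realizes the C → ∞
least-squares limit instead of amplifying round-off — with a linear kernel
on full-rank data the predictions then coincide with ordinary one-hot
least-squares regression.  Defaults: RBF kernel with the median-distance
bandwidth heuristic (γ = 1/(2·median²)), C = 100.  Reports carry accuracy,
a row-percentage confusion matrix, macro sensitivity (unweighted mean of the
confusion diagonal) and FNR = 100 − sensitivity, an exact identity.

## Synthetic fixtures (`lesionkit.fixtures`)

Lesion images are hard-edged ellipses (no anti-aliasing, so the ground-truth
mask is exact) that are darker and redder than a skin-toned background by a
configurable contrast (gray-level gap = contrast × 255); texture is Gaussian
noise low-pass filtered at σ = 1.5 and rescaled to a target SD (default 6
gray levels); optional hair artifacts are thin dark Bézier polylines
(default 0).  Class identity modulates lesion contrast (0.25–0.55 across
classes, centered on 0.4) and size, so image-level labels carry a
lesion-confined signal for the saliency CNN.  Feature datasets plant
informative columns whose adjacent-class means differ by exactly
`class_separation` noise-SDs (random sign per column); the remaining columns
are pure noise; the informative index set is returned for recovery tests.
The seven-class imbalance shape (327, 541, 1099, 155, 6705, 1113, 142) is
available for scaled-down class directories (proportional rounding, floor
1 per class).  Every generator is a pure function of (spec, seed).

What the fixtures deliberately do not model: photorealistic dermoscopy
statistics, irregular lesion borders, multi-modal lesion pigmentation,
illumination gradients, or annotation noise.  Passing tests therefore
demonstrate that the chain's machinery is correct and well-behaved under
controlled conditions, not that its accuracy transfers to clinical archives.

## Problem sizes and numerical choices

Desk-scale defaults: 64×64 images, 200-image segmentation sets (50/50
train/test), 10 training epochs for the segmentation experiments (the
cross-entropy plateaus there at this scale; an under-trained net leaves
diffuse background saliency that can hand the largest-component rule a
spurious blob), population 20 with 30–50 selection iterations, and
two-class feature sets of 200 samples.  The exhaustive
oracle is used up to 12 of its 15 permitted dimensions (4095 gates).  All
stochastic stages draw from `numpy` generators seeded from a single config
seed; identical configs reproduce identical outputs bit for bit.  Strict
inequalities at thresholds (saliency τ, sigmoid/entropy gates) send ties to
background / non-selection.  Min-max normalization of a constant array is
defined as all zeros throughout.

## Known limitations

* The saliency CNN is a numpy implementation tuned for clarity at desk
  scale; it is single-threaded BLAS and not meant for 224×224 training runs
  of thousands of images.
* On fixtures whose hold-out error saturates at zero, the sparsity term
  alone ranks zero-error subsets, and the optimizer converges to minimal
  subsets whose downstream accuracy can trail denser ones — an intrinsic
  property of the wrapper fitness, discussed with the measured numbers in
  the repository's test suite.
* The enhancement chain can smear very small, low-contrast lesions into
  mid-tones (the Otsu band then cuts inside the background mode); the
  contour refinement on the original image compensates at segmentation
  time.
* Pretrained backbones are interface-only; no download or weight file is
  bundled.
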