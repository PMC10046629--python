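# Methods

## The operational convolution

A self-organized operational neural network (Self-ONN) generalizes the
convolutional layer by letting every connection apply a learned
nonlinear transform of its input. The transform is a polynomial — a
Taylor expansion truncated at order Q around an anchor point `a`. The
networks here use tanh activations, which bound every activation to
[-1, 1] and make 0 the natural anchor, so each connection computes

    psi(w, y) = sum_{q=1..Q} w_q * y^q .

The order-0 Taylor term is constant in the input and is folded into one
bias per output channel (not per tap), which keeps the parameter count
at Q kernel banks plus a bias vector. Summing over a neighborhood gives
the layer form

    out = bias + sum_{q=1..Q} conv2d(x^q, W_q) ,

with `x^q` element-wise: the layer is exactly the sum of Q plain
convolutions of the input's powers, and Q = 1 is a conventional CNN
layer. Because tanh bounds activations, input powers cannot overflow and
no clipping is applied; the first layer sees z-scored images, whose
cubes remain well within float range. Convolution means
cross-correlation (no kernel flip), the deep-learning convention —
immaterial for learned weights. "Same" padding is zero padding.

Each neuron has per-tap polynomial coefficients (bank q holds the
order-q coefficient of every tap). An alternative reading shares one
coefficient vector per neuron across taps; the per-tap form is the
common Self-ONN formulation and is the one implemented.

Weight initialization (not specified in the source material): bank 1 is
fan-in-scaled uniform, U(±1/sqrt(fan_in)); banks q ≥ 2 start at one
tenth of that scale so the layer begins near-linear and higher-order
terms grow in as training finds them useful.

### Differentiability

All layers carry explicit backward passes. The operational layer's
gradients are

    dL/dW_q  = corr(x^q, dL/dout)
    dL/dx    = sum_q q * x^(q-1) * conv_full(dL/dout, W_q^T)

and are verified against central finite differences (float64, relative
error ≤ 1e-4, in practice ~1e-9) for every bank coefficient, the bias
and the input, as are the plain convolution, transposed convolution and
batch-norm layers.

## MSegNet

A U-shaped encoder-decoder cut down to two levels. Encoder block: two
3×3 conv + batch-norm + ReLU stages, then 2×2 max-pool. A bottleneck of
two conv stages at 4× the initial width joins the paths — the
two-pooling topology would otherwise waste the second downsampling, and
the bottleneck is standard for U-shaped networks (it can be read as the
"floor" of the U rather than a third level). Decoder block: 2×2
stride-2 transposed convolution, a conv stage, concatenation with the
matching encoder skip, another conv stage. Channel widths double per
level: 32 → 64 → 128 → 64 → 32 at the default feature width. A final
1×1 convolution maps to two channels under a per-pixel softmax;
probability ties at exactly 0.5 resolve to background (conservative
tumor calls). Batch norm follows every convolution but not the
transposed convolutions (which only resample); running statistics are
frozen at evaluation, so inference is deterministic.

The analytic parameter count for the default configuration is 467,842
(≈0.5 M), enumerated layer by layer and asserted in tests. A reported
headline count of ~8 M is not reachable by a 2-level, 32-feature network
of this shape; the analytic count is the contract.

## BINet

Six blocks of operational convolution (3×3, same padding, Q = 3) → tanh
→ 2×2 max-pool, then a flatten and a single 3-neuron dense layer under
softmax. The first four operational layers have 8 output channels, the
last two 16. Pooling floor-divides odd sizes (7 → 3) — the only
convention under which a 224-px input yields the documented 144-neuron
flatten (224 → 112 → 56 → 28 → 14 → 7 → 3; 3·3·16 = 144). No
normalization layers: tanh already bounds activations. Setting Q = 1
yields the vanilla 6-layer CNN baseline on the identical graph; other
comparison variants (4-layer, extra dense) are expressible through the
configuration but are not first-class models. Training uses categorical
cross-entropy (the standard criterion for a softmax head).

## Synthetic phantoms

The generator emulates reconstructed microwave images of a four-layer
tissue-mimicking head phantom, which are private. It reproduces their
*geometry and reading task*, not their physics:

- head: an ellipse with four concentric intensity rings standing in for
  dura / CSF / gray matter / white matter;
- reconstruction artifacts: a low-spatial-frequency multiplicative
  clutter field (Gaussian-filtered noise, σ = size/16) plus additive
  Gaussian noise (default 0.04 of full scale);
- tumors: Gaussian-profiled disks whose peak sits at 1.8× the 90th
  percentile of the head background (tumors are the dominant
  scatterers); the ground-truth mask is the disk at the profile's
  half-maximum, so mask radius equals the nominal tumor radius exactly;
- rendering: a fixed, injective jet-like piecewise-linear pseudo-color
  transfer to 3 channels, invertible to intensity up to quantization
  (round-trip error < 2e-3), mimicking the heatmap renderings that the
  classifier consumes.

Geometry floors at the 256-px reference size: tumor radius ≥ 10 px
(a 5 mm tumor at 0.2645833333 mm/px) and two-tumor center separation
≥ 38 px (10 mm); both scale proportionally at smaller image sizes so
scaled experiments keep the same relative difficulty. Two-tumor draws
are rejected and resampled until the separation holds (bounded retries).

What passing tests on these phantoms shows: the layers learn, the
cascade is wired correctly, segmentation quality transfers to
classification gains. What they do not show: performance on real
microwave reconstructions, whose intensity statistics, artifact
structure and tumor appearance are unpublished — the generator's
parameters are stated defaults, not calibrated values.

## Augmentation

Three geometric families, drawn jointly into one affine per sample:
rotation 3–50° either direction, scaling 2–15% shrink or enlarge,
translation 3–10% of the frame per axis, either sign. Images warp
bilinearly, masks nearest-neighbor (they stay binary), out-of-frame
pixels are zero. A draw that changes the mask's connected-component
count (tumor pushed out of frame or merged) is rejected and redrawn, so
labels stay correct. Originals are cycled in class-interleaved order,
keeping output class proportions within one sample of the input's; the
default per-fold target is 6000. (A reported per-class breakdown of
1980/2008/2012 follows no stated rule; equal thirds are the default.)
Only the fitting subset is augmented; validation and test stay raw
originals. Whether the full training portion (240) or the
post-validation subset (192) feeds augmentation is ambiguous in the
source; the fixed-target mechanism makes both readings produce the same
count, and the fitting subset is used to keep validation strictly
held out.

## Training

Stratified 5-fold cross-validation after a seeded shuffle: per fold 20%
of each class is test, 20% of the remaining training portion is
validation (for 300 images: 60 / 48 / 192), every sample appearing in
exactly one fold's test set. Images are z-scored per channel with
statistics computed from the fitting originals only — computing them
over all images would leak test statistics, so the leakage-free variant
is used deliberately.

Optimization: Adam at learning rate 5e-4, at most 30 epochs, batch 8
for segmentation and 16 for classification. The monitored quantity is
validation Dice (maximized) for segmentation and validation loss
(minimized) for classification. An epoch improves only if strictly
better than the best so far (min-delta 0). After 10 (segmentation) or
5 (classification) consecutive non-improving epochs the learning rate
is multiplied by 0.2; after 15 / 10 consecutive non-improving epochs
training stops. Fully seeded: a re-run reproduces outputs bit for bit.

Segmentation loss: per-image soft Dice with smoothing ε = 1
(1 − (2Σpg + ε)/(Σp + Σg + ε)), averaged over the *two* softmax
channels and the batch. The two-channel average matters: with the tumor
channel alone, an empty-mask (non-tumor) image contributes a gradient
of order ε/denominator², effectively zero, and the trained network
hallucinated large false-positive blobs on exactly those images (its
per-image Dice was 0 on every non-tumor test image while tumor images
scored 0.86–0.97). The background channel restores a full-strength
penalty on false positives. ε = 1 also keeps empty-vs-empty pairs at
loss 0 rather than 0/0.

Non-tumor images (empty masks) are part of segmentation training — the
network must learn to output empty masks, and the evaluation convention
(below) rewards it.

## Evaluation

Pixel metrics per mask pair: accuracy (TP+TN)/total, IoU TP/(TP+FN+FP),
Dice 2TP/(2TP+FN+FP); the algebraic identity DSC = 2·IoU/(1+IoU) is
asserted per pair. Both masks empty scores IoU = Dice = 1, so correct
empty predictions on non-tumor images are rewarded. Test-set scores are
per-image means (the segmentation norm); a pooled-pixel variant is
available by flag.

Classification metrics come from the 3×3 confusion matrix (rows true,
columns predicted; order non-tumor / single / double), reduced
one-vs-rest per class and averaged with true-class-frequency weights —
the plain mean for balanced classes, in which case weighted recall
equals trace/total accuracy identically. Overall accuracy is
trace/total. One documented discrepancy: for the raw-image worked
example the reported overall accuracy (89.33%) disagrees with its own
confusion matrix, whose counts give 266/300 = 88.67%; the
implementation reports trace/total. The reported weighted F1 of 88.61%
is likewise a rounding artifact (full precision gives 88.6049% → 88.60;
88.61 arises only if per-class precision is rounded before combining).

Internal values are full precision; percentages round to two decimals
only at report time, decimal half-up (so 0.88605 → 88.61, not the
banker's 88.60). Fold statistics: mean and sample STD (ddof = 1) over
folds, two-sided paired t-test against a baseline; zero-variance paired
differences make the test degenerate and are flagged (p = 1 for
identical values, the p → 0 limit for an exactly constant shift).

## The cascade

Superimposition is a hard mask: output pixel = input pixel where the
mask is 1, zero elsewhere, in all channels. An alpha-blend overlay was
rejected because it would leak background texture into the "segmented"
variant. By default the masks come from the fold's own trained MSegNet
(the deployed cascade); a flag substitutes ground-truth masks as an
upper bound — which of the two produced the published segmented-image
results is unstated, so both modes exist. Images are resized (bilinear;
masks nearest) to the classifier's 224-px input. Coordinates are
0-based, row-major, origin top-left.

## Scaled-down experiment sizes

The learning acceptance checks run at reduced size, chosen once: 64-px
phantoms, 60 training originals augmented to 600 (the same ~10×
expansion ratio the full pipeline uses at 192 → 6000), a 16-feature
MSegNet, 10 epochs — reaching held-out per-image Dice ≈ 0.94 — and for
classification 300 augmented images, 10 epochs, 64-px inputs (flatten
16), where the segmented variant beats its raw twin at the same seed
(typically 1.00 vs ~0.73 accuracy). The tiny end-to-end run used for
the reproducibility check is smaller still (48-px images, 2 epochs,
one fold).

## Known limitations

- The generator does not model electromagnetics, beamforming
  reconstruction, or dielectric tissue properties; conclusions about
  real RMW images require real data.
- The per-class augmented-count breakdown and the exact provenance of
  the published segmented-image inputs (predicted vs ground-truth
  masks) are unresolved in the source; both are parameterized.
- The numpy engine is CPU-only and single-threaded by design; it is
  sized for the desk-scale experiments here, not for 6000-image
  full-resolution training.
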