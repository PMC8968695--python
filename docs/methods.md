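# Methods

## Pipeline overview

The package segments kidneys (label 1) and kidney tumors (label 2) in 2D
axial CT slices with a two-stage cascade:

1. **Preparation.** 3D volumes are cut into 2D slices; slices without any
   kidney marker are discarded. Intensities are clipped to the pooled
   [0.5, 99.5] percentile range of the training slices (removing
   metal-artifact-like outlier voxels) and z-scored with the mean and
   standard deviation of the *foreground* (label > 0) pixels. The statistics
   are fit once on the training pool and frozen; training and test data
   receive the identical rule, so there is no test-set leakage.
2. **Coarse stage.** A binary model (kidney ∪ tumor vs background) is
   trained on full preprocessed slices and at inference produces a kidney
   mask whose 8-connected components seed the ROIs.
3. **ROI geometry.** Each component's tight bounding box expands to a square
   window: the small class when both tight sides fit within it, the large
   class otherwise (the large side is twice the small side; defaults
   128/256). Windows are centered on the tight box and translated — never
   shrunk — to stay inside the canvas. Large-class crops are down-scaled to
   the small side (bilinear images, nearest labels) before entering the fine
   model; predictions are up-scaled back by nearest neighbor and pasted onto
   the full-size canvas, larger components first so that smaller, later ROIs
   win inside overlaps.
4. **Fine stage.** A 3-class model operates on enhanced ROI crops. Its
   training crops derive from *ground-truth* masks rather than coarse
   predictions, which decouples the stages and makes unit-level training
   reproducible; the inference path always uses coarse predictions.
5. **Evaluation.** Per-class smoothed Dice, averaged over test images, and
   the composite score (rounded mean of the two class means).

## Fuzzy gray-level enhancement

Membership functions over the normalized gray axis: *dark* is 1 below b1 and
falls linearly to 0 at b2; *bright* is 0 below b2 and rises to 1 at b3;
*gray* is the triangle peaking at b2. Defaults b = (0.15, 0.43, 0.71) with
output singletons (0, 127, 255). Center-of-gravity defuzzification collapses
the three degrees to one output gray.

The closed-form transform is implemented exactly as printed, with the
third-branch offset 0.45 (not 0.43). The resulting jumps at m = 0.43
(127 → ≈108.8) and m = 0.71 (≈236.8 → 255) are properties of the printed
formula and are preserved; tests assert monotonicity only within branches.
The optional `continuous=True` mode replaces the offset with 0.43, which
coincides with the center-of-gravity route. Integer images are enhanced
through a lookup table indexed by raw gray level (8- or 16-bit); float
images are evaluated directly. Integer output uses round-half-to-even.

**Normalization choice.** For standalone images, `enhance_image` normalizes
per image by min–max (the mapping of raw intensities to [0, 1] is otherwise
undefined). Inside the cascade the fine crops are foreground-z-scored
floats, and a per-crop min–max would let a single extreme noise pixel shift
every tissue's gray level from crop to crop; in early experiments this made
tumor-free kidneys indistinguishable from bright-tumor crops. The cascade's
adapter (`training.enhance_for_net`) therefore uses a *fixed* affine map —
the foreground mean (z = 0) is anchored at the gray breakpoint b2 = 0.43 and
8 z-units span the full gray axis — the analogue of a fixed CT display
window. The mapping is identical at training and inference.

## Network

* **R2P block.** One branch per kernel size; each branch is two stacked
  recurrent convolution units. A unit computes `z = conv(x)` then `t`
  accumulation steps `h ← act(norm(conv_r(h) + z))` with `conv_r` shared
  across steps; `t = 0` degenerates to a plain conv-norm-activation layer,
  so a single-kernel block with zeroed residual equals a standard double-conv
  block (asserted in tests). Branch outputs are concatenated and projected
  back to the block width by a 1×1 convolution (skipped for a single
  branch); a 1×1-projected copy of the block input is added as the residual.
* **Attention gate.** The skip feature x and the one-level-coarser decoder
  signal g: g is nearest-upsampled and 3×3-convolved onto x's grid, both are
  1×1-projected to half of x's channels, summed, passed through Leaky-ReLU,
  reduced to one channel, and squashed by the logistic function into a map
  in (0, 1) multiplying x. Zeroing the final projection yields exactly 0.5·x.
* **U shape.** `depth` encoder levels (R2P block + 2×2 max pooling), a
  bottleneck block with dropout, symmetric decoder levels (nearest ×2
  upsampling + 3×3 conv, attention-gated skip concatenation, R2P block), and
  a 1×1 classification head. The bottleneck side is
  `input_size / 2^depth` — e.g. input 128 at depths 4/5/6 gives 8/4/2.
* **Defaults and open choices.** Recurrence `t = 2` (family convention;
  unstated in the source method), base filters 32 doubling per level
  (channel widths unstated), batch normalization after every convolution and
  dropout 0.2 at the bottleneck (reading "a 20% batch normalization layer"
  as a dropout rate), conv → norm → activation ordering, Leaky-ReLU slope
  0.01, max-pool down / nearest-up sampling. All are configurable.
* **Implementation.** Layers run on a small reverse-mode autodiff tape over
  NumPy float32 arrays: 'same'-padded stride-1 convolution via im2col + GEMM
  (the column matrix is materialized once and reused for the weight
  gradient; the input gradient uses a k² shift scatter-add), 2×2 max pooling
  with argmax routing, nearest upsampling, broadcast arithmetic with
  gradient unbroadcasting, and a numerically stabilized log-softmax/logistic.
  Every primitive's gradient is checked against central finite differences
  in the test suite. Weight sharing in recurrent units is handled by
  gradient accumulation on the tape.

## Training

Adam (lr 0.001, batch 8), seeded shuffled batches that cycle through the
dataset, loss = soft Dice (smooth 1, averaged over classes) + pixel-wise
cross-entropy. The loss choice is a package decision: the evaluation metric
is Dice-based, and the Dice term stabilizes learning of small structures
while cross-entropy stabilizes early training. Training is deterministic
given the config seed on a fixed platform. Full-scale defaults are 500 steps
per epoch × 100 epochs; the committed **desk profile** uses 96-pixel
phantoms, depth-3 networks with 8 base filters and single-kernel R2P blocks
(t = 1), ROI classes 48/96, coarse 4×40 and fine 5×80 steps — chosen so the
whole cascade trains in minutes on a single CPU while exercising every
architectural element on its real code path. The coarse stage converges much
earlier than the fine stage, hence the asymmetric step split.

## Synthetic phantoms

Each slice contains one or two bright rotated-ellipse kidneys (intensity
0.55 ± 0.05 vs background 0.15, arbitrary units) on a noisy background
(Gaussian σ = 0.04); a kidney may embed a disk-shaped tumor, darker (0.32)
or brighter (0.85) than parenchyma, with its pixel area drawn from the
configured range and the disk placed strictly inside the ellipse; a small
fraction (0.2 %) of isolated pixels is set to extreme values (−2.0 / +3.0)
so percentile clipping has artifacts to remove. Kidney axes scale with the
requested tumor area so every configuration is geometrically feasible; a
two-kidney layout falls back to one kidney when the canvas is too small.
Output is a pure function of the config seed.

What the phantoms do **not** emulate: anatomical shape variability, partial
volume effects, Hounsfield-unit physics, organ neighbors that mimic kidney
texture, low-contrast or infiltrating tumors, and inter-slice 3D continuity.
Passing the desk-scale benchmark therefore demonstrates that the pipeline's
mechanics (localization, ROI geometry, enhancement, balancing, optimization,
evaluation) are correct and trainable — not clinical-grade performance on
real CT.

## Numerical choices and degenerate inputs

* Percentiles use linear interpolation between order statistics (pinned for
  reproducibility).
* Composite-score rounding is half-to-even at 3 decimals in *decimal*
  arithmetic on the printed values: (0.948 + 0.911)/2 = 0.9295 must round to
  0.930, while the binary double nearest 0.9295 is slightly below the tie.
* Kidney Dice counts label 1 only by default (tumor pixels are not kidney);
  a `union` mode scoring label > 0 is provided, as the per-class convention
  is ambiguous in the source description.
* Constant images cannot be min–max normalized: enhancement passes them
  through with a warning. Constant foreground (zero variance) and empty
  sample pools raise dedicated errors, as do all-zero membership vectors.
* Oversized components (tight box beyond the large ROI class) still receive
  the large window; content is handled by the rescale step. Window sizes
  other than the two classes cannot escape `expand_roi`.
* Balancing bins a sample by its total tumor pixel count; augmented shifts
  that would clip tumor pixels off the patch are rejected and resampled.
  Bins empty in the source histogram stay empty (there is nothing to copy).

## Known limitations

* CPU-only NumPy training: practical for the desk profile, not for
  512×512-scale training with full channel widths.
* 2D slices only; no volumetric variants or cross-slice ROI tracking.
* Attention gates require the gating signal to be exactly equal to or half
  the skip's spatial side.
* The large ROI class must be exactly twice the small class (integer-factor
  rescale).
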