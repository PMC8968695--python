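# renalseg

Coarse-to-fine kidney tumor segmentation for contrast-enhanced abdominal CT
slices, built around four ideas:

1. **Fuzzy-set gray-level enhancement.** Each pixel's normalized gray level
   `m ∈ [0, 1]` is fuzzified into *dark / gray / bright* membership degrees
   (breakpoints 0.15, 0.43, 0.71) and defuzzified by the center-of-gravity
   rule `v₀ = (μ_d·v_d + μ_g·v_g + μ_b·v_b) / (μ_d + μ_g + μ_b)` with output
   singletons 0 / 127 / 255 — dark pixels are darkened, bright pixels
   brightened. The closed-form piecewise transform (including its
   discontinuities at m = 0.43 and 0.71, which stem from a 0.45 offset in
   the third branch) is implemented literally; a repaired `continuous` mode
   is available behind a flag.
2. **FR2PAttU-Net.** A U-shaped encoder-decoder whose double-conv blocks are
   recurrent-residual *parallel* convolution (R2P) blocks — one branch per
   kernel size (3×3, optionally 5×5), each branch two stacked recurrent
   convolution units with weight sharing across `t` accumulation steps, a
   1×1 projection after channel concatenation, and a 1×1-projected residual
   — with attention gates on the skip connections and Leaky-ReLU
   activations. Implemented from scratch on NumPy with a small reverse-mode
   autodiff engine (im2col convolution, max pooling, nearest upsampling,
   batch normalization, Adam); no deep-learning framework required.
3. **Coarse→fine ROI cascade.** A binary (kidney ∪ tumor vs background)
   model localizes kidneys on full slices; each 8-connected component's
   tight bounding box is expanded to a square window — 128² when both sides
   fit in 128 pixels, 256² otherwise — translated to stay inside the canvas,
   cropped, enhanced, segmented into background/kidney/tumor by the fine
   model, and pasted back onto the full-size canvas.
4. **Tumor-size rebalancing.** The tumor-area histogram of the fine-stage
   training crops is equalized by appending augmented copies (flips,
   right-angle rotations, shifts, diagonal mirroring) of under-represented
   size bins.

Evaluation uses the smoothed Dice coefficient
`D = (2|A∩B| + 1) / (|A| + |B| + 1)` per class and the leaderboard-style
composite score, the 3-decimal-rounded mean of the kidney and tumor Dice.

A deterministic synthetic-phantom generator (bright rotated-ellipse kidneys,
embedded contrasting tumor disks, Gaussian noise, extreme-intensity artifact
pixels) makes the entire pipeline trainable and testable on one CPU in
minutes, with no dataset download.

## Worked example

```python
import numpy as np
from renalseg import (PhantomConfig, generate_slice_dataset, desk_profile,
                      train_cascade, evaluate)

phantom, cascade = desk_profile(seed=1)          # 96x96 slices, depth-3 nets
train = generate_slice_dataset(300, phantom)
held_out = generate_slice_dataset(
    60, PhantomConfig(**{**phantom.__dict__, "seed": phantom.seed + 9999}))

model = train_cascade(train, cascade, seed=1)    # ~7 min on one CPU
preds = [model.segment(s.image) for s in held_out]
report = evaluate(preds, [s.label for s in held_out])
print(report.kidney_dice_mean, report.tumor_dice_mean, report.composite)
```

prints (exactly reproducible with these seeds):

```
0.9872... 0.9294... 0.958
```

i.e. on 60 held-out synthetic slices the cascade recovers kidneys with mean
smoothed Dice 0.987 and tumors with 0.929; the composite score is their
rounded mean. The smoothed-Dice arithmetic itself:

```python
from renalseg import composite_score, dice_smoothed
composite_score(0.948, 0.911)   # -> 0.930
dice_smoothed(np.zeros((4, 4)), np.zeros((4, 4)))  # both empty -> 1.0
```

The same pipeline is scriptable from the shell:

```bash
renalseg init-config --out desk.yaml
renalseg pipeline --config desk.yaml --out run/ --mode all
renalseg enhance slice.png enhanced.png
```

Stages write manifests keyed by the config hash, so re-running a completed
stage with an unchanged configuration is a no-op.

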