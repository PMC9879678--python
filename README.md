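# emdeblur

Blind deblurring of serial scanning-electron-microscopy (sSEM) micrographs
with a semisupervised GAN, for connectomics preprocessing.

During months-long automated sSEM acquisition of brain tissue, autofocus
and autostigmation occasionally fail, leaving tiles blurred by underfocus,
overfocus, astigmatism, or both.  Re-imaging is impractical, and blurry
tiles wreck downstream neuron segmentation.  `emdeblur` restores such
images blindly — no knowledge of the blur kernel — and is trainable from a
small set of paired (blurry, clear) images plus an *unpaired* bank of
blurry-only images, the situation a real acquisition actually leaves you
in.

## Method

A blurry image is modeled as `z = k ∗ x + η`.  The generator G is a
five-scale pyramid encoder followed by a two-stage decoder: a coarse
top-down pass (upsample + 1×1-reduced encoder skips), then a triangular
grid of fifteen feature nodes `X[i,j]` (`i ∈ {0..4}`, `j ≤ 5−i`) in which
each node refines its same-scale predecessor with features upsampled from
the two immediately coarser scales of the previous step — high-resolution
detail is re-decoded five times instead of once.  A Tanh head predicts a
bounded residual added to the input.  The critic D is a least-squares
patch discriminator (4×4 stride-2 stages, instance norm, LeakyReLU) seeing
only differentiably augmented images `T(·)` (color/translation/cutout).
G minimizes

    L_G = L_c + 0.1·L_adv + 0.01·L_us + 0.02·L_p

with L1 content loss, a frozen-backbone perceptual loss, the least-squares
adversarial term `(D(T(ẑ_s)) − 1)²`, and the semisupervised term
`(D(T(ẑ_s)) − D(T(ẑ_u)))²` that pulls deblurred *unpaired* images toward
the score distribution of deblurred *supervised* images.  D minimizes
`½(D(T(x)) − 1)² + ½ D(T(ẑ_s))²` (coding: fake 0, real 1).  Both networks
train with momentum SGD under a linear learning-rate warm-up.

Because no deep-learning framework is assumed, the networks run on a small
reverse-mode autodiff engine over numpy that ships with the package; every
operator is finite-difference tested.  A synthetic phantom module
(myelinated-axon cross-sections under parametric defocus/astigmatism
kernels and seeded noise) makes the whole pipeline trainable and testable
with no external data.  See `docs/methods.md` for the full account.

## Worked example

```
$ python examples/train_tiny_deblurrer.py
steps trained:          250
held-out PSNR  blurry:   25.13 dB
held-out PSNR  deblur:   31.25 dB   (gain +6.11 dB)
held-out SSIM  blurry:   0.840
held-out SSIM  deblur:   0.946   (gain +0.106)
```

A scaled-down generator (8 base channels) trained for 250 SGD steps on
48×48 crops of synthetic defocus-blurred phantoms recovers ~6 dB of
held-out PSNR relative to the blurry inputs: the model learned to undo
the defocus kernel, not to copy its input.  The other examples cover
phantom simulation (`simulate_phantoms.py`), the loss arithmetic
(`loss_anatomy.py`), and segmentation agreement metrics
(`segmentation_metrics.py`).

Library use in three lines:

```python
import emdeblur as ed
trainer = ed.load_checkpoint("run/checkpoint_0000250.npz")
restored = ed.deblur_field(trainer.G, blurry_array)  # [0,1] 2-D array
```

Large micrographs are processed in overlapping feather-blended tiles
(`ed.TilingPlan`).  A thin CLI wraps the same calls:
`emdeblur simulate|train|deblur|evaluate --help`.

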