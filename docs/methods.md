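# Methods

## Problem and formation model

Serial scanning-EM acquisition of brain tissue runs for months under
autofocus/autostigmation control; a fraction of tiles comes out blurred by
underfocus, overfocus, astigmatism, or both, and re-imaging is impractical.
A blurry micrograph is modeled linearly as

    z = k * x + eta,

where `x` is the latent clear image, `k` a parametric point-spread
function, `*` convolution and `eta` additive noise.  The package restores
`x` blindly (no access to `k` at inference) with a conditional GAN trained
on a small supervised bank of (blurry, clear) pairs plus an unpaired bank
of blurry-only images.

## Generator

A five-scale pyramid encoder (stride-2 convolutions between scales,
normalization-free lightweight residual blocks within a scale, instance
normalization at each scale's output) feeds a two-stage decoder:

1. **Coarse decoding** — a top-down pass; each finer map is the upsampled
   coarser map plus a 1x1-reduced encoder skip.  These five maps form
   column `j = 1` of the decoding grid and receive no further processing.
2. **Progressive decoding** — a triangular grid of nodes `X[i, j]`,
   `i ∈ {0..4}` (0 = full resolution), `1 ≤ j ≤ 5 − i`: fifteen nodes,
   (5, 4, 3, 2, 1) per scale.  Node `(i, j)` is produced by a hybrid
   feature extractor (HFE): features from the two immediately coarser
   scales at the previous step, `(i+1, j−1)` and `(i+2, j−1)`, are
   upsampled (x2, x4), concatenated with the same-scale predecessor
   `(i, j−1)`, convolved, added to the predecessor through a skip
   connection, and passed through a final residual convolution block.
   Where a coarser node falls outside the triangle it is simply omitted.
   High-resolution features are thereby refined five times rather than
   once, each time re-infused with coarse context.

A 3x3 head convolution and a Tanh produce a bounded residual added to the
input (global residual).  Consequences used by the tests: a zero-weight
generator is the exact identity, and `|output − input| ≤ 1` everywhere.

The grid wiring deserves a note: the source description indexes the
coarser inputs at the *same* step, which is unsatisfiable at the triangle
boundary under `j ≤ 5 − i`; consuming the previous step's coarser nodes is
the unique wiring consistent with that constraint and with progressive
coarse-to-fine decoding, and is what this package implements.

Channel widths (default 32·(1, 2, 4, 8, 8)), residual-block depth (2 per
scale) and the upsampler (bilinear + 3x3 convolution; nearest and
zero-stuffed transposed variants available) are configurable; published
accounts of this architecture do not pin them down.  All test and
reference configurations shrink `base_channels`, never the five-scale
structure.

## Discriminator and objectives

The critic is a patch discriminator: `n_layers` stages of 4x4 stride-2
convolution + instance normalization (skipped in the first stage) +
LeakyReLU(0.2), then a linear 1-channel head; no output nonlinearity.
Losses use the least-squares coding a = 0 (fake), b = c = 1:

    L_D   = 1/2 E[(D(T(x)) − 1)^2] + 1/2 E[D(T(ẑ_s))^2]
    L_adv = E[(D(T(ẑ_s)) − 1)^2]
    L_us  = E[(D(T(ẑ_s)) − D(T(ẑ_u)))^2]
    L_c   = E|x − ẑ_s|
    L_p   = ||phi(x) − phi(ẑ_s)||^2 / (C·H·W)
    L_G   = L_c + 0.1·L_adv + 0.01·L_us + 0.02·L_p

`ẑ_s`, `ẑ_u` are generator outputs for supervised and unpaired blurry
inputs.  `L_us` pulls the *deblurred unpaired* images toward the critic
score distribution of *deblurred supervised* images — not toward real
clears, which would let the critic separate the two banks instead of the
two distributions.  When the two banks' score populations have different
shapes, batch means are compared (the loss is written over expectations);
an empty bank makes the term 0, degenerating to a plain supervised
least-squares GAN — a degeneration the tests assert bitwise.

`phi` is a frozen feature backbone behind a pluggable contract
(deterministic image → C×H×W features).  The shipped default is a
fixed-seed random three-stage conv stack: random frozen features are a
known serviceable perceptual-loss basis, the contract accepts any frozen
network (e.g. a pretrained classification slice) where one is available,
and a random backbone keeps the package fully self-contained.

`T(·)` is differentiable augmentation applied to every critic input:
grayscale color jitter (brightness ±0.5, contrast 0.5–1.5, about a
stop-gradient image mean so the pixel gradient is exactly the contrast
factor), integer translation up to 1/8 of the side with zero padding, and
cutout of half the side.  Ranges follow the published defaults of the
data-efficient GAN augmentation method.  Real and fake batches get
independent draws each call.  Cutout below half the side guarantees a
nonzero-gradient region, so `T` never severs the adversarial gradient.

## Training

Momentum SGD (0.9) for both networks under a shared linear warm-up:
lr(step) = peak·min(1, step/warmup), holding at the peak (1e-4 at full
scale) thereafter.  Each step: one critic update on augmented real clears
vs augmented detached supervised outputs, then one generator update on the
four-term objective; critic gradients produced during the generator pass
are explicitly discarded (gradient hygiene is tested).  Supervised and
unpaired batches are drawn independently with replacement; supervised
training augmentation is random cropping plus horizontal/vertical flips
(distinct from `T`, which touches only critic inputs).  Any non-finite
loss aborts the step naming the offending term.  A checkpoint stores both
networks, optimizer velocities, the RNG state and all configs, so a
resumed run reproduces the original loss trace bitwise.

## Synthetic data

The phantom generator emulates osmium-stained corpus-callosum tissue: a
smoothed-noise textured background (level 0.55 ± 0.08), `n_axons`
non-overlapping myelinated axon cross-sections — dark annulus (gray level
0.15) around a lighter textured lumen (0.70) — placed by rejection
sampling, plus per-axon instance labels for segmentation metrics.  Blur
specs cover the acquisition failure modes: underfocus and overfocus as
antialiased defocus discs (overfocus one radius tier wider, factor 1.5;
in a linear intensity model the two defocus signs are otherwise
indistinguishable), astigmatism as an oriented anisotropic Gaussian,
`combined` as their convolution, all normalized to unit mass; noise is
zero-mean seeded Gaussian (a standard SEM read-noise surrogate that keeps
the formation model linear-plus-noise).  Convolution uses reflective
boundaries to avoid dark borders leaking into training.  What the phantoms
do **not** emulate: charging, stitching seams, section-thickness effects,
non-Gaussian detector noise, and the full morphological diversity of real
neuropil (mitochondria, vesicles, vessels).  Passing tests therefore
demonstrate that the mechanism works on the formation model above, not
field performance on real micrographs.

## Scaled-down reference experiments

Full-scale training (256x256 crops, thousands of steps, multi-GPU) is out
of desk-scale reach, so the verification experiments in
`emdeblur.experiments` fix a scaled recipe chosen once: 8 base channels
with multipliers (1, 1, 2, 2, 2) and one residual block per scale; 48x48
crops of 96x96 phantoms with 5 axons; batch 2; 250 steps of SGD with a
50-step warm-up to a 0.01 peak learning rate (a from-scratch schedule
appropriate to the short run; the full-scale peak of 1e-4 presumes a far
longer one); supervised bank of 6 pairs, unpaired bank of 6–8 images,
held-out set of 4 pairs.  The defocus experiment trains on underfocus
(radius 2, noise 0.01) and reports held-out PSNR/SSIM of blurry inputs vs
deblurred outputs.  The domain-shift experiment keeps supervised pairs
pure-defocus but draws the unpaired bank and the held-out set from a
shifted domain (defocus + astigmatism, sigma 2.5/0.8) and compares a
semisupervised run against a supervised-only run at equal steps — a
directional probe of cross-sample generalization, evaluated over seed
majorities, not a numeric reproduction of full-scale results.

## Numerical choices

* Computation runs on an in-package reverse-mode autodiff engine over
  numpy (exactly the operator set the models need); every operator is
  finite-difference tested.  Training uses float32 parameters; gradient
  checks use float64.
* He-style initialization from a per-network seed; the generator head is
  scaled by 0.02 so an untrained model starts near the identity map.
* Instance normalization uses eps = 1e-5; a zero feature map normalizes
  to zero rather than NaN.
* SSIM: 11x11 Gaussian window (sigma 1.5), K1 = 0.01, K2 = 0.03,
  population covariances, valid-interior averaging; PSNR uses data range
  1.0 on unit-scaled images and reports +inf for identical inputs.
* Adapted Rand error: foreground-restricted (ground-truth background
  excluded) pair counting with n·(n−1)/2 pair arithmetic; permutation
  invariant; both-all-singleton partitions score 0 by convention.
* Tiled inference reflect-pads to multiples of 16 and blends overlapping
  tiles with a linear feather ramp (seam suppression); instance-norm
  statistics differ slightly between tile and whole-image passes, so
  tiled and whole outputs agree only near the identity operating point —
  exactly for a zero-weight model.

## Known limitations

* The phantom domain gap (above) means measured gains bound nothing about
  real tissue; the synthetic blur parameters are uncalibrated because the
  physical acquisition parameters of real blurred series are unpublished.
* The unsupervised term compares critic score distributions; its weighted
  gradient is an order of magnitude below the content gradient.  In the
  scaled recipe the two banks' score distributions match within a few
  hundredths after a couple hundred steps, so the term adds little beyond
  mild gradient noise, and the domain-shift comparison sits at or below
  the ~0.3 dB between-run noise floor.  Demonstrating the cross-domain
  advantage appears to require full-scale banks and schedules; the
  package's directional check reports what the scaled recipe actually
  measures.
* The engine is single-threaded CPU; at full 256x256/thousands-of-steps
  scale a compiled framework implementation of the same architecture
  would be required.
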