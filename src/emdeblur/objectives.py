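"""Training objectives of the semisupervised deblurring GAN.

Generator total:  L_G = L_c + lambda_adv * L_adv + lambda_us * L_us
                        + lambda_p * L_p
with L_c the pixel-wise L1 content loss, L_p a frozen-backbone perceptual
loss normalized by feature volume C*H*W, L_adv the least-squares
adversarial term (D(T(z_hat_s)) - 1)^2 and L_us the semisupervised term
(D(T(z_hat_s)) - D(T(z_hat_u)))^2, which pulls the deblurred *unpaired*
images toward the score distribution of deblurred *supervised* images
rather than toward real data — the constraint that makes the unsupervised
bank safe to use when it is unpaired and from a different sample.

Discriminator:  L_D = 1/2 (D(T(x)) - 1)^2 + 1/2 D(T(z_hat_s))^2,
the least-squares critic with the 0-1 coding a = 0 (fake), b = c = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, conv2d


class LossDiverged(RuntimeError):
    """A loss term became non-finite; carries the offending term's name."""


@dataclass(frozen=True)
class LsganCoding:
    """Least-squares GAN label coding: fake a, real b, generator target c."""

    a: float = 0.0
    b: float = 1.0
    c: float = 1.0


@dataclass
class LossWeights:
    lambda_adv: float = 0.1
    lambda_us: float = 0.01
    lambda_p: float = 0.02
    coding: LsganCoding = field(default_factory=LsganCoding)

    def __post_init__(self):
        if min(self.lambda_adv, self.lambda_us, self.lambda_p) < 0:
            raise ValueError("loss weights must be nonnegative")


class RandomFeatureBackbone:
    """Frozen fixed-seed convolutional feature extractor for the
    perceptual loss.

    Three stride-(1,2,2) 3x3 conv + LeakyReLU stages mapping a 1-channel
    image to a C x H/4 x W/4 feature block.  Weights are drawn once from
    the seed and never trained, satisfying the deterministic-frozen
    backbone contract; any other frozen ``image -> features`` callable
    (e.g. a pretrained classification-network slice) can be plugged in
    through the same interface.
    """

    def __init__(self, channels: int = 16, seed: int = 7):
        rng = np.random.default_rng(seed)
        specs = [(1, channels, 1), (channels, channels, 2), (channels, channels, 2)]
        self.weights = []
        self.strides = []
        for cin, cout, stride in specs:
            std = np.sqrt(2.0 / (cin * 9))
            self.weights.append(Tensor(rng.normal(0.0, std, size=(cout, cin, 3, 3))))
            self.strides.append(stride)

    def __call__(self, img: Tensor) -> Tensor:
        f = img
        for w, s in zip(self.weights, self.strides):
            f = conv2d(f, w, stride=s, padding=1).leaky_relu(0.1)
        return f

    def astype(self, dtype) -> "RandomFeatureBackbone":
        for w in self.weights:
            w.data = w.data.astype(dtype)
        return self


class IdentityBackbone:
    """Pass-through backbone (pixel-space 'features'); used in oracles."""

    def __call__(self, img: Tensor) -> Tensor:
        return img


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def content_loss(x, z_hat) -> Tensor:
    """Pixel-wise L1 between the clear image and the deblurred output."""
    x, z_hat = _as_tensor(x), _as_tensor(z_hat)
    if x.shape != z_hat.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {z_hat.shape}")
    return (x - z_hat).abs().mean()


def perceptual_loss(x, z_hat, backbone) -> Tensor:
    """Squared feature-space distance normalized by feature volume C*H*W."""
    x, z_hat = _as_tensor(x), _as_tensor(z_hat)
    fx, fz = backbone(x), backbone(z_hat)
    if fx.shape != fz.shape:
        raise RuntimeError("backbone produced mismatched feature shapes")
    c, h, w = fx.shape[-3], fx.shape[-2], fx.shape[-1]
    diff = fx - fz
    per_image = (diff * diff).sum() / float(c * h * w)
    n_batch = fx.shape[0] if fx.ndim == 4 else 1
    return per_image * (1.0 / n_batch)


def adversarial_loss_G(d_scores_fake_sup, coding: LsganCoding = LsganCoding()) -> Tensor:
    """Least-squares generator term: mean (D(T(z_hat_s)) - c)^2."""
    s = _as_tensor(d_scores_fake_sup)
    d = s - coding.c
    return (d * d).mean()


def unsupervised_loss(d_scores_fake_sup, d_scores_fake_unsup) -> Tensor:
    """Mean squared score gap between deblurred supervised and unpaired
    outputs; batch means are compared when populations differ in size.
    An empty unsupervised bank degrades to 0 (supervised-only fallback)."""
    s = _as_tensor(d_scores_fake_sup)
    if d_scores_fake_unsup is None:
        return Tensor(0.0)
    u = _as_tensor(d_scores_fake_unsup)
    if u.data.size == 0:
        return Tensor(0.0)
    if s.shape == u.shape:
        d = s - u
        return (d * d).mean()
    d = s.mean() - u.mean()
    return d * d


def total_G_loss(l_content: Tensor, l_adv: Tensor, l_us: Tensor, l_p: Tensor,
                 weights: LossWeights) -> Tensor:
    """Weighted four-term generator objective."""
    for name, term in (("content", l_content), ("adversarial", l_adv),
                       ("unsupervised", l_us), ("perceptual", l_p)):
        if not np.all(np.isfinite(_as_tensor(term).data)):
            raise LossDiverged(f"{name} loss is non-finite")
    return (_as_tensor(l_content)
            + weights.lambda_adv * _as_tensor(l_adv)
            + weights.lambda_us * _as_tensor(l_us)
            + weights.lambda_p * _as_tensor(l_p))


def d_loss(d_scores_real_aug, d_scores_fake_sup_aug,
           coding: LsganCoding = LsganCoding()) -> Tensor:
    """Least-squares critic: 1/2 E(D(T(x)) - b)^2 + 1/2 E(D(T(z_hat_s)) - a)^2."""
    r = _as_tensor(d_scores_real_aug)
    f = _as_tensor(d_scores_fake_sup_aug)
    dr = r - coding.b
    df = f - coding.a
    return 0.5 * (dr * dr).mean() + 0.5 * (df * df).mean()
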