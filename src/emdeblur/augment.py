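"""Differentiable augmentation T(.) for discriminator inputs.

Every image shown to the critic — real or generated — passes through a
random composition of grayscale color jitter (brightness shift + contrast
scale about the image mean), integer-pixel translation with zero padding,
and cutout.  All three are differentiable in the pixel values wherever
defined, so adversarial gradients still reach the generator; this is what
lets a least-squares GAN train stably on small supervised banks without
the critic memorizing them.  Real and fake batches receive independent
draws each step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor


@dataclass
class AugPolicy:
    enable_color: bool = True
    enable_translation: bool = True
    enable_cutout: bool = True
    brightness_range: float = 0.5
    contrast_range: tuple[float, float] = (0.5, 1.5)
    translation_fraction: float = 0.125
    cutout_fraction: float = 0.5

    def __post_init__(self):
        if not (0.0 <= self.translation_fraction <= 0.5):
            raise ValueError("translation_fraction must lie in [0, 0.5]")
        if not (0.0 <= self.cutout_fraction <= 0.5):
            raise ValueError("cutout_fraction must lie in [0, 0.5]")

    @classmethod
    def disabled(cls) -> "AugPolicy":
        return cls(enable_color=False, enable_translation=False, enable_cutout=False)


def apply_color(img: Tensor, brightness: float | np.ndarray,
                contrast: float | np.ndarray) -> Tensor:
    """out = mean + contrast * (img + brightness - mean).

    The per-image spatial mean is treated as a constant, so the gradient
    with respect to the pixels is exactly ``contrast`` everywhere.
    """
    mean = img.data.mean(axis=(-2, -1), keepdims=True)  # stop-gradient
    return Tensor(mean) + contrast * (img + (brightness - mean))


def apply_translation(img: Tensor, shift: tuple[int, int]) -> Tensor:
    """Shift content by (dy, dx) pixels; vacated pixels are zero."""
    dy, dx = int(shift[0]), int(shift[1])
    h, w = img.shape[-2], img.shape[-1]
    if dy == 0 and dx == 0:
        return img
    padded = img.pad2d(max(dy, 0), max(-dy, 0), max(dx, 0), max(-dx, 0))
    return padded.crop2d(max(-dy, 0), max(-dx, 0), h, w)


def apply_cutout(img: Tensor, center: tuple[int, int], size: int) -> Tensor:
    """Zero a size x size square at ``center`` (clipped to the frame)."""
    if size <= 0:
        return img
    h, w = img.shape[-2], img.shape[-1]
    cy, cx = center
    y0, y1 = max(cy - size // 2, 0), min(cy - size // 2 + size, h)
    x0, x1 = max(cx - size // 2, 0), min(cx - size // 2 + size, w)
    mask = np.ones((h, w))
    mask[y0:y1, x0:x1] = 0.0
    return img * Tensor(mask)


def sample_aug(policy: AugPolicy, rng: np.random.Generator,
               height: int, width: int) -> dict:
    """Draw one set of augmentation parameters for a given image size."""
    params: dict = {}
    if policy.enable_color:
        params["brightness"] = rng.uniform(-policy.brightness_range,
                                           policy.brightness_range)
        params["contrast"] = rng.uniform(*policy.contrast_range)
    if policy.enable_translation:
        m_y = int(round(policy.translation_fraction * height))
        m_x = int(round(policy.translation_fraction * width))
        params["shift"] = (int(rng.integers(-m_y, m_y + 1)),
                           int(rng.integers(-m_x, m_x + 1)))
    if policy.enable_cutout:
        params["cutout_size"] = int(round(policy.cutout_fraction * min(height, width)))
        params["cutout_center"] = (int(rng.integers(0, height)),
                                   int(rng.integers(0, width)))
    return params


def apply_aug(img: Tensor, params: dict) -> Tensor:
    """Apply a drawn parameter set: color -> translation -> cutout."""
    out = img
    if "brightness" in params:
        out = apply_color(out, params["brightness"], params["contrast"])
    if "shift" in params:
        out = apply_translation(out, params["shift"])
    if "cutout_size" in params:
        out = apply_cutout(out, params["cutout_center"], params["cutout_size"])
    return out


def T(img: Tensor, policy: AugPolicy, rng: np.random.Generator) -> Tensor:
    """Random differentiable composition color -> translation -> cutout,
    with freshly drawn parameters on every call.

    When two images must be compared under the *same* augmentation (the
    two terms of the unsupervised score-gap loss), draw once with
    :func:`sample_aug` and apply with :func:`apply_aug` instead.
    """
    h, w = img.shape[-2], img.shape[-1]
    return apply_aug(img, sample_aug(policy, rng, h, w))
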