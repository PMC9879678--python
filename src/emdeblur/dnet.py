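"""Least-squares patch discriminator.

A stack of 4x4 stride-2 convolutions with instance normalization and
LeakyReLU, followed by a linear 1-channel head that emits a spatial score
map (no output nonlinearity — the least-squares objective needs unbounded
real scores).  Patch scores are averaged to a scalar when a single
realism score is wanted, which keeps the network input-size agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .autograd import Tensor
from .nn import Conv2d, InstanceNorm2d, Module


@dataclass
class DiscriminatorConfig:
    n_layers: int = 4
    base_channels: int = 64
    leaky_slope: float = 0.2

    def __post_init__(self):
        if self.n_layers < 3:
            raise ValueError("n_layers must be >= 3")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DiscriminatorConfig":
        return cls(**d)


class Discriminator(Module):
    def __init__(self, cfg: DiscriminatorConfig | None = None, seed: int = 0):
        self.cfg = cfg or DiscriminatorConfig()
        rng = np.random.default_rng(seed)
        chans = [1] + [min(self.cfg.base_channels * 2 ** i, 8 * self.cfg.base_channels)
                       for i in range(self.cfg.n_layers)]
        self.convs = [Conv2d(chans[i], chans[i + 1], 4, rng, stride=2, padding=1)
                      for i in range(self.cfg.n_layers)]
        # first stage skips normalization, as is conventional for patch critics
        self.norms = [None] + [InstanceNorm2d(chans[i + 1])
                               for i in range(1, self.cfg.n_layers)]
        self.head = Conv2d(chans[-1], 1, 3, rng)

    def score_map(self, img: Tensor) -> Tensor:
        h, w = img.shape[2], img.shape[3]
        if min(h, w) < 2 ** self.cfg.n_layers:
            raise ValueError("input smaller than the discriminator's downsampling factor")
        f = img
        for conv, norm in zip(self.convs, self.norms):
            f = conv(f)
            if norm is not None:
                f = norm(f)
            f = f.leaky_relu(self.cfg.leaky_slope)
        return self.head(f)

    def score(self, img: Tensor) -> Tensor:
        """Scalar realism score: mean of the patch score map."""
        return self.score_map(img).mean()

    forward = score_map
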