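"""The deblurring generator: pyramid encoder, coarse decoder, and the
progressive hybrid-feature-extractor (HFE) decoding grid.

The decoder is a triangular grid of feature nodes ``X[i, j]`` indexed by
scale ``i`` (0 = full resolution .. 4 = 1/16) and decoding step ``j`` with
``1 <= j <= 5 - i`` — fifteen nodes in all, (5, 4, 3, 2, 1) per scale.
Column ``j = 1`` holds the coarse-decoded features and receives no further
processing; each later node refines its predecessor at the same scale with
features upsampled from the two immediately coarser scales at the previous
step, so high-resolution representation is enriched progressively rather
than in a single top-down pass.  A Tanh head on ``X[0, 5]`` predicts a
bounded residual that is added to the blurry input.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .autograd import Tensor, concat, upsample2d
from .nn import (Conv2d, InstanceNorm2d, Module, ResidualBlock, Sequential,
                 Upsample)

N_SCALES = 5


def grid_nodes() -> list[tuple[int, int]]:
    """Enumerate the (scale, step) node indices of the decoding grid."""
    return [(i, j) for i in range(N_SCALES) for j in range(1, N_SCALES - i + 1)]


@dataclass
class GeneratorConfig:
    base_channels: int = 32
    channel_multipliers: tuple[int, ...] = (1, 2, 4, 8, 8)
    residual_blocks_per_scale: int = 2
    upsample_mode: str = "bilinear"
    norm: str = "instance"

    def __post_init__(self):
        if self.base_channels < 4:
            raise ValueError("base_channels must be >= 4")
        if len(self.channel_multipliers) != N_SCALES:
            raise ValueError("exactly five channel multipliers (five scales)")
        if self.upsample_mode not in ("bilinear", "nearest", "transposed"):
            raise ValueError(f"unknown upsample mode {self.upsample_mode!r}")
        if self.norm not in ("instance", "none"):
            raise ValueError(f"unknown norm {self.norm!r}")

    @property
    def channels(self) -> list[int]:
        return [self.base_channels * m for m in self.channel_multipliers]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["channel_multipliers"] = list(self.channel_multipliers)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        d["channel_multipliers"] = tuple(d["channel_multipliers"])
        return cls(**d)


@dataclass
class NodeGrid:
    """The populated decoder grid; values are NCHW feature tensors."""

    nodes: dict[tuple[int, int], Tensor]
    channels_per_scale: list[int]

    def __post_init__(self):
        expected = set(grid_nodes())
        if set(self.nodes) - expected:
            raise ValueError("grid holds an out-of-range node index")

    @property
    def complete(self) -> bool:
        return set(self.nodes) == set(grid_nodes())

    def nodes_at_scale(self, i: int) -> list[Tensor]:
        return [t for (si, _), t in self.nodes.items() if si == i]


class HfeBlock(Module):
    """Hybrid feature extractor producing node (i, j) of the grid.

    Coarser features from scales i+1 (x2) and, when present, i+2 (x4) are
    upsampled to the target scale and concatenated with the same-scale
    predecessor inside a lightweight (normalization-free) residual block;
    a skip connection adds the predecessor to the convolution of the
    concatenation, and a final residual convolution block follows the sum.
    All-zero weights therefore make the block an exact identity on the
    predecessor.
    """

    def __init__(self, channels: int, coarser_channels: list[int],
                 upsample_mode: str, rng: np.random.Generator):
        self.ups = [
            Upsample(c, channels, 2 ** (k + 1), upsample_mode, rng)
            for k, c in enumerate(coarser_channels)
        ]
        n_in = channels * (1 + len(coarser_channels))
        self.cat_conv = Conv2d(n_in, channels, 3, rng, init_scale=0.2)
        self.out_block = ResidualBlock(channels, rng)

    def forward(self, skip: Tensor, coarser: list[Tensor]) -> Tensor:
        if len(coarser) != len(self.ups):
            raise ValueError("wrong number of coarser inputs for this node")
        parts = [skip] + [up(c) for up, c in zip(self.ups, coarser)]
        y = self.cat_conv(concat(parts, axis=1))
        return self.out_block(skip + y)


class Generator(Module):
    """Blind-deblurring generator G: z (in [-1,1]) -> z + Tanh(head(X[0,5]))."""

    def __init__(self, cfg: GeneratorConfig | None = None, seed: int = 0):
        self.cfg = cfg or GeneratorConfig()
        rng = np.random.default_rng(seed)
        ch = self.cfg.channels
        use_norm = self.cfg.norm == "instance"

        self.in_conv = Conv2d(1, ch[0], 3, rng)
        self.enc_blocks = [
            Sequential(*[ResidualBlock(ch[i], rng)
                         for _ in range(self.cfg.residual_blocks_per_scale)])
            for i in range(N_SCALES)
        ]
        self.enc_norms = [InstanceNorm2d(ch[i]) if use_norm else None
                          for i in range(N_SCALES)]
        self.down = [Conv2d(ch[i], ch[i + 1], 3, rng, stride=2)
                     for i in range(N_SCALES - 1)]

        # coarse decoding: 1x1-reduced encoder skips summed with upsampled
        # coarser decoded features, top-down; moderate init keeps the
        # column-1 features near unit scale
        self.skip_reduce = [Conv2d(ch[i], ch[i], 1, rng, padding=0, init_scale=0.5)
                            for i in range(N_SCALES - 1)]
        self.up_coarse = [Upsample(ch[i + 1], ch[i], 2, self.cfg.upsample_mode, rng,
                                   init_scale=0.5)
                          for i in range(N_SCALES - 1)]

        self.hfe = {}
        for (i, j) in grid_nodes():
            if j == 1:
                continue
            coarser_ch = [ch[i + k] for k in (1, 2)
                          if i + k < N_SCALES and (j - 1) <= N_SCALES - (i + k)]
            self.hfe[(i, j)] = HfeBlock(ch[i], coarser_ch, self.cfg.upsample_mode, rng)
        self._hfe_list = list(self.hfe.values())  # parameter discovery

        # small head init keeps the residual near zero at the start, so an
        # untrained generator is close to the identity map
        self.head = Conv2d(ch[0], 1, 3, rng, init_scale=0.02)

    # -- stages -----------------------------------------------------------

    def encode(self, z: Tensor) -> list[Tensor]:
        """Five-scale pyramid; scale-i features have spatial size /2^i."""
        h, w = z.shape[2], z.shape[3]
        if h % 16 or w % 16:
            raise ValueError("input spatial dims must be divisible by 16; pad required")
        feats = []
        f = self.in_conv(z)
        for i in range(N_SCALES):
            f = self.enc_blocks[i](f)
            e = self.enc_norms[i](f) if self.enc_norms[i] is not None else f
            feats.append(e)
            if i < N_SCALES - 1:
                f = self.down[i](e)
        return feats

    def coarse_decode(self, enc: list[Tensor]) -> dict[tuple[int, int], Tensor]:
        """Top-down pass filling column j=1 of the grid."""
        if len(enc) != N_SCALES:
            raise ValueError("expected five encoder blocks")
        col: dict[tuple[int, int], Tensor] = {(N_SCALES - 1, 1): enc[-1]}
        for i in range(N_SCALES - 2, -1, -1):
            up = self.up_coarse[i](col[(i + 1, 1)])
            red = self.skip_reduce[i](enc[i])
            if up.shape != red.shape:
                raise RuntimeError("coarse-decode shape mismatch")
            col[(i, 1)] = up + red
        return col

    def hfe_step(self, i: int, j: int, skip: Tensor, coarser: list[Tensor]) -> Tensor:
        return self.hfe[(i, j)](skip, coarser)

    def progressive_decode(self, column1: dict[tuple[int, int], Tensor]) -> NodeGrid:
        """Fill the grid in increasing step order; terminal node is X[0,5]."""
        grid = dict(column1)
        for j in range(2, N_SCALES + 1):
            for i in range(N_SCALES):
                if j > N_SCALES - i:
                    continue
                coarser = [grid[(i + k, j - 1)] for k in (1, 2)
                           if (i + k, j - 1) in grid and i + k < N_SCALES
                           and (j - 1) <= N_SCALES - (i + k)]
                grid[(i, j)] = self.hfe_step(i, j, grid[(i, j - 1)], coarser)
        return NodeGrid(grid, self.cfg.channels)

    def forward(self, z: Tensor) -> Tensor:
        grid = self.forward_grid(z)
        return z + self.head(grid.nodes[(0, N_SCALES)]).tanh()

    def forward_grid(self, z: Tensor) -> NodeGrid:
        return self.progressive_decode(self.coarse_decode(self.encode(z)))
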