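"""Tiled inference for micrographs larger than the training resolution.

Real serial-SEM tiles run 1K-3K px while the network trains on small
crops, so large images are processed in overlapping tiles whose outputs
are blended back together — feathered (linear-ramp) weighting by default,
which suppresses visible seams that would corrupt downstream
segmentation.  Images are reflect-padded to a multiple of 16 before the
network and cropped back afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .autograd import Tensor
from .gnet import Generator


@dataclass
class TilingPlan:
    tile: int = 256
    overlap: int = 32
    blend: str = "feather"

    def __post_init__(self):
        if self.tile % 16:
            raise ValueError("tile size must be divisible by 16")
        if not (0 <= self.overlap < self.tile / 2):
            raise ValueError("overlap must satisfy 0 <= overlap < tile/2")
        if self.blend not in ("feather", "average"):
            raise ValueError("blend must be 'feather' or 'average'")


def _pad_to_multiple(img: np.ndarray, m: int = 16) -> tuple[np.ndarray, int, int]:
    h, w = img.shape
    ph, pw = (-h) % m, (-w) % m
    if ph or pw:
        img = np.pad(img, ((0, ph), (0, pw)), mode="reflect")
    return img, h, w


def _forward_unit(G: Generator, img: np.ndarray) -> np.ndarray:
    """Run a [0,1] 2-D array through G (which works on [-1,1] NCHW)."""
    padded, h, w = _pad_to_multiple(img)
    dtype = G.head.weight.data.dtype
    z = Tensor((2.0 * padded[None, None] - 1.0).astype(dtype))
    out = G(z).data.astype(np.float64)[0, 0]
    return np.clip((out[:h, :w] + 1.0) / 2.0, 0.0, 1.0)


def deblur_field(G: Generator, img: np.ndarray,
                 plan: TilingPlan | None = None) -> np.ndarray:
    """Deblur a [0,1] grayscale array, tiling when it exceeds the plan."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale array")
    plan = plan or TilingPlan()
    h, w = img.shape
    if h <= plan.tile and w <= plan.tile:
        return _forward_unit(G, img)

    def starts(length: int) -> list[int]:
        if length <= plan.tile:
            return [0]
        step = plan.tile - plan.overlap
        s = list(range(0, length - plan.tile, step))
        s.append(length - plan.tile)
        return s

    if plan.blend == "feather":
        ramp = np.minimum(np.arange(1, plan.tile + 1),
                          np.arange(plan.tile, 0, -1)).astype(np.float64)
        ramp = np.minimum(ramp, plan.overlap + 1)
        weight = np.outer(ramp, ramp)
    else:
        weight = np.ones((plan.tile, plan.tile))

    acc = np.zeros_like(img)
    wacc = np.zeros_like(img)
    for y0 in starts(h):
        for x0 in starts(w):
            tile = img[y0:y0 + plan.tile, x0:x0 + plan.tile]
            th, tw = tile.shape
            out = _forward_unit(G, tile)
            acc[y0:y0 + th, x0:x0 + tw] += out * weight[:th, :tw]
            wacc[y0:y0 + th, x0:x0 + tw] += weight[:th, :tw]
    return np.clip(acc / wacc, 0.0, 1.0)


def deblur_image(path: str | Path, checkpoint: str | Path,
                 plan: TilingPlan | None = None,
                 out_path: str | Path | None = None) -> Path:
    """Deblur an image file with a trained checkpoint; preserves bit depth."""
    from .imgio import read_gray, write_gray
    from .trainer import load_checkpoint

    path = Path(path)
    img, bitdepth = read_gray(path)
    trainer = load_checkpoint(checkpoint)
    out = deblur_field(trainer.G, img, plan)
    if out_path is None:
        out_path = path.with_name(path.stem + "_deblurred" + path.suffix)
    write_gray(out_path, out, bitdepth=bitdepth)
    return Path(out_path)
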