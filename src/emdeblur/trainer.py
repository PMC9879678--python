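"""Alternating generator/discriminator optimization with a supervised
paired bank and an unpaired blurry bank.

Each step: (1) the generator deblurs a supervised batch and, when a bank
is present, an unsupervised batch; (2) the critic takes one (or more)
least-squares updates on augmented real clears vs augmented detached
deblurred supervised outputs; (3) the generator takes one update on the
weighted content + perceptual + adversarial + unsupervised objective.
Both networks use momentum SGD under a shared linear warm-up learning
rate.  All randomness — batch sampling, crops/flips, augmentation draws —
flows from a single seeded generator whose state is checkpointed, so a
resumed run reproduces the original loss trace bitwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .augment import AugPolicy, T, apply_aug, sample_aug
from .autograd import Tensor
from .dnet import Discriminator, DiscriminatorConfig
from .gnet import Generator, GeneratorConfig
from .nn import SGD
from .objectives import (LossDiverged, LossWeights, RandomFeatureBackbone,
                         adversarial_loss_G, content_loss, d_loss,
                         perceptual_loss, total_G_loss, unsupervised_loss)
from .quality import psnr, ssim
from .simdata import SynthDataset
from .tiling import deblur_field


@dataclass
class TrainConfig:
    batch_size: int = 2
    crop_size: int = 256
    peak_lr: float = 1e-4
    momentum: float = 0.9
    warmup_steps: int = 1000
    total_steps: int = 0
    d_steps_per_g_step: int = 1
    eval_interval: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.peak_lr <= 0:
            raise ValueError("peak_lr must be positive")
        if self.crop_size % 16:
            raise ValueError("crop_size must be divisible by 16")
        if self.warmup_steps < 1:
            raise ValueError("warmup_steps must be >= 1")


def warmup_lr(step: int, cfg: TrainConfig) -> float:
    """Linear ramp from peak_lr/warmup_steps, reaching peak_lr at
    ``warmup_steps`` and constant thereafter."""
    if step < 0:
        raise ValueError("step must be nonnegative")
    return cfg.peak_lr * min(1.0, max(step, 1) / cfg.warmup_steps)


@dataclass
class TrainResult:
    losses: list[dict]
    eval_history: list[dict]
    generator: Generator
    discriminator: Discriminator


class Trainer:
    def __init__(self, train_cfg: TrainConfig | None = None,
                 gen_cfg: GeneratorConfig | None = None,
                 disc_cfg: DiscriminatorConfig | None = None,
                 weights: LossWeights | None = None,
                 policy: AugPolicy | None = None,
                 backbone=None, dtype=np.float32):
        self.cfg = train_cfg or TrainConfig()
        self.gen_cfg = gen_cfg or GeneratorConfig()
        self.disc_cfg = disc_cfg or DiscriminatorConfig()
        self.weights = weights or LossWeights()
        self.policy = policy if policy is not None else AugPolicy()
        self.backbone = backbone or RandomFeatureBackbone()
        self.dtype = np.dtype(dtype)
        self.G = Generator(self.gen_cfg, seed=self.cfg.seed).astype(self.dtype)
        self.D = Discriminator(self.disc_cfg, seed=self.cfg.seed + 1).astype(self.dtype)
        if hasattr(self.backbone, "astype"):
            self.backbone.astype(self.dtype)
        self.optG = SGD(self.G.parameters(), self.cfg.peak_lr, self.cfg.momentum)
        self.optD = SGD(self.D.parameters(), self.cfg.peak_lr, self.cfg.momentum)
        self.rng = np.random.default_rng(self.cfg.seed)
        self.step = 0

    # -- single optimization step ----------------------------------------

    def train_step(self, sup_z: np.ndarray, sup_x: np.ndarray,
                   unsup_z: np.ndarray | None = None) -> dict:
        """One alternating D/G update on NCHW batches in [-1, 1]."""
        lr = warmup_lr(self.step, self.cfg)
        sup_z = np.asarray(sup_z, dtype=self.dtype)
        x = Tensor(np.asarray(sup_x, dtype=self.dtype))
        n_sup = len(sup_z)
        if unsup_z is not None and len(unsup_z):
            # one generator pass over both banks (they share the network)
            both = self.G(Tensor(np.concatenate(
                [sup_z, np.asarray(unsup_z, dtype=self.dtype)])))
            zhat_s = both.crop_batch(0, n_sup)
            zhat_u = both.crop_batch(n_sup, len(unsup_z))
        else:
            zhat_s = self.G(Tensor(sup_z))
            zhat_u = None

        fake_detached = zhat_s.detach()
        ld_val = None
        for _ in range(self.cfg.d_steps_per_g_step):
            real_scores = self.D.score_map(T(x, self.policy, self.rng))
            fake_scores = self.D.score_map(T(fake_detached, self.policy, self.rng))
            ld = d_loss(real_scores, fake_scores, self.weights.coding)
            if not np.isfinite(ld.data):
                raise LossDiverged("discriminator loss is non-finite")
            self.optD.zero_grad()
            ld.backward()
            self.optD.step(lr)
            ld_val = float(ld.data)

        sup_scores = self.D.score_map(T(zhat_s, self.policy, self.rng))
        lc = content_loss(x, zhat_s)
        lp = perceptual_loss(x, zhat_s, self.backbone)
        ladv = adversarial_loss_G(sup_scores, self.weights.coding)
        if zhat_u is not None:
            # the score-gap term compares the two banks under ONE shared
            # augmentation draw, so the gap reflects content rather than
            # augmentation misalignment
            params = sample_aug(self.policy, self.rng,
                                zhat_s.shape[2], zhat_s.shape[3])
            lus = unsupervised_loss(
                self.D.score_map(apply_aug(zhat_s, params)),
                self.D.score_map(apply_aug(zhat_u, params)))
        else:
            lus = unsupervised_loss(sup_scores, None)
        lg = total_G_loss(lc, ladv, lus, lp, self.weights)
        self.optG.zero_grad()
        self.optD.zero_grad()
        lg.backward()
        self.optG.step(lr)
        self.optD.zero_grad()  # critic grads from the G pass are discarded

        self.step += 1
        return {
            "step": self.step,
            "lr": lr,
            "content": float(lc.data),
            "perceptual": float(lp.data),
            "adversarial": float(ladv.data),
            "unsupervised": float(lus.data),
            "generator_total": float(lg.data),
            "discriminator": ld_val,
        }

    # -- data plumbing ----------------------------------------------------

    def _crop_pair(self, z: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        c = self.cfg.crop_size
        h, w = z.shape
        if h < c or w < c:
            raise ValueError("images smaller than crop_size")
        y0 = int(self.rng.integers(0, h - c + 1))
        x0 = int(self.rng.integers(0, w - c + 1))
        zc, xc = z[y0:y0 + c, x0:x0 + c], x[y0:y0 + c, x0:x0 + c]
        if self.rng.random() < 0.5:
            zc, xc = zc[::-1], xc[::-1]
        if self.rng.random() < 0.5:
            zc, xc = zc[:, ::-1], xc[:, ::-1]
        return zc.copy(), xc.copy()

    def _sample_batches(self, ds: SynthDataset):
        n = self.cfg.batch_size
        zs, xs = [], []
        for _ in range(n):
            i = int(self.rng.integers(len(ds.pairs)))
            z, x = self._crop_pair(ds.pairs[i][0].pixels, ds.pairs[i][1].pixels)
            zs.append(z)
            xs.append(x)
        sup_z = 2.0 * np.stack(zs)[:, None] - 1.0
        sup_x = 2.0 * np.stack(xs)[:, None] - 1.0
        unsup = None
        if ds.unsup:
            us = []
            for _ in range(n):
                i = int(self.rng.integers(len(ds.unsup)))
                u, _ = self._crop_pair(ds.unsup[i].pixels, ds.unsup[i].pixels)
                us.append(u)
            unsup = 2.0 * np.stack(us)[:, None] - 1.0
        return sup_z, sup_x, unsup

    # -- full runs --------------------------------------------------------

    def evaluate(self, heldout: list[tuple[np.ndarray, np.ndarray]]) -> dict:
        """Mean PSNR/SSIM of deblurred held-out blurry images vs clears."""
        ps, ss, pb, sb = [], [], [], []
        for blurry, clear in heldout:
            deb = deblur_field(self.G, blurry)
            ps.append(psnr(clear, deb))
            ss.append(ssim(clear, deb))
            pb.append(psnr(clear, blurry))
            sb.append(ssim(clear, blurry))
        return {
            "step": self.step,
            "psnr_deblurred": float(np.mean(ps)),
            "ssim_deblurred": float(np.mean(ss)),
            "psnr_blurry": float(np.mean(pb)),
            "ssim_blurry": float(np.mean(sb)),
        }

    def fit(self, ds: SynthDataset,
            heldout: list[tuple[np.ndarray, np.ndarray]] | None = None,
            out_dir: str | Path | None = None) -> TrainResult:
        if not ds.pairs:
            raise ValueError("supervised bank is empty")
        out_dir = Path(out_dir) if out_dir is not None else None
        log_fh = None
        if out_dir is not None:
            out_dir.mkdir(parents=True, exist_ok=True)
            save_checkpoint(out_dir / "checkpoint_init.npz", self)
            log_fh = open(out_dir / "losses.jsonl", "a")
        losses: list[dict] = []
        evals: list[dict] = []
        try:
            for _ in range(self.cfg.total_steps):
                sup_z, sup_x, unsup = self._sample_batches(ds)
                rec = self.train_step(sup_z, sup_x, unsup)
                losses.append(rec)
                if log_fh is not None:
                    log_fh.write(json.dumps(rec) + "\n")
                if (heldout and self.cfg.eval_interval
                        and self.step % self.cfg.eval_interval == 0):
                    evals.append(self.evaluate(heldout))
        finally:
            if log_fh is not None:
                log_fh.close()
        if heldout and (not evals or evals[-1]["step"] != self.step):
            evals.append(self.evaluate(heldout))
        if out_dir is not None:
            save_checkpoint(out_dir / f"checkpoint_{self.step:07d}.npz", self)
        return TrainResult(losses, evals, self.G, self.D)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(path: str | Path, trainer: Trainer) -> None:
    meta = {
        "step": trainer.step,
        "train_cfg": asdict(trainer.cfg),
        "gen_cfg": trainer.gen_cfg.to_dict(),
        "disc_cfg": trainer.disc_cfg.to_dict(),
        "weights": {"lambda_adv": trainer.weights.lambda_adv,
                    "lambda_us": trainer.weights.lambda_us,
                    "lambda_p": trainer.weights.lambda_p},
        "policy": asdict(trainer.policy),
        "rng_state": trainer.rng.bit_generator.state,
    }
    arrays = {}
    for k, v in trainer.G.state_dict().items():
        arrays[f"G::{k}"] = v
    for k, v in trainer.D.state_dict().items():
        arrays[f"D::{k}"] = v
    for i, v in enumerate(trainer.optG.velocity):
        arrays[f"optG::{i}"] = v
    for i, v in enumerate(trainer.optD.velocity):
        arrays[f"optD::{i}"] = v
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path: str | Path, backbone=None) -> Trainer:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        arrays = {k: data[k] for k in data.files if k != "__meta__"}
    cfg = TrainConfig(**meta["train_cfg"])
    trainer = Trainer(cfg,
                      GeneratorConfig.from_dict(meta["gen_cfg"]),
                      DiscriminatorConfig.from_dict(meta["disc_cfg"]),
                      LossWeights(**meta["weights"]),
                      AugPolicy(**{**meta["policy"],
                                   "contrast_range": tuple(meta["policy"]["contrast_range"])}),
                      backbone=backbone)
    trainer.G.load_state_dict({k.split("::", 1)[1]: v for k, v in arrays.items()
                               if k.startswith("G::")})
    trainer.D.load_state_dict({k.split("::", 1)[1]: v for k, v in arrays.items()
                               if k.startswith("D::")})
    trainer.optG.velocity = [arrays[f"optG::{i}"].copy()
                             for i in range(len(trainer.optG.params))]
    trainer.optD.velocity = [arrays[f"optD::{i}"].copy()
                             for i in range(len(trainer.optD.params))]
    trainer.rng.bit_generator.state = meta["rng_state"]
    trainer.step = meta["step"]
    return trainer
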