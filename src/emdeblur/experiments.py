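"""Scaled-down reference experiments on synthetic phantoms.

Full-scale training of this model is a multi-GPU undertaking; these
recipes shrink the network (8 base channels), the crops (48 px of 96 px
phantoms) and the schedule (a few hundred momentum-SGD steps with a short
warm-up to a 0.01 peak learning rate) until a run fits in minutes on one
CPU core, while keeping the architecture, losses and training loop
exactly as in full-scale use.  They are the basis of the package's
verification experiments and of the worked examples.

Two experiments are provided:

* ``defocus_deblurring_experiment`` — supervised + same-domain
  unsupervised training on underfocus blur; reports held-out PSNR/SSIM of
  the blurry inputs and the deblurred outputs.
* ``domain_shift_experiment`` — the unsupervised bank and the held-out
  set come from a *shifted* degradation domain (defocus + astigmatism)
  the supervised pairs never show; a semisupervised run is compared with
  a supervised-only run at equal steps, probing whether the unpaired bank
  improves cross-domain generalization.
"""

from __future__ import annotations

import numpy as np

from .dnet import DiscriminatorConfig
from .gnet import GeneratorConfig
from .simdata import BlurSpec, PhantomSpec, make_dataset
from .trainer import TrainConfig, Trainer

TINY_GENERATOR = GeneratorConfig(base_channels=8, channel_multipliers=(1, 1, 2, 2, 2),
                                 residual_blocks_per_scale=1)
TINY_DISCRIMINATOR = DiscriminatorConfig(n_layers=4, base_channels=16)

#: supervised degradation domain: moderate defocus plus mild read noise
DEFOCUS_BLUR = BlurSpec(mode="underfocus", defocus_radius=2.0, noise_sigma=0.01)
#: shifted domain: the same defocus compounded with astigmatism
SHIFTED_BLUR = BlurSpec(mode="combined", defocus_radius=2.0,
                        sigma_major=2.5, sigma_minor=0.8, angle=0.6,
                        noise_sigma=0.01)
PHANTOM = PhantomSpec(n_axons=5, height=96, width=96)

DEFAULT_STEPS = 250


def tiny_train_config(seed: int, total_steps: int = DEFAULT_STEPS) -> TrainConfig:
    return TrainConfig(batch_size=2, crop_size=48, peak_lr=0.01, warmup_steps=50,
                       total_steps=total_steps, seed=seed)


def _heldout(blur: BlurSpec, seed: int, n: int = 4):
    ds = make_dataset(n, 0, PHANTOM, [blur], seed=seed)
    return [(z.pixels, x.pixels) for z, x in ds.pairs]


def defocus_deblurring_experiment(seed: int, total_steps: int = DEFAULT_STEPS) -> dict:
    """Train the tiny model on synthetic defocus blur; held-out quality."""
    ds = make_dataset(6, 6, PHANTOM, [DEFOCUS_BLUR], seed=seed * 1000 + 1)
    heldout = _heldout(DEFOCUS_BLUR, seed=seed * 1000 + 2)
    trainer = Trainer(tiny_train_config(seed, total_steps),
                      TINY_GENERATOR, TINY_DISCRIMINATOR)
    result = trainer.fit(ds, heldout=heldout)
    final = result.eval_history[-1]
    return {
        "seed": seed,
        "steps": total_steps,
        "psnr_blurry": final["psnr_blurry"],
        "psnr_deblurred": final["psnr_deblurred"],
        "psnr_gain_db": final["psnr_deblurred"] - final["psnr_blurry"],
        "ssim_blurry": final["ssim_blurry"],
        "ssim_deblurred": final["ssim_deblurred"],
        "ssim_gain": final["ssim_deblurred"] - final["ssim_blurry"],
    }


def domain_shift_experiment(seed: int, total_steps: int = DEFAULT_STEPS) -> dict:
    """Semisupervised vs supervised-only training under domain shift.

    Supervised pairs show only defocus blur; the unpaired bank and the
    held-out set show defocus + astigmatism.  Both runs share the seed,
    the architecture and the schedule; they differ solely in whether the
    unpaired bank (and hence the unsupervised loss term) is present.
    """
    heldout = _heldout(SHIFTED_BLUR, seed=seed * 1000 + 12)

    ds_semi = make_dataset(6, 8, PHANTOM, [DEFOCUS_BLUR], seed=seed * 1000 + 11,
                           unsup_blur_distribution=[SHIFTED_BLUR])
    semi = Trainer(tiny_train_config(seed, total_steps),
                   TINY_GENERATOR, TINY_DISCRIMINATOR)
    semi_final = semi.fit(ds_semi, heldout=heldout).eval_history[-1]

    ds_sup = make_dataset(6, 0, PHANTOM, [DEFOCUS_BLUR], seed=seed * 1000 + 11)
    sup = Trainer(tiny_train_config(seed, total_steps),
                  TINY_GENERATOR, TINY_DISCRIMINATOR)
    sup_final = sup.fit(ds_sup, heldout=heldout).eval_history[-1]

    return {
        "seed": seed,
        "steps": total_steps,
        "psnr_blurry": semi_final["psnr_blurry"],
        "psnr_semisupervised": semi_final["psnr_deblurred"],
        "psnr_supervised_only": sup_final["psnr_deblurred"],
        "semisup_advantage_db": (semi_final["psnr_deblurred"]
                                 - sup_final["psnr_deblurred"]),
    }
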