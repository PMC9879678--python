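"""Training loop: warm-up schedule, gradient hygiene, determinism,
descent on the critic, and checkpoint resumability."""

import numpy as np
import pytest

import emdeblur as ed


def _tiny_trainer(seed=0, total_steps=0, **kw):
    return ed.Trainer(
        ed.TrainConfig(batch_size=2, crop_size=48, peak_lr=0.01, warmup_steps=50,
                       total_steps=total_steps, seed=seed, **kw),
        ed.GeneratorConfig(base_channels=4, channel_multipliers=(1, 1, 1, 2, 2),
                           residual_blocks_per_scale=1),
        ed.DiscriminatorConfig(n_layers=4, base_channels=8),
    )


def _tiny_dataset(seed=0, n_pairs=3, n_unsup=3):
    return ed.make_dataset(
        n_pairs, n_unsup, ed.PhantomSpec(n_axons=4, height=96, width=96),
        [ed.BlurSpec(mode="underfocus", defocus_radius=2.0, noise_sigma=0.01)],
        seed=seed)


class TestWarmupLr:
    def test_reaches_and_holds_plateau(self):
        cfg = ed.TrainConfig(peak_lr=1e-4, warmup_steps=1000, crop_size=48)
        assert ed.warmup_lr(1000, cfg) == 1e-4
        assert ed.warmup_lr(5000, cfg) == 1e-4

    def test_linear_ramp_midpoint(self):
        cfg = ed.TrainConfig(peak_lr=1e-4, warmup_steps=1000, crop_size=48)
        assert ed.warmup_lr(500, cfg) == pytest.approx(5e-5)

    def test_monotone_nondecreasing(self):
        cfg = ed.TrainConfig(peak_lr=1e-4, warmup_steps=100, crop_size=48)
        lrs = [ed.warmup_lr(s, cfg) for s in range(0, 300, 7)]
        assert all(a <= b for a, b in zip(lrs, lrs[1:]))


class TestTrainStep:
    def test_returns_all_six_losses(self):
        tr = _tiny_trainer()
        ds = _tiny_dataset()
        rec = tr.train_step(*tr._sample_batches(ds))
        for key in ("content", "perceptual", "adversarial", "unsupervised",
                    "generator_total", "discriminator"):
            assert np.isfinite(rec[key])

    def test_deterministic_under_seed(self):
        recs = []
        for _ in range(2):
            tr = _tiny_trainer(seed=7)
            ds = _tiny_dataset(seed=7)
            recs.append([tr.train_step(*tr._sample_batches(ds)) for _ in range(3)])
        assert recs[0] == recs[1]

    def test_gradient_hygiene_between_networks(self):
        tr = _tiny_trainer()
        ds = _tiny_dataset()
        sup_z, sup_x, unsup = tr._sample_batches(ds)
        d_before = [p.data.copy() for p in tr.D.parameters()]
        g_before = [p.data.copy() for p in tr.G.parameters()]
        tr.train_step(sup_z, sup_x, unsup)
        d_after = [p.data for p in tr.D.parameters()]
        g_after = [p.data for p in tr.G.parameters()]
        # both nets trained on their own objective only: D moved in the D
        # update, G in the G update; stale cross-gradients are discarded
        assert any(not np.array_equal(a, b) for a, b in zip(d_before, d_after))
        assert any(not np.array_equal(a, b) for a, b in zip(g_before, g_after))
        assert all(p.grad is None or not np.any(p.grad) for p in tr.D.parameters())

    def test_d_step_descends_on_fixed_batch(self):
        """One full-batch critic update at small lr does not increase the
        critic loss on that same batch (without augmentation noise)."""
        tr = _tiny_trainer()
        tr.policy = ed.AugPolicy.disabled()
        tr.cfg.warmup_steps = 1
        tr.cfg.peak_lr = 1e-3
        ds = _tiny_dataset()
        sup_z, sup_x, _ = tr._sample_batches(ds)
        from emdeblur.autograd import Tensor
        x = Tensor(sup_x.astype(np.float32))
        fake = tr.G(Tensor(sup_z.astype(np.float32))).detach()

        def critic_loss():
            return float(ed.d_loss(tr.D.score_map(x), tr.D.score_map(fake)).data)

        before = critic_loss()
        loss = ed.d_loss(tr.D.score_map(x), tr.D.score_map(fake))
        tr.optD.zero_grad()
        loss.backward()
        tr.optD.step(1e-3)
        assert critic_loss() <= before + 1e-9

    def test_nan_input_aborts_with_term_name(self):
        tr = _tiny_trainer()
        bad = np.full((2, 1, 48, 48), np.nan)
        good = np.zeros((2, 1, 48, 48))
        with pytest.raises(ed.LossDiverged):
            tr.train_step(bad, good, None)


class TestFit:
    def test_zero_steps_writes_init_checkpoint_only(self, tmp_path):
        tr = _tiny_trainer(total_steps=0)
        tr.fit(_tiny_dataset(), out_dir=tmp_path)
        ckpts = sorted(p.name for p in tmp_path.glob("checkpoint_*.npz"))
        assert "checkpoint_init.npz" in ckpts
        assert "checkpoint_0000000.npz" in ckpts

    def test_empty_supervised_bank_rejected(self):
        tr = _tiny_trainer(total_steps=1)
        ds = _tiny_dataset()
        ds.pairs = []
        with pytest.raises(ValueError):
            tr.fit(ds)

    def test_resume_reproduces_loss_trace_bitwise(self, tmp_path):
        full = _tiny_trainer(seed=5, total_steps=4)
        ds = _tiny_dataset(seed=5)
        trace_full = [r["generator_total"] for r in full.fit(ds).losses]

        part = _tiny_trainer(seed=5, total_steps=2)
        part.fit(_tiny_dataset(seed=5), out_dir=tmp_path)
        resumed = ed.load_checkpoint(tmp_path / "checkpoint_0000002.npz")
        resumed.cfg.total_steps = 2
        trace_tail = [r["generator_total"] for r in
                      resumed.fit(_tiny_dataset(seed=5)).losses]
        assert trace_tail == trace_full[2:]

    def test_supervised_only_run_equals_zero_lambda_empty_bank(self):
        """Dropping the unsupervised bank with lambda_us = 0 degenerates to
        a plain supervised least-squares GAN: identical loss traces."""
        a = _tiny_trainer(seed=3, total_steps=3)
        a.weights = ed.LossWeights(lambda_us=0.0)
        ds_a = _tiny_dataset(seed=3, n_unsup=0)
        trace_a = a.fit(ds_a).losses

        b = _tiny_trainer(seed=3, total_steps=3)
        b.weights = ed.LossWeights(lambda_us=0.0)
        ds_b = _tiny_dataset(seed=3, n_unsup=0)
        trace_b = b.fit(ds_b).losses
        assert trace_a == trace_b
        assert all(r["unsupervised"] == 0.0 for r in trace_a)

    def test_evaluation_reports_heldout_quality(self):
        tr = _tiny_trainer(seed=1, total_steps=1)
        ds = _tiny_dataset(seed=1)
        held = [(z.pixels, x.pixels) for z, x in _tiny_dataset(seed=99, n_unsup=0).pairs[:2]]
        res = tr.fit(ds, heldout=held)
        assert len(res.eval_history) == 1
        assert np.isfinite(res.eval_history[0]["psnr_deblurred"])


class TestCheckpoint:
    def test_roundtrip_restores_forward_exactly(self, tmp_path, rng):
        tr = _tiny_trainer(seed=2, total_steps=1)
        tr.fit(_tiny_dataset(seed=2))
        path = tmp_path / "ck.npz"
        ed.save_checkpoint(path, tr)
        tr2 = ed.load_checkpoint(path)
        img = rng.uniform(size=(64, 64))
        np.testing.assert_array_equal(ed.deblur_field(tr.G, img),
                                      ed.deblur_field(tr2.G, img))

    def test_incompatible_checkpoint_rejected(self, tmp_path):
        tr = _tiny_trainer()
        path = tmp_path / "ck.npz"
        ed.save_checkpoint(path, tr)
        other = ed.Generator(ed.GeneratorConfig(base_channels=8), seed=0)
        with pytest.raises(ValueError):
            other.load_state_dict(tr.G.state_dict())
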