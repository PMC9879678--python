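"""Loss arithmetic: each term is checked against hand evaluation at its
analytic optimum and at off-optimum scalar scores."""

import numpy as np
import pytest

import emdeblur as ed
from emdeblur.autograd import Tensor
from emdeblur.objectives import IdentityBackbone


class TestContentLoss:
    def test_zero_at_identity(self, rng):
        x = rng.uniform(size=(1, 1, 8, 8))
        assert ed.content_loss(x, x).data == 0.0

    def test_constant_images_mean_absolute_difference(self):
        a = np.full((1, 1, 4, 4), 0.2)
        b = np.full((1, 1, 4, 4), 0.5)
        assert ed.content_loss(a, b).data == pytest.approx(0.3, abs=1e-6)

    def test_symmetry(self, rng):
        a, b = rng.uniform(size=(2, 1, 8, 8)), rng.uniform(size=(2, 1, 8, 8))
        assert ed.content_loss(a, b).data == pytest.approx(ed.content_loss(b, a).data)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ed.content_loss(np.zeros((1, 1, 4, 4)), np.zeros((1, 1, 8, 8)))


class TestPerceptualLoss:
    def test_zero_for_identical_inputs(self, rng):
        x = rng.uniform(size=(1, 1, 16, 16))
        backbone = ed.RandomFeatureBackbone(channels=4, seed=0)
        assert ed.perceptual_loss(x, x, backbone).data == pytest.approx(0.0, abs=1e-12)

    def test_identity_backbone_unit_difference(self):
        # features differing by 1 on a 1x2x2 block: (1^2 * 4) / (1*2*2) = 1
        x = np.zeros((1, 2, 2))
        y = np.ones((1, 2, 2))
        assert ed.perceptual_loss(x, y, IdentityBackbone()).data == pytest.approx(1.0)

    def test_nonnegative(self, rng):
        backbone = ed.RandomFeatureBackbone(channels=4, seed=0)
        a = rng.uniform(size=(2, 1, 16, 16))
        b = rng.uniform(size=(2, 1, 16, 16))
        assert ed.perceptual_loss(a, b, backbone).data >= 0.0

    def test_backbone_is_frozen_and_deterministic(self, rng):
        x = rng.uniform(size=(1, 1, 16, 16))
        f1 = ed.RandomFeatureBackbone(channels=4, seed=3)(Tensor(x)).data
        f2 = ed.RandomFeatureBackbone(channels=4, seed=3)(Tensor(x)).data
        np.testing.assert_array_equal(f1, f2)


class TestAdversarialLossG:
    @pytest.mark.parametrize("score,expected", [(1.0, 0.0), (0.5, 0.25), (0.0, 1.0)])
    def test_least_squares_generator_objective(self, score, expected):
        scores = np.full((2, 1, 4, 4), score)
        assert ed.adversarial_loss_G(scores).data == pytest.approx(expected, abs=1e-6)


class TestUnsupervisedLoss:
    def test_zero_for_equal_populations(self, rng):
        s = rng.normal(size=(2, 1, 4, 4))
        assert ed.unsupervised_loss(s, s.copy()).data == 0.0

    def test_mean_gap_squared_for_unequal_batches(self):
        s = np.full((2, 1, 4, 4), 0.9)
        u = np.full((3, 1, 4, 4), 0.4)
        assert ed.unsupervised_loss(s, u).data == pytest.approx(0.25, abs=1e-6)

    def test_empty_unsup_bank_falls_back_to_zero(self, rng):
        s = rng.normal(size=(2, 1, 4, 4))
        assert ed.unsupervised_loss(s, None).data == 0.0
        assert ed.unsupervised_loss(s, np.empty((0,))).data == 0.0


class TestTotalGLoss:
    def test_printed_weights_at_unit_components(self):
        one = Tensor(1.0)
        total = ed.total_G_loss(one, one, one, one, ed.LossWeights())
        assert total.data == pytest.approx(1.13, abs=1e-6)  # 1 + 0.1 + 0.01 + 0.02

    def test_zero_weights_reduce_to_content(self, rng):
        w = ed.LossWeights(lambda_adv=0.0, lambda_us=0.0, lambda_p=0.0)
        lc = Tensor(0.7)
        total = ed.total_G_loss(lc, Tensor(5.0), Tensor(5.0), Tensor(5.0), w)
        assert total.data == pytest.approx(0.7)

    def test_zero_components_give_zero(self):
        zero = Tensor(0.0)
        assert ed.total_G_loss(zero, zero, zero, zero, ed.LossWeights()).data == 0.0

    def test_nan_component_aborts_with_term_name(self):
        with pytest.raises(ed.LossDiverged, match="perceptual"):
            ed.total_G_loss(Tensor(1.0), Tensor(1.0), Tensor(1.0),
                            Tensor(np.nan), ed.LossWeights())


class TestDLoss:
    @pytest.mark.parametrize("real,fake,expected", [
        (1.0, 0.0, 0.0),        # perfect critic
        (0.7, 0.2, 0.065),      # 0.5*0.09 + 0.5*0.04
        (0.5, 0.5, 0.25),       # 0.5*0.25 + 0.5*0.25
    ])
    def test_least_squares_critic_objective(self, real, fake, expected):
        r = np.full((2, 1, 4, 4), real)
        f = np.full((2, 1, 4, 4), fake)
        assert ed.d_loss(r, f).data == pytest.approx(expected, abs=1e-6)


class TestCodingConsistency:
    """With a=0, b=c=1 the implemented losses equal the generic
    least-squares objectives evaluated at scalar scores."""

    def test_generator_objective_matches_coding_form(self):
        coding = ed.LsganCoding()
        for s in (0.0, 0.3, 1.0, 1.7):
            direct = (s - coding.c) ** 2
            assert ed.adversarial_loss_G(np.array([[s]])).data == pytest.approx(direct)

    def test_discriminator_objective_matches_coding_form(self):
        coding = ed.LsganCoding()
        for r, f in [(1.2, -0.1), (0.0, 0.0), (0.8, 0.6)]:
            direct = 0.5 * (r - coding.b) ** 2 + 0.5 * (f - coding.a) ** 2
            got = ed.d_loss(np.array([[r]]), np.array([[f]])).data
            assert got == pytest.approx(direct)

    def test_coding_constants_are_immutable(self):
        coding = ed.LsganCoding()
        assert (coding.a, coding.b, coding.c) == (0.0, 1.0, 1.0)
        with pytest.raises(Exception):
            coding.a = 0.5


class TestGradientIsolation:
    def test_d_loss_gradients_do_not_reach_generator(self, tiny_gen_cfg,
                                                     tiny_disc_cfg, rng):
        G = ed.Generator(tiny_gen_cfg, seed=0)
        D = ed.Discriminator(tiny_disc_cfg, seed=1)
        z = Tensor(rng.uniform(-1, 1, size=(1, 1, 64, 64)))
        fake = G(z).detach()
        real = Tensor(rng.uniform(-1, 1, size=(1, 1, 64, 64)))
        ed.d_loss(D.score_map(real), D.score_map(fake)).backward()
        assert all(p.grad is None for p in G.parameters())
        assert any(p.grad is not None and np.any(p.grad) for p in D.parameters())

    def test_perceptual_loss_does_not_train_backbone(self, rng):
        backbone = ed.RandomFeatureBackbone(channels=4, seed=0)
        a = Tensor(rng.uniform(size=(1, 1, 16, 16)), requires_grad=True)
        b = rng.uniform(size=(1, 1, 16, 16))
        ed.perceptual_loss(a, b, backbone).backward()
        assert all(not w.requires_grad for w in backbone.weights)
        assert a.grad is not None
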