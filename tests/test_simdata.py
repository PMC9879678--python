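"""Blur formation model and phantom generator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

import emdeblur as ed


class TestRenderKernel:
    def test_identity_mode_is_delta(self):
        k = ed.render_kernel(ed.BlurSpec(mode="identity"))
        assert k.shape == (1, 1)
        assert k.sum() == 1.0

    @pytest.mark.parametrize("mode,kwargs", [
        ("underfocus", {"defocus_radius": 3.0}),
        ("overfocus", {"defocus_radius": 3.0}),
        ("astigmatism", {"sigma_major": 4.0, "sigma_minor": 1.0}),
        ("combined", {"defocus_radius": 2.0, "sigma_major": 3.0, "sigma_minor": 1.0}),
    ])
    def test_kernels_nonnegative_and_normalized(self, mode, kwargs):
        k = ed.render_kernel(ed.BlurSpec(mode=mode, **kwargs))
        assert (k >= 0).all()
        assert abs(k.sum() - 1.0) < 1e-6

    def test_astigmatic_kernel_second_moment_ratio(self):
        # sigma 4 vs 1 at angle 0 -> axis variance ratio of about 16
        k = ed.render_kernel(ed.BlurSpec(mode="astigmatism", sigma_major=4.0,
                                         sigma_minor=1.0, angle=0.0))
        vy, vx = ed.kernel_moments(k)
        assert vx / vy == pytest.approx(16.0, rel=0.05)

    def test_overfocus_kernel_is_wider_tier_than_underfocus(self):
        under = ed.kernel_moments(ed.render_kernel(
            ed.BlurSpec(mode="underfocus", defocus_radius=3.0)))
        over = ed.kernel_moments(ed.render_kernel(
            ed.BlurSpec(mode="overfocus", defocus_radius=3.0)))
        assert over[0] > under[0] and over[1] > under[1]

    def test_defocus_kernels_are_isotropic(self):
        vy, vx = ed.kernel_moments(ed.render_kernel(
            ed.BlurSpec(mode="underfocus", defocus_radius=4.0)))
        assert vy == pytest.approx(vx, rel=1e-6)

    def test_combined_composes_moments_additively(self):
        # variances add under convolution of independent kernels
        disc = ed.kernel_moments(ed.render_kernel(
            ed.BlurSpec(mode="underfocus", defocus_radius=2.0)))
        astig = ed.kernel_moments(ed.render_kernel(
            ed.BlurSpec(mode="astigmatism", sigma_major=3.0, sigma_minor=1.0)))
        comb = ed.kernel_moments(ed.render_kernel(
            ed.BlurSpec(mode="combined", defocus_radius=2.0,
                        sigma_major=3.0, sigma_minor=1.0)))
        assert comb[0] == pytest.approx(disc[0] + astig[0], rel=0.02)
        assert comb[1] == pytest.approx(disc[1] + astig[1], rel=0.02)

    def test_astigmatism_requires_unequal_sigmas(self):
        with pytest.raises(ValueError):
            ed.BlurSpec(mode="astigmatism", sigma_major=2.0, sigma_minor=2.0)


class TestApplyBlur:
    def test_identity_zero_noise_is_fixed_point(self, phantom_96):
        z = ed.apply_blur(phantom_96.image, ed.BlurSpec(mode="identity", noise_sigma=0.0))
        np.testing.assert_array_equal(z.pixels, phantom_96.image.pixels)

    def test_mean_preserved_by_normalized_kernel(self, phantom_96):
        z = ed.apply_blur(phantom_96.image,
                          ed.BlurSpec(mode="underfocus", defocus_radius=3.0))
        assert abs(z.pixels.mean() - phantom_96.image.pixels.mean()) < 1e-3

    def test_noise_is_seeded_and_deterministic(self, phantom_96):
        spec = ed.BlurSpec(mode="underfocus", defocus_radius=2.0,
                           noise_sigma=0.05, seed=42)
        z1 = ed.apply_blur(phantom_96.image, spec)
        z2 = ed.apply_blur(phantom_96.image, spec)
        np.testing.assert_array_equal(z1.pixels, z2.pixels)

    def test_kernel_larger_than_image_rejected(self):
        small = ed.ImageField(np.full((16, 16), 0.5))
        with pytest.raises(ValueError):
            ed.apply_blur(small, ed.BlurSpec(mode="underfocus", defocus_radius=12.0))

    def test_psnr_monotone_nonincreasing_in_defocus_radius(self, phantom_96):
        x = phantom_96.image
        psnrs = [
            ed.psnr(x.pixels, ed.apply_blur(
                x, ed.BlurSpec(mode="underfocus", defocus_radius=r)).pixels)
            for r in (1, 2, 4, 8)
        ]
        assert all(a >= b for a, b in zip(psnrs, psnrs[1:]))


class TestGeneratePhantom:
    def test_zero_axons_gives_pure_background(self):
        ph = ed.generate_phantom(ed.PhantomSpec(n_axons=0, seed=3))
        assert ph.labels.max() == 0
        assert ph.image.pixels.min() > ed.simdata.MYELIN_THRESHOLD

    def test_deterministic_under_seed(self):
        spec = ed.PhantomSpec(n_axons=5, height=96, width=96, seed=1)
        a, b = ed.generate_phantom(spec), ed.generate_phantom(spec)
        np.testing.assert_array_equal(a.image.pixels, b.image.pixels)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_annulus_component_count_matches_axon_count(self):
        ph = ed.generate_phantom(ed.PhantomSpec(n_axons=5, height=128, width=128, seed=7))
        dark = ph.image.pixels < ed.simdata.MYELIN_THRESHOLD
        _, n = ndimage.label(dark)
        assert n == 5
        assert ph.labels.max() == 5

    def test_canvas_too_small_rejected(self):
        with pytest.raises(ValueError):
            ed.PhantomSpec(n_axons=1, radius_range=(30.0, 40.0), height=64, width=64)

    def test_myelin_darker_than_lumen_and_background(self):
        ph = ed.generate_phantom(ed.PhantomSpec(n_axons=4, height=96, width=96, seed=5))
        myelin = ph.image.pixels[(ph.labels > 0)
                                 & (ph.image.pixels < ed.simdata.MYELIN_THRESHOLD)]
        rest = ph.image.pixels[ph.labels == 0]
        assert myelin.size > 0
        assert myelin.mean() < rest.mean()


class TestMakeDataset:
    def test_counts_and_alignment(self):
        ds = ed.make_dataset(4, 0, ed.PhantomSpec(n_axons=3, height=96, width=96),
                             [ed.BlurSpec(mode="underfocus", defocus_radius=2.0)], seed=0)
        assert len(ds.pairs) == 4 and len(ds.unsup) == 0 and len(ds.labels) == 4
        for z, x in ds.pairs:
            assert z.pixels.shape == x.pixels.shape

    def test_empty_blur_distribution_rejected(self):
        with pytest.raises(ValueError):
            ed.make_dataset(1, 0, ed.PhantomSpec(), [], seed=0)

    def test_combined_distribution_yields_anisotropic_wide_kernels(self):
        dist = [ed.BlurSpec(mode="combined", defocus_radius=2.0,
                            sigma_major=3.0, sigma_minor=1.0)]
        ds = ed.make_dataset(3, 0, ed.PhantomSpec(n_axons=3, height=96, width=96),
                             dist, seed=1)
        for spec in ds.pair_specs:
            vy, vx = ed.kernel_moments(ed.render_kernel(spec))
            disc_v = ed.kernel_moments(ed.render_kernel(
                ed.BlurSpec(mode="underfocus", defocus_radius=2.0)))[0]
            assert max(vy, vx) > disc_v        # astigmatic elongation present
            assert min(vy, vx) > 0.5 * disc_v  # defocus contribution present

    def test_fixed_seed_reproduces_manifest(self):
        args = (2, 2, ed.PhantomSpec(n_axons=3, height=96, width=96),
                [ed.BlurSpec(mode="underfocus", defocus_radius=2.0, noise_sigma=0.01)])
        a = ed.make_dataset(*args, seed=9)
        b = ed.make_dataset(*args, seed=9)
        assert a.manifest == b.manifest
        np.testing.assert_array_equal(a.pairs[0][0].pixels, b.pairs[0][0].pixels)

    def test_shifted_unsup_distribution_is_used(self):
        ds = ed.make_dataset(
            1, 3, ed.PhantomSpec(n_axons=3, height=96, width=96),
            [ed.BlurSpec(mode="underfocus", defocus_radius=2.0)], seed=2,
            unsup_blur_distribution=[ed.BlurSpec(mode="astigmatism",
                                                 sigma_major=3.0, sigma_minor=1.0)])
        assert all(s.mode == "astigmatism" for s in ds.unsup_specs)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(r=st.floats(min_value=0.5, max_value=6.0),
       sm=st.floats(min_value=0.5, max_value=5.0))
def test_every_rendered_kernel_is_a_probability_mass(r, sm):
    for spec in (ed.BlurSpec(mode="underfocus", defocus_radius=r),
                 ed.BlurSpec(mode="astigmatism", sigma_major=sm + 1.0, sigma_minor=sm)):
        k = ed.render_kernel(spec)
        assert (k >= 0).all()
        assert abs(k.sum() - 1.0) < 1e-6
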