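"""Generate a synthetic myelinated-axon phantom, degrade it with each
blur mode, and quantify the damage.

The phantom mimics an osmium-stained corpus-callosum micrograph: dark
myelin annuli around lighter axoplasm on textured neuropil.  Each blur
mode corresponds to an electron-optical failure of automated
acquisition; PSNR/SSIM against the clear phantom show how much structure
each one destroys (lower = worse).
"""

import emdeblur as ed

phantom = ed.generate_phantom(ed.PhantomSpec(n_axons=8, height=128, width=128, seed=7))
print(f"phantom: {phantom.image.height}x{phantom.image.width}, "
      f"{phantom.labels.max()} axons, "
      f"intensity range [{phantom.image.pixels.min():.2f}, "
      f"{phantom.image.pixels.max():.2f}]")

specs = {
    "underfocus": ed.BlurSpec(mode="underfocus", defocus_radius=2.0, noise_sigma=0.01),
    "overfocus": ed.BlurSpec(mode="overfocus", defocus_radius=2.0, noise_sigma=0.01),
    "astigmatism": ed.BlurSpec(mode="astigmatism", sigma_major=3.0, sigma_minor=1.0,
                               angle=0.5, noise_sigma=0.01),
    "combined": ed.BlurSpec(mode="combined", defocus_radius=2.0, sigma_major=2.5,
                            sigma_minor=0.8, angle=0.5, noise_sigma=0.01),
}

print(f"\n{'mode':<12} {'kernel':>8} {'PSNR dB':>8} {'SSIM':>7}")
for name, spec in specs.items():
    kernel = ed.render_kernel(spec)
    blurry = ed.apply_blur(phantom.image, spec)
    p = ed.psnr(phantom.image.pixels, blurry.pixels)
    s = ed.ssim(phantom.image.pixels, blurry.pixels)
    print(f"{name:<12} {'x'.join(map(str, kernel.shape)):>8} {p:8.2f} {s:7.3f}")

print("\nLower PSNR/SSIM = stronger degradation; astigmatism smears along "
      "one axis, 'combined' compounds both aberrations.")
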