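"""Synthetic serial-SEM phantoms and the blur formation model.

Real corpus-callosum micrographs show densely packed myelinated-axon
cross-sections: a dark osmium-stained myelin annulus around a lighter
axoplasm lumen, embedded in textured neuropil.  The phantom generator
emulates that geometry; the degradation model is the standard linear
formation ``z = k * x + eta`` with a parametric point-spread function
covering the electron-optical failure modes of automated acquisition —
underfocus, overfocus (defocus discs of different radius tiers),
astigmatism (an oriented anisotropic Gaussian) and their combination —
plus additive Gaussian read noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage, signal

BLUR_MODES = ("underfocus", "overfocus", "astigmatism", "combined", "identity")

#: gray levels of the phantom (unit intensity range, myelin darkest)
MYELIN_LEVEL = 0.15
LUMEN_LEVEL = 0.70
#: threshold separating myelin annuli from everything brighter
MYELIN_THRESHOLD = 0.30
#: overfocus discs sit one radius tier above underfocus at equal |defocus|
OVERFOCUS_TIER = 1.5


@dataclass
class ImageField:
    """A grayscale raster with an explicit value-range convention."""

    pixels: np.ndarray
    convention: str = "unit"  # "unit" = [0,1] at I/O, "symmetric" = [-1,1] in-network

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("ImageField is 2-D")
        h, w = self.pixels.shape
        if h < 16 or w < 16:
            raise ValueError("ImageField must be at least 16x16")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("non-finite pixel values")
        lo, hi = (0.0, 1.0) if self.convention == "unit" else (-1.0, 1.0)
        if self.pixels.min() < lo - 1e-9 or self.pixels.max() > hi + 1e-9:
            raise ValueError(f"pixels outside declared range [{lo},{hi}]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class BlurSpec:
    """Parametric description of the blur kernel k and noise eta."""

    mode: str = "underfocus"
    defocus_radius: float = 3.0
    sigma_major: float = 0.0
    sigma_minor: float = 0.0
    angle: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.mode not in BLUR_MODES:
            raise ValueError(f"unknown blur mode {self.mode!r}")
        if self.defocus_radius < 0 or self.sigma_major < 0 or self.sigma_minor < 0:
            raise ValueError("kernel scales must be nonnegative")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.mode in ("astigmatism", "combined") and self.sigma_major == self.sigma_minor:
            raise ValueError("astigmatism requires sigma_major != sigma_minor")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "BlurSpec":
        return cls(**d)


@dataclass
class PhantomSpec:
    """Myelinated-axon phantom parameters."""

    n_axons: int = 12
    radius_range: tuple[float, float] = (6.0, 14.0)
    myelin_thickness_range: tuple[float, float] = (2.0, 4.0)
    texture_amplitude: float = 0.08
    background_level: float = 0.55
    height: int = 128
    width: int = 128
    seed: int = 0

    def __post_init__(self):
        if self.n_axons < 0:
            raise ValueError("n_axons must be nonnegative")
        r_hi = self.radius_range[1] + self.myelin_thickness_range[1]
        if 2 * r_hi + 4 > min(self.height, self.width):
            raise ValueError("canvas too small for the requested axon radii")


@dataclass
class Phantom:
    image: ImageField
    labels: np.ndarray  # instance labels, 0 = background


# ---------------------------------------------------------------------------
# kernels


def _disc(radius: float) -> np.ndarray:
    """Antialiased defocus disc convolved with a 0.5-px Gaussian."""
    r = max(radius, 1e-3)
    half = int(np.ceil(r)) + 2
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
    dist = np.hypot(yy, xx)
    disc = np.clip(r + 0.5 - dist, 0.0, 1.0)
    return ndimage.gaussian_filter(disc, 0.5, mode="constant")


def _oriented_gaussian(sigma_major: float, sigma_minor: float, angle: float) -> np.ndarray:
    s1, s2 = max(sigma_major, 1e-3), max(sigma_minor, 1e-3)
    half = int(np.ceil(3.0 * max(s1, s2))) + 1
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
    c, s = np.cos(angle), np.sin(angle)
    u = c * xx + s * yy       # along major axis
    v = -s * xx + c * yy
    return np.exp(-0.5 * ((u / s1) ** 2 + (v / s2) ** 2))


def render_kernel(spec: BlurSpec) -> np.ndarray:
    """Render the PSF of a :class:`BlurSpec`; nonnegative, sums to one."""
    if spec.mode == "identity":
        return np.ones((1, 1))
    if spec.mode == "underfocus":
        k = _disc(spec.defocus_radius)
    elif spec.mode == "overfocus":
        k = _disc(OVERFOCUS_TIER * spec.defocus_radius)
    elif spec.mode == "astigmatism":
        k = _oriented_gaussian(spec.sigma_major, spec.sigma_minor, spec.angle)
    else:  # combined
        k = signal.convolve2d(
            _disc(spec.defocus_radius),
            _oriented_gaussian(spec.sigma_major, spec.sigma_minor, spec.angle),
            mode="full",
        )
    total = k.sum()
    if total <= 0 or k.size == 0:
        raise ValueError("kernel has nonpositive support")
    return k / total


def kernel_moments(k: np.ndarray) -> tuple[float, float]:
    """Second central moments (var_y, var_x) of a normalized kernel."""
    h, w = k.shape
    yy, xx = np.mgrid[:h, :w]
    my, mx = (k * yy).sum(), (k * xx).sum()
    return float((k * (yy - my) ** 2).sum()), float((k * (xx - mx) ** 2).sum())


def apply_blur(x: ImageField, spec: BlurSpec) -> ImageField:
    """Degrade a clear image: z = clip(k * x + eta, 0, 1), reflective edges."""
    k = render_kernel(spec)
    if k.shape[0] > x.height or k.shape[1] > x.width:
        raise ValueError("kernel larger than image")
    z = ndimage.convolve(x.pixels, k, mode="reflect")
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        z = z + rng.normal(0.0, spec.noise_sigma, size=z.shape)
    return ImageField(np.clip(z, 0.0, 1.0))


# ---------------------------------------------------------------------------
# phantoms


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Draw a myelinated-axon phantom plus its instance label mask."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width

    texture = rng.normal(0.0, 1.0, size=(h, w))
    texture = ndimage.gaussian_filter(texture, 2.0)
    texture /= max(np.abs(texture).max(), 1e-9)
    img = spec.background_level + spec.texture_amplitude * texture
    img = np.clip(img, MYELIN_THRESHOLD + 0.08, 0.92)  # background stays above myelin
    labels = np.zeros((h, w), dtype=np.int32)

    placed: list[tuple[float, float, float]] = []  # (cy, cx, outer radius)
    yy, xx = np.mgrid[:h, :w]
    attempts, placed_count = 0, 0
    while placed_count < spec.n_axons and attempts < 400 * max(spec.n_axons, 1):
        attempts += 1
        r = rng.uniform(*spec.radius_range)
        t = rng.uniform(*spec.myelin_thickness_range)
        r_out = r + t
        cy = rng.uniform(r_out + 2, h - r_out - 2)
        cx = rng.uniform(r_out + 2, w - r_out - 2)
        if any(np.hypot(cy - py, cx - px) < r_out + pr + 2.0 for py, px, pr in placed):
            continue
        dist = np.hypot(yy - cy, xx - cx)
        lumen = np.clip(r - dist, 0.0, 1.0)          # antialiased coverage
        annulus = np.clip(r_out - dist, 0.0, 1.0) - lumen
        lumen_tex = 1.0 + 0.08 * np.tanh(np.sin(0.9 * (yy - cy)) * np.sin(0.9 * (xx - cx)))
        img = img * (1.0 - lumen - annulus) \
            + annulus * MYELIN_LEVEL \
            + lumen * LUMEN_LEVEL * lumen_tex
        placed_count += 1
        placed.append((cy, cx, r_out))
        labels[dist < r_out] = placed_count
    if placed_count < spec.n_axons:
        raise ValueError("could not place all axons without overlap; enlarge canvas")
    return Phantom(ImageField(np.clip(img, 0.0, 1.0)), labels)


# ---------------------------------------------------------------------------
# datasets


@dataclass
class SynthDataset:
    """Paired supervised bank, unpaired blurry bank, and label masks."""

    pairs: list[tuple[ImageField, ImageField]]   # (blurry z_s, clear x)
    unsup: list[ImageField]                      # blurry-only z_u
    labels: list[np.ndarray]                     # instance masks of the paired clears
    pair_specs: list[BlurSpec] = field(default_factory=list)
    unsup_specs: list[BlurSpec] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)


def _draw_blur(rng: np.random.Generator, distribution: list[BlurSpec]) -> BlurSpec:
    base = distribution[rng.integers(len(distribution))]
    d = base.to_dict()
    d["seed"] = int(rng.integers(2 ** 31 - 1))  # fresh noise per image
    return BlurSpec.from_dict(d)


def make_dataset(n_pairs: int, n_unsup: int, phantom_spec: PhantomSpec,
                 blur_distribution: list[BlurSpec], seed: int = 0,
                 unsup_blur_distribution: list[BlurSpec] | None = None) -> SynthDataset:
    """Build aligned (blurry, clear) pairs and an unpaired blurry bank.

    ``unsup_blur_distribution`` lets the unsupervised bank come from a
    shifted degradation domain, emulating acquisition drift between
    samples; it defaults to the supervised distribution.
    """
    if n_pairs < 0 or n_unsup < 0:
        raise ValueError("counts must be nonnegative")
    if not blur_distribution:
        raise ValueError("blur_distribution must be nonempty")
    unsup_dist = unsup_blur_distribution or blur_distribution
    if n_unsup > 0 and not unsup_dist:
        raise ValueError("unsupervised blur distribution must be nonempty")
    rng = np.random.default_rng(seed)

    pairs, labels, pair_specs = [], [], []
    for _ in range(n_pairs):
        pspec = PhantomSpec(**{**asdict(phantom_spec), "seed": int(rng.integers(2 ** 31 - 1))})
        ph = generate_phantom(pspec)
        bspec = _draw_blur(rng, blur_distribution)
        pairs.append((apply_blur(ph.image, bspec), ph.image))
        labels.append(ph.labels)
        pair_specs.append(bspec)

    unsup, unsup_specs = [], []
    for _ in range(n_unsup):
        pspec = PhantomSpec(**{**asdict(phantom_spec), "seed": int(rng.integers(2 ** 31 - 1))})
        ph = generate_phantom(pspec)
        bspec = _draw_blur(rng, unsup_dist)
        unsup.append(apply_blur(ph.image, bspec))
        unsup_specs.append(bspec)

    manifest = {
        "seed": seed,
        "phantom_spec": asdict(phantom_spec),
        "pairs": [s.to_dict() for s in pair_specs],
        "unsup": [s.to_dict() for s in unsup_specs],
    }
    return SynthDataset(pairs, unsup, labels, pair_specs, unsup_specs, manifest)


# ---------------------------------------------------------------------------
# on-disk form


def save_dataset(ds: SynthDataset, directory: str | Path) -> Path:
    """Write 16-bit PNGs plus a JSON manifest; returns the manifest path."""
    from .imgio import write_gray

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {"pairs": [], "unsup": [], "labels": []}
    for i, (z, x) in enumerate(ds.pairs):
        zp, xp = f"pair{i:04d}_blurry.png", f"pair{i:04d}_clear.png"
        write_gray(directory / zp, z.pixels, bitdepth=16)
        write_gray(directory / xp, x.pixels, bitdepth=16)
        files["pairs"].append([zp, xp])
    for i, z in enumerate(ds.unsup):
        p = f"unsup{i:04d}_blurry.png"
        write_gray(directory / p, z.pixels, bitdepth=16)
        files["unsup"].append(p)
    for i, lab in enumerate(ds.labels):
        p = f"pair{i:04d}_labels.png"
        write_gray(directory / p, lab.astype(np.float64) / 65535.0, bitdepth=16)
        files["labels"].append(p)
    manifest = dict(ds.manifest)
    manifest["files"] = files
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def load_dataset(directory: str | Path) -> SynthDataset:
    from .imgio import read_gray

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    pairs = [
        (ImageField(read_gray(directory / zp)[0]), ImageField(read_gray(directory / xp)[0]))
        for zp, xp in manifest["files"]["pairs"]
    ]
    unsup = [ImageField(read_gray(directory / p)[0]) for p in manifest["files"]["unsup"]]
    labels = [
        np.round(read_gray(directory / p)[0] * 65535.0).astype(np.int32)
        for p in manifest["files"]["labels"]
    ]
    return SynthDataset(
        pairs, unsup, labels,
        [BlurSpec.from_dict(d) for d in manifest["pairs"]],
        [BlurSpec.from_dict(d) for d in manifest["unsup"]],
        manifest,
    )
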