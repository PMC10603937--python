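"""Synthetic layered OCT phantoms with exact ground-truth masks.

A phantom emulates the statistical structure of a retinal B-scan that a
segmenter exploits: vertically ordered, non-crossing layer boundaries with
smooth lateral undulation; a characteristic mean reflectivity per layer;
multiplicative speckle (the Gamma-distributed surrogate standard for
coherent imaging) plus additive Gaussian detector noise; optionally a
parabolic optic-disc cup cutting through all layers and an elliptical
intraretinal "fluid" blob.  It is not a physical OCT forward model — there
is no A-scan point-spread function and no shadowing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schema import ImageSample, LabelScheme, make_label_scheme


@dataclass
class PhantomConfig:
    """Generation parameters for one phantom family.

    ``n_layers`` tissue layers occupy classes ``1..n_layers``; background is
    class 0 above and below.  When disc or fluid insertion is enabled the
    disc class is ``n_layers + 1`` and the fluid class ``n_layers + 2``.
    ``speckle_looks`` is the shape parameter of the unit-mean Gamma speckle
    (smaller = noisier; ``None`` disables speckle).
    """

    width: int = 64
    height: int = 64
    n_layers: int = 4
    boundary_smoothness: float = 3.0      # undulation/jitter amplitude, pixels
    layer_intensity: tuple = ()           # per-layer means in [0,1]; auto if empty
    background_intensity: float = 0.05
    speckle_looks: float | None = 4.0
    gaussian_sigma: float = 0.02
    disc_probability: float = 0.0
    fluid_probability: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError("need at least one layer")
        if not self.layer_intensity:
            # alternate bright/dark strata like the plexiform/nuclear pattern
            base = np.linspace(0.35, 0.85, self.n_layers)
            base[1::2] *= 0.45
            self.layer_intensity = tuple(float(v) for v in base)
        if len(self.layer_intensity) != self.n_layers:
            raise ValueError("layer_intensity must have n_layers entries")
        if any(not 0.0 <= v <= 1.0 for v in self.layer_intensity):
            raise ValueError("layer intensities must lie in [0,1]")
        if self.speckle_looks is not None and self.speckle_looks <= 0:
            raise ValueError("speckle_looks must be positive")

    @property
    def n_classes(self) -> int:
        """Classes a phantom mask may contain (incl. background, disc, fluid)."""
        extra = int(self.disc_probability > 0) + int(self.fluid_probability > 0)
        return self.n_layers + 1 + extra

    @property
    def disc_class(self) -> int | None:
        return self.n_layers + 1 if self.disc_probability > 0 else None

    @property
    def fluid_class(self) -> int | None:
        if self.fluid_probability <= 0:
            return None
        return self.n_layers + 1 + int(self.disc_probability > 0)

    def scheme(self) -> LabelScheme:
        names = ["background"] + [f"layer{j}" for j in range(1, self.n_layers + 1)]
        if self.disc_class is not None:
            names.append("disc")
        if self.fluid_class is not None:
            names.append("fluid")
        return make_label_scheme(names)


@dataclass
class BoundarySet:
    """n_layers + 1 real-valued boundary curves, one row per curve, sampled
    at every column; non-crossing and confined to [0, height]."""

    curves: np.ndarray  # (n_layers + 1, width)
    height: int

    def __post_init__(self):
        d = np.diff(self.curves, axis=0)
        if d.size and d.min() < 0:
            raise ValueError("boundary curves cross")
        if self.curves.min() < 0 or self.curves.max() > self.height:
            raise ValueError("boundary curves leave the image")


def sample_boundaries(config: PhantomConfig, rng: np.random.Generator) -> BoundarySet:
    """Draw one set of smooth, ordered layer boundaries.

    Each curve is an equally spaced base depth plus a seeded vertical jitter
    and a sum of three low-frequency sinusoids, all scaled by
    ``boundary_smoothness``; curves are then sorted column-wise and clipped,
    which enforces the non-crossing invariant.  ``boundary_smoothness == 0``
    yields perfectly flat, equally spaced boundaries.
    """
    h, w, nl = config.height, config.width, config.n_layers
    if h < 2 * (nl + 1):
        raise ValueError(f"height {h} too small for {nl} layers")
    amp = float(config.boundary_smoothness)
    base = (np.arange(1, nl + 2) * h / (nl + 2.0))[:, None]  # equally spaced
    x = np.arange(w) / max(w - 1, 1)
    curves = np.broadcast_to(base, (nl + 1, w)).astype(float).copy()
    if amp > 0:
        curves += rng.uniform(-amp, amp, size=(nl + 1, 1))
        for k in range(1, 4):
            a = rng.uniform(0, amp / k, size=(nl + 1, 1))
            phase = rng.uniform(0, 2 * np.pi, size=(nl + 1, 1))
            curves += a * np.sin(2 * np.pi * k * x[None, :] + phase)
    curves = np.sort(curves, axis=0)
    curves = np.clip(curves, 0.0, float(h))
    return BoundarySet(curves=curves, height=h)


def _mask_from_boundaries(boundaries: BoundarySet, config: PhantomConfig) -> np.ndarray:
    h, w = config.height, config.width
    ys = np.arange(h)[:, None]
    # r = number of curves at or above this pixel; r in 1..n_layers is tissue
    r = (ys[None, :, :] >= boundaries.curves[:, None, :]).sum(axis=0)
    mask = np.where((r >= 1) & (r <= config.n_layers), r, 0)
    return mask.astype(np.int64)


def render_phantom(boundaries: BoundarySet, config: PhantomConfig,
                   rng: np.random.Generator, source_id: str = "phantom") -> ImageSample:
    """Rasterise boundaries into a mask and synthesise the noisy image.

    The mask assigns class ``j`` to pixels between curve ``j-1`` and curve
    ``j`` (background above the first and below the last curve).  The image
    is the per-class mean intensity, multiplied by unit-mean Gamma speckle
    and perturbed by additive Gaussian noise, clipped to [0, 1].
    """
    h, w = config.height, config.width
    mask = _mask_from_boundaries(boundaries, config)

    means = np.zeros(config.n_classes, dtype=float)
    means[0] = config.background_intensity
    means[1:config.n_layers + 1] = config.layer_intensity

    # optional parabolic optic-disc cup through all layers
    if config.disc_class is not None and rng.random() < config.disc_probability:
        cx = rng.uniform(0.3, 0.7) * w
        half = rng.uniform(0.10, 0.20) * w
        rim = float(boundaries.curves[0].min())
        xs = np.arange(w)
        cup = rim + ((xs - cx) / half) ** 2 * (h - rim) * 0.5
        region = (np.arange(h)[:, None] >= cup[None, :]) & (mask > 0)
        mask[region] = config.disc_class
        means[config.disc_class] = rng.uniform(0.15, 0.35)

    # optional elliptical fluid blob confined to one layer, darker than tissue
    if config.fluid_class is not None and rng.random() < config.fluid_probability:
        layer = int(rng.integers(1, config.n_layers + 1))
        col = int(rng.integers(w // 4, 3 * w // 4))
        top = boundaries.curves[layer - 1, col]
        bot = boundaries.curves[layer, col]
        cy = 0.5 * (top + bot)
        ry = max((bot - top) * 0.4, 1.0)
        rx = rng.uniform(0.05, 0.15) * w
        yy, xx = np.mgrid[0:h, 0:w]
        ell = ((xx - col) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
        region = ell & (mask == layer)
        mask[region] = config.fluid_class
        means[config.fluid_class] = 0.08

    image = means[mask].astype(float)
    if config.speckle_looks is not None and np.isfinite(config.speckle_looks):
        looks = float(config.speckle_looks)
        image = image * rng.gamma(shape=looks, scale=1.0 / looks, size=image.shape)
    if config.gaussian_sigma > 0:
        image = image + rng.normal(0.0, config.gaussian_sigma, size=image.shape)
    image = np.clip(image, 0.0, 1.0)
    return ImageSample(image=image, mask=mask, source_id=source_id, augmented=False)


def make_phantom(config: PhantomConfig, rng: np.random.Generator,
                 source_id: str = "phantom") -> ImageSample:
    return render_phantom(sample_boundaries(config, rng), config, rng, source_id)


def generate_dataset(n: int, config: PhantomConfig, seed: int | None = None) -> list[ImageSample]:
    """Generate ``n`` independent phantoms.

    Per-sample generators are spawned from a counter-keyed ``SeedSequence``
    so the dataset is reproducible and order-independent: sample ``i`` is
    identical whether generated alone or as part of a batch.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    master = config.seed if seed is None else seed
    out = []
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=master, spawn_key=(i,)))
        out.append(make_phantom(config, rng, source_id=f"phantom-{master}-{i:05d}"))
    return out


def threshold_oracle_segmenter(image: np.ndarray, config: PhantomConfig) -> np.ndarray:
    """Nearest-mean-intensity labeling — exact on noise-free phantoms.

    Serves as the independent check that phantoms are learnable by
    construction: with speckle disabled and zero Gaussian noise each class
    is a constant gray level, so nearest-mean classification is perfect
    (layer means must be distinct).
    """
    means = np.concatenate([[config.background_intensity],
                            np.asarray(config.layer_intensity, dtype=float)])
    dist = np.abs(image[None, :, :] - means[:, None, None])
    return np.argmin(dist, axis=0).astype(np.int64)
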