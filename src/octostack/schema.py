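"""Label schemes, image/mask samples, one-hot encoding, and dataset splitting.

The default scheme covers the ten retinal strata visible in a peripapillary
OCT B-scan — RNFL, GCL, IPL, INL, OPL, ONL, IS/OS, RPE, choroid, and the
optic disc — plus an explicit background class at index 0 for the vitreous
and anything below the choroid.  Background is a deliberate addition: a
softmax segmenter needs a sink class for unlabeled area, and synthetic
phantoms have one by construction.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import KFold

RETINAL_LAYER_NAMES = (
    "background",
    "RNFL",       # retinal nerve fiber layer
    "GCL",        # ganglion cell layer
    "IPL",        # inner plexiform layer
    "INL",        # inner nuclear layer
    "OPL",        # outer plexiform layer
    "ONL",        # outer nuclear layer
    "IS/OS",      # inner/outer photoreceptor segment
    "RPE",        # retinal pigment epithelium
    "choroid",
    "optic disc",
)


def default_palette(n: int) -> list[tuple[int, int, int]]:
    """Deterministic palette: evenly spaced hues; background is black."""
    colors: list[tuple[int, int, int]] = [(0, 0, 0)]
    for i in range(1, n):
        h = (i - 1) / max(n - 1, 1)
        r, g, b = colorsys.hsv_to_rgb(h, 0.75, 0.95)
        colors.append((int(round(r * 255)), int(round(g * 255)), int(round(b * 255))))
    return colors


@dataclass(frozen=True)
class LabelScheme:
    """Ordered class list with a display palette; index 0 is background."""

    names: tuple[str, ...]
    palette: tuple[tuple[int, int, int], ...]

    @property
    def C(self) -> int:
        return len(self.names)

    def index_of(self, name: str) -> int:
        return self.names.index(name)


def make_label_scheme(names=RETINAL_LAYER_NAMES, palette=None) -> LabelScheme:
    """Build a :class:`LabelScheme`, assigning a default palette if none given.

    Raises ``ValueError`` on duplicate or empty names or a palette of the
    wrong length.
    """
    names = tuple(names)
    if not names:
        raise ValueError("scheme needs at least one class name")
    if any(not n for n in names):
        raise ValueError("class names must be non-empty")
    if len(set(names)) != len(names):
        raise ValueError("class names must be unique")
    if palette is None:
        palette = default_palette(len(names))
    palette = tuple(tuple(int(v) for v in rgb) for rgb in palette)
    if len(palette) != len(names):
        raise ValueError(f"palette has {len(palette)} entries for {len(names)} classes")
    return LabelScheme(names=names, palette=palette)


DEFAULT_SCHEME = make_label_scheme()


@dataclass
class ImageSample:
    """One grayscale image in [0, 1] with an integer label mask of equal shape."""

    image: np.ndarray
    mask: np.ndarray
    source_id: str = ""
    augmented: bool = False

    def copy(self) -> "ImageSample":
        return ImageSample(self.image.copy(), self.mask.copy(),
                           self.source_id, self.augmented)


def validate_sample(sample: ImageSample, scheme: LabelScheme) -> list[str]:
    """Return a list of invariant violations (empty when the sample is valid)."""
    violations: list[str] = []
    img, mask = np.asarray(sample.image), np.asarray(sample.mask)
    if img.ndim != 2:
        violations.append(f"image must be rank 2, got rank {img.ndim}")
    if mask.ndim != 2:
        violations.append(f"mask must be rank 2, got rank {mask.ndim}")
    if img.shape != mask.shape:
        violations.append(f"shape mismatch: image {img.shape} vs mask {mask.shape}")
    if img.size and (img.min() < 0 or img.max() > 1):
        violations.append(
            f"image intensities outside [0,1]: min {img.min():.4g}, max {img.max():.4g}")
    if mask.size:
        lo, hi = int(mask.min()), int(mask.max())
        if lo < 0 or hi >= scheme.C:
            n_bad = int(((mask < 0) | (mask >= scheme.C)).sum())
            violations.append(
                f"label out of range [0,{scheme.C}): values span [{lo},{hi}], "
                f"{n_bad} offending pixels")
    return violations


def one_hot(mask: np.ndarray, C: int) -> np.ndarray:
    """Encode an (H, W) integer mask as a (C, H, W) binary indicator stack."""
    mask = np.asarray(mask)
    if mask.size and (mask.min() < 0 or mask.max() >= C):
        raise ValueError(f"mask values must lie in [0,{C})")
    out = np.zeros((C,) + mask.shape, dtype=np.float64)
    for c in range(C):
        out[c] = mask == c
    return out


@dataclass
class DatasetSplit:
    train: list[ImageSample]
    val: list[ImageSample]
    test: list[ImageSample]
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0

    @property
    def sizes(self) -> tuple[int, int, int]:
        return len(self.train), len(self.val), len(self.test)


def split_dataset(samples: list, ratios=(0.6, 0.2, 0.2), seed: int = 0) -> DatasetSplit:
    """Seeded train/val/test split.

    Sizes follow floor(r_val * n) and floor(r_test * n) with the remainder
    going to train — the rounding rule under which 244 samples at 60/20/20
    give 148/48/48.
    """
    ratios = tuple(float(r) for r in ratios)
    if len(ratios) != 3 or any(r < 0 for r in ratios):
        raise ValueError("need three non-negative ratios")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {sum(ratios)}")
    n = len(samples)
    if n < 3 and min(ratios) > 0:
        raise ValueError("need at least 3 samples for a three-way split")
    n_val = int(np.floor(ratios[1] * n))
    n_test = int(np.floor(ratios[2] * n))
    n_train = n - n_val - n_test
    perm = np.random.default_rng(seed).permutation(n)
    ordered = [samples[i] for i in perm]
    return DatasetSplit(
        train=ordered[:n_train],
        val=ordered[n_train:n_train + n_val],
        test=ordered[n_train + n_val:],
        ratios=ratios, seed=seed)


def kfold_split(samples: list, k: int, seed: int = 0) -> list[tuple[list, list]]:
    """Seeded k-fold partition: k (train, val) pairs whose validation folds
    partition the dataset with sizes differing by at most one."""
    n = len(samples)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds dataset size n={n}")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for train_idx, val_idx in kf.split(np.arange(n)):
        folds.append(([samples[i] for i in train_idx],
                      [samples[i] for i in val_idx]))
    return folds
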