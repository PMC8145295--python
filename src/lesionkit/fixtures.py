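"""Synthetic dermoscopy-like fixtures.

Real dermoscopy images of pigmented lesions are characterised by a darker,
redder, roughly elliptical lesion on a lighter textured skin background, often
with low lesion/background contrast and occasional hair occlusion.  This
module renders a controlled caricature of that situation — a hard-edged
ellipse of configurable contrast on low-pass-filtered Gaussian skin texture,
with optional hair-like dark polylines — together with the exact ground-truth
mask, plus labeled feature matrices with a known informative subset.  Every
generator is a pure function of (spec, seed).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .features import FeatureMatrix

# Skin-like background color (R, G, B); luminance ~ 178.
_BACKGROUND_RGB = np.array([205.0, 175.0, 150.0])
# Per-channel tilt of the lesion offset: lesions lose less red than blue,
# so they come out darker *and* redder; the tilt averages to zero so the
# gray-level contrast equals lesion_contrast * 255 exactly.
_CHANNEL_TILT = np.array([-0.1, 0.0, 0.1])


@dataclass
class LesionImageSpec:
    """Parameters of one synthetic lesion image.

    lesion_contrast is the fractional mean-intensity gap between lesion and
    background (0 = invisible lesion, 1 = full 255-level gap).
    background_texture_sd is the pixel SD of the low-pass skin texture, in
    8-bit intensity units.
    """

    height: int = 64
    width: int = 64
    center: tuple[float, float] = (32.0, 32.0)     # (row, col)
    axes: tuple[float, float] = (16.0, 10.0)       # semi-axes (pixels)
    rotation: float = 0.0                          # degrees, CCW
    lesion_contrast: float = 0.4
    background_texture_sd: float = 6.0
    hair_artifacts: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("image dimensions must be positive")
        if not 0.0 <= self.lesion_contrast <= 1.0:
            raise ValueError("lesion_contrast must be in [0, 1]")
        if self.background_texture_sd < 0:
            raise ValueError("background_texture_sd must be >= 0")
        a, b = self.axes
        if a <= 0 or b <= 0:
            raise ValueError("ellipse axes must be positive")
        th = np.deg2rad(self.rotation)
        half_h = np.hypot(a * np.sin(th), b * np.cos(th))
        half_w = np.hypot(a * np.cos(th), b * np.sin(th))
        r, c = self.center
        if (r - half_h < 0 or r + half_h > self.height - 1
                or c - half_w < 0 or c + half_w > self.width - 1):
            raise ValueError(
                f"ellipse (center {self.center}, axes {self.axes}, rotation "
                f"{self.rotation} deg) does not fit inside {self.height}x{self.width}"
            )


@dataclass
class FeatureDatasetSpec:
    """Parameters of a synthetic labeled feature matrix."""

    n_samples_per_class: tuple[int, ...] = (50, 50)
    n_features: int = 100
    n_informative: int = 10
    class_separation: float = 2.0   # adjacent-class mean gap, in noise-SD units
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.n_samples_per_class) == 0:
            raise ValueError("at least one class is required")
        if any(n < 1 for n in self.n_samples_per_class):
            raise ValueError("all class counts must be positive")
        if self.n_features < 1:
            raise ValueError("n_features must be positive")
        if not 0 <= self.n_informative <= self.n_features:
            raise ValueError("n_informative must be <= n_features")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def ellipse_mask(spec: LesionImageSpec) -> np.ndarray:
    """Binary mask of the spec's ellipse via an exact point-in-ellipse test."""
    rr, cc = np.mgrid[0:spec.height, 0:spec.width]
    th = np.deg2rad(spec.rotation)
    dr, dc = rr - spec.center[0], cc - spec.center[1]
    u = dc * np.cos(th) + dr * np.sin(th)
    v = -dc * np.sin(th) + dr * np.cos(th)
    a, b = spec.axes
    return ((u / a) ** 2 + (v / b) ** 2 <= 1.0).astype(np.uint8)


def _bezier_points(p0, p1, p2, n=200):
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t ** 2 * p2


def generate_lesion_image(spec: LesionImageSpec):
    """Render (RGB image, binary mask) for a lesion spec.

    The lesion ellipse has a hard (non-anti-aliased) boundary so the mask is
    unambiguous; lesion pixels are darker and redder than the background by
    ``lesion_contrast`` (gray-level gap lesion_contrast * 255).  Texture is
    Gaussian noise low-pass filtered with a fixed small kernel and rescaled to
    the requested SD, shared across channels.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    mask = ellipse_mask(spec)

    img = np.empty((spec.height, spec.width, 3), dtype=float)
    img[:] = _BACKGROUND_RGB
    offset = spec.lesion_contrast * 255.0 * (1.0 + _CHANNEL_TILT)
    img[mask == 1] = _BACKGROUND_RGB - offset

    if spec.background_texture_sd > 0:
        noise = rng.standard_normal((spec.height, spec.width))
        noise = gaussian_filter(noise, sigma=1.5, mode="reflect")
        sd = noise.std()
        if sd > 0:
            noise *= spec.background_texture_sd / sd
        img += noise[:, :, None]

    for _ in range(spec.hair_artifacts):
        pts = rng.uniform([0, 0], [spec.height - 1, spec.width - 1], size=(3, 2))
        curve = _bezier_points(*pts)
        rr = np.clip(np.round(curve[:, 0]).astype(int), 0, spec.height - 1)
        cc = np.clip(np.round(curve[:, 1]).astype(int), 0, spec.width - 1)
        img[rr, cc] = [40.0, 30.0, 30.0]

    return np.clip(np.round(img), 0, 255).astype(np.uint8), mask


def generate_feature_dataset(spec: FeatureDatasetSpec):
    """Labeled feature matrix with a known informative subset.

    Informative columns carry class-dependent means: adjacent classes are
    separated by exactly ``class_separation`` noise-SDs on every informative
    column (with a per-column random sign); the remaining columns are pure
    N(0, noise_sd) noise.  Returns (FeatureMatrix, labels, informative_indices).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_classes = len(spec.n_samples_per_class)
    n_total = int(sum(spec.n_samples_per_class))

    informative = np.sort(rng.choice(spec.n_features, size=spec.n_informative, replace=False))
    signs = rng.choice([-1.0, 1.0], size=spec.n_informative)

    labels = np.repeat(np.arange(n_classes), spec.n_samples_per_class)
    X = rng.normal(0.0, spec.noise_sd, size=(n_total, spec.n_features))
    centered = labels - (n_classes - 1) / 2.0
    X[:, informative] += (
        spec.class_separation * spec.noise_sd * centered[:, None] * signs[None, :]
    )
    matrix = FeatureMatrix(X, labels)
    return matrix, labels, informative


def scale_class_counts(counts, factor: float) -> list[int]:
    """Proportionally scale class counts, rounding half-up with a floor of 1."""
    if len(counts) == 0:
        raise ValueError("empty class list")
    return [max(1, int(np.floor(c * factor + 0.5))) for c in counts]


# Per-class count shape of a well-known seven-class dermoscopy archive
# (actinic keratoses, basal cell carcinoma, benign keratoses, dermatofibroma,
# nevi, melanoma, vascular lesions) — used only as an imbalance shape.
HAM10000_CLASS_COUNTS = (327, 541, 1099, 155, 6705, 1113, 142)
HAM10000_CLASS_NAMES = ("AKIEC", "BCC", "BKL", "DF", "NV", "MEL", "VASC")


def generate_class_directory(counts, out_dir, image_size: int = 64,
                             class_names=None, seed: int = 0) -> dict:
    """Write per-class subdirectories of synthetic lesion PNGs.

    ``counts`` gives the number of images per class (use
    :func:`scale_class_counts` to emulate an imbalanced archive at desk
    scale).  Classes differ systematically in lesion contrast and size so
    that they are learnable.  Returns {class_name: count_written}.
    """
    counts = list(counts)
    if len(counts) == 0:
        raise ValueError("empty class list")
    if any(c < 1 for c in counts):
        raise ValueError("all class counts must be positive")
    if class_names is None:
        class_names = [f"class{k}" for k in range(len(counts))]
    os.makedirs(out_dir, exist_ok=True)
    written = {}
    rng = np.random.default_rng(seed)
    for k, (name, n) in enumerate(zip(class_names, counts)):
        sub = os.path.join(out_dir, name)
        os.makedirs(sub, exist_ok=True)
        for i in range(n):
            spec = class_image_spec(k, len(counts), image_size,
                                    seed=int(rng.integers(0, 2**31 - 1)), rng=rng)
            img, _ = generate_lesion_image(spec)
            Image.fromarray(img).save(os.path.join(sub, f"{name}_{i:04d}.png"))
        written[name] = n
    return written


def class_image_spec(class_index: int, n_classes: int, image_size: int = 64,
                     seed: int = 0, rng=None) -> LesionImageSpec:
    """Lesion spec for one image of a given class.

    Classes are distinguished by lesion contrast (spread over [0.25, 0.55])
    and mean size; within-class geometry jitters with the seed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    frac = 0.0 if n_classes == 1 else class_index / (n_classes - 1)
    contrast = 0.25 + 0.30 * frac
    base_axis = image_size * (0.18 + 0.10 * frac)
    a = base_axis * rng.uniform(0.85, 1.15)
    b = a * rng.uniform(0.55, 0.8)
    rot = rng.uniform(0.0, 180.0)
    margin = np.hypot(a, b) + 1
    lo, hi = margin, image_size - 1 - margin
    if lo >= hi:
        raise ValueError("image too small for the class lesion size")
    center = (rng.uniform(lo, hi), rng.uniform(lo, hi))
    return LesionImageSpec(
        height=image_size, width=image_size, center=center, axes=(a, b),
        rotation=rot, lesion_contrast=contrast, background_texture_sd=6.0,
        hair_artifacts=0, seed=seed,
    )


@dataclass
class SegmentationDataset:
    """In-memory bundle of images, ground-truth masks and class labels."""

    images: list = field(default_factory=list)
    masks: list = field(default_factory=list)
    labels: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))


def generate_segmentation_dataset(n_images: int, image_size: int = 64,
                                  n_classes: int = 2, seed: int = 0) -> SegmentationDataset:
    """n_images lesion images with masks, split evenly over n_classes.

    Class identity modulates lesion contrast/size (via
    :func:`class_image_spec`), giving the saliency CNN a learnable signal.
    """
    rng = np.random.default_rng(seed)
    ds = SegmentationDataset()
    labels = []
    for i in range(n_images):
        k = i % n_classes
        spec = class_image_spec(k, n_classes, image_size,
                                seed=int(rng.integers(0, 2**31 - 1)), rng=rng)
        img, mask = generate_lesion_image(spec)
        ds.images.append(img)
        ds.masks.append(mask)
        labels.append(k)
    ds.labels = np.asarray(labels, dtype=int)
    return ds


def load_image_directory(images_dir, masks_dir=None) -> SegmentationDataset:
    """Read a per-class image directory (and optional mask directory).

    ``images_dir`` holds one subdirectory per class of PNG/JPEG images —
    the layout :func:`generate_class_directory` writes and public dermoscopy
    archives commonly use.  Masks, when given, are matched by file stem
    (``<stem>.png``) anywhere under ``masks_dir``; images without a mask get
    an all-zero placeholder and are flagged via the returned dataset's
    ``masks`` entries being ``None``-free only when every mask was found.
    """
    import pathlib

    root = pathlib.Path(images_dir)
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not class_dirs:
        raise ValueError(f"{images_dir}: no class subdirectories found")
    mask_index = {}
    if masks_dir is not None:
        for p in pathlib.Path(masks_dir).rglob("*.png"):
            mask_index[p.stem] = p
    ds = SegmentationDataset()
    labels = []
    for k, cdir in enumerate(class_dirs):
        for img_path in sorted(cdir.iterdir()):
            if img_path.suffix.lower() not in (".png", ".jpg", ".jpeg"):
                continue
            img = np.asarray(Image.open(img_path).convert("RGB"))
            mask_path = mask_index.get(img_path.stem)
            mask = load_mask(mask_path) if mask_path else None
            ds.images.append(img)
            ds.masks.append(mask)
            labels.append(k)
    ds.labels = np.asarray(labels, dtype=int)
    if len(ds.images) == 0:
        raise ValueError(f"{images_dir}: no images found")
    return ds


def save_mask(mask: np.ndarray, path) -> None:
    """Write a binary mask as a single-channel PNG with values {0, 255}."""
    Image.fromarray((np.asarray(mask) > 0).astype(np.uint8) * 255).save(path)


def load_mask(path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"))
    return (arr > 127).astype(np.uint8)
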