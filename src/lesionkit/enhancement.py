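"""Hybrid lesion-contrast stretching.

Dermoscopic lesions sit in the dark band of the gray-level histogram.  The
enhancement chain implemented here:

1. histogram of the luminance image;
2. lesion band [k1, kn]: from the lowest occupied level up to the Otsu split
   (lesions are the darker mode), giving an in-band pixel patch;
3. global population variance, normalized by the maximum possible 8-bit
   variance, as a bounded gain weight for the patch;
4. variance-weighted contrast amplification of the patch about its mean,
   followed by histogram equalization *within the patch only* (classic CDF
   mapping onto the patch's own level range);
5. a 50/50 convex blend of the original with the patch-composited image;
6. two sequential gain passes: candidate gains g in {1..5} applied about the
   image mean, scored by Otsu between-class variance, arg-max retained.

Color images are processed on luminance; chroma is preserved by rescaling
each channel by the per-pixel luminance ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

K_LEVELS = 256
# Maximum population variance of an 8-bit image: half mass at 0, half at 255.
MAX_VARIANCE_8BIT = (255.0 / 2.0) ** 2


@dataclass
class GrayHistogram:
    """Occurrence counts per gray level j in 0..K-1."""

    counts: np.ndarray
    K: int = K_LEVELS


@dataclass
class LesionRange:
    """Contiguous dark gray-level band [k1, kn] and its pixel patch."""

    k1: int
    kn: int
    patch_mask: np.ndarray
    degenerate: bool = False


@dataclass
class EnhancementResult:
    fused: np.ndarray
    pass1: np.ndarray
    pass2: np.ndarray
    sigma2: float
    mu: float


def to_gray(image: np.ndarray) -> np.ndarray:
    """8-bit luminance (ITU-R BT.601 weights) of an RGB or gray image."""
    arr = np.asarray(image)
    if arr.ndim == 2:
        return arr.astype(np.uint8)
    if arr.ndim == 3 and arr.shape[2] == 3:
        y = arr[..., 0] * 0.299 + arr[..., 1] * 0.587 + arr[..., 2] * 0.114
        return np.clip(np.round(y), 0, 255).astype(np.uint8)
    raise ValueError("expected HxW gray or HxWx3 RGB image")


def compute_histogram(image: np.ndarray) -> GrayHistogram:
    """256-bin occurrence histogram of an 8-bit single-channel image."""
    gray = to_gray(image)
    if gray.size == 0:
        raise ValueError("empty image")
    counts = np.bincount(gray.ravel(), minlength=K_LEVELS)
    return GrayHistogram(counts=counts)


def otsu_threshold_from_histogram(counts: np.ndarray) -> int:
    """Otsu's threshold t maximizing between-class variance.

    Foreground/background split is levels <= t vs > t; ties broken by the
    lowest t.  Returns -1 for a histogram occupying a single level.
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    levels = np.arange(counts.size, dtype=float)
    occupied = np.flatnonzero(counts)
    if occupied.size <= 1:
        return -1
    w0 = np.cumsum(counts) / total
    m = np.cumsum(counts * levels) / total
    mu_total = m[-1]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        between = (mu_total * w0 - m) ** 2 / (w0 * w1)
    between[~np.isfinite(between)] = -1.0
    return int(np.argmax(between))


def otsu_between_class_variance(image: np.ndarray) -> float:
    """Between-class variance at the Otsu split of an image's histogram."""
    counts = compute_histogram(image).counts.astype(float)
    t = otsu_threshold_from_histogram(counts)
    if t < 0:
        return 0.0
    total = counts.sum()
    levels = np.arange(counts.size, dtype=float)
    w0 = counts[: t + 1].sum() / total
    w1 = 1.0 - w0
    if w0 == 0 or w1 == 0:
        return 0.0
    mu0 = (counts[: t + 1] * levels[: t + 1]).sum() / counts[: t + 1].sum()
    mu1 = (counts[t + 1:] * levels[t + 1:]).sum() / counts[t + 1:].sum()
    return float(w0 * w1 * (mu0 - mu1) ** 2)


def locate_lesion_range(hist: GrayHistogram, image: np.ndarray) -> LesionRange:
    """Lesion gray-level band: lowest occupied level up to the Otsu split.

    On a unimodal or constant image the full occupied range is returned with
    ``degenerate=True``.
    """
    gray = to_gray(image)
    counts = hist.counts
    if counts.sum() == 0:
        raise ValueError("empty histogram")
    occupied = np.flatnonzero(counts)
    t = otsu_threshold_from_histogram(counts)
    if t < 0:
        k1, kn = int(occupied[0]), int(occupied[-1])
        return LesionRange(k1, kn, np.ones_like(gray, dtype=np.uint8), degenerate=True)
    k1, kn = int(occupied[0]), t
    patch = ((gray >= k1) & (gray <= kn)).astype(np.uint8)
    return LesionRange(k1, kn, patch)


def image_variance(image: np.ndarray):
    """(population variance, mean) of the luminance image."""
    gray = to_gray(image).astype(float)
    if gray.size == 0:
        raise ValueError("empty image")
    mu = gray.mean()
    sigma2 = (gray ** 2).mean() - mu ** 2
    return float(max(sigma2, 0.0)), float(mu)


def _equalize_within_patch(values: np.ndarray) -> np.ndarray:
    """Classic CDF histogram equalization mapped onto the values' own range."""
    counts = np.bincount(values, minlength=K_LEVELS).astype(float)
    n = counts.sum()
    cdf = np.cumsum(counts) / n
    occupied = np.flatnonzero(counts)
    lo, hi = occupied[0], occupied[-1]
    cdf_min = cdf[lo]
    if cdf_min >= 1.0:       # single level: equalization is degenerate
        return values.copy()
    mapped = lo + (cdf - cdf_min) / (1.0 - cdf_min) * (hi - lo)
    return np.clip(np.round(mapped[values]), 0, 255).astype(np.uint8)


def weight_and_equalize_patch(lesion_range: LesionRange, sigma2: float,
                              image: np.ndarray) -> np.ndarray:
    """Variance-weighted amplification + in-patch equalization.

    Patch pixels are contrast-amplified about the patch mean with gain
    (1 + w), w = sigma2 / max possible 8-bit variance, then histogram
    equalized within the patch only.  Pixels outside the patch are returned
    unchanged; an empty patch is the identity.
    """
    gray = to_gray(image)
    patch = lesion_range.patch_mask.astype(bool)
    out = gray.copy()
    if not patch.any():
        return out
    w = float(np.clip(sigma2 / MAX_VARIANCE_8BIT, 0.0, 1.0))
    vals = gray[patch].astype(float)
    amplified = np.clip(np.round(vals.mean() + (1.0 + w) * (vals - vals.mean())),
                        0, 255).astype(np.uint8)
    out[patch] = _equalize_within_patch(amplified)
    return out


def fuse_with_original(image: np.ndarray, patch_image: np.ndarray,
                       alpha: float = 0.5, patch_mask: np.ndarray | None = None) -> np.ndarray:
    """Convex blend of the original with the patch-composited image.

    fused = clip(alpha * image + (1 - alpha) * composited); outside the patch
    the original is returned unchanged (the composite equals the original
    there by construction when ``patch_mask`` is given).
    """
    gray = to_gray(image)
    patch_image = np.asarray(patch_image)
    if gray.shape != patch_image.shape:
        raise ValueError("image and patch image shapes differ")
    composited = patch_image.astype(float)
    if patch_mask is not None:
        composited = np.where(patch_mask.astype(bool), composited, gray.astype(float))
    fused = alpha * gray.astype(float) + (1.0 - alpha) * composited
    return np.clip(np.round(fused), 0, 255).astype(np.uint8)


def _best_gain(image: np.ndarray, gains=(1, 2, 3, 4, 5)) -> np.ndarray:
    gray = to_gray(image).astype(float)
    mu = gray.mean()
    best, best_score = None, -1.0
    for g in gains:
        cand = np.clip(np.round(mu + g * (gray - mu)), 0, 255).astype(np.uint8)
        score = otsu_between_class_variance(cand)
        if score > best_score:
            best, best_score = cand, score
    return best


def apply_gain_passes(image: np.ndarray):
    """Two sequential separability-scored gain passes.

    Each pass tries contrast gains 1..5 about the image mean and keeps the
    candidate with the largest Otsu between-class variance (ties -> the
    smallest gain); the second pass repeats the search on the first pass's
    output.  Returns (pass1, pass2).
    """
    pass1 = _best_gain(image)
    pass2 = _best_gain(pass1)
    return pass1, pass2


def enhance_gray(gray: np.ndarray) -> EnhancementResult:
    """Full enhancement chain on a single-channel 8-bit image."""
    hist = compute_histogram(gray)
    lesion_range = locate_lesion_range(hist, gray)
    sigma2, mu = image_variance(gray)
    patch_img = weight_and_equalize_patch(lesion_range, sigma2, gray)
    fused = fuse_with_original(gray, patch_img, patch_mask=lesion_range.patch_mask)
    pass1, pass2 = apply_gain_passes(fused)
    return EnhancementResult(fused=fused, pass1=pass1, pass2=pass2,
                             sigma2=sigma2, mu=mu)


def enhance(image: np.ndarray) -> np.ndarray:
    """Contrast-enhance an RGB or gray image; shape is preserved.

    The chain runs on luminance; for color inputs each channel is rescaled by
    the per-pixel luminance ratio so hue is kept stable.
    """
    arr = np.asarray(image)
    gray = to_gray(arr)
    result = enhance_gray(gray)
    if arr.ndim == 2:
        return result.pass2
    ratio = result.pass2.astype(float) / np.maximum(gray.astype(float), 1.0)
    out = np.clip(np.round(arr.astype(float) * ratio[:, :, None]), 0, 255)
    return out.astype(np.uint8)
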