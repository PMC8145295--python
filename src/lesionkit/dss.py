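"""Deep Saliency Segmentation (DSS).

A small CNN is trained to discriminate lesion classes; because the classes
differ only through their lesions, its third convolutional layer learns
lesion-sensitive channels.  Those channel activations are fused into a
real-valued saliency map, homogenized over SLIC superpixels of the (enhanced)
image, binarized at the map mean, and cleaned up morphologically; the lesion
boundary is finally refined with a region-based active contour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage import measure
from skimage.segmentation import morphological_chan_vese, slic
from skimage.transform import resize

from .enhancement import to_gray
from .nn import SaliencyNet, SaliencyNetSpec

__all__ = [
    "SaliencyNetSpec", "SaliencyMap", "LesionMask", "SegmentationReport",
    "build_saliency_net", "train_saliency_net", "compute_saliency_map",
    "refine_with_superpixels", "threshold_saliency", "postprocess_mask",
    "refine_mask_chan_vese", "extract_lesion_boundary",
    "evaluate_segmentation", "segment_image",
]


@dataclass
class SaliencyMap:
    """Real-valued lesion-ness map in [0, 1], same grid as the input image."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("saliency map must be finite")
        if v.size and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
            raise ValueError("saliency map must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)


@dataclass
class LesionMask:
    """Binary lesion mask plus the threshold that produced it."""

    values: np.ndarray
    tau: float = float("nan")
    empty_warning: bool = False

    def __post_init__(self) -> None:
        self.values = (np.asarray(self.values) > 0).astype(np.uint8)


@dataclass
class SegmentationReport:
    """Pixel accuracy (%), error = 100 - accuracy, and Dice overlap."""

    accuracy: float
    error: float
    dice: float


def _minmax(a: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]; a constant array maps to all zeros."""
    lo, hi = float(a.min()), float(a.max())
    if hi - lo <= 0:
        return np.zeros_like(a, dtype=float)
    return (a - lo) / (hi - lo)


def build_saliency_net(spec: SaliencyNetSpec) -> SaliencyNet:
    """Untrained ten-layer CNN with conv filter counts (64, 64, 128)."""
    return SaliencyNet(spec)


def train_saliency_net(net: SaliencyNet, images, class_labels):
    """Train the CNN on image-level class labels; returns (net, loss history)."""
    history = net.train(images, class_labels)
    return net, history


def compute_saliency_map(net: SaliencyNet, image: np.ndarray) -> SaliencyMap:
    """Fuse all third-conv-layer channels into one saliency map.

    Each channel is min-max normalized, the channels are averaged, the result
    is bilinearly upsampled to the network input size and min-max normalized
    again.  Constant (dead) channels normalize to zero.
    """
    if not getattr(net, "trained", False):
        raise ValueError("compute_saliency_map requires a trained network")
    act = net.conv_activations(image)
    if not np.all(np.isfinite(act)):
        raise ValueError("network produced non-finite activations")
    lo = act.min(axis=(0, 1), keepdims=True)
    hi = act.max(axis=(0, 1), keepdims=True)
    span = hi - lo
    span[span <= 0] = 1.0
    normed = np.where(hi - lo > 0, (act - lo) / span, 0.0)
    fusedsmall = normed.mean(axis=2)
    s = net.spec.input_size
    fused = resize(fusedsmall, (s, s), order=1, preserve_range=True)
    return SaliencyMap(_minmax(fused))


def refine_with_superpixels(sal: SaliencyMap, image: np.ndarray,
                            n_segments: int = 200) -> SaliencyMap:
    """Replace saliency within each SLIC superpixel by its mean.

    SLIC runs on the image (lesion-aligned color boundaries); the averaging
    runs on the map.  The result is renormalized to [0, 1].
    """
    vals = sal.values
    if n_segments < 2:
        raise ValueError("n_segments must be >= 2")
    if n_segments > vals.size:
        raise ValueError("n_segments exceeds the pixel count")
    img = np.asarray(image)
    if img.shape[:2] != vals.shape:
        img = resize(img, vals.shape, order=1, preserve_range=True)
    labels = slic(img.astype(float) / 255.0, n_segments=n_segments,
                  channel_axis=-1 if img.ndim == 3 else None, start_label=0)
    sums = np.bincount(labels.ravel(), weights=vals.ravel())
    counts = np.bincount(labels.ravel())
    means = sums / np.maximum(counts, 1)
    return SaliencyMap(_minmax(means[labels]))


def threshold_saliency(sal: SaliencyMap) -> LesionMask:
    """Binarize at the map mean: foreground strictly above tau."""
    tau = float(sal.values.mean())
    return LesionMask((sal.values > tau).astype(np.uint8), tau=tau)


def postprocess_mask(mask: LesionMask) -> LesionMask:
    """Fill holes, then keep only the largest connected foreground component."""
    m = mask.values.astype(bool)
    if not m.any():
        return LesionMask(np.zeros_like(mask.values), tau=mask.tau, empty_warning=True)
    filled = binary_fill_holes(m)
    labels = measure.label(filled, connectivity=2)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    return LesionMask((labels == largest).astype(np.uint8), tau=mask.tau)


def refine_mask_chan_vese(mask: LesionMask, image: np.ndarray,
                          iterations: int = 50) -> LesionMask:
    """Evolve the mask with a region-based (Chan-Vese) active contour.

    The contour is initialized from the binary mask and evolved on the gray
    image for a fixed number of iterations; 0 iterations returns the mask
    unchanged.  Evolution that collapses to an empty set is discarded.
    """
    m = mask.values.astype(bool)
    if iterations <= 0 or not m.any():
        return mask
    gray = to_gray(image).astype(float) / 255.0
    if gray.shape != m.shape:
        gray = resize(gray, m.shape, order=1, preserve_range=True)
    if m.all() or abs(gray[m].mean() - gray[~m].mean()) < 0.02:
        return mask     # no region contrast to drive the contour
    evolved = morphological_chan_vese(gray, num_iter=iterations,
                                      init_level_set=m, smoothing=1)
    if not evolved.any():
        return mask
    return LesionMask(evolved.astype(np.uint8), tau=mask.tau)


def extract_lesion_boundary(mask: LesionMask, image: np.ndarray,
                            iterations: int = 50) -> np.ndarray:
    """Closed boundary polygon of the lesion after active-contour refinement.

    0 iterations returns the marching-squares contour of the mask itself.
    Returns (K, 2) row/col coordinates.
    """
    if not mask.values.any():
        raise ValueError("cannot extract a boundary from an empty mask")
    m = refine_mask_chan_vese(mask, image, iterations).values
    contours = measure.find_contours(m.astype(float), 0.5)
    if not contours:
        raise ValueError("no boundary found")
    return max(contours, key=len)


def evaluate_segmentation(pred: LesionMask, truth) -> SegmentationReport:
    """Pixelwise accuracy/error/Dice of a predicted mask vs ground truth."""
    p = pred.values.astype(bool)
    t = (np.asarray(truth.values if isinstance(truth, LesionMask) else truth) > 0)
    if p.shape != t.shape:
        raise ValueError("prediction and ground truth shapes differ")
    tp = int(np.sum(p & t))
    tn = int(np.sum(~p & ~t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    accuracy = 100.0 * (tp + tn) / p.size
    dice = 1.0 if (2 * tp + fp + fn) == 0 else 2.0 * tp / (2 * tp + fp + fn)
    return SegmentationReport(accuracy=accuracy, error=100.0 - accuracy, dice=dice)


def segment_image(net: SaliencyNet, image: np.ndarray, n_segments: int = 200,
                  refine_image: np.ndarray | None = None,
                  refine_iterations: int = 50) -> LesionMask:
    """Full DSS chain: saliency -> SLIC -> threshold -> cleanup -> contour.

    The final active-contour refinement runs on ``refine_image`` when given
    (typically the un-enhanced original, whose clean lesion/background
    statistics the region-based contour exploits), else on ``image``.  The
    returned mask lives on the network input grid; upsample with
    nearest-neighbor to compare against masks at other resolutions.
    """
    sal = compute_saliency_map(net, image)
    sal = refine_with_superpixels(sal, image, n_segments=n_segments)
    mask = threshold_saliency(sal)
    mask = postprocess_mask(mask)
    target = image if refine_image is None else refine_image
    return refine_mask_chan_vese(mask, target, iterations=refine_iterations)


def resize_mask(mask: LesionMask, shape) -> LesionMask:
    """Nearest-neighbor resize of a binary mask to ``shape``."""
    if mask.values.shape == tuple(shape):
        return mask
    out = resize(mask.values.astype(float), shape, order=0, preserve_range=True)
    return LesionMask((out > 0.5).astype(np.uint8), tau=mask.tau)
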