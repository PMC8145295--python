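"""Class balancing by deterministic augmentation and deep-feature extraction.

Feature vectors are taken as the global-average-pooled activations of a
convolutional backbone.  The desk-scale default backbone is the package's own
small CNN (:mod:`lesionkit.nn`), whose last convolutional layer is 128
channels wide; pretrained ResNet101 / DenseNet201 backbones are accepted
through the same interface but require their optional deep-learning
dependency and are never needed for the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class FeatureMatrix:
    """N samples x d real-valued features with aligned labels.

    Attributes
    ----------
    values : (N, d) float array, finite.
    labels : (N,) integer class labels aligned 1:1 with rows.
    sample_ids : (N,) identifiers; generated as consecutive ints if omitted.
    """

    values: np.ndarray
    labels: np.ndarray
    sample_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] < 1:
            raise ValueError("feature matrix must be 2-D with at least one column")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")
        self.labels = np.asarray(self.labels)
        if self.labels.shape != (self.values.shape[0],):
            raise ValueError("labels must align 1:1 with feature rows")
        if self.sample_ids is None:
            self.sample_ids = np.arange(self.values.shape[0])
        else:
            self.sample_ids = np.asarray(self.sample_ids)
            if self.sample_ids.shape != (self.values.shape[0],):
                raise ValueError("sample_ids must align 1:1 with feature rows")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def feature_dim(self) -> int:
        return self.values.shape[1]

    def select_columns(self, indices) -> "FeatureMatrix":
        idx = np.asarray(indices, dtype=int)
        return FeatureMatrix(self.values[:, idx], self.labels.copy(), self.sample_ids.copy())

    def to_csv(self, path) -> None:
        """Write as comma-delimited text: header row, final ``label`` column."""
        df = pd.DataFrame(self.values, columns=[f"f{j}" for j in range(self.feature_dim)])
        df["label"] = self.labels
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        if "label" not in df.columns:
            raise ValueError(f"{path}: expected a final 'label' column")
        labels = df.pop("label").to_numpy()
        return cls(df.to_numpy(dtype=float), labels)


@dataclass
class BackboneSpec:
    """Feature-extraction backbone: global-average pooling over its last conv map.

    ``tiny-cnn`` is the built-in numpy CNN (output_dim 128).  ``resnet101`` and
    ``densenet201`` name pretrained networks that require an optional deep
    learning dependency; the interface reports whatever width the backbone
    emits and never hard-codes one.
    """

    name: str = "tiny-cnn"
    pooling: str = "global-average"
    output_dim: int | None = None

    def __post_init__(self) -> None:
        if self.pooling != "global-average":
            raise ValueError("only global-average pooling is supported")
        if self.name not in {"tiny-cnn", "resnet101", "densenet201"}:
            raise ValueError(f"unknown backbone {self.name!r}")


# Deterministic augmentation variants, applied in exactly this order.
_VARIANTS = (
    ("identity", lambda a: a),
    ("hflip", lambda a: a[:, ::-1]),
    ("vflip", lambda a: a[::-1, :]),
    ("transpose", lambda a: np.swapaxes(a, 0, 1)),
    ("transpose-hflip", lambda a: np.swapaxes(a[:, ::-1], 0, 1)),
    ("transpose-vflip", lambda a: np.swapaxes(a[::-1, :], 0, 1)),
)


def augment_to_balance(images, labels, target_per_class: int):
    """Grow every class to exactly ``target_per_class`` images.

    Each original contributes up to six variants — identity, horizontal flip,
    vertical flip, and the transposes of all three — cycled deterministically
    (variant-major, originals in input order) until the target is reached.

    Returns ``(images, labels)`` lists; raises if a class cannot reach the
    target with six variants per original.
    """
    labels = np.asarray(labels)
    if len(images) != len(labels):
        raise ValueError("images and labels must align")
    out_images: list[np.ndarray] = []
    out_labels: list = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        originals = [np.asarray(images[i]) for i in idx]
        cap = 6 * len(originals)
        if target_per_class > cap:
            raise ValueError(
                f"class {cls!r}: target {target_per_class} unreachable with "
                f"{len(originals)} originals x 6 variants (max {cap})"
            )
        kept = 0
        for _, fn in _VARIANTS:
            for img in originals:
                if kept == target_per_class:
                    break
                out_images.append(np.ascontiguousarray(fn(img)))
                out_labels.append(cls)
                kept += 1
            if kept == target_per_class:
                break
    return out_images, np.asarray(out_labels)


def extract_features(backbone: BackboneSpec, images, net=None) -> FeatureMatrix:
    """Per-image deep features: global-average-pooled backbone activations.

    For the ``tiny-cnn`` backbone, ``net`` is a trained
    :class:`lesionkit.nn.SaliencyNet`; row i is the spatial mean of each of
    its last-conv-layer channels on image i (d = 128).
    """
    if backbone.name in ("resnet101", "densenet201"):
        raise ImportError(
            f"backbone {backbone.name!r} requires the optional pretrained-model "
            "dependency (torch/torchvision), which is not installed; use the "
            "'tiny-cnn' backbone or install the extra"
        )
    if net is None:
        raise ValueError("the tiny-cnn backbone needs a trained net (see lesionkit.dss)")
    rows = []
    for img in images:
        act = net.conv_activations(img)          # (H', W', C)
        rows.append(act.mean(axis=(0, 1)))       # global average pool
    values = np.asarray(rows, dtype=float)
    labels = np.zeros(len(rows), dtype=int)
    return FeatureMatrix(values, labels)


def split_dataset(matrix: FeatureMatrix, train_frac: float, seed: int):
    """Stratified train/test split of a feature matrix.

    Per class, ``round(train_frac * count)`` rows (clamped so both partitions
    are nonempty when the class has >= 2 samples) go to train.  A class with a
    single sample goes entirely to train.  Deterministic in ``seed``.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in np.unique(matrix.labels):
        idx = np.flatnonzero(matrix.labels == cls)
        rng.shuffle(idx)
        if len(idx) < 2:
            train_idx.extend(idx)
            continue
        n_train = int(round(train_frac * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    train_idx = np.sort(np.asarray(train_idx, dtype=int))
    test_idx = np.sort(np.asarray(test_idx, dtype=int))

    def take(ix):
        return FeatureMatrix(matrix.values[ix], matrix.labels[ix], matrix.sample_ids[ix])

    return take(train_idx), take(test_idx)
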