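"""End-to-end experiment orchestration.

Two experiment drivers mirror the two halves of the analysis chain:

* :func:`run_segmentation_experiment` — (optional) contrast enhancement,
  saliency-CNN training on one half of a lesion image set, DSS segmentation
  of the other half, pixel accuracy / Dice against ground truth.
* :func:`run_classification_experiment` — two feature streams, (I)MFO
  selection per stream on the training partition, correlation fusion, KELM
  classification, macro metrics.

Both are pure functions of their config (every stochastic stage is seeded
from the config's global seed), and both return plain dicts that serialize
to JSON.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import dss, enhancement, fusion, imfo, kelm
from .features import FeatureMatrix, split_dataset
from .fixtures import FeatureDatasetSpec, SegmentationDataset, generate_feature_dataset, generate_segmentation_dataset
from .nn import SaliencyNetSpec


@dataclass
class SegmentationConfig:
    n_images: int = 200
    image_size: int = 64
    n_classes: int = 2
    train_frac: float = 0.5
    use_enhancement: bool = True
    n_segments: int = 200
    epochs: int = 10
    seed: int = 0


def _stratified_split_indices(labels: np.ndarray, train_frac: float, seed: int):
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n_train = max(1, min(int(round(train_frac * len(idx))), len(idx) - 1))
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    return np.sort(train_idx), np.sort(test_idx)


def run_segmentation_experiment(cfg: SegmentationConfig,
                                dataset: SegmentationDataset | None = None,
                                net=None) -> dict:
    """Train the saliency CNN on half the images, segment and score the rest.

    Returns a report dict with per-image and mean accuracy / error / dice,
    plus the trained net under the ``"_net"`` key for reuse.
    """
    if dataset is None:
        dataset = generate_segmentation_dataset(
            cfg.n_images, cfg.image_size, cfg.n_classes, seed=cfg.seed)
    if len(dataset.images) == 0:
        raise ValueError("empty image set")
    images = dataset.images
    if cfg.use_enhancement:
        images = [enhancement.enhance(img) for img in images]
    tr, te = _stratified_split_indices(dataset.labels, cfg.train_frac, cfg.seed + 11)

    if net is None:
        spec = SaliencyNetSpec(input_size=cfg.image_size, n_classes=cfg.n_classes,
                               epochs=cfg.epochs, seed=cfg.seed)
        net = dss.build_saliency_net(spec)
        dss.train_saliency_net(net, [images[i] for i in tr], dataset.labels[tr])

    per_image = []
    n_unevaluated = 0
    for i in te:
        mask = dss.segment_image(net, images[i], n_segments=cfg.n_segments,
                                 refine_image=dataset.images[i])
        truth = dataset.masks[i]
        if truth is None:       # no ground truth: segmentation only
            n_unevaluated += 1
            continue
        mask = dss.resize_mask(mask, truth.shape)
        rep = dss.evaluate_segmentation(mask, truth)
        per_image.append({"index": int(i), "accuracy": rep.accuracy,
                          "error": rep.error, "dice": rep.dice})
    report = {
        "enhancement": cfg.use_enhancement,
        "n_train": int(len(tr)),
        "n_test": int(len(te)),
        "n_unevaluated": n_unevaluated,
        "per_image": per_image,
        "_net": net,
    }
    if per_image:
        report["mean_accuracy"] = float(np.mean([r["accuracy"] for r in per_image]))
        report["mean_error"] = float(np.mean([r["error"] for r in per_image]))
        report["mean_dice"] = float(np.mean([r["dice"] for r in per_image]))
    else:
        report["warning"] = "no ground-truth masks available; evaluation skipped"
    return report


@dataclass
class ClassificationConfig:
    """Two synthetic feature streams stand in for the two backbone streams."""

    stream_a: FeatureDatasetSpec = field(default_factory=lambda: FeatureDatasetSpec(
        n_samples_per_class=(70, 70), n_features=100, n_informative=10,
        class_separation=2.0, seed=0))
    stream_b: FeatureDatasetSpec = field(default_factory=lambda: FeatureDatasetSpec(
        n_samples_per_class=(70, 70), n_features=80, n_informative=10,
        class_separation=2.0, seed=1))
    train_frac: float = 0.7
    variant: str = "imfo"
    select: bool = True
    n_iter: int = 30
    n_pop: int = 20
    r_weight: float = 0.9
    correlation_threshold: float = 0.5
    kernel: str = "rbf"
    C: float = 100.0
    seed: int = 0


def run_classification_experiment(cfg: ClassificationConfig,
                                  streams: tuple[FeatureMatrix, FeatureMatrix] | None = None) -> dict:
    """Features -> (I)MFO per stream -> fusion -> KELM -> report.

    The two streams must carry identical labels (they describe the same
    samples through two backbones).  Selection and fusion are fitted on the
    training partition only, then applied to the test partition.
    """
    if streams is None:
        a_spec, b_spec = cfg.stream_a, cfg.stream_b
        if tuple(a_spec.n_samples_per_class) != tuple(b_spec.n_samples_per_class):
            raise ValueError("the two streams must describe the same samples")
        A, _, _ = generate_feature_dataset(a_spec)
        B, _, _ = generate_feature_dataset(b_spec)
    else:
        A, B = streams
    if not np.array_equal(A.labels, B.labels):
        raise ValueError("stream labels must be identical")

    A_tr, A_te = split_dataset(A, cfg.train_frac, cfg.seed + 3)
    B_tr, B_te = split_dataset(B, cfg.train_frac, cfg.seed + 3)

    manifest = {"variant": cfg.variant, "seed": cfg.seed,
                "dims_before": [A.feature_dim, B.feature_dim]}
    fit_cfg = imfo.FitnessConfig(r_weight=cfg.r_weight, seed=cfg.seed + 7)
    if cfg.select:
        sel_a = imfo.select_features(A_tr, A_tr.labels, fit_cfg, n_iter=cfg.n_iter,
                                     seed=cfg.seed + 13, variant=cfg.variant,
                                     n_pop=cfg.n_pop)
        sel_b = imfo.select_features(B_tr, B_tr.labels, fit_cfg, n_iter=cfg.n_iter,
                                     seed=cfg.seed + 29, variant=cfg.variant,
                                     n_pop=cfg.n_pop)
        idx_a, idx_b = sel_a.selected_indices, sel_b.selected_indices
    else:
        idx_a = np.arange(A.feature_dim)
        idx_b = np.arange(B.feature_dim)
    manifest["dims_after_selection"] = [int(len(idx_a)), int(len(idx_b))]

    red_a_tr, red_b_tr = A_tr.select_columns(idx_a), B_tr.select_columns(idx_b)
    red_a_te, red_b_te = A_te.select_columns(idx_a), B_te.select_columns(idx_b)

    fus_cfg = fusion.FusionConfig(correlation_threshold=cfg.correlation_threshold)
    pad_a_tr, pad_b_tr = fusion.pad_to_max_length(red_a_tr, red_b_tr, fus_cfg.padding_mode)
    fused_tr = fusion.fuse_features(pad_a_tr, pad_b_tr, fus_cfg)
    manifest["dim_after_fusion"] = int(fused_tr.k3)

    if fused_tr.k3 == 0:
        # Nothing survived the correlation filter; fall back to concatenation.
        train_vals = np.hstack([red_a_tr.values, red_b_tr.values])
        test_vals = np.hstack([red_a_te.values, red_b_te.values])
        manifest["fusion_fallback"] = "concatenation"
    else:
        pad_a_te, pad_b_te = fusion.pad_to_max_length(red_a_te, red_b_te, fus_cfg.padding_mode)
        train_vals = fused_tr.values
        test_vals = fusion.apply_source_pairs(fused_tr.source_pairs, pad_a_te, pad_b_te)

    model = kelm.train_kelm(FeatureMatrix(train_vals, A_tr.labels),
                            kernel=cfg.kernel, C=cfg.C)
    pred = kelm.predict(model, test_vals)
    report = kelm.evaluate(pred, A_te.labels, classes=model.classes)
    return {
        "accuracy": report.accuracy,
        "sensitivity": report.sensitivity,
        "fnr": report.fnr,
        "confusion": report.confusion.tolist(),
        "classes": [int(c) for c in report.classes],
        "manifest": manifest,
    }
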