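"""Maximal-correlation fusion of two optimized feature streams.

The two selected feature matrices are first brought to a common width by
padding the narrower one (entropy padding by default: each padded column of a
sample carries the normalized Shannon entropy of that sample's original
feature row).  Columns are then paired positionally, the Pearson correlation
of each pair is computed, and every pair at or above the correlation
threshold contributes *both* of its columns to the fused matrix — which is
why the fused width can exceed either input width.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureMatrix
from .imfo import ENTROPY_BINS


@dataclass
class FusionConfig:
    """Correlation threshold ('near 1' retention) and padding mode."""

    correlation_threshold: float = 0.5
    padding_mode: str = "entropy"

    def __post_init__(self) -> None:
        if not 0.0 <= self.correlation_threshold <= 1.0:
            raise ValueError("correlation_threshold must be in [0, 1]")
        if self.padding_mode not in ("entropy", "zero"):
            raise ValueError("padding_mode must be 'entropy' or 'zero'")


@dataclass
class FusedFeatures:
    """Fused matrix plus provenance of every retained column pair."""

    values: np.ndarray
    source_pairs: list = field(default_factory=list)  # (idx_v1, idx_v2, rho)
    k3: int = 0
    empty_warning: bool = False


def _sample_entropy(row: np.ndarray) -> float:
    """Normalized Shannon entropy of one sample's feature values."""
    finite = row[np.isfinite(row)]
    counts, _ = np.histogram(finite, bins=ENTROPY_BINS)
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum() / np.log(ENTROPY_BINS))


def pad_to_max_length(V1: FeatureMatrix, V2: FeatureMatrix, mode: str = "entropy"):
    """Pad the narrower matrix with constant per-sample columns to max(d1, d2).

    In entropy mode every padded entry of sample i is the normalized Shannon
    entropy of that sample's original feature row; in zero mode it is 0.
    Original columns are unchanged.
    """
    if V1.n_samples != V2.n_samples:
        raise ValueError("matrices must have the same sample count")
    d1, d2 = V1.feature_dim, V2.feature_dim
    if d1 == d2:
        return V1, V2

    def pad(m: FeatureMatrix, width: int) -> FeatureMatrix:
        extra = width - m.feature_dim
        if mode == "zero":
            block = np.zeros((m.n_samples, extra))
        else:
            ent = np.array([_sample_entropy(r) for r in m.values])
            block = np.repeat(ent[:, None], extra, axis=1)
        return FeatureMatrix(np.hstack([m.values, block]), m.labels.copy(),
                             m.sample_ids.copy())

    width = max(d1, d2)
    return (pad(V1, width) if d1 < width else V1,
            pad(V2, width) if d2 < width else V2)


def pairwise_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation Cov(x,y)/sqrt(Var x * Var y); 0 if either is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D and equal length")
    if x.size < 2:
        raise ValueError("need at least two observations")
    xc, yc = x - x.mean(), y - y.mean()
    denom = float(np.sqrt(xc @ xc) * np.sqrt(yc @ yc))
    if denom == 0.0 or not np.isfinite(denom):
        return 0.0
    rho = float(xc @ yc) / denom
    if not np.isfinite(rho):
        return 0.0
    return float(np.clip(rho, -1.0, 1.0))


def fuse_features(V1: FeatureMatrix, V2: FeatureMatrix,
                  cfg: FusionConfig | None = None) -> FusedFeatures:
    """Positional-pair correlation filtering.

    For every column index i, rho_i is the Pearson correlation of V1[:, i]
    with V2[:, i]; every pair with rho_i >= threshold contributes both
    columns (V1's then V2's) to the fused matrix.  Pairs are ordered by
    descending rho, ties by lower index, so k3 = 2 x retained pairs.
    """
    if cfg is None:
        cfg = FusionConfig()
    if V1.feature_dim != V2.feature_dim:
        raise ValueError("pad_to_max_length must be applied before fusing")
    if V1.n_samples != V2.n_samples:
        raise ValueError("matrices must have the same sample count")
    d = V1.feature_dim
    rhos = np.array([pairwise_correlation(V1.values[:, i], V2.values[:, i])
                     for i in range(d)])
    retained = np.flatnonzero(rhos >= cfg.correlation_threshold)
    if retained.size == 0:
        warnings.warn("no column pair reaches the correlation threshold; "
                      "the fused matrix is empty", stacklevel=2)
        return FusedFeatures(values=np.zeros((V1.n_samples, 0)),
                             source_pairs=[], k3=0, empty_warning=True)
    order = retained[np.lexsort((retained, -rhos[retained]))]
    cols, pairs = [], []
    for i in order:
        cols.append(V1.values[:, i])
        cols.append(V2.values[:, i])
        pairs.append((int(i), int(i), float(rhos[i])))
    values = np.column_stack(cols)
    return FusedFeatures(values=values, source_pairs=pairs, k3=values.shape[1])


def fused_matrix(fused: FusedFeatures, labels) -> FeatureMatrix:
    """Wrap fused values with labels for downstream classification."""
    return FeatureMatrix(fused.values, labels)


def apply_source_pairs(pairs, V1: FeatureMatrix, V2: FeatureMatrix) -> np.ndarray:
    """Re-assemble a fused matrix on new rows from recorded source pairs.

    Used to carry a fusion fitted on training rows over to test rows: the
    retained (i, j) column pairs are looked up in the padded test-matrices.
    """
    cols = []
    for i, j, _ in pairs:
        cols.append(V1.values[:, i])
        cols.append(V2.values[:, j])
    if not cols:
        return np.zeros((V1.n_samples, 0))
    return np.column_stack(cols)
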