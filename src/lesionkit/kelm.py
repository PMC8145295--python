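"""Kernel Extreme Learning Machine (KELM) classification.

KELM is a single-shot kernel classifier: with one-hot targets T and the
kernel Gram matrix Omega of the training rows, the output weights solve the
regularized linear system

    (I / C + Omega) beta = T,

and a test point is scored as K(x, X_train) beta with arg-max decision.  As
C grows the solution approaches unregularized kernel least-squares; with a
linear kernel on full-rank data that limit coincides with ordinary one-hot
least-squares regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.metrics.pairwise import linear_kernel, polynomial_kernel, rbf_kernel

from .features import FeatureMatrix


@dataclass
class KernelSpec:
    """Kernel family and parameters.

    For the RBF kernel, ``gamma=None`` applies the median-distance heuristic
    gamma = 1 / (2 * median(pairwise distances)^2) on the training rows.
    """

    name: str = "rbf"
    gamma: float | None = None
    degree: int = 3
    coef0: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in ("rbf", "linear", "polynomial"):
            raise ValueError("kernel must be 'rbf', 'linear' or 'polynomial'")


@dataclass
class KelmModel:
    kernel: KernelSpec
    C: float
    support_data: np.ndarray
    output_weights: np.ndarray
    classes: np.ndarray
    gamma_: float | None = None


@dataclass
class ClassificationReport:
    """Accuracy, macro sensitivity, FNR (all %) and a row-percentage confusion."""

    accuracy: float
    sensitivity: float
    fnr: float
    confusion: np.ndarray
    classes: np.ndarray = field(default=None)  # type: ignore[assignment]


def _gram(spec: KernelSpec, A: np.ndarray, B: np.ndarray, gamma: float | None) -> np.ndarray:
    if spec.name == "linear":
        return linear_kernel(A, B)
    if spec.name == "polynomial":
        return polynomial_kernel(A, B, degree=spec.degree, coef0=spec.coef0, gamma=None)
    return rbf_kernel(A, B, gamma=gamma)


def _median_gamma(X: np.ndarray) -> float:
    if X.shape[0] < 2:
        return 1.0
    med = float(np.median(pdist(X)))
    if med <= 0:
        return 1.0
    return 1.0 / (2.0 * med ** 2)


def train_kelm(train: FeatureMatrix, kernel: KernelSpec | str = "rbf",
               C: float = 100.0) -> KelmModel:
    """Solve the regularized kernel system for one-hot targets."""
    if isinstance(kernel, str):
        kernel = KernelSpec(name=kernel)
    if C <= 0:
        raise ValueError("C must be positive")
    classes = np.unique(train.labels)
    if classes.size < 2:
        raise ValueError("training requires at least two classes")
    X = train.values
    T = (train.labels[:, None] == classes[None, :]).astype(float)
    gamma = _median_gamma(X) if (kernel.name == "rbf" and kernel.gamma is None) else kernel.gamma
    omega = _gram(kernel, X, X, gamma)

    # Solve (I/C + Omega) beta = T through the eigendecomposition of the
    # symmetric PSD Gram matrix.  When the ridge 1/C falls below the
    # eigenvalue round-off floor (very large C on a rank-deficient kernel),
    # noise-level directions are dropped, which realizes the C -> infinity
    # least-squares limit instead of amplifying round-off.
    lam, Q = np.linalg.eigh(omega)
    lam = np.clip(lam, 0.0, None)
    n = X.shape[0]
    noise_floor = lam.max() * n * np.finfo(float).eps * 10 if lam.max() > 0 else 0.0
    ridge = 1.0 / C
    factors = 1.0 / (lam + ridge)
    well_posed = ridge >= noise_floor
    if not well_posed:
        factors[lam < noise_floor] = 0.0
    beta = Q @ (factors[:, None] * (Q.T @ T))
    if not np.all(np.isfinite(beta)):
        raise ValueError("kernel system is singular beyond regularization")
    if well_posed:
        residual = float(np.abs((omega + np.eye(n) * ridge) @ beta - T).max())
        if not np.isfinite(residual) or residual > 1e-4:
            raise ValueError(f"kernel system is ill-conditioned (residual {residual:.2e})")
    return KelmModel(kernel=kernel, C=float(C), support_data=X.copy(),
                     output_weights=beta, classes=classes, gamma_=gamma)


def decision_scores(model: KelmModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.support_data.shape[1]:
        raise ValueError("feature width does not match the training data")
    K = _gram(model.kernel, X, model.support_data, model.gamma_)
    return K @ model.output_weights


def predict(model: KelmModel, X) -> np.ndarray:
    """Arg-max class per row; ties break toward the earlier class."""
    if isinstance(X, FeatureMatrix):
        X = X.values
    scores = decision_scores(model, X)
    return model.classes[np.argmax(scores, axis=1)]


def evaluate(pred_labels, true_labels, classes=None) -> ClassificationReport:
    """Accuracy, row-percentage confusion, macro sensitivity and FNR.

    Sensitivity is the unweighted mean of the confusion diagonal (per-class
    recall, %); FNR = 100 - sensitivity exactly.
    """
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise ValueError("prediction and truth lengths differ")
    if classes is None:
        classes = np.unique(true)
    else:
        classes = np.asarray(classes)
    if not np.isin(pred, classes).all() or not np.isin(true, classes).all():
        raise ValueError("labels outside the known class set")
    k = classes.size
    lookup = {c: i for i, c in enumerate(classes)}
    conf = np.zeros((k, k), dtype=float)
    for t, p in zip(true, pred):
        conf[lookup[t], lookup[p]] += 1
    row_sums = conf.sum(axis=1, keepdims=True)
    conf_pct = 100.0 * conf / np.maximum(row_sums, 1)
    present = row_sums.ravel() > 0
    sensitivity = float(np.diag(conf_pct)[present].mean())
    accuracy = 100.0 * float(np.mean(pred == true))
    return ClassificationReport(accuracy=accuracy, sensitivity=sensitivity,
                                fnr=100.0 - sensitivity, confusion=conf_pct,
                                classes=classes)
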