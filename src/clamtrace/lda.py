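"""From-scratch linear discriminant analysis with leave-one-out CV.

The classifier is the shared-covariance Gaussian discriminant: class k is
scored by the linear discriminant function

    δ_k(x) = xᵀ Σ⁻¹ μ_k − ½ μ_kᵀ Σ⁻¹ μ_k + log π_k

with μ_k the class mean, Σ the pooled within-class covariance (divisor
N − K) and π_k the prior.  Posteriors are the softmax of the δ_k.  The
discriminant (canonical) axes solve the generalized eigenproblem of
between-class vs pooled within-class scatter; at most min(K − 1, p) axes
exist.  Near-singular pooled covariances — routine when a class has only
three samples — are ridge-stabilized with λI, λ = 1e-8 · trace(Σ)/p.

LOOCV refits the model n times, each time holding out one sample, and pools
the held-out predictions into a confusion matrix (rows = true class,
columns = predicted class).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from ._round import percent_1dp, percent_2dp_trunc
from .scaling import apply_scaler, fit_scaler

__all__ = ["LDAModel", "ConfusionMatrix", "LoocvResult", "fit_lda", "predict", "project", "loocv"]

logger = logging.getLogger(__name__)

_COND_THRESHOLD = 1e10
_RIDGE_SCALE = 1e-8


@dataclass
class LDAModel:
    """A fitted linear discriminant model (scaled feature space)."""

    class_labels: list
    class_means: np.ndarray          # K × p
    pooled_cov: np.ndarray           # p × p, divisor N − K, post-ridge
    priors: np.ndarray               # K, sums to 1
    axes: np.ndarray                 # p × n_axes discriminant directions
    eigenvalues: np.ndarray          # n_axes, nonincreasing
    grand_mean: np.ndarray           # p, prior-weighted data mean
    regularization: float            # ridge λ actually added (0 if none)

    @property
    def n_features(self) -> int:
        return self.class_means.shape[1]


@dataclass
class ConfusionMatrix:
    """K×K LOOCV counts; rows are true classes, columns predicted."""

    classes: list
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.classes), len(self.classes)):
            raise ValueError("counts must be K x K for K classes")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be nonnegative")

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def per_class_rates(self) -> dict:
        """Per-class prediction %, half-up to 1 decimal."""
        out = {}
        for i, label in enumerate(self.classes):
            total = int(self.counts[i].sum())
            if total == 0:
                raise ValueError(f"class {label!r} has no samples")
            out[label] = percent_1dp(int(self.counts[i, i]), total)
        return out

    def overall_rate(self) -> float:
        """Pooled prediction % (trace/total), truncated to 2 decimals."""
        total = int(self.counts.sum())
        if total == 0:
            raise ValueError("empty confusion matrix")
        return percent_2dp_trunc(int(np.trace(self.counts)), total)

    def to_table(self) -> pd.DataFrame:
        """Report layout: one row per true class, predicted-count columns,
        then a one-decimal ``Prediction (%)`` column."""
        rates = self.per_class_rates()
        frame = pd.DataFrame(self.counts, index=self.classes, columns=self.classes)
        frame.index.name = "Region"
        frame["Prediction (%)"] = [rates[c] for c in self.classes]
        return frame


@dataclass
class LoocvResult:
    """Pooled LOOCV outcome: the confusion matrix plus per-sample detail."""

    confusion: ConfusionMatrix
    true_labels: list
    predicted_labels: list
    sample_index: list = field(default_factory=list)


def _validate_classes(labels: np.ndarray, min_per_class: int):
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    for cls, n in zip(classes, counts):
        if n < min_per_class:
            raise ValueError(
                f"class {cls!r} has {n} sample(s); need at least {min_per_class}"
            )
    return classes, counts


def fit_lda(X, labels, priors_mode: str = "proportional") -> LDAModel:
    """Fit the shared-covariance discriminant model.

    Parameters
    ----------
    X
        Samples × features matrix in (already scaled) feature space.
    labels
        Per-sample class labels; classes are ordered lexicographically.
    priors_mode
        ``"proportional"`` (class frequencies) or ``"uniform"``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be a 2-D samples x features matrix")
    labels = np.asarray(labels)
    if labels.shape[0] != X.shape[0]:
        raise ValueError("labels length must match number of samples")
    classes, counts = _validate_classes(labels, min_per_class=2)
    n, p = X.shape
    k = classes.size
    if n <= k:
        raise ValueError(f"need more samples ({n}) than classes ({k})")

    if priors_mode == "proportional":
        priors = counts / n
    elif priors_mode == "uniform":
        priors = np.full(k, 1.0 / k)
    else:
        raise ValueError(f"unknown priors_mode {priors_mode!r}")

    means = np.vstack([X[labels == cls].mean(axis=0) for cls in classes])
    within = np.zeros((p, p))
    for i, cls in enumerate(classes):
        centered = X[labels == cls] - means[i]
        within += centered.T @ centered
    pooled = within / (n - k)

    ridge = 0.0
    if np.linalg.cond(pooled) > _COND_THRESHOLD:
        ridge = _RIDGE_SCALE * np.trace(pooled) / p
        if ridge <= 0:  # all-zero within-class scatter
            ridge = _RIDGE_SCALE
        pooled = pooled + ridge * np.eye(p)
        logger.debug("pooled covariance ridge-stabilized with lambda=%g", ridge)

    grand_mean = priors @ means
    between = np.zeros((p, p))
    for i in range(k):
        d = (means[i] - grand_mean).reshape(-1, 1)
        between += counts[i] * (d @ d.T)

    eigvals, eigvecs = scipy.linalg.eigh(between, pooled)
    order = np.argsort(eigvals)[::-1]
    n_axes = min(k - 1, p)
    axes = eigvecs[:, order[:n_axes]]
    eigenvalues = np.maximum(eigvals[order[:n_axes]], 0.0)

    return LDAModel(
        class_labels=list(classes),
        class_means=means,
        pooled_cov=pooled,
        priors=priors,
        axes=axes,
        eigenvalues=eigenvalues,
        grand_mean=grand_mean,
        regularization=ridge,
    )


def discriminant_scores(model: LDAModel, X) -> np.ndarray:
    """δ_k(x) for every sample and class (n × K)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"dimension mismatch: model has {model.n_features} features, "
            f"input has {X.shape[1]}"
        )
    # Solve rather than invert: Σ⁻¹ μ_kᵀ via Cholesky-backed solve.
    inv_mu = scipy.linalg.solve(model.pooled_cov, model.class_means.T, assume_a="pos")
    linear = X @ inv_mu                                    # n × K
    const = -0.5 * np.sum(model.class_means * inv_mu.T, axis=1) + np.log(model.priors)
    return linear + const


def predict(model: LDAModel, X):
    """Classify samples: argmax of the discriminant scores.

    Returns ``(labels, posteriors)`` where posteriors are the softmax of the
    scores (rows sum to 1).  Exact score ties break to the earliest class in
    ``model.class_labels`` and are logged.
    """
    scores = discriminant_scores(model, X)
    best = np.argmax(scores, axis=1)  # argmax takes the first max: earliest class
    n_ties = int(np.sum(np.sum(scores == scores.max(axis=1, keepdims=True), axis=1) > 1))
    if n_ties:
        logger.info("%d tied discriminant score(s); broke to earliest class", n_ties)
    shifted = scores - scores.max(axis=1, keepdims=True)
    expd = np.exp(shifted)
    posteriors = expd / expd.sum(axis=1, keepdims=True)
    labels = [model.class_labels[i] for i in best]
    return labels, posteriors


def project(model: LDAModel, X) -> np.ndarray:
    """Coordinates of samples on the discriminant (LD) axes.

    The grand mean projects to the origin; axis 1 carries at least as much
    between-class variance as axis 2, and so on.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"dimension mismatch: model has {model.n_features} features, "
            f"input has {X.shape[1]}"
        )
    return (X - model.grand_mean) @ model.axes


def loocv(
    X,
    labels,
    priors_mode: str = "proportional",
    scaling_policy: str = "prefit",
) -> LoocvResult:
    """Leave-one-out cross-validation of the discriminant model.

    ``scaling_policy`` controls min–max scaling inside the folds:

    - ``"prefit"`` (default): the scaler is fit once on the full matrix
      before the folds, mirroring a normalize-then-cross-validate order.
    - ``"per_fold"``: the scaler is refit on each fold's n−1 training
      samples, the leakage-free variant.

    Every class needs at least 3 samples so each training fold keeps >= 2.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    _validate_classes(labels, min_per_class=3)
    if scaling_policy not in ("prefit", "per_fold"):
        raise ValueError(f"unknown scaling_policy {scaling_policy!r}")

    n = X.shape[0]
    if scaling_policy == "prefit":
        params = fit_scaler(X)
        X_work = apply_scaler(params, X)

    classes = list(np.unique(labels))
    index = {cls: i for i, cls in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    predicted = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if scaling_policy == "per_fold":
            params = fit_scaler(X[mask])
            train = apply_scaler(params, X[mask])
            test = apply_scaler(params, X[i : i + 1])
        else:
            train = X_work[mask]
            test = X_work[i : i + 1]
        model = fit_lda(train, labels[mask], priors_mode=priors_mode)
        pred = predict(model, test)[0][0]
        predicted.append(pred)
        counts[index[labels[i]], index[pred]] += 1

    return LoocvResult(
        confusion=ConfusionMatrix(classes=classes, counts=counts),
        true_labels=list(labels),
        predicted_labels=predicted,
        sample_index=list(range(n)),
    )
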