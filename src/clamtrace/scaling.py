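"""Min–max feature scaling to the unit interval.

Each feature A is mapped by x′ = (x − min A)/(max A − min A), so values seen
at fit time land in [0, 1].  Held-out samples may fall outside the training
range; they are returned as computed (possibly outside [0, 1]) and counted in
a warning, because clipping would silently discard discriminant information.
Constant (degenerate) columns map to 0 with a warning — the column then
carries no information but keeps the matrix finite for downstream LDA.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ScalingParams", "fit_scaler", "apply_scaler"]


@dataclass
class ScalingParams:
    """Per-feature minima/maxima remembered from the fit, in fit order."""

    feature_names: list[str]
    minima: np.ndarray
    maxima: np.ndarray

    def __post_init__(self) -> None:
        self.minima = np.asarray(self.minima, dtype=float)
        self.maxima = np.asarray(self.maxima, dtype=float)
        if not (len(self.feature_names) == self.minima.size == self.maxima.size):
            raise ValueError("feature_names, minima and maxima lengths differ")
        if np.any(self.maxima < self.minima):
            raise ValueError("max < min for at least one feature")

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_names": self.feature_names,
                "minima": self.minima.tolist(),
                "maxima": self.maxima.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ScalingParams":
        payload = json.loads(text)
        return cls(
            feature_names=list(payload["feature_names"]),
            minima=np.asarray(payload["minima"], dtype=float),
            maxima=np.asarray(payload["maxima"], dtype=float),
        )


def _as_matrix(matrix, feature_names=None):
    if isinstance(matrix, pd.DataFrame):
        return matrix.to_numpy(dtype=float), list(matrix.columns)
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim == 1:
        arr = arr.reshape(1, -1)
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(arr.shape[1])]
    return arr, list(feature_names)


def fit_scaler(matrix, feature_names: list[str] | None = None) -> ScalingParams:
    """Learn column-wise min/max from a samples × features matrix.

    Accepts a DataFrame (feature names from columns) or array-like.  Any
    non-finite entry is rejected with its row/column location.
    """
    arr, names = _as_matrix(matrix, feature_names)
    if arr.size == 0:
        raise ValueError("need at least one sample and one feature")
    bad = np.argwhere(~np.isfinite(arr))
    if bad.size:
        i, j = bad[0]
        raise ValueError(f"non-finite value at row {i}, column {names[j]!r}")
    return ScalingParams(
        feature_names=names, minima=arr.min(axis=0), maxima=arr.max(axis=0)
    )


def apply_scaler(params: ScalingParams, matrix):
    """Apply x′ = (x − min)/(max − min) column-wise.

    Returns the same container kind as the input (DataFrame in → DataFrame
    out).  Emits a warning counting out-of-training-range values and another
    for degenerate (constant) columns, which map to 0.
    """
    is_frame = isinstance(matrix, pd.DataFrame)
    arr, names = _as_matrix(matrix, params.feature_names if not is_frame else None)
    if names != params.feature_names:
        raise ValueError(
            f"feature mismatch: scaler was fit on {params.feature_names}, "
            f"got {names}"
        )
    span = params.maxima - params.minima
    degenerate = span == 0
    safe_span = np.where(degenerate, 1.0, span)
    scaled = (arr - params.minima) / safe_span
    scaled[:, degenerate] = 0.0
    if degenerate.any():
        cols = [params.feature_names[j] for j in np.flatnonzero(degenerate)]
        warnings.warn(
            f"degenerate (constant) column(s) mapped to 0: {cols}", stacklevel=2
        )
    n_outside = int(np.sum((scaled < 0) | (scaled > 1)))
    if n_outside:
        warnings.warn(
            f"{n_outside} value(s) fall outside the training range "
            "(scaled outside [0, 1])",
            stacklevel=2,
        )
    if is_frame:
        return pd.DataFrame(scaled, index=matrix.index, columns=params.feature_names)
    return scaled
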