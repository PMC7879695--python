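"""Quantile normalization and log2 transformation.

The normalization step forces every sample's intensity distribution onto a
common reference: the per-rank mean of the column-sorted matrix. Ties within
a column receive the mean of the reference values of the ranks they span
(the classic rank-mean method). The operation is rank-preserving, and for
tie-free data it is idempotent and leaves every column with the same value
multiset; ties (measure-zero for continuous intensities) perturb both
properties at the level of the spanned-rank means. Raw intensities are
normalized first and log2-transformed second.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .errors import StateError, ValidationError
from .io_formats import ExpressionMatrix


@dataclass
class NormalizationReport:
    """Bookkeeping for one quantile-normalization run."""

    n_probes: int
    n_samples: int
    reference_distribution: np.ndarray

    def __post_init__(self) -> None:
        ref = np.asarray(self.reference_distribution, dtype=float)
        if ref.shape != (self.n_probes,):
            raise ValidationError("reference distribution length must equal n_probes")
        if np.any(np.diff(ref) < 0):
            raise ValidationError("reference distribution must be non-decreasing")
        self.reference_distribution = ref


def _map_column_to_reference(col: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Substitute each value by the reference value of its rank; tie groups
    get the mean of the reference values over the ranks they span."""
    order = np.argsort(col, kind="stable")
    mapped = np.empty(col.shape, dtype=float)
    mapped[order] = ref
    _, inverse, counts = np.unique(col, return_inverse=True, return_counts=True)
    if np.any(counts > 1):
        sums = np.bincount(inverse, weights=mapped)
        mapped = (sums / counts)[inverse]
    return mapped


def quantile_normalize_array(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Quantile-normalize the columns of a probes x samples array.

    Returns the normalized array and the reference distribution (sorted,
    length = number of probes).
    """
    # C-contiguity pins the floating reduction order, so results do not
    # depend on whether the matrix arrived from memory or from a file
    X = np.ascontiguousarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("expected a 2-D probes x samples array")
    if X.shape[1] < 2:
        raise ValidationError("quantile normalization requires at least 2 samples")
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        out[:, j] = _map_column_to_reference(X[:, j], reference)
    return out, reference


def quantile_normalize(m: ExpressionMatrix) -> tuple[ExpressionMatrix, NormalizationReport]:
    """Quantile-normalize a raw-scale expression matrix across samples."""
    if m.scale != "raw":
        raise StateError("quantile_normalize expects a raw-scale matrix")
    normalized, reference = quantile_normalize_array(m.data.to_numpy(dtype=float))
    data = m.data.copy()
    data.iloc[:, :] = normalized
    report = NormalizationReport(m.n_probes, m.n_samples, reference)
    return m.with_data(data, scale="raw"), report


def log2_transform(m: ExpressionMatrix, offset: float = 0.0) -> ExpressionMatrix:
    """Map every intensity v to log2(v + offset) and retag the matrix."""
    if m.scale != "raw":
        raise StateError("matrix is already on the log2 scale")
    if offset < 0:
        raise ValidationError("offset must be non-negative")
    values = m.data.to_numpy(dtype=float) + offset
    if np.any(values <= 0):
        raise ValidationError(
            "log2 undefined for non-positive intensities; use a positive --log2-offset"
        )
    data = m.data.copy()
    data.iloc[:, :] = np.log2(values)
    return m.with_data(data, scale="log2")


class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer mapping each sample (row) onto the mean
    quantile profile learned from the training samples.

    ``fit`` stores the reference distribution (the per-rank mean over the
    row-sorted training matrix); ``transform`` substitutes each row's order
    statistics by the reference values, averaging over ties. Note the sklearn
    orientation: rows are samples, columns are probes.
    """

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=2, dtype=float)
        self.reference_distribution_ = np.sort(X, axis=1).mean(axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_distribution_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        out = np.empty_like(X, dtype=float)
        for i in range(X.shape[0]):
            out[i] = _map_column_to_reference(X[i], self.reference_distribution_)
        return out


class Log2Transformer(TransformerMixin, BaseEstimator):
    """Elementwise log2(x + offset) with an exact inverse."""

    def __init__(self, offset: float = 0.0):
        self.offset = offset

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        if self.offset < 0:
            raise ValidationError("offset must be non-negative")
        if np.any(X + self.offset <= 0):
            raise ValidationError("log2 undefined for non-positive values")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        X = check_array(X, dtype=float)
        if np.any(X + self.offset <= 0):
            raise ValidationError("log2 undefined for non-positive values")
        return np.log2(X + self.offset)

    def inverse_transform(self, X):
        X = check_array(X, dtype=float)
        return np.exp2(X) - self.offset
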