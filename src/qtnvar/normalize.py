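"""Sequencing-depth normalization and low-expression filtering.

Raw RNA-seq counts differ between libraries mainly through sequencing depth.
The median-of-ratios method estimates one positive *size factor* per sample:
for every gene with strictly positive counts in all samples, form the ratio
of its count in a sample to its geometric mean across samples; the sample's
size factor is the median of those ratios.  Dividing each sample's counts by
its factor puts the libraries on a common scale under the assumption that
most genes are not differentially expressed.

Filtering then removes the weakest genes — those in the lowest quantile of
total normalized counts across samples — to reduce the number of hypotheses
tested downstream.

The scikit-learn estimators here follow the (n_samples, n_features)
convention: rows are samples, columns are genes.  The module-level functions
operate on the gene-rows count-matrix orientation used by the file formats
and simply transpose around the estimators.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .exceptions import DegenerateInputError, InvalidInputError


def _as_frame(X) -> pd.DataFrame:
    X = pd.DataFrame(X)
    if (X.to_numpy() < 0).any():
        raise InvalidInputError("count matrices must be nonnegative")
    return X


class MedianOfRatiosNormalizer(TransformerMixin, BaseEstimator):
    """Median-of-ratios size-factor normalization (samples x genes).

    ``fit`` learns the per-gene reference (the geometric mean over the fitted
    samples, restricted to genes positive in every fitted sample); ``transform``
    computes one size factor per row as the median ratio to that reference and
    divides the row by it.

    Attributes
    ----------
    log_reference_ : ndarray of shape (n_genes,)
        Log geometric mean per gene; ``nan`` for genes excluded from
        size-factor estimation (a zero count in some fitted sample).
    eligible_ : ndarray of bool, shape (n_genes,)
        Genes used for size-factor estimation.
    size_factors_ : pandas.Series
        Size factors of the fitted samples.
    """

    def fit(self, X, y=None):
        X = _as_frame(X)
        values = X.to_numpy(dtype=float)
        eligible = (values > 0).all(axis=0)
        if not eligible.any():
            raise DegenerateInputError(
                "no gene has strictly positive counts in every sample; "
                "size factors are undefined"
            )
        with np.errstate(divide="ignore"):
            logs = np.log(values)
        log_ref = np.full(values.shape[1], np.nan)
        log_ref[eligible] = logs[:, eligible].mean(axis=0)
        self.n_features_in_ = values.shape[1]
        self.feature_names_in_ = np.asarray(X.columns)
        self.eligible_ = eligible
        self.log_reference_ = log_ref
        self.size_factors_ = pd.Series(
            self._factors(values), index=X.index, name="size_factor"
        )
        return self

    def _factors(self, values: np.ndarray) -> np.ndarray:
        el = self.eligible_
        with np.errstate(divide="ignore"):
            log_ratios = np.log(values[:, el]) - self.log_reference_[el]
        if not np.isfinite(log_ratios).all():
            raise DegenerateInputError(
                "a sample has a zero count in an eligible gene; its size factor "
                "is undefined under the fitted reference"
            )
        return np.exp(np.median(log_ratios, axis=1))

    def transform(self, X):
        check_is_fitted(self)
        X = _as_frame(X)
        if X.shape[1] != self.n_features_in_:
            raise InvalidInputError(
                f"expected {self.n_features_in_} genes, got {X.shape[1]}"
            )
        factors = self._factors(X.to_numpy(dtype=float))
        return X.div(pd.Series(factors, index=X.index), axis=0)


class LowExpressionFilter(TransformerMixin, BaseEstimator):
    """Drop the lowest-``quantile`` fraction of genes by total count.

    Removes exactly ``ceil(quantile * n_genes)`` genes with the smallest
    total (normalized) count summed across samples; ties in the totals are
    broken by gene label order, so the survivor set is deterministic.  With
    ``quantile=0.20`` a 5792-gene matrix with distinct totals keeps 4633.
    """

    def __init__(self, quantile: float = 0.20):
        self.quantile = quantile

    def fit(self, X, y=None):
        if not 0 <= self.quantile < 1:
            raise InvalidInputError("quantile must be in [0, 1)")
        X = _as_frame(X)
        totals = X.sum(axis=0)
        n_remove = math.ceil(self.quantile * X.shape[1])
        if n_remove >= X.shape[1]:
            raise DegenerateInputError("filter would remove every gene")
        # ties in totals break lexicographically on the gene label
        rank = (
            pd.DataFrame({"total": totals.to_numpy(), "label": totals.index.astype(str)})
            .sort_values(["total", "label"], kind="mergesort")
            .index
        )
        removed = set(rank[:n_remove])
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns)
        self.support_ = np.array([i not in removed for i in range(X.shape[1])])
        self.totals_ = totals
        return self

    def get_support(self) -> np.ndarray:
        check_is_fitted(self)
        return self.support_

    def transform(self, X):
        check_is_fitted(self)
        X = _as_frame(X)
        if X.shape[1] != self.n_features_in_:
            raise InvalidInputError(
                f"expected {self.n_features_in_} genes, got {X.shape[1]}"
            )
        return X.loc[:, self.support_]


# ---------------------------------------------------------------------------
# Functional interface on gene-rows count matrices
# ---------------------------------------------------------------------------

def compute_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Per-sample median-of-ratios size factors from a genes x samples matrix."""
    norm = MedianOfRatiosNormalizer().fit(counts.T)
    return norm.size_factors_


def normalize_counts(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Divide each sample (column) by its size factor.

    If ``factors`` is omitted they are computed from ``counts`` itself.  The
    returned frame carries ``attrs["normalized"] = True``.
    """
    if factors is None:
        factors = compute_size_factors(counts)
    missing = set(counts.columns) - set(factors.index)
    if missing:
        raise InvalidInputError(f"no size factor for samples: {sorted(missing)}")
    if (factors <= 0).any():
        raise InvalidInputError("size factors must be strictly positive")
    out = counts.div(factors[counts.columns], axis=1)
    out.attrs["normalized"] = True
    return out


def filter_low_expression(counts: pd.DataFrame, quantile: float = 0.20) -> pd.DataFrame:
    """Remove the ``ceil(quantile * G)`` genes with the smallest totals."""
    filt = LowExpressionFilter(quantile=quantile).fit(counts.T)
    out = counts.loc[filt.get_support()]
    out.attrs.update(counts.attrs)
    return out
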