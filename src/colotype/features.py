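"""Feature selection and gene-wise centering.

Unsupervised subtype discovery operates on the most variant genes of the
cohort (default 1,459), and centroid assignment operates on expression
centered gene-by-gene within each cohort so that profiles from different
platforms are comparable on the correlation scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

DEFAULT_N_FEATURES = 1459


@dataclass(frozen=True)
class FeatureSelection:
    """An ordered set of selected gene identifiers."""

    selected_gene_ids: tuple
    criterion: str
    n_requested: int


def select_most_variant(expr: pd.DataFrame, n: int = DEFAULT_N_FEATURES
                        ) -> FeatureSelection:
    """Top ``n`` genes of a genes x samples matrix by sample standard
    deviation (descending; ties broken by gene identifier order)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > len(expr):
        warnings.warn(
            f"requested {n} genes but matrix has {len(expr)}; returning all")
        n = len(expr)
    sd = expr.std(axis=1, ddof=1)
    order = sorted(expr.index, key=lambda g: (-sd[g], g))
    return FeatureSelection(tuple(order[:n]), criterion="sd", n_requested=n)


def center_genes(expr: pd.DataFrame, statistic: str = "median"
                 ) -> pd.DataFrame:
    """Shift each gene row so its median (or mean) across samples is zero."""
    if statistic == "median":
        center = expr.median(axis=1)
    elif statistic == "mean":
        center = expr.mean(axis=1)
    else:
        raise ValueError(f"unknown centering statistic {statistic!r}")
    return expr.sub(center, axis=0)


class MostVariantSelector(BaseEstimator, TransformerMixin):
    """Select the most variant genes, sklearn-transformer style.

    Follows the samples x genes orientation of scikit-learn.  ``fit`` ranks
    genes by standard deviation across the fit data; ``transform`` subsets
    columns to the selected genes.

    Parameters
    ----------
    n_features : int
        Number of genes to keep (default 1459).
    """

    def __init__(self, n_features: int = DEFAULT_N_FEATURES):
        self.n_features = n_features

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        selection = select_most_variant(X.T, self.n_features)
        self.selection_ = selection
        self.selected_genes_ = list(selection.selected_gene_ids)
        return self

    def transform(self, X):
        check_is_fitted(self, "selected_genes_")
        X = pd.DataFrame(X)
        return X[self.selected_genes_]


class GeneCenterer(BaseEstimator, TransformerMixin):
    """Center each gene (column, samples x genes) by its fitted median or
    mean.  For per-cohort centering at assignment time use
    :func:`center_genes` on the cohort itself."""

    def __init__(self, statistic: str = "median"):
        self.statistic = statistic

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        if self.statistic == "median":
            self.center_ = X.median(axis=0)
        elif self.statistic == "mean":
            self.center_ = X.mean(axis=0)
        else:
            raise ValueError(f"unknown centering statistic {self.statistic!r}")
        return self

    def transform(self, X):
        check_is_fitted(self, "center_")
        return pd.DataFrame(X).sub(self.center_, axis=1)
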