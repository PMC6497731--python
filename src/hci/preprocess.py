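"""Feature filtering, column normalization and variable-gene selection.

Filters act on rows (features), normalization on columns (samples):
uninformative all-zero genes are dropped, overly sparse features can be
removed by a zero-fraction cutoff, each sample is brought to a common
scale, and robustness experiments can subset to the most variable genes.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .datatypes import ExpressionMatrix

__all__ = [
    "filter_zero_features",
    "filter_sparse_features",
    "normalize_columns",
    "select_top_variable_features",
]


def filter_zero_features(X: ExpressionMatrix) -> ExpressionMatrix:
    """Drop features that are zero in every sample.

    Row order of the survivors is preserved.  Raises if nothing survives.
    """
    keep = np.flatnonzero(np.any(X.values != 0, axis=1))
    if keep.size == 0:
        raise ValueError("no informative features: all rows are zero")
    return X.subset_features(keep)


def filter_sparse_features(
    X: ExpressionMatrix, max_zero_fraction: float = 0.8
) -> ExpressionMatrix:
    """Drop features whose zero fraction strictly exceeds ``max_zero_fraction``.

    The default 0.8 removes features with *more than* 80% zero values
    across samples; a row with exactly the threshold fraction is kept.
    """
    if not 0.0 <= max_zero_fraction <= 1.0:
        raise ValueError("max_zero_fraction must lie in [0, 1]")
    zero_frac = np.mean(X.values == 0, axis=1)
    keep = np.flatnonzero(zero_frac <= max_zero_fraction)
    if keep.size == 0:
        raise ValueError("no informative features after sparsity filter")
    return X.subset_features(keep)


def normalize_columns(
    X: ExpressionMatrix, method: str = "log1p-zscore"
) -> ExpressionMatrix:
    """Normalize each sample (column) to a comparable scale.

    method:
        ``"zscore"``       -- center and scale each column to mean 0,
                              sample variance 1 (n-1 denominator).
        ``"log1p-zscore"`` -- log(x + 1) first, then zscore; the default
                              for nonnegative count-like data.
        ``"none"``         -- return the input unchanged.
    """
    if method == "none":
        return X
    if method not in ("zscore", "log1p-zscore"):
        raise ValueError(f"unknown normalization method: {method!r}")
    V = X.values
    if method == "log1p-zscore":
        if np.any(V < 0):
            raise ValueError("log1p-zscore requires nonnegative values")
        V = np.log1p(V)
    mu = V.mean(axis=0)
    sd = V.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = [X.sample_ids[i] for i in bad[:5]]
        raise ValueError(f"zero-variance column(s) under zscore: {names}")
    out = (V - mu) / sd
    return ExpressionMatrix(out, X.feature_ids, X.sample_ids, X.view_name)


def select_top_variable_features(
    X: ExpressionMatrix, fraction: float = 1.0, use_cv: bool = False
) -> ExpressionMatrix:
    """Keep the ceil(fraction * m) features with largest variance.

    This is the "CV genes" robustness subset: genes ranked by expression
    variability.  By default plain per-row sample variance is the ranking
    statistic; ``use_cv=True`` switches to the coefficient of variation
    sigma/mu.  Ties are broken in favour of earlier rows, and the
    survivors keep their original row order.
    """
    if fraction <= 0 or fraction > 1:
        raise ValueError("fraction must lie in (0, 1]")
    m = X.n_features
    r = math.ceil(fraction * m)
    score = X.values.var(axis=1, ddof=1)
    if use_cv:
        mu = X.values.mean(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            score = np.sqrt(score) / np.abs(mu)
        score = np.where(np.isfinite(score), score, np.inf)
    order = np.argsort(-score, kind="stable")  # stable => earlier row wins ties
    keep = np.sort(order[:r])
    return X.subset_features(keep)
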