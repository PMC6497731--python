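"""High-order Pearson sample-correlation matrices.

The first-order matrix F1 holds the Pearson correlation between every
pair of sample columns of the expression matrix X.  The second-order
matrix F2 is the Pearson correlation between the columns of F1 itself,
and higher orders recurse the same way.  Iterating the correlation
sharpens block structure: samples from the same cluster correlate not
only in expression but in *how* they correlate with everyone else, which
is more robust to entry-level noise.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datatypes import CorrelationMatrix, ExpressionMatrix

__all__ = ["pearson_sample_correlation", "high_order_correlation"]


def _pearson_columns(V: np.ndarray, on_constant: str, order: int) -> np.ndarray:
    """Pearson correlation between all column pairs of V."""
    sd = V.std(axis=0)
    const = np.flatnonzero(sd == 0)
    if const.size:
        msg = f"constant column(s) at order {order}: indices {const[:5].tolist()}"
        if on_constant == "error":
            raise ValueError(msg)
        warnings.warn(msg + "; their off-diagonal correlations set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        F = np.corrcoef(V, rowvar=False)
    if const.size:
        F[const, :] = 0.0
        F[:, const] = 0.0
    # symmetry then range guard against floating-point rounding
    F = (F + F.T) / 2.0
    np.clip(F, -1.0, 1.0, out=F)
    np.fill_diagonal(F, 1.0)
    return F


def pearson_sample_correlation(
    X: ExpressionMatrix, on_constant: str = "error"
) -> CorrelationMatrix:
    """First-order Pearson correlation between samples (columns of X).

    ``on_constant`` controls the policy for a constant column, whose
    correlation is undefined: ``"error"`` (default) raises; ``"zero"``
    sets its off-diagonal entries to 0 with a warning.
    """
    if X.n_features < 2:
        raise ValueError("Pearson correlation needs at least 2 features")
    F = _pearson_columns(X.values, on_constant, order=1)
    return CorrelationMatrix(F, order=1, sample_ids=list(X.sample_ids))


def high_order_correlation(
    X: ExpressionMatrix, max_order: int = 2, on_constant: str = "error"
) -> list[CorrelationMatrix]:
    """Return [F1, ..., F^max_order].

    F^(t+1) is the Pearson correlation of the columns of F^t, treating
    F^t as an n-feature-by-n-sample matrix; the unit diagonal of F^t is
    kept as data in the recursion (the sum runs over all n entries).
    The default stops at order 2, beyond which the gain saturates.
    """
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    if X.n_samples < 3:
        raise ValueError("high-order correlation needs at least 3 samples")
    out = [pearson_sample_correlation(X, on_constant=on_constant)]
    for t in range(2, max_order + 1):
        F = _pearson_columns(out[-1].values, on_constant, order=t)
        out.append(CorrelationMatrix(F, order=t, sample_ids=list(X.sample_ids)))
    return out
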