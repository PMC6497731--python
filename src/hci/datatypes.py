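"""Core containers: expression matrices, label vectors, correlation matrices.

All containers are thin, validated wrappers around numpy arrays plus
identifier lists.  Features are rows, samples are columns, matching the
usual genes-by-cells orientation of expression matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "LabelVector", "CorrelationMatrix"]


def _check_ids(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate {what} identifiers: {dupes[:5]}")
    return ids


@dataclass
class ExpressionMatrix:
    """A features-by-samples numeric matrix with identifiers.

    Parameters
    ----------
    values : ndarray, shape (n_features, n_samples)
        Expression values (counts, FPKM/CPM, beta-values, ...).  Must be
        finite; missing values are rejected at load time.
    feature_ids, sample_ids : sequences of unique strings
        Row / column identifiers.
    view_name : str
        Tag for the data modality (e.g. ``"mRNA"``, ``"miRNA"``).
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    view_name: str = "expression"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        self.feature_ids = _check_ids(self.feature_ids, "feature")
        self.sample_ids = _check_ids(self.sample_ids, "sample")
        m, n = self.values.shape
        if m != len(self.feature_ids):
            raise ValueError(
                f"{m} rows but {len(self.feature_ids)} feature identifiers"
            )
        if n != len(self.sample_ids):
            raise ValueError(
                f"{n} columns but {len(self.sample_ids)} sample identifiers"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(
                "expression matrix contains missing/non-finite values; "
                "use impute_zero=True at load time to map them to 0"
            )

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_features(self, row_index: np.ndarray) -> "ExpressionMatrix":
        """New matrix keeping the given rows (order preserved as given)."""
        ids = [self.feature_ids[i] for i in row_index]
        return replace(self, values=self.values[row_index], feature_ids=ids)

    def subset_samples(self, col_index: np.ndarray) -> "ExpressionMatrix":
        ids = [self.sample_ids[i] for i in col_index]
        return replace(self, values=self.values[:, col_index], sample_ids=ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, view_name: str = "expression"
    ) -> "ExpressionMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            feature_ids=list(map(str, df.index)),
            sample_ids=list(map(str, df.columns)),
            view_name=view_name,
        )


@dataclass
class LabelVector:
    """Per-sample categorical assignment aligned to sample identifiers."""

    labels: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.sample_ids = _check_ids(self.sample_ids, "sample")
        if self.labels.ndim != 1 or len(self.labels) != len(self.sample_ids):
            raise ValueError("labels and sample_ids must have equal length")
        if len(self.labels) and len(np.unique(self.labels)) < 1:
            raise ValueError("at least one distinct label required")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_groups(self) -> int:
        return len(np.unique(self.labels))

    def reorder(self, sample_ids: Sequence[str]) -> "LabelVector":
        """Return labels re-ordered to match another sample ordering."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise ValueError(f"labels missing for samples: {missing[:5]}")
        idx = np.array([pos[s] for s in sample_ids])
        return LabelVector(self.labels[idx], list(map(str, sample_ids)))


@dataclass
class CorrelationMatrix:
    """An order-tagged n-by-n sample-similarity matrix.

    ``order=1`` is the Pearson correlation of the expression columns,
    ``order=2`` the Pearson correlation of the columns of the order-1
    matrix, and so on.  Symmetric, unit diagonal, entries in [-1, 1].
    """

    values: np.ndarray
    order: int
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != n:
            raise ValueError("correlation matrix must be square")
        if self.order < 1:
            raise ValueError("order must be a positive integer")
        if not self.sample_ids:
            self.sample_ids = [f"S{i}" for i in range(n)]
        self.sample_ids = _check_ids(self.sample_ids, "sample")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length must match matrix size")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric to 1e-10")
        if np.any(np.abs(self.values) > 1 + 1e-12):
            raise ValueError("correlation entries must lie in [-1, 1]")
        if not np.array_equal(np.diag(self.values), np.ones(n)):
            raise ValueError("correlation diagonal must be exactly 1")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.sample_ids
        )
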