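"""Differential-feature calling from factorization loadings.

A feature's importance profile across the d patterns is its row of the
loading-weight matrix.  Features that matter for the sample structure
contribute strongly to a few patterns and weakly elsewhere, so their
weight row varies a lot relative to its average; the coefficient of
variation

    c_i = delta_i / mu_i

(sd over mean of row i) ranks features, and those with c_i above a
threshold T are called differential (DEGs / DE-miRNAs).

A feature's *weight* in pattern r is |u_ir| * sqrt(eigenvalue_r) by
default -- the magnitude of its contribution to that pattern's signal.
Bare eigenvector entries are available via flags, but their rows have
near-zero mean after centering, which makes delta/mu scale-free and
uninformative; the contribution scale is what lets the CV separate
structure-carrying features from noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .pfa import LocalPattern

__all__ = ["FeatureWeightTable", "cv_weights", "select_differential",
           "export_edges"]

_MEAN_FLOOR = 1e-12


@dataclass
class FeatureWeightTable:
    feature_ids: list[str]
    view_name: str
    mean_weight: np.ndarray
    sd_weight: np.ndarray
    cv: np.ndarray
    selected: np.ndarray
    threshold: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "view": self.view_name,
                "mean_weight": self.mean_weight,
                "sd_weight": self.sd_weight,
                "cv": self.cv,
                "selected": self.selected,
            }
        )

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())


def cv_weights(
    local: LocalPattern,
    feature_ids: list[str] | None = None,
    view_map: np.ndarray | None = None,
    scale_by_eigenvalues: bool = True,
    abs_loadings: bool = True,
    signed_mean: bool = False,
) -> FeatureWeightTable:
    """Per-feature coefficient of variation of the loading-weight rows.

    ``scale_by_eigenvalues`` multiplies each loading column by the
    square root of its eigenvalue, turning eigenvector entries into
    contribution weights (default).  ``view_map`` (the view's alignment
    map A_i) expresses the weights in the global pattern space via
    pinv(A_i) before the row statistics; omit it to analyse the raw
    local weights.  Because eigenvector signs are arbitrary, weights are
    taken in magnitude by default (``abs_loadings=True``); the mean is
    additionally used in absolute value unless ``signed_mean=True``.
    Rows whose mean weight is numerically zero get cv = +inf and are
    excluded from any selection.
    """
    U = local.loadings
    if scale_by_eigenvalues:
        U = U * np.sqrt(local.eigenvalues[: U.shape[1]])
    if view_map is not None:
        U = U @ np.linalg.pinv(view_map)
    if U.shape[1] < 2:
        raise ValueError("CV undefined for one-dimensional loadings")
    W = np.abs(U) if abs_loadings else U
    mu = W.mean(axis=1)
    if not signed_mean:
        mu = np.abs(mu)
    sd = W.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mu > _MEAN_FLOOR, sd / mu, np.inf)
    ids = feature_ids or [f"f{i}" for i in range(U.shape[0])]
    if len(ids) != U.shape[0]:
        raise ValueError("feature_ids length must match loading rows")
    return FeatureWeightTable(
        feature_ids=list(ids),
        view_name=local.view_name,
        mean_weight=mu,
        sd_weight=sd,
        cv=cv,
        selected=np.zeros(U.shape[0], dtype=bool),
    )


def select_differential(
    table: FeatureWeightTable, threshold: float | None = None
) -> FeatureWeightTable:
    """Flag features with cv strictly greater than T.

    When T is not given it defaults to the 90th percentile of the finite
    cv values of the table, so a selection is defined on any dataset.
    Rows flagged cv = +inf (numerically zero mean) are never selected.
    """
    finite = np.isfinite(table.cv)
    if threshold is None:
        if not np.any(finite):
            raise ValueError("no finite cv values to set a default threshold")
        threshold = float(np.percentile(table.cv[finite], 90))
    selected = finite & (table.cv > threshold)
    return replace(table, selected=selected, threshold=float(threshold))


def export_edges(
    selected_mrna: FeatureWeightTable,
    selected_mirna: FeatureWeightTable | None = None,
    path=None,
) -> pd.DataFrame:
    """Ranked candidate list for external network / enrichment tools.

    Rows are the selected features of both views sorted by descending cv
    (ties broken by feature id); no database queries are performed here.
    """
    frames = [t.to_frame()[t.selected] for t in (selected_mrna, selected_mirna)
              if t is not None]
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if out.empty:
        warnings.warn("empty selection: writing an empty candidate list")
        out = pd.DataFrame(
            columns=["feature_id", "view", "mean_weight", "sd_weight", "cv",
                     "selected"]
        )
    else:
        out = out.sort_values(
            ["cv", "feature_id"], ascending=[False, True]
        ).reset_index(drop=True)
    if path is not None:
        out.to_csv(path, sep="\t", index=False)
    return out
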