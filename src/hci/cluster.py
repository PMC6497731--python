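"""Sample clustering on the fused pattern, K estimation by RDC, and ARI.

Samples (columns of the global pattern Y) are clustered with K-means.
The number of clusters is estimated from the ratio-of-distance curve

    RDC(K) = D_in / D_out

where D_in is the mean Euclidean distance over all within-cluster sample
pairs and D_out the mean over all between-cluster pairs.  Averaged over
repeated K-means runs, the curve drops steeply until K reaches the true
cluster number and then flattens; the chosen K is the smallest one at
which the forward slope is nearly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .datatypes import LabelVector
from .pfa import GlobalPattern

__all__ = [
    "ClusteringOutcome",
    "RDCCurve",
    "kmeans_on_pattern",
    "rdc",
    "estimate_k",
    "adjusted_rand_index",
]


@dataclass
class ClusteringOutcome:
    labels: LabelVector
    k: int
    inertia: float
    seed: int
    ari_vs_reference: float | None = None


@dataclass
class RDCCurve:
    k_values: np.ndarray
    mean_rdc: np.ndarray
    per_run_rdc: np.ndarray      # repeats x K grid
    chosen_k: int
    plateau_ks: list[int] = field(default_factory=list)
    slope_threshold: float = 0.05

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "K": self.k_values,
                "mean_rdc": self.mean_rdc,
                "sd_rdc": self.per_run_rdc.std(axis=0, ddof=1)
                if self.per_run_rdc.shape[0] > 1
                else np.zeros_like(self.mean_rdc),
            }
        )


def _pattern_points(Y) -> np.ndarray:
    """Samples-as-points array (n, d) from a GlobalPattern or raw (d, n) array."""
    if isinstance(Y, GlobalPattern):
        return Y.pattern.T
    return np.asarray(Y, dtype=float).T


def _pattern_ids(Y, n: int) -> list[str]:
    if isinstance(Y, GlobalPattern) and Y.sample_ids:
        return list(Y.sample_ids)
    return [f"S{i}" for i in range(n)]


def kmeans_on_pattern(
    Y, k: int, n_restarts: int = 10, seed: int = 0
) -> ClusteringOutcome:
    """Best-of-restarts K-means on the samples (columns of Y)."""
    pts = _pattern_points(Y)
    n = pts.shape[0]
    if not 2 <= k <= n - 1:
        raise ValueError(f"k must lie in [2, {n - 1}], got {k}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=int(seed))
    labels = km.fit_predict(pts)
    return ClusteringOutcome(
        labels=LabelVector(labels, _pattern_ids(Y, n)),
        k=k,
        inertia=float(km.inertia_),
        seed=int(seed),
    )


def rdc(Y, labels) -> float:
    """Ratio of the mean within-cluster to mean between-cluster distance.

    Singleton clusters contribute no within-cluster pairs.  Raises when
    either pair set is empty (a single cluster, or all singletons).
    """
    pts = _pattern_points(Y)
    lab = labels.labels if isinstance(labels, LabelVector) else np.asarray(labels)
    if len(lab) != pts.shape[0]:
        raise ValueError("labels length must match the sample count")
    if len(np.unique(lab)) < 2:
        raise ValueError("RDC needs at least 2 clusters (D_out undefined)")
    D = squareform(pdist(pts))
    iu = np.triu_indices_from(D, k=1)
    same = lab[iu[0]] == lab[iu[1]]
    if not np.any(same):
        raise ValueError("all clusters are singletons (D_in undefined)")
    d_in = float(D[iu][same].mean())
    d_out = float(D[iu][~same].mean())
    return d_in / d_out


def estimate_k(
    Y,
    k_max: int = 15,
    n_repeats: int = 100,
    slope_threshold: float = 0.05,
    seed: int = 0,
    n_restarts: int = 10,
    relative_drop: float = 0.1,
) -> RDCCurve:
    """Estimate the cluster number from the averaged RDC curve.

    For each K on the grid 2..k_max, K-means is run ``n_repeats`` times
    with seeds derived from the master seed and the RDC recorded.  The
    chosen K is the smallest one at which the forward slope
    |meanRDC(K+1) - meanRDC(K)| is nearly zero, in either of two senses:
    below ``slope_threshold`` times the range of the mean curve, or (for
    K > 2) collapsed by an order of magnitude relative to the preceding
    slope (ratio below ``relative_drop``).  The second condition makes
    the elbow detection robust to a slow residual drift of the curve
    after the true K, where the slope never quite reaches a fixed
    fraction of the range but drops abruptly at the elbow.  All K
    meeting either criterion are reported as ``plateau_ks`` so plateau
    ties stay visible.
    """
    if k_max < 3:
        raise ValueError("k_max must be >= 3")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    k_values = np.arange(2, k_max + 1)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=(n_repeats, len(k_values)))
    per_run = np.empty((n_repeats, len(k_values)))
    for j, k in enumerate(k_values):
        for r in range(n_repeats):
            out = kmeans_on_pattern(Y, int(k), n_restarts, int(seeds[r, j]))
            per_run[r, j] = rdc(Y, out.labels)
    mean_rdc = per_run.mean(axis=0)
    rng_curve = float(mean_rdc.max() - mean_rdc.min())
    if rng_curve == 0.0:
        warnings.warn("flat RDC curve: defaulting to K = 2")
        return RDCCurve(k_values, mean_rdc, per_run, 2, [2], slope_threshold)
    slopes = np.abs(np.diff(mean_rdc))
    flat = slopes < slope_threshold * rng_curve
    # abrupt slope collapse relative to the preceding step also counts
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = slopes[1:] / slopes[:-1]
    flat[1:] |= np.where(np.isfinite(ratio), ratio, np.inf) < relative_drop
    plateau = [int(k_values[i]) for i in np.flatnonzero(flat)]
    chosen = plateau[0] if plateau else int(k_values[int(np.argmin(slopes))])
    return RDCCurve(k_values, mean_rdc, per_run, chosen, plateau, slope_threshold)


def adjusted_rand_index(a, b) -> float:
    """Hubert-Arabie adjusted Rand index between two partitions.

    Accepts LabelVectors (aligned by sample id when both carry ids) or
    plain label sequences of equal length.
    """
    if isinstance(a, LabelVector) and isinstance(b, LabelVector):
        if set(a.sample_ids) != set(b.sample_ids):
            raise ValueError("partitions cover different sample sets")
        b = b.reorder(a.sample_ids)
        x, y = a.labels, b.labels
    else:
        x = a.labels if isinstance(a, LabelVector) else np.asarray(a)
        y = b.labels if isinstance(b, LabelVector) else np.asarray(b)
    if len(x) != len(y):
        raise ValueError("partitions must have equal length")
    return float(adjusted_rand_score(x, y))
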