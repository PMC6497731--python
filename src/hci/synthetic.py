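"""Ground-truth-labeled synthetic expression data, single- and multi-view.

The generator emulates the statistical shape of droplet / plate scRNA-seq
and bulk omics matrices: a genes-by-samples matrix with K planted sample
clusters, marker-style up-shifts on a subset of signal genes, Gaussian
noise on a log scale, exponentiation to a nonnegative FPKM/CPM-like
scale, and Bernoulli dropout zeros.  Multi-view bundles share one sample
partition across views with independent feature spaces and per-view
effect sizes (a zero effect size makes a pure-noise view).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .datatypes import ExpressionMatrix, LabelVector

__all__ = ["SyntheticSpec", "simulate_expression", "simulate_multiview"]


@dataclass
class SyntheticSpec:
    """Conditions for one synthetic dataset.

    Defaults describe the standard recovery benchmark: 90 samples, 500
    genes, 3 balanced clusters, 10% marker genes up-shifted by 3 noise
    standard deviations, and a 30% dropout rate.
    """

    n_samples: int = 90
    n_features: int = 500
    k_true: int = 3
    signal_feature_fraction: float = 0.1
    effect_size: float = 3.0
    noise_sd: float = 1.0
    dropout_rate: float = 0.3
    n_views: int = 1
    seed: int = 0
    distribution: str = "lognormal"  # or "nb" for negative-binomial counts

    def __post_init__(self) -> None:
        if self.k_true < 1 or self.k_true > self.n_samples // 3:
            raise ValueError("k_true must satisfy 1 <= k_true <= n_samples/3")
        for name in ("signal_feature_fraction", "dropout_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd < 0 or self.effect_size < 0:
            raise ValueError("noise_sd and effect_size must be nonnegative")
        if self.n_features < 1 or self.n_samples < 3:
            raise ValueError("need at least 1 feature and 3 samples")
        if self.distribution not in ("lognormal", "nb"):
            raise ValueError("distribution must be 'lognormal' or 'nb'")


def _balanced_labels(n: int, k: int) -> np.ndarray:
    """Cluster sizes differing by at most 1."""
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    return np.repeat(np.arange(k), sizes)


def simulate_expression(
    spec: SyntheticSpec, return_info: bool = False
):
    """One labeled expression matrix with planted cluster structure.

    Signal genes are assigned a home cluster round-robin and up-shifted
    by ``effect_size * noise_sd`` (on the log scale) in that cluster.
    Log-normal values by default; ``distribution="nb"`` draws
    negative-binomial counts with the same log-scale mean structure.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    m, n, k = spec.n_features, spec.n_samples, spec.k_true
    labels = _balanced_labels(n, k)

    n_signal = int(round(spec.signal_feature_fraction * m))
    signal = rng.choice(m, size=n_signal, replace=False)
    home = np.arange(n_signal) % k  # round-robin marker assignment

    baseline = rng.normal(1.0, 0.5, size=m)
    Z = baseline[:, None] + rng.normal(0.0, spec.noise_sd, size=(m, n))
    shift = spec.effect_size * spec.noise_sd
    for f, c in zip(signal, home):
        Z[f, labels == c] += shift

    if spec.distribution == "nb":
        mu = np.exp(Z)
        r = 5.0  # dispersion
        X = rng.negative_binomial(r, r / (r + mu)).astype(float)
    else:
        X = np.exp(Z)
    if spec.dropout_rate > 0:
        X[rng.random(size=X.shape) < spec.dropout_rate] = 0.0

    width = len(str(m))
    em = ExpressionMatrix(
        X,
        feature_ids=[f"gene{i:0{width}d}" for i in range(m)],
        sample_ids=[f"S{j:03d}" for j in range(n)],
        view_name="expression",
    )
    lv = LabelVector(labels, list(em.sample_ids))
    if return_info:
        return em, lv, {"signal_features": signal, "marker_cluster": home}
    return em, lv


def simulate_multiview(
    spec: SyntheticSpec,
    effect_sizes: list[float] | None = None,
    view_names: list[str] | None = None,
    return_info: bool = False,
):
    """Matched multi-view matrices sharing one sample partition.

    Each view gets its own feature space and its own seed derived from
    the master seed; per-view effect sizes allow e.g. a pure-noise view
    (effect 0) for testing adaptive down-weighting.
    """
    if spec.n_views < 2:
        raise ValueError("simulate_multiview needs n_views >= 2")
    effects = effect_sizes if effect_sizes is not None else [
        spec.effect_size
    ] * spec.n_views
    if len(effects) != spec.n_views:
        raise ValueError("effect_sizes length must equal n_views")
    names = view_names or [f"view{i + 1}" for i in range(spec.n_views)]
    child_seeds = np.random.SeedSequence(spec.seed).generate_state(spec.n_views)
    views = []
    labels = None
    infos = []
    for i in range(spec.n_views):
        sub = replace(
            spec,
            n_views=1,
            effect_size=float(effects[i]),
            seed=int(child_seeds[i] % (2**31 - 1)),
        )
        em, lv, info = simulate_expression(sub, return_info=True)
        em.view_name = names[i]
        em.feature_ids = [f"{names[i]}_{f}" for f in em.feature_ids]
        views.append(em)
        infos.append(info)
        labels = lv  # same partition in every view: sizes depend only on n, k
    if return_info:
        return views, labels, infos
    return views, labels
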