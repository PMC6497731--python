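"""The HCI model: correlation-augmented pattern fusion of omics views.

``HCI`` is built from one expression matrix or a list of matched views
over the same samples.  ``fit()`` augments every view with its first-
and second-order Pearson sample-correlation matrices, extracts each
matrix's local low-rank sample pattern, fuses all patterns into the
global sample-pattern matrix Y with adaptive view weights, and returns
an ``HCIResults`` carrying Y, the per-view factorizations, alignment
diagnostics, and downstream clustering / K-estimation / feature-ranking
methods.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as _cluster
from .datatypes import ExpressionMatrix, LabelVector
from .features import FeatureWeightTable, cv_weights, select_differential
from .hocorr import high_order_correlation
from .pfa import GlobalPattern, LocalPattern, align_patterns, local_decompose

__all__ = ["HCI", "HCIResults"]


class HCI:
    """Correlation-augmented pattern-fusion model.

    Parameters
    ----------
    data : ExpressionMatrix or list of ExpressionMatrix
        One view, or several views over the same samples (any sample
        ordering; views are aligned to the intersection of sample ids).
    max_order : int
        Highest correlation order to append per view (default 2: the
        view itself plus F1 and F2).  0 uses the raw views only.
    expr_variance_threshold, corr_variance_threshold : float
        Cumulative-eigenvalue ratios governing each view's local
        dimension: 0.8 for expression-type matrices, 0.9 for the
        (lower-feature-dimension) correlation matrices.
    on_constant : str
        Policy when a constant column makes a Pearson correlation
        undefined: "error" (default) or "zero".
    """

    def __init__(
        self,
        data,
        max_order: int = 2,
        expr_variance_threshold: float = 0.8,
        corr_variance_threshold: float = 0.9,
        on_constant: str = "error",
    ):
        views = [data] if isinstance(data, ExpressionMatrix) else list(data)
        if not views:
            raise ValueError("at least one view is required")
        if max_order < 0:
            raise ValueError("max_order must be >= 0")
        self.views = self._align_samples(views)
        self.sample_ids = list(self.views[0].sample_ids)
        self.max_order = int(max_order)
        self.expr_variance_threshold = float(expr_variance_threshold)
        self.corr_variance_threshold = float(corr_variance_threshold)
        self.on_constant = on_constant

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, view_name: str = "expression", **kw):
        """Build from a features-by-samples DataFrame."""
        return cls(ExpressionMatrix.from_frame(df, view_name), **kw)

    @staticmethod
    def _align_samples(views: list[ExpressionMatrix]) -> list[ExpressionMatrix]:
        common = set(views[0].sample_ids)
        for v in views[1:]:
            common &= set(v.sample_ids)
        if not common:
            raise ValueError("empty sample intersection across views")
        order = [s for s in views[0].sample_ids if s in common]
        aligned = []
        for v in views:
            pos = {s: i for i, s in enumerate(v.sample_ids)}
            aligned.append(v.subset_samples(np.array([pos[s] for s in order])))
        return aligned

    def fit(self, tol: float = 1e-6, max_iter: int = 100) -> "HCIResults":
        """Factorize every view and fuse the local patterns into Y."""
        locals_: list[LocalPattern] = []
        view_kinds: list[str] = []
        correlations = {}
        for v in self.views:
            try:
                lp = local_decompose(
                    v.values, self.expr_variance_threshold, view_name=v.view_name
                )
            except ValueError as exc:
                raise ValueError(f"local decomposition of {v.view_name!r}: {exc}") from exc
            locals_.append(lp)
            view_kinds.append("expression")
            if self.max_order >= 1:
                try:
                    fs = high_order_correlation(
                        v, self.max_order, on_constant=self.on_constant
                    )
                except ValueError as exc:
                    raise ValueError(
                        f"correlation construction for {v.view_name!r}: {exc}"
                    ) from exc
                correlations[v.view_name] = fs
                for F in fs:
                    name = f"{v.view_name}_F{F.order}"
                    locals_.append(
                        local_decompose(
                            F.values, self.corr_variance_threshold, view_name=name
                        )
                    )
                    view_kinds.append("correlation")
        try:
            gp = align_patterns(
                locals_, tol=tol, max_iter=max_iter, sample_ids=self.sample_ids
            )
        except ValueError as exc:
            raise ValueError(f"pattern alignment: {exc}") from exc
        return HCIResults(self, gp, locals_, view_kinds, correlations)


class HCIResults:
    """Fitted global pattern plus diagnostics and downstream analyses."""

    def __init__(self, model, global_pattern, local_patterns, view_kinds,
                 correlations):
        self.model = model
        self.global_pattern: GlobalPattern = global_pattern
        self.local_patterns: list[LocalPattern] = local_patterns
        self.view_kinds: list[str] = view_kinds
        self.correlations = correlations
        self.rdc_curve = None
        self.clustering = None

    # -- convenience accessors -------------------------------------------
    @property
    def pattern(self) -> np.ndarray:
        """Global sample-pattern matrix Y, shape (d, n_samples)."""
        return self.global_pattern.pattern

    @property
    def view_weights(self) -> pd.Series:
        return pd.Series(
            self.global_pattern.view_weights,
            index=self.global_pattern.view_names,
            name="weight",
        )

    def local_pattern(self, view_name: str) -> LocalPattern:
        for lp in self.local_patterns:
            if lp.view_name == view_name:
                return lp
        raise KeyError(f"no view named {view_name!r}; have "
                       f"{[lp.view_name for lp in self.local_patterns]}")

    # -- clustering ------------------------------------------------------
    def estimate_k(
        self,
        k_max: int = 15,
        n_repeats: int = 100,
        slope_threshold: float = 0.05,
        seed: int = 0,
        n_restarts: int = 10,
        relative_drop: float = 0.1,
    ):
        """RDC-curve estimate of the cluster number (cached on results)."""
        self.rdc_curve = _cluster.estimate_k(
            self.global_pattern, k_max, n_repeats, slope_threshold, seed,
            n_restarts, relative_drop,
        )
        return self.rdc_curve

    def cluster(
        self,
        k: int | None = None,
        n_restarts: int = 10,
        seed: int = 0,
        reference: LabelVector | None = None,
    ):
        """K-means partition of the samples on Y.

        ``k`` defaults to the RDC estimate (running it if needed); a
        reference LabelVector adds the ARI against the known partition.
        """
        if k is None:
            if self.rdc_curve is None:
                self.estimate_k(seed=seed)
            k = self.rdc_curve.chosen_k
        out = _cluster.kmeans_on_pattern(self.global_pattern, k, n_restarts, seed)
        if reference is not None:
            out.ari_vs_reference = _cluster.adjusted_rand_index(
                out.labels, reference
            )
        self.clustering = out
        return out

    # -- differential features -------------------------------------------
    def feature_weights(
        self,
        view_name: str | None = None,
        adjusted: bool = True,
        threshold: float | None = None,
        **cv_kw,
    ) -> FeatureWeightTable:
        """CV-of-loadings feature ranking for one expression view.

        Only expression-type views are meaningful here (correlation-view
        loadings index samples, not molecules).  ``adjusted=True`` maps
        the loadings through the view's alignment map into the global
        pattern space before the row statistics.
        """
        expr_idx = [i for i, k in enumerate(self.view_kinds) if k == "expression"]
        if view_name is None:
            idx = expr_idx[0]
        else:
            idx = next(
                (i for i in expr_idx
                 if self.local_patterns[i].view_name == view_name),
                None,
            )
            if idx is None:
                raise KeyError(f"no expression view named {view_name!r}")
        lp = self.local_patterns[idx]
        ids = self.model.views[expr_idx.index(idx)].feature_ids
        vm = self.global_pattern.view_maps[idx] if adjusted else None
        table = cv_weights(lp, feature_ids=ids, view_map=vm, **cv_kw)
        return select_differential(table, threshold)

    # -- reporting / persistence -----------------------------------------
    def summary(self) -> str:
        gp = self.global_pattern
        lines = [
            "HCI pattern fusion results",
            "=" * 60,
            f"samples: {gp.n_samples}    global dimension: {gp.dim}",
            f"alignment: {gp.n_iter} iterations, "
            f"converged={gp.converged}",
            "",
            f"{'view':<24}{'kind':<13}{'dim':>4}{'weight':>10}{'residual':>12}",
            "-" * 63,
        ]
        for lp, kind, w, r in zip(
            self.local_patterns, self.view_kinds, gp.view_weights, gp.residuals
        ):
            lines.append(
                f"{lp.view_name:<24}{kind:<13}{lp.dim:>4}{w:>10.4f}{r:>12.4g}"
            )
        if self.rdc_curve is not None:
            c = self.rdc_curve
            lines += [
                "",
                f"RDC cluster-number estimate: K = {c.chosen_k}"
                + (f" (plateau ties: {c.plateau_ks})"
                   if len(c.plateau_ks) > 1 else ""),
            ]
        if self.clustering is not None:
            o = self.clustering
            ari = ("" if o.ari_vs_reference is None
                   else f", ARI vs reference = {o.ari_vs_reference:.4f}")
            lines.append(f"clustering: k = {o.k}, inertia = {o.inertia:.4g}{ari}")
        return "\n".join(lines)

    def save(self, path) -> None:
        """Serialize the fitted model to one .npz archive."""
        path = Path(path)
        arrays = {
            "pattern": self.global_pattern.pattern,
            "view_weights": self.global_pattern.view_weights,
            "residuals": self.global_pattern.residuals,
        }
        meta = {
            "sample_ids": self.model.sample_ids,
            "view_names": self.global_pattern.view_names,
            "view_kinds": self.view_kinds,
            "n_iter": self.global_pattern.n_iter,
            "converged": bool(self.global_pattern.converged),
            "max_order": self.model.max_order,
            "feature_ids": {
                v.view_name: v.feature_ids for v in self.model.views
            },
        }
        for i, lp in enumerate(self.local_patterns):
            arrays[f"center_{i}"] = lp.center
            arrays[f"loadings_{i}"] = lp.loadings
            arrays[f"local_pattern_{i}"] = lp.pattern
            arrays[f"eigenvalues_{i}"] = lp.eigenvalues
            arrays[f"view_map_{i}"] = self.global_pattern.view_maps[i]
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "HCIResults":
        """Reload a saved bundle (a lightweight results object: the model
        attribute carries only sample/feature identifiers)."""
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            n_local = len(meta["view_names"])
            locals_ = []
            maps = []
            for i in range(n_local):
                ev = z[f"eigenvalues_{i}"]
                loadings = z[f"loadings_{i}"]
                locals_.append(
                    LocalPattern(
                        view_name=meta["view_names"][i],
                        center=z[f"center_{i}"],
                        loadings=loadings,
                        pattern=z[f"local_pattern_{i}"],
                        eigenvalues=ev,
                        dim=loadings.shape[1],
                        variance_threshold=float("nan"),
                    )
                )
                maps.append(z[f"view_map_{i}"])
            gp = GlobalPattern(
                pattern=z["pattern"],
                view_maps=maps,
                view_weights=z["view_weights"],
                residuals=z["residuals"],
                n_iter=int(meta["n_iter"]),
                converged=bool(meta["converged"]),
                view_names=meta["view_names"],
                sample_ids=meta["sample_ids"],
            )

        class _Stub:
            pass

        stub = _Stub()
        stub.sample_ids = meta["sample_ids"]
        stub.max_order = meta["max_order"]
        stub.views = [
            type("V", (), {"view_name": name, "feature_ids": fids})()
            for name, fids in meta["feature_ids"].items()
        ]
        return cls(stub, gp, locals_, meta["view_kinds"], {})
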