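# hci — high-order correlation integration for sample clustering

`hci` clusters the samples of one or several omics matrices (scRNA-seq
cells, bulk RNA-seq / miRNA / methylation patients) by augmenting each
matrix with its **high-order Pearson sample-correlation matrices** and
fusing everything with an adaptive **pattern fusion** step.

Grouping cells or patients from a noisy genes-by-samples matrix is hard
because entry-level noise drowns the between-sample structure.  The key
observation behind this method is that correlation sharpens structure
when iterated: the first-order matrix **F¹** holds the Pearson
correlation between every pair of sample columns of the expression
matrix **X** (m genes × n samples); the second-order matrix **F²** is
the Pearson correlation between the *columns of F¹ itself* — samples
from one cluster agree not only in expression but in how they relate to
every other sample, which is far more robust to noise.

Each matrix W ∈ {X, F¹, F²} is then reduced to a low-dimensional
*local sample pattern*: with c = W·1/n the per-feature means, the
loadings U are the eigenvectors of (W − c1ᵀ)(W − c1ᵀ)ᵀ belonging to the
top d eigenvalues, and Yᵢ = Uᵀ(W − c1ᵀ).  The dimension d is the
smallest one whose eigenvalues cover 80% of the spectrum for expression
matrices and 90% for correlation matrices.  The local patterns are
aligned into one global sample-pattern matrix **Y** by minimising

    Σᵢ wᵢ ‖Y − AᵢYᵢ‖²_F

with orthogonal-Procrustes maps Aᵢ and adaptive weights
wᵢ ∝ 1/(ε + rᵢ), so views that disagree with the consensus (e.g. a
noise-dominated assay) are automatically down-weighted.

Samples are clustered by K-means on the columns of Y.  The cluster
number K is estimated from the **RDC curve**, RDC(K) = D_in/D_out (mean
within- over mean between-cluster pairwise distance, averaged over
repeated K-means runs): the curve drops steeply until K reaches the true
cluster number and then flattens.  Agreement with known labels is scored
by the adjusted Rand index (ARI), and differential features (DEGs /
DE-miRNAs) are ranked by the coefficient of variation cᵢ = δᵢ/μᵢ of each
feature's row of the loading-weight matrix.

## Worked example

```python
from hci import (HCI, SyntheticSpec, simulate_expression,
                 filter_zero_features, normalize_columns)

# 500 genes x 90 cells, 3 planted clusters, 30% dropout
X, truth = simulate_expression(SyntheticSpec(seed=0))
X = normalize_columns(filter_zero_features(X), "log1p-zscore")

results = HCI(X).fit()                                  # X + F1 + F2 fused
curve = results.estimate_k(k_max=8, n_repeats=30, seed=0)
outcome = results.cluster(seed=0, reference=truth)
print(results.summary())
```

```
HCI pattern fusion results
============================================================
samples: 90    global dimension: 9
alignment: 5 iterations, converged=True

view                    kind          dim    weight    residual
---------------------------------------------------------------
expression              expression     55    0.3217      0.0674
expression_F1           correlation    49    0.3755    0.006267
expression_F2           correlation     9    0.3028      0.0945

RDC cluster-number estimate: K = 3 (plateau ties: [3, 4, 5, 6, 7])
clustering: k = 3, inertia = 0.362, ARI vs reference = 1.0000
```

The three views were reduced to 55-, 49- and 9-dimensional local
patterns and fused into a 9-dimensional global pattern; the RDC curve
flattens first at K = 3 (the planted cluster number; every K from the
plateau onward is listed so ties stay visible) and the resulting
partition matches the planted labels exactly (ARI = 1).  Feature
ranking then flags the genes driving the separation:

```python
table = results.feature_weights()     # CV of loading weights, T = 90th pct
print(table.to_frame().sort_values("cv", ascending=False).head())
```

The 50 selected genes (cv above the default 90th-percentile threshold
1.01 in this run) are strongly enriched for the planted marker genes.

The same objects work for matched multi-omics views:

```python
model = HCI([mrna, mirna, methylation])   # aligned on shared sample ids
results = model.fit()                     # 9 matrices fused: 3 views x {X, F1, F2}
```

## Command line

```sh
hci simulate --spec spec.yaml -o fixture/          # labeled synthetic bundle
hci cluster -i expr.tsv --labels ref.tsv -o out/   # single-matrix workflow
hci integrate -i mrna.tsv -i mirna.tsv -o out/     # multi-omics workflow
hci features --model out/model.npz -o weights/     # DEG / DE-miRNA tables
```

Dense TSV/CSV (first column = feature ids, header = sample ids) and
Matrix-Market triplets with feature/barcode files are accepted.  Every
run writes `summary.json` with the full configuration and seeds, plus
`pattern.tsv`, `labels.tsv`, `rdc_curve.tsv` and a reloadable
`model.npz` bundle.

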