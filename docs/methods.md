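# Methods

## Model overview

`hci` treats sample clustering as a multi-view consensus problem.  From
every input matrix X (features × samples) it derives two extra views:

* **F¹**, the Pearson correlation between all pairs of sample columns
  of X, and
* **F²**, the Pearson correlation between the columns of F¹, treating
  F¹ as an n-feature × n-sample matrix (the unit diagonal is kept as
  data; the sum in the correlation runs over all n entries).

Higher orders follow the same recursion and are supported, but the
default stops at order 2: the gain saturates there, and the second
order is where the within/between-cluster contrast of the similarity
matrix peaks on noisy data (this is asserted as a statistical test in
the suite, not assumed).  Spearman or other rank kernels are
deliberately not offered — on rank-transformed data the recursion adds
little because F² of ranks resembles F¹.

Each view W is factorized around its row means, W ≈ c1ᵀ + U·Y_local,
with U the top-d eigenvectors of the centered scatter
(W − c1ᵀ)(W − c1ᵀ)ᵀ and Y_local = Uᵀ(W − c1ᵀ).  This is computed
through the thin SVD of the centered matrix, whose squared singular
values are exactly the scatter eigenvalues; eigenvalues below
1e-10 × the largest are treated as zero.  Eigenvector signs are fixed
(largest-magnitude entry positive) so repeated runs are bit-identical.

### Choice of the local dimension

d is the smallest dimension whose eigenvalues cover a cumulative
fraction of the nonzero spectrum: **0.8** for expression-type views and
**0.9** for correlation views (whose feature dimension is the sample
count, hence flatter spectra).  Both thresholds are exposed as
parameters.  The boundary is inclusive (a spectrum {8,1,1} at 0.8
yields d = 1).

## Alignment of local patterns

The global sample-pattern matrix Y minimizes, to local optimality,

    J = Σᵢ wᵢ ‖Y − Aᵢ Yᵢ‖²_F

by block coordinate descent in the style of generalized Procrustes
analysis:

1. **Scale.**  Each local pattern is brought to unit Frobenius norm.
   Pattern norms of an expression view and its correlation views differ
   by an order of magnitude or more; without this step the largest view
   dictates the consensus regardless of quality.
2. **Consensus dimension.**  The target dimension defaults to the
   *smallest* local dimension.  The consensus is only identifiable on
   directions the views can share; padding up to the largest view
   imports that view's unshared — typically noise — directions into Y,
   which measurably blurs the downstream RDC elbow.  Views with more
   dimensions contribute their leading rows.  The dimension can be
   overridden.
3. **Maps.**  Each Aᵢ is an orthogonal-Procrustes partial isometry
   (orthonormal columns), obtained in closed form from the SVD of
   Y·Yᵢᵀ.  Rigid maps are essential: an unconstrained least-squares map
   lets any high-dimensional noise view reproduce the consensus almost
   exactly, which would invert the adaptive weighting.  No per-view
   scale factor is fitted — a free scale admits the trivial fixed point
   Y → 0 (the classic degeneracy of generalized Procrustes without a
   size constraint).
4. **Weights.**  wᵢ ∝ 1/(ε + rᵢ) with rᵢ the view's squared residual,
   renormalized each iteration.  This is the majorize–minimize update
   for the concave surrogate Σᵢ log(ε + rᵢ), which therefore decreases
   monotonically (the recorded `objective_history`; the invariant is
   tested).  ε is calibrated **once**, to the mean per-view residual of
   the first iteration, and held fixed: a vanishing ε lets any view
   with a near-zero residual absorb all the weight and collapse the
   fusion onto itself, while ε at the residual scale keeps weight
   ratios bounded yet still down-weights disagreeing views.
5. **Initialization and convergence.**  Y starts as the uniform average
   of the zero-padded local patterns, so no view begins with an exactly
   zero residual.  Iteration stops when the relative objective change
   drops below `tol` (default 1e-6) or after `max_iter` (default 100)
   iterations.

A single view bypasses the loop entirely and returns its local pattern
unchanged with weight 1 — the one-matrix factorization baseline.

Y is defined only up to an orthogonal transform of its rows; every
downstream consumer (K-means, RDC) depends on Y through inter-sample
distances only, and the tests compare geometries, never raw
coordinates.

## Cluster number estimation

For each K on the grid 2..k_max (default 15), K-means (scikit-learn
backend, 10 restarts per run, seeds derived from one master seed) is
repeated `n_repeats` times (default 100) on the columns of Y, and

    RDC(K) = D_in / D_out

is recorded, where D_in is the mean Euclidean distance over all
within-cluster sample pairs and D_out over all between-cluster pairs —
pairwise means, not centroid distances; singleton clusters contribute
no within-pairs, so D_in stays a true pair average.  All rows of Y
enter the distance with equal weight.

The chosen K is the smallest one at which the forward slope
|meanRDC(K+1) − meanRDC(K)| of the averaged curve is *nearly zero*, in
either of two senses:

* below `slope_threshold` (default 0.05) × the range of the mean curve,
  or
* for K > 2, collapsed by at least an order of magnitude relative to
  the preceding slope (`relative_drop`, default 0.1).

The second, scale-free condition is needed because a well-defined elbow
can sit on a slowly drifting tail: after a drop covering ~90% of the
curve's range the residual drift often stays near 5–7% of the range per
step, which a pure range-fraction rule misreads.  An order-of-magnitude
slope collapse is the natural scale-free reading of "the slope becomes
nearly zero".  Every K satisfying either condition is reported
(`plateau_ks`), so plateau ties such as "5 or 6" remain visible, and
the full curve is always returned for manual override.  A curve with
zero range falls back to K = 2 with a warning.

Partition agreement uses the Hubert–Arabie adjusted Rand index
(scikit-learn implementation, oracle-checked against explicit pair
enumeration in the tests), aligned by sample identifier when both
partitions carry them.

## Differential features

A feature's weight in pattern r is defined as |u_ir|·√δ_r — the
magnitude of its contribution to that pattern's signal, i.e. the
eigenvector entry put back on the scale of the variance it explains.
Feature i is scored by the coefficient of variation of its weight row,
cᵢ = δᵢ/μᵢ (sample sd over mean), and called differential when cᵢ
exceeds a threshold T, by default the 90th percentile of the finite cᵢ
in the view so a selection is defined on any dataset.  Features whose
mean weight is numerically zero (|μ| < 1e-12) are flagged cᵢ = +∞ and
excluded from selection.

The contribution scale is load-bearing.  Rows of a bare (centered)
eigenvector matrix have near-zero mean, so δ/μ becomes a scale-free
ratio with the same distribution for structure-carrying and noise
features — it cannot rank anything.  With contribution magnitudes, a
marker gene concentrates large weights on few patterns (high δ relative
to μ) while a noise gene spreads small weights evenly (cv tightly
concentrated near the half-normal value ≈ 0.76), and the separation is
decisive (Mann–Whitney p ≈ 1e-7 or better on the synthetic benchmark;
tested).  Flags restore bare or signed loadings for inspection.  By
default the analysis applies to the expression-view loadings mapped
through the view's alignment map (U·Aᵢ⁺), expressing weights in the
global pattern space; the raw local loadings are available via
`adjusted=False`.  Correlation-view loadings index samples, not
molecules, and are not eligible.

## Synthetic data

The generator plants K balanced clusters (sizes within 1) in an
m-features × n-samples matrix: per-feature log-scale baselines
~ N(1, 0.5); a fraction (default 10%) of features are markers assigned
round-robin to a home cluster and up-shifted there by
effect_size × noise_sd on the log scale; i.i.d. Gaussian noise
(sd = noise_sd); exponentiation to a nonnegative FPKM/CPM-like scale;
then independent Bernoulli dropout zeros.  A negative-binomial count
mode (dispersion 5) is available behind `distribution="nb"`.
Multi-view bundles share one sample partition with independent feature
spaces and per-view effect sizes (zero gives a pure-noise view).  All
randomness derives from one seed; outputs round-trip through the
package's TSV readers.

Benchmark conditions used by the test suite and the acceptance script:

* **Recovery benchmark** (the generator defaults): n = 90, m = 500,
  K = 3, 3σ markers, 30% dropout, 20 generator seeds; K-selection uses
  the grid 2..8 with 30 K-means realizations per K.
* **Noisy ablation benchmark**: same, with 1.8σ markers — chosen so the
  single-view baseline lands at mid-range ARI (≈ 0.4), the regime where
  integration differences are observable at all; ARI is compared at the
  true K = 3.
* **Adaptive-weighting benchmark**: three views with effects
  (3σ, 3σ, 0), 20 seeds.

What passing these benchmarks does **not** show: the generator has
i.i.d. noise, no gene–gene correlation modules, no library-size or
batch effects, and dropout independent of expression level.  Its
spectra are therefore much flatter than real scRNA-seq (the 0.8 rule
retains ~55 of 89 possible dimensions instead of a handful), which makes
the benchmarks conservative for the correlation views but easy for mean
shifts.  Also, because F¹ and F² are deterministic transforms of X, the
correlation views add no *independent* information here — the fused run
matches the best single view (a statistical tie with F²-only) rather
than strictly beating it, whereas on real data the orders can carry
complementary noise structure.  Real-data performance claims require
real data.

## Numerical choices and degenerate inputs

* Correlation entries are symmetrized (average with transpose), clipped
  into [−1, 1], and the diagonal set to exactly 1.
* A constant sample column makes Pearson correlation undefined: the
  default is an error naming the column and the order at which it
  occurred; a flag substitutes zero off-diagonal correlations with a
  warning.
* Variances use the n−1 denominator throughout.
* Zero-variance columns under z-scoring raise with the offending sample
  named; all-zero feature sets raise "no informative features".
* The "more than 80% zeros" multi-omics feature filter is strict: a row
  at exactly the threshold is kept.
* Variable-feature selection ranks by plain per-row variance (a
  `use_cv` flag switches to σ/μ); ties break in favour of earlier rows;
  survivors keep their input order.
* Missing values are rejected at load time unless explicitly imputed to
  zero (`impute_zero`), which warns with a count.
* K-means is fully deterministic given the seed; the RDC machinery
  derives all per-run seeds from one master seed.

## Limitations

* The alignment finds a local optimum; with adversarial view sets the
  weighted consensus depends on initialization (fixed and deterministic
  here).
* RDC-based K selection assumes a single dominant granularity; under
  hierarchical structure it reports the coarse level, with the finer
  level visible as a secondary flattening of the emitted curve.
* K estimation degrades when clusters are small relative to their
  spread (e.g. K = 5 with 18 samples per cluster at 3σ markers
  overshoots by one on these benchmarks); the curve should be inspected
  rather than trusted blindly near that regime.
* Memory is O(n²) per correlation matrix and the factorization is
  dense; tens of thousands of samples need sub-sampling or a sparse
  re-implementation.
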