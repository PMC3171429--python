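# Methods

This note documents the generative model, the imputation algorithms, the
evaluation protocol, and the numerical and design choices behind
`mvimpute`, including what the synthetic data do and do not emulate.

## Generative model

A dataset is a genes × samples matrix of log2-ratio expression values,
`measured = signal + noise`, with two balanced sample classes.

**Signal.** `s_ij = f_i(c_j) + z_ij`. The first `n_markers` (default 30 of
500) genes are markers: each draws two magnitudes from N(`mu_fold`,
`sd_fold`²) = N(0.58, 0.1²) — one per class — and a random sign applied
oppositely to the two classes, so the expected between-class separation is
2 × 0.58 in log2 units. Marker placement at the first indices is
deterministic for reproducibility; markers therefore span the first
⌈30/block_size⌉ correlation blocks, and correlation between markers and
their block-mates is intended model behaviour. The gene effect `z` is
multivariate normal with a block-diagonal covariance: within a block of
`block_size` genes, all pairs share correlation `block_corr` and every gene
has SD `block_sd`; between blocks the covariance is zero. Sampling is done
block-by-block with the exact two-component decomposition (shared +
idiosyncratic standard normal), avoiding a full-matrix Cholesky.

**Noise.** Per-gene noise SDs are exponential with mean `noise_mean`;
entries are independent normals with their gene's SD. This produces the
strongly heterogeneous probe quality seen in real arrays (the 90th/10th
percentile ratio of per-gene SDs exceeds 3) and thereby a non-uniform
missingness pattern.

**Missingness.** Quality mode discards the entries with the largest |noise|:
the threshold is the (1 − `mv_rate`) quantile of pooled |noise|, and the
training mask hits `round(mv_rate · n · d)` entries *exactly* by rank
thresholding, ties broken toward lower (gene, sample) coordinates. Test
partitions score their own noise against the *training* threshold, so
realised test MV rates fluctuate around the nominal rate — the test set is
generated independently but identically. Random mode masks a uniform subset
of the same size. A fully masked gene row aborts generation with an error
rather than being dropped silently.

**Random streams.** One root seed; child generators are derived per
(repetition, partition) through `numpy` `SeedSequence` spawn keys, so runs
are reproducible and resumable.

### Defaults and what they represent

| parameter | default | meaning |
|---|---|---|
| `n_genes` / `n_markers` | 500 / 30 | filtered array, small marker panel |
| `n_train` / `n_test` | 60 / 200 | small-sample design; large test set for precise error estimates |
| `mu_fold`, `sd_fold` | 0.58, 0.1 (log2) | 1.5-fold change, reliably detectable |
| `block_sd`, `block_corr`, `block_size` | 0.8, 0.5, 25 | moderate pathway-scale correlation |
| `noise_mean` | 0.4 (log2) | mid grid point of {0.1, 0.2, 0.4, 0.8, 1.2, 1.6} |
| `mv_rate` | 0.10 | centre of the swept range {0.01 … 0.25} |

The block/noise/rate grids are package choices exposed in configuration;
sweeps over them are first-class (`ExperimentPlan`).

## Imputation algorithms

All methods return the input unchanged at observed cells and are
deterministic without any seed (BPCA initialises from a row-average fill
plus an eigendecomposition).

* **RAVG** — gene's observed mean. Computed per row with `np.mean` of the
  observed slice so fills are bitwise equal to the textbook arithmetic.
* **KNNimpute** — eligible candidates must be observed at all of the
  target's missing positions; distance is Euclidean over jointly observed
  positions scaled by their count (making genes with different observation
  patterns comparable); weights ∝ 1/(distance + ε), ε = 10⁻⁶, normalised —
  a convex combination, so fills stay inside the candidates' range. A
  target with no eligible candidate falls back to RAVG and is logged.
  Default K = 10 (the commonly recommended 10–20 neighbourhood).
* **LLS.L2 / LLS.PC** — candidates are the `k_candidates` genes nearest in
  L2 over the target's observed positions, or with largest |Pearson r| over
  jointly observed positions; candidate MVs are pre-filled by RAVG; the
  weight vector is the minimum-norm least-squares solution (via
  `lstsq`/pseudoinverse) of regressing the target's observed part on the
  candidates' observed parts, applied to their missing parts. The
  combination is unconstrained, so fills can leave the candidates' range.
* **LS** — candidates by largest |r|; each yields a univariate regression
  estimate (slope = cov/var, matching intercept); estimates are combined
  convexly with weights `w = (r²/(1 − r² + 10⁻⁶))²`, normalised.
  Zero-variance candidates get r = 0 and weight 0; if all weights vanish
  the fill degrades to the target's observed mean.
* **BPCA** — probabilistic PCA on gene rows (dimension = samples,
  q = samples − 1 factors), isotropic residual precision τ, and an ARD
  prior giving each loading column its own precision α_j; a variational
  EM loop alternates posterior expectations of scores and missing entries
  with updates of loadings, mean, τ and α. Redundant axes are driven to
  zero; a factor counts as *effective* while its loading-column energy
  exceeds the residual noise variance (‖w_j‖²·τ > 1). Convergence is
  declared when the RMS change of the imputed entries drops below
  `bpca_tol` (default 10⁻³ — changes at that scale are far below the fill
  error itself), capped at `bpca_max_iter` = 200 with a warning and
  best-iterate return.

**Candidate count.** `k_candidates` defaults to 10. With 60-sample
matrices a target gene has ~54 observed positions; as the candidate count
approaches that, the local regression saturates and the minimum-norm
solution interpolates the target's noise, producing unbounded
extrapolation at the missing positions (NRMSE can explode by orders of
magnitude). Keeping the default at the KNN neighbourhood scale — also
below the correlation block size — avoids the degenerate regime while
remaining configurable for sensitivity sweeps.

**BPCA implementation.** The per-row posterior precision differs from the
shared `Rx = I + τW'W + ΣW` only in the row's missing coordinates, so its
inverse is obtained with the Woodbury identity from per-row m × m systems;
rows are processed batched, bucketed by missing count to keep padding
tight. The vectorised step is verified in the test suite against a naive
per-row reference implementation to 10⁻¹⁴.

## Evaluation protocol

Training data are imputed once per method; the classifier (feature
selection + rule) is designed entirely on that completed matrix. A test
point is completed by adjoining it *alone* to the measured training matrix
and its mask, running the same imputation on the augmented matrix, and
extracting the completed column; training-column fills are discarded. Test
points are therefore mutually invisible — deleting or permuting test
points changes nothing about the others (asserted by test) — and
imputation of future examples is part of the classification rule. Signal
and measured ("orgn") baselines are evaluated like-on-like against their
own complete test views.

Two protocol-scale optimisations preserve this contract exactly: local
methods fill only the gene rows missing in the adjoined column (nothing
else of the completion is consumed), and BPCA warm-starts the augmented
fit from the training fit's parameters — the new column's loading row is
grafted on by regressing its observed values on the training factor
scores, ridge-regularised by the model's own ARD precisions — with
refinement capped at 50 iterations and convergence tracked on the adjoined
column. Warm and cold fits agree to well within the fill error.

**Feature selection.** Pooled-variance two-sample t statistics (the model
draws both classes with equal covariance, so pooling is the matched
choice), with 10⁻¹² added to the denominator against zero-variance genes.
The wrapper path filters to `stage1_size` = 100 genes and runs SFFS with
bolstered resubstitution as criterion, recomputed per evaluated subset;
criterion ties break toward the lower gene index.

**Bolstered error.** Each training point is replaced by a spherical
Gaussian whose SD makes the kernel's median radial distance (the χ_D
median) equal its class's mean same-class nearest-neighbour distance. For
linear rules the error integral is the Gaussian tail of the signed margin,
computed in closed form; for 3NN it is Monte-Carlo with a derived seed.
Identical points give SD 0 and plain resubstitution.

**Rules.** LDA with equal priors and a ridge of 10⁻⁶·trace(Σ)/D on the
pooled covariance diagonal (feature counts up to 30 on 60 samples are
near-singular); boundary ties go to class 0. 3NN with Euclidean distance
(ties impossible at k = 3 with two classes). Linear soft-margin SVM with
cost 1 via scikit-learn's `SVC`.

**NRMSE.** RMS of (imputed − signal) over masked entries divided by the
*population* SD (divide by count) of the signal over those entries, making
"fill with the mean of the true masked values → NRMSE = 1" an exact
identity.

## What the simulation does and does not emulate

It reproduces: log-scale additive signal/noise structure, cluster-scale
gene correlation, heterogeneous probe quality, quality-driven missingness,
and class structure carried by a small marker panel. It does not model
intensity-dependent (Lowess-correctable) artefacts, more than two classes,
batch effects, non-Gaussian heavy-tailed noise, or correlation structure
beyond disjoint equicorrelated blocks. Consequently, passing tests show
the algorithms behave correctly *under this model*; relative method
rankings on real arrays — where global correlation is far richer — can
differ, and the local regression methods in particular benefit from the
stronger gene–gene correlation of real data.

## Problem sizes used by the shipped checks

The default test suite and `scripts/acceptance.py` run the full pipeline
at the paper-scale geometry (500 genes, 60/200 samples) but with 10–20
repetitions per condition rather than 150; the full factorial grid at 150
repetitions remains available through `ExperimentPlan(repetitions=150)`
and the `mvimpute run` CLI as a long-running configuration. Statistical
acceptance checks (sign tests, curve shapes) are formulated to be valid at
the reduced repetition counts.

## Known limitations

* BPCA's variational loop can stall just above a tight tolerance on hard
  high-noise fits; the cap-and-warn behaviour returns the best iterate,
  which is adequate for imputation but means `converged=False` fits are
  not exact posterior optima.
* LLS's minimum-norm solution is faithful to its definition and therefore
  inherits its instability for targets with few observed positions at
  high MV rates; this is reported honestly in NRMSE rather than clipped.
* `impute_test_point` re-runs imputation once per test point by design;
  for large test sets this is the dominant cost (mitigated but not removed
  by the warm-start machinery).
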