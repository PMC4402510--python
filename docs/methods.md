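# Methods

This note documents the statistical models in `genelm`, the defaults and
numerical choices, what the synthetic-data generators emulate, and known
limitations. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Gene-wise linear models

Each gene's expression vector (length N) is regressed on a shared N × p
design matrix by least squares, vectorized across genes. Variants:

* **Weights.** Observation weights (e.g. voom precision weights) and
  sample weights multiply into a per-gene diagonal weight matrix. Missing
  values (allowed for log-intensity data only) are treated as weight-zero
  observations with the residual df reduced accordingly; the unscaled
  coefficient covariance is then gene-specific and stored per gene.
* **Blocked correlation (GLS).** With a block structure and consensus
  correlation ρ, fitting whitens by the Cholesky factor of the
  equicorrelated within-block covariance. ρ = 0 reproduces OLS exactly
  (tested bit-for-bit). Weights and blocking may be combined (weights
  applied as a per-gene rescaling of the correlation matrix); this
  combination is exercised less and should be considered experimental.
* **Robust regression.** Iteratively reweighted least squares with Huber
  weights (k = 1.345, 20 iterations, MAD scale). The residual df is not
  reduced; the robust residual sd is the Huber-weighted RSS over df. This
  guards coefficients against single-observation outliers but is not a
  high-breakdown estimator.

Contrasts re-express a fit as C'β with standard deviations from
sqrt(diag(C'VC)) per gene; composition of contrast transformations is
associative (property-tested).

### Consensus intrablock correlation

Per gene, the REML log-likelihood of the equicorrelated random-intercept
model is profiled over ρ on a shared grid (81 points from
max(−0.95, −1/(k−1)+0.02) to 0.99), evaluated for all genes at once via a
per-ρ whitening transform; per-gene maximizers are refined by local
quadratic interpolation, clamped to |ρ| ≤ 0.99, combined by a 15%-trimmed
mean on the atanh (Fisher-z) scale and transformed back. The grid + 
quadratic refinement resolves ρ far below the consensus's sampling noise;
the trim fraction follows the common default for consensus estimators.
Recovery of ρ = 0.5 within ±0.05 at 5000 genes (blocks of two) is part of
the acceptance checks.

### Sample (array) quality weights

The heteroscedastic model Var(ε_gj) = σ_g²/w_j is fitted by alternating
gene-wise weighted least squares with a moment update: each sample's
factor is updated by the mean (over genes) leverage-corrected standardized
squared residual. This is the Fisher-scoring fixed point approached
coordinate-wise; iteration stops when log-weights move < 1e-4 (typically
10–30 iterations; the update converges geometrically and warns at the
50-iteration cap). Weights are normalized to geometric mean 1.

## Empirical Bayes moderation

Hyperparameters of the scaled inverse-chi-square variance prior are
estimated on z = log s² using E[z] and Var[z] identities in the digamma /
trigamma functions; d₀ solves trigamma(d₀/2) = excess variance by Newton
inversion. When the excess variance is non-positive the prior df is
infinite and the prior variance is the natural-scale mean of the s² (exact
for constant variances). With the trend option, log s₀²(A) follows a
robust lowess (span 0.5, 3 iterations) of z on average log-expression and
the moments use residuals from that curve.

**Robust variant.** z is winsorized at its (5%, 95%) quantiles before
moment matching, with the winsorized variance de-attenuated by the
normal-theory factor for those quantiles (an approximation — the exact
digamma-based correction would differ slightly). Genes whose variance is a
Bonferroni-scaled upper-tail outlier under the fitted prior receive a
per-gene prior df interpolated down to 0.01, so hypervariable genes keep
essentially their own variance and are not promoted to significance by
shrinkage.

Moderated t uses the posterior variance and d₀ + d_g degrees of freedom;
per-gene moderated F orthogonalizes the coefficient columns through the
(rank-safe, pseudo-inverse) coefficient correlation, so redundant
contrasts collapse rather than error. The B-statistic (log posterior odds)
uses a two-component model with prior DE probability 0.01 (configurable);
the coefficient-variance prior v₀ is estimated by quantile matching on the
top proportion/2 fraction of |t| — matching an overall fixed quantile
(e.g. the 90th percentile) cannot identify v₀ when the DE fraction is 1%,
so the target quantile scales with the assumed proportion. B is a ranking
diagnostic; inference should use p-values.

TREAT p-values for |log₂FC| > τ are the sum of the two shifted t tails;
τ = 0 reproduces the ordinary two-sided p exactly, and p is monotone
non-decreasing in τ (both tested).

**π₀ estimation.** Four estimators: twice-the-mean-p; the iterative
histogram estimator; a convex decreasing density estimate — the maximum
likelihood fit of a mixture of the uniform density and triangular
densities on a 100-point grid, by EM, with π₀ = f̂(1) = the uniform
weight; and an average-local-fdr estimate, mean of min(1, 1/f̂(p)) under
the same density fit (an upper-bound form, slightly conservative by
construction).

## Count pipeline

logCPM = log₂((count + 0.5) / (lib + 1) × 10⁶). TMM normalization factors
follow the published trimmed-mean-of-M-values procedure: reference column
by the 75th-percentile rule, gene-wise M on library-normalized
proportions, double trimming (30% on M, 5% on A), inverse
asymptotic-variance weights, geometric-mean-1 rescaling. An independent
Bioconductor implementation reproduces these factors to ~0.3% in
development cross-checks; factors for an exact library-size doubling are
1 (library scaling is not a composition bias).

voom fits the gene-wise model on logCPM, lowesses sqrt residual sd on
average log₂ count (span 0.5), maps each observation's fitted logCPM to a
fitted log count and interpolates the curve — flat beyond the observed
range, so extreme fitted counts cannot produce explosive weights — and
returns weight = predicted sqrt-sd⁻⁴. The quality-weight variant
alternates voom with sample-weight estimation (two rounds) and finishes
with a final voom layer under the final sample weights, so the returned
observation weights factor exactly into (voom layer) × (sample layer).

Gene filtering before voom keeps genes with CPM > 1 in at least
min-group-size samples (configurable); all-zero genes trigger a warning if
left in.

## Gene set tests

* **Rank test:** Wilcoxon rank-sum of the set's statistics vs the rest
  (|t| for the mixed alternative); exact null when the smaller group has
  ≤ 10 members and no ties, else normal approximation with continuity
  correction. Assumes inter-gene independence, hence optimistic p-values
  for correlated sets — demonstrated in the acceptance checks.
* **camera:** gene-wise moderated t → normal-score equivalents; per set,
  mean inter-gene correlation from unit-normalized residual-space effects,
  floored at 0 (a VIF < 1 would be anti-conservative); modified
  two-sample t with the set variance inflated by VIF = 1 + (m−1)ρ̄. The
  reference t-distribution has min(residual df, G−2) df when ρ̄ is
  estimated (the estimate carries only residual-df information) and G−2 df
  when ρ is supplied. Singleton sets get VIF = 1 with a note.
* **Rotation tests:** data are projected onto the unit vector estimating
  the contrast plus an orthonormal residual basis; under the gene-wise
  null these d+1 coordinates are iid normal, so replacing the contrast
  coordinate by a uniformly random direction (standard normals normalized
  to the sphere) resamples the statistic exactly. Variances inside the
  scores are moderated with the prior fitted to all genes. p = (b+1)/(nrot+1),
  so p-values take exactly the values k/(nrot+1). Set summaries: mean
  (default), floored mean, top-half mean, mean square; the mixed
  alternative always uses mean-squared scores. mroast shares one rotation
  stream across sets; romer recomputes and ranks all gene scores per
  rotation (mean set rank, competitive), processing rotations in blocks of
  500 to bound memory. Per-gene direction/weight annotations multiply the
  scores before summarizing; only their relative magnitude matters.
* **Overlap enrichment:** one-sided hypergeometric upper tail on a
  user-supplied universe and set collection; no annotation database access
  and no gene-length bias adjustment.
* **Barcode profile:** ranked positions of set genes plus a
  Gaussian-kernel (bandwidth 0.1 of the ranking, boundary-reflected)
  relative-enrichment curve.

## Differential splicing

Exon-level coefficients are compared with the precision-weighted
(1/u² weights) average coefficient of their gene. Residual variances are
pooled within genes (exons of a gene share a variance) and moderated
across genes. The per-exon t divides the deviation by its exact standard
deviation including the leverage term 1 − w_e/Σw; the gene-level F is the
mean of the k−1 free squared deviations against F(k−1, pooled df + d₀);
the gene-level Simes p multiplies the k−1 smallest exon p-values by
(k−1)/rank (the deviations carry only k−1 degrees of freedom). Single-exon
genes are dropped with a logged count.

The F-based gene p-value is exactly uniform under the null. The Simes
aggregate is not — the k deviations are negatively equicorrelated at
−1/(k−1), which leaves the Simes level approximately (and in simulation
mildly above) nominal; the tests therefore assert exact uniformity for F
and level-control (≤ ~0.065 at 0.05) for Simes. Simes is kept because it
ranks genes by their strongest exon, the quantity of applied interest.

## Exploration

Leading-fold-change MDS: the distance between two samples is the RMS of
their `top` (default 500) largest absolute log-differences, either
per-pair or on one common top set; classical (Torgerson) double-centred
eigen-embedding with the first non-zero loading of each axis forced
positive for reproducible orientation. Mean-difference values against the
virtual (leave-one-out average) array; sigma-vs-abundance profiles return
the same lowess curve the trended prior would use.

## Pre-processing of intensities

Background correction uses the normal + exponential convolution
(observed = N(μ, σ²) noise + Exp(α) signal): maximum likelihood on the
closed-form convolution density evaluated in log space (log Φ via
`log_ndtr`), Nelder–Mead from a method-of-moments start; the corrected
value is the posterior mean of the signal — a truncated-normal mean that
is strictly positive and monotone, so log₂(x + offset) afterwards is
always finite. Default offset 16 on the raw intensity scale (a moderate
value; configurable). Quantile normalization forces identical column
distributions with ties receiving the mean of their tied targets; this is
exactly idempotent for tie-free data, while with ties a second application
can move untied columns by a small tie-induced target shift (the tie rule
and exact idempotency cannot hold simultaneously). Cyclic loess subtracts
half of each pairwise M-vs-A loess curve (local linear, tricube,
span 0.7, 3 cycles, 3 robustness iterations, evaluated on a 200-point grid);
observation weights act as prior weights in the local regressions, so
zero-weight probes are adjusted without influencing the curve.

## Synthetic data

The generators are pure functions of their seed (NumPy PCG64) and
parameters, and return the ground truth used by every calibration test:

* `sim_log_matrix` — the moderation model itself: baselines uniform on
  [4, 14] log₂, variances from the scaled inverse-chi-square prior
  (optionally abundance-dependent), DE effects N(0, logfc_sd²) on a chosen
  design column. Defaults (d₀ = 4, s₀² = 0.05, 10% DE, logfc_sd = 1)
  represent a typical small microarray experiment.
* `sim_counts_nb` — negative-binomial counts, gene means log-uniform on
  [5, 5000], dispersion 0.05 + 10/μ (biological floor plus shot-noise-like
  technical component, decreasing in abundance), library sizes ±30%.
* `sim_blocks` / `sim_correlated_sets` — equicorrelated within-block
  errors; latent-factor-induced within-set correlation with no DE.
* `sim_exon_matrix` — exon rows sharing one per-gene variance (the regime
  the pooled splicing model assumes), with an optional shifted first exon.

What they do **not** emulate: probe-level artefacts, batch structure,
outlier samples (unless injected), correlated genes outside designated
sets, zero-inflation, gene length or GC effects, and any read-level
process. Passing calibration on these generators shows the estimators are
correct under their stated models — not that real data satisfy those
models.

## Numerical conventions and edge cases

Gene identifiers are opaque, case-sensitive strings. Matrices are genes ×
samples everywhere. Saturated fits (df = 0) carry σ = NA, are excluded
from prior estimation, and receive the prior variance and df under
moderation so they remain testable. Result tables are written with floats
at six significant digits and NaN as "NA"; row order is deterministic
(p-value with |t| tie-break for top tables). Duplicate sample ids are
rejected; duplicate gene ids only with an explicit opt-in that suffixes
them. All stochastic CLI subcommands take `--seed` (default 0) and record
it in output header comments.

## Problem sizes in the automated checks

The test suite and acceptance script use 2000–20000 genes, 6–20 samples,
8–20 FDR replicates, 199–999 rotations and 300–1000 Monte-Carlo sets per
calibration estimate. These sizes put the Monte-Carlo error comfortably
inside each asserted band while keeping a full run in the minutes range;
the estimators themselves have no dependence on these choices.
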