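# Methods

## Model and pipeline

The analysis treats a methylation cohort as a probes × samples matrix of
beta values β ∈ [0,1] plus per-sample metadata (group, age, sex, batch) and
a probe manifest (genomic position, platform membership, SNP and
cross-reactivity flags, gene annotations). Stages, in order:

1. **Probe QC.** A probe is removed if its detection p-value exceeds 0.01
   in *any* sample (strictest reading of the per-sample quality rule; a
   summary-rate rule would be a config extension), if it lies on chrX/chrY,
   or if it carries a SNP or cross-reactivity flag. Counts are reported per
   criterion, first-match in that order. Probes missing a value in any
   sample are then dropped (complete cases).
2. **Transform.** β is clipped to [ε, 1−ε], ε = 0.001, and logit
   transformed: M = log₂(β/(1−β)). The clip keeps |M| ≲ 10 without
   distorting the bulk of the distribution; modelling happens on M (closer
   to homoscedastic), effect thresholds stay on β (interpretable as
   methylation percentage).
3. **Deconvolution covariates.** Blood is a cell mixture and composition
   differs between people, so per-sample leukocyte proportions are
   estimated from a reference beta matrix by non-negative least squares
   with a sum-to-one constraint (implemented as NNLS on a system augmented
   with a heavily weighted sum row, then exact renormalisation). The
   equality constraint (rather than ≤ 1) avoids scale ambiguity in
   covariates; one proportion column is dropped from the design to avoid
   collinearity with the intercept.
4. **Per-probe models.** OLS of M on [intercept, case, proportions], with
   bi- and mono-allelic carriers pooled as "case". Residual variances are
   squeezed toward a prior: s̃²_g = (d₀s₀² + d_g s²_g)/(d₀+d_g), the prior
   (d₀, s₀²) estimated by moment matching on log s² (digamma/trigamma
   inversion). The moderated t = coef/(s̃·sd_unscaled) is referred to t with
   d₀+d_g df (normal at d₀ = ∞). When the log-variance spread is no larger
   than its sampling variance the prior df is infinite; a perfectly
   degenerate ensemble (all s² identical) returns the common value as the
   prior so the squeeze is the identity. The whole construction is verified
   against R limma's `eBayes` to ~1e-8 in the test suite. Multiple testing
   uses Benjamini–Hochberg by default (Bonferroni/Holm via config) — the
   de-facto default of this ecosystem; the choice is a package convention,
   not a claim about any particular study.
5. **Selection cascade.** (a) |Δβ| ≥ 0.10 (inclusive) AND adjusted
   p < 0.001 (strict); Δβ is the beta-scale case-minus-control mean.
   (b) ROC filter: per probe, AUC = fraction of (case, control) pairs with
   case β > control β (ties ½; the Mann–Whitney U/(n₁n₂) identity), kept if
   max(AUC, 1−AUC) > 0.9 so hypomethylated probes are retained.
   (c) Correlation pruning: candidates ordered by ascending adjusted p are
   swept greedily; a probe is removed when its Pearson |r| with an
   already-kept probe exceeds 0.8 **in both** the case-only and the
   control-only samples. (d) Signature assembly with per-probe direction,
   group means and full provenance (thresholds, per-stage counts).
6. **MVP scoring.** Linear-kernel SVM on the signature-probe betas with
   inverse-frequency class weights (cases are typically outnumbered 4–5:1),
   followed by a Platt sigmoid fitted to the training decision values with
   the usual regularised targets. Scoring is a deterministic pure function
   of the features. Reporting bands (< 0.2 negative, ≥ 0.5 positive) are
   package conventions for readability, not decision thresholds.
   One-against-all multiclass: per disorder, a binary model against all
   remaining samples, stratified 75/25 train/test split per cohort from the
   seed.
7. **Unsupervised checks.** Classical (Torgerson) metric MDS on pairwise
   Euclidean distances of signature-probe betas — eigen-decomposition of
   the double-centred squared-distance matrix, axis signs fixed by making
   the largest-magnitude coordinate positive, null eigendirections zeroed.
   Hierarchical clustering is Ward on the same vectors (SciPy linkage, with
   its deterministic tie-breaks).
8. **DMR calling.** Per chromosome, significant CpGs (adjusted p < 0.01)
   are chained while consecutive gaps are ≤ 1 kb; a chain with ≥ 5
   significant CpGs spans first→last significant CpG. The regional Δβ
   averages **all** array CpGs in the span (conservative: dilution by
   non-significant CpGs counts against the region); Fisher's method
   combines the raw p-values of all span CpGs (X² = −2Σln pᵢ, χ² with 2k
   df). Regions need regional |Δβ| ≥ 0.10 and combined p < 0.01. Chaining
   on gaps between *significant* CpGs is the default; a strict mode
   additionally caps the whole span at 1 kb (config). Chains are disjoint
   by construction, so regions never overlap. This explicit rule set
   replaces kernel-smoothing DMR statistics by design: it is enumerable by
   a brute-force oracle and therefore testable.
9. **Expression comparison.** Each DMR contributes its highest-expressed
   annotated gene in the evaluated cell type (duplicates collapsed); the
   set is tested against all remaining background genes by a one-tailed
   Wilcoxon rank-sum (DMR genes higher), exact by enumeration when
   n₁+n₂ ≤ 12, tie-corrected normal approximation otherwise. The background
   is data-driven: all genes present in the supplied expression matrix
   minus the DMR genes.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes, on
the M scale:

M(p,s) = μ_p + δ_p·g(s) + γ_p·c(s) + ε, ε ~ N(0, noise_sd); β = 2^M/(1+2^M)

- **Baselines.** Background probes draw μ_p ~ N(1.9, 1.5²) M (bulk beta
  median ≈ 0.79, blood-like). Planted signature probes emulate CpG-island
  promoter probes gaining methylation — the canonical episignature/DMR
  substrate — with baseline beta ~ U(0.03, 0.10).
- **Dose effect.** δ_p is the M-offset whose beta-scale shift at the
  probe's baseline equals `effect_bi` (default 0.15) for bi-allelic
  carriers and `effect_bi·dose_factor` (default 0.5) for mono-allelic
  carriers — multiplicative dosing reproduces the bi > mono > control
  ordering without asserting a mechanism.
- **Confounding.** Per-sample leukocyte composition ~ Dirichlet around a
  realistic blood profile; 10% of background probes load on composition
  with N(0,1) weights, centred so the mean-composition sample is
  unshifted. The matching cell-type reference matrix is emitted so the
  deconvolution covariates can absorb this.
- **Clusters.** Part of the planted set is laid out as tight CpG clusters
  (default 10 clusters × 6 CpGs at 150 bp) on autosomes, annotated as TSS
  of synthetic genes — the DMR ground truth.
- **Detection failures** are injected per probe×sample at rate 1e-4
  (~0.8% of probes lost under the any-sample rule at 80 samples, matching
  the small detection-attributable loss of real array QC).
- Noise is Gaussian on M (logit-normal on beta), keeping β strictly inside
  (0,1). The generator is a pure function of (config, seed).

Not emulated: batch/chip effects beyond a label, realistic genome-wide
co-methylation (noise is independent across probes, so the correlation
filter sees redundancy only where planted), age/sex-associated probes, and
raw intensities. Passing recovery tests therefore demonstrate the
pipeline's statistical behaviour under its own model assumptions, not
robustness to technical artefacts.

## Design choices where the design was open

- **Correlation-pruning rule.** Redundancy must appear in *both* groups to
  remove a probe. With a dose effect, every true signature probe correlates
  with every other *within the pooled case group* (the bi/mono pattern is
  shared signal, not redundancy); pruning on case-only correlation
  discards independent signature probes essentially at random once the
  kept set grows — at 16 cases the sampling spread of r around ~0.4 pushes
  ~1% of pairs past 0.8, which cascades through a greedy sweep. True
  co-methylation (neighbouring CpGs, technical duplicates) is correlated in
  cases *and* controls and is exactly what the filter should remove. The
  stricter either-group rule is available as `corr_rule: either`.
- **Keep-one vs remove-all** for correlated blocks: greedy keep-best-p
  (most significant representative survives) — deterministic and
  reproducible given the p-ordering.
- **Correlations on the beta scale** (matching the scale of the reported
  signature and heatmaps); M-scale is a config toggle.
- **AUC two-sided** so rare hypomethylated signature probes survive.
- **Calibration.** Platt scaling on training decision values instead of
  cross-validated calibration: deterministic, cheap, and adequate for a
  score whose use is ordinal (band reporting), at the cost of optimistic
  probabilities on the training set.
- **Tie-breaks.** Control matching resolves equal age gaps younger-first
  then lexicographically by sample id; PCA outliers use median/MAD robust
  z-scores (zero MAD: only exact-median scores are inliers).

## Numerical notes

- Logit clip ε = 0.001; round-trip β↔M is identity to 1e-12 inside the
  clip range.
- Trigamma inversion by Newton iteration (50 iterations, 1e-10 relative
  tolerance); d₀ = ∞ when the moment equation has no positive solution,
  with a logged warning.
- Fisher combination clips p = 0 to 1e-300 with a warning.
- KS p-values use the asymptotic Kolmogorov distribution (exact
  small-sample p out of scope).
- Deconvolution's sum constraint uses augmentation weight 1000 followed by
  exact renormalisation; recovery error < 0.05 at beta noise sd 0.02 over
  200 probes.
- MDS eigenvalues below 1e-12 of the largest are treated as null
  directions and contribute zero coordinates.

## Problem sizes used in tests

The validation suite runs the discovery-scale study at 20,000 probes and
16 + 64 samples (seed 7), type-I calibration at 5,000 probes × 36 samples
× 20 seeds, false-DMR rates over 20 effect-free 4,000-probe genomes, and
oracle equivalences (BH, AUC, KS, OLS, DMR chaining, exact Wilcoxon) on
100–500 random small instances each. These sizes give stable Monte-Carlo
estimates while keeping the suite fast; the generator scales to full array
size (850k probes) linearly in memory and time.

## Known limitations

- The moderated model assumes Gaussian M-values and a shared variance
  prior across probes; heteroscedastic trends (limma-trend style) and
  probe weights are out of scope.
- The correlation filter's greedy sweep depends on the p-ordering; a
  different ordering can keep a different representative of a correlated
  block (the block membership itself is stable).
- Signature re-discovery on growing cohorts is a driver pattern (re-run
  the cascade), not a special incremental operation.
- MVP probabilities are calibrated on training data only and should be
  read as ordinal scores near the extremes.
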