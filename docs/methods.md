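# Methods

## Scope

`nichecoloc` implements the quantitative core of a spatial validation study
of immune-stromal crosstalk in fibrotic aortic disease: given spot-level
prediction scores for an SPP1-myeloid program and a POSTN-fibroblast
program, it asks whether the two programs co-occur in space more often in
disease tissue than in control tissue, and surrounds that question with the
standard single-cell statistics (QC, differential expression, gene-set
overlap, module scores) and the matching multiplex-immunofluorescence (mIF)
quantification. Everything runs on synthetic data whose statistical
structure mirrors the real study design, so the full pipeline is exercised
and validated without any external download.

## The colocalization statistic

For each tissue sample separately, with per-spot scores A and B in [0, 1]:

1. standardize each score within the sample: z_X(i) = (X_i − mean(X)) / sd(X);
2. find each spot's k nearest other spots by Euclidean distance on the
   tissue coordinates (self excluded; distance ties broken by ascending spot
   index, so results are deterministic);
3. let z̄_X,k(i) be the mean standardized score over spot i's k neighbors;
4. coloc_i = z_A(i) · z̄_B,k(i) + z_B(i) · z̄_A,k(i).

This is a symmetric, bivariate local-Moran-style cross product: positive
when a spot and its neighborhood are concordantly enriched (or depleted) in
both programs, negative when they are discordant. A spot is
*colocalization-positive* when coloc_i > 0 (strictly). Per neighborhood
size k, spots are pooled across samples within condition into a 2×2
condition × positivity table; enrichment in disease is tested with a
one-sided Fisher's exact test (hypergeometric tail P[X ≥ a]) and
summarized by the sample odds ratio with a Woolf log-OR 95% interval
(Haldane-Anscombe +0.5 on all cells iff any cell is zero; the p-value is
always computed on the uncorrected table; a conditional-MLE odds ratio and
interval are available as an alternative). The analysis is repeated for
k ∈ {3, 4, 5, 6, 8, 10, 12, 15} to check robustness across spatial scales.

Design notes on genuinely open points:

* **Functional form.** The exact printed formula for the original statistic
  is not recoverable from the source text; the symmetric centered
  cross-product was adopted because it uses exactly the named quantities
  (A, B, and their kNN means), admits negative values so the "> 0"
  threshold is informative, and is symmetric in the two programs as the
  biology implies. An uncentered variant (`centering="none"`,
  coloc = A·B̄_k + B·Ā_k) is provided for comparison, but for nonnegative
  scores it is almost always positive and the threshold becomes vacuous.
* **Standardization scope.** z-scores are computed per sample, never pooled,
  so between-sample depth or composition differences cannot masquerade as
  colocalization.
* **Joint depletion.** The default counts concordantly *depleted* spots
  (both programs below their sample means) as positive, since the statistic
  cannot distinguish the authors' handling; `require_joint_enrichment=True`
  additionally demands both own z-scores above the sample mean.
* **CI phrasing.** A one-sided exact test does not define a two-sided
  confidence interval, so the interval reported next to the one-sided p is
  the Woolf interval (conditional-MLE as an option).

## Hub-gene panel and spot-level tests

The 18-gene hub panel combines the two population markers (SPP1, POSTN),
eleven ligand-receptor genes (ITGAV, ITGB1, ITGA8, ITGA5, MDK, SDC4, SDC2,
NCL, LRP1, ITGA6, ITGA4) and five shared stress-pathway genes (GADD45B,
GADD45A, PMEPA1, PTX3, IL6). Per gene, disease vs control spot expression
(log1p scale) is compared with a one-sided Wilcoxon rank-sum test
(disease greater), and Benjamini-Hochberg adjusted p-values are reported
across the panel.

## Single-cell statistics

* **QC.** Cells are removed when UMI < 1,000 or > 50,000, detected genes
  < 300 or > 5,000, mitochondrial fraction > 10%, or flagged as doublets.
  The removal rules are strict inequalities, so cells exactly on a bound
  are retained. Filtering is idempotent and reports per-rule counts.
* **Normalization.** Counts per 10,000 followed by log1p (the ecosystem
  default; the source text does not specify a recipe).
* **Differential expression.** One-vs-rest per group; genes expressed in
  ≥ 10% of the in-group cells are tested with a two-sided Wilcoxon rank-sum
  test (tie-corrected normal approximation with continuity correction;
  exact when both groups have ≤ 25 cells), BH-adjusted within each group
  contrast across the tested genes. Selection requires |log2FC| > 0.25 and
  adjusted p < 0.05; "up" keeps log2FC > 0. The fold-change convention is
  log2(mean(expm1(lognorm_in)) + 1) − log2(mean(expm1(lognorm_out)) + 1),
  matching the convention the thresholds were calibrated against.
* **Jaccard.** |A∩B| / |A∪B| between gene sets; undefined (raises) for
  empty sets.
* **Module score.** Genes are ordered by mean expression (ties broken by a
  tiny seeded jitter) and cut into `n_bins` equal-frequency bins
  (default 24); for each panel gene, `n_ctrl` control genes (default 100)
  are sampled from its bin without replacement (with replacement plus a
  warning when the bin is smaller); the per-cell score is the mean
  expression of the panel minus the mean expression of the pooled unique
  controls. The score is exactly invariant to adding a constant to the
  expression matrix, and is identically zero when the control pool equals
  the panel.

## mIF ROI quantification

Per region of interest (default 15 per group, 150 μm squares), the
double-positive proportion of a marker pair (CD68⁺SPP1⁺, α-SMA⁺POSTN⁺) is
the double-positive cell count over all detected cells in the ROI. Group
comparison pools counts within group into a 2×2 table tested by the same
`fisher_or` used in the spatial module. Mean fluorescence intensity of SPP1
(resp. POSTN) over the double-positive cells is divided by the ROI's mean
DAPI intensity over *all* detected cells ("normalized to DAPI in the same
ROI" is read as an ROI-level denominator; a double-positive-only
denominator is exposed via `dapi_over="double_positive"`). Per-ROI ratios
are compared between groups with a two-sided Mann-Whitney U test: full
enumeration with mid-rank tie handling when feasible, tie-corrected normal
approximation otherwise; all-tied input gives p = 1. Phenotype gating is
taken as boolean inputs (classifier training is out of scope); a simple
intensity-threshold gater exists for fixtures.

## Synthetic data generators

The generators define the study conditions under which the pipeline is
validated.

**Spots.** Each sample holds n spots (default 1,000) on a regular grid in
the unit square (spacing ≈ 0.032; `uniform_random` available). Latent
program fields are smooth random surfaces built as weighted sums of 150
Gaussian bumps at random centers (a cheap, seeded stand-in for a Gaussian
process with controllable length scale). The second focal field is built
from the first by empirical Gram-Schmidt mixing, f_B = ρ·f_A +
√(1−ρ²)·f_⊥, so the within-sample latent correlation equals rho_control /
rho_disease *exactly*, before noise. Scores are logistic squashes of field
plus Gaussian noise, keeping them in (0, 1) without boundary mass. Defaults:
`field_length_scale=0.03` (correlation length about one spot spacing —
niche-scale structure at the resolution limit of spot-based assays) and
`score_noise_sd=1.2` (label-transfer scores are noisy at spot level; the
latent field explains ~40% of pre-squash variance). Within the ranges that
keep the planted co-enrichment recoverable across all k, these were chosen
at the short-smoothness / high-noise end to keep spot-level dependence — and
hence the miscalibration documented under Limitations — as small as the
design allows. Hub-gene counts are negative binomial (gamma-Poisson,
dispersion 1.5) with log2 mean = log2(base_expr) + hub_effect·(A + B − 1)
plus an optional per-gene disease log2 fold change; `base_expr=1` reflects
the sparsity of single-gene spot counts. Per-spot scores are *not*
constrained to sum to 1 across programs (label-transfer scores are
per-type posteriors); `normalize_scores=True` enables the constrained
behavior.

**Cells.** Negative-binomial profiles over a lognormal gene-mean vector
scaled to ~5,000 UMIs, with 13 `MT-` genes carrying ~3% of counts, 20
marker genes per cluster elevated by `marker_log2fc`, and 50
condition-responsive genes (the first 18 named after the hub panel)
elevated in disease by `condition_effect`. Exactly
⌈frac_low_quality·n_cells⌉ cells are post-processed to violate at least one
QC rule (thinned to 600 UMIs; boosted past 50,000 UMIs; truncated to ≤ 150
detected genes; mitochondrial share pushed above 16%; or doublet-flagged —
doublets are counted inside the low-quality quota, so `frac_doublet` must
not exceed `frac_low_quality`). All metadata are recomputed from the final
matrix, so UMI equals the column sum and detected genes the nonzero count
by construction.

**ROIs.** Per group, 15 square ROIs with ~Poisson(120) cells at uniform
positions. Double-positive labels are Bernoulli with the group's
probability (defaults 0.40 disease vs 0.05 control); marker and DAPI
intensities are lognormal, with a disease shift of 0.7 on the log
intensity of SPP1 and POSTN in positive cells.

What the generators do *not* emulate: histology images and barcode
chemistry, segmentation errors, doublet expression mechanisms (flags only),
batch effects, spatially varying cell density, or any real gene-gene
covariance beyond the planted structure. Tests passing on this synthetic
structure validate the statistical machinery, not biological conclusions on
real tissue.

## Reproducibility and numerics

Every generator is a pure function of its parameter object; a single
`numpy.random.default_rng(seed)` stream makes identical parameters produce
byte-identical output. The pipeline fans one global seed out through
`numpy.random.SeedSequence(entropy=seed, spawn_key=(stage_index,))`, so
enabling or disabling a stage never perturbs another stage's stream. The
run manifest records the config snapshot and a sha256 per output file; its
fingerprint hashes exactly that deterministic part (wall-clock timings are
stored separately). Zero-variance scores yield coloc ≡ 0 with a warning;
empty QC input returns empty output with a warning; exact rank tests fall
back to the tie-corrected normal approximation when the enumeration would
exceed ~2·10⁵ subsets.

Validation problem sizes: the k-sweep calibration and power studies use the
study's scale (2 samples per condition × 1,000 spots); oracle-equivalence
checks enumerate all 2×2 tables with total ≤ 30 and all rank-test group
splits with n₁+n₂ ≤ 12; the end-to-end demo uses 400-spot samples and 300
cells.

## Known limitations

* **Pooled Fisher inference on spots is anticonservative.** The 2×2 tables
  pool spots across samples within condition, treating spots as independent
  Bernoulli draws. They are not: neighboring spots share the latent tissue
  fields *and* the statistic itself couples nearby spots through shared
  neighborhood means. Empirically, the per-sample positivity fraction has
  ~1.5-1.8× the binomial variance even when scores are i.i.d. noise, so the
  nominal 5% one-sided test rejects ~8-13% of null datasets in this
  package's simulations, at every k and for every smoothness/noise setting
  tried. This mirrors a general caveat of spot-pooled count tests in
  spatial transcriptomics with few samples; the per-sample diagnostic
  tables emitted by `k_sensitivity` exist precisely so users can judge
  between-sample consistency rather than rely on the pooled p-value alone.
* The coloc functional form is a documented reconstruction, not a verbatim
  equation (see above).
* The conditional-MLE odds-ratio interval can be slow for large tables and
  is therefore off by default inside the k-sweep.
* DEG p-values for large groups use the asymptotic rank-sum test; exact
  enumeration is reserved for small groups.
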