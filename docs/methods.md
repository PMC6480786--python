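# Methods

This note documents the models and procedures `panclock` implements, the
defaults and why they were chosen, what the synthetic generator does and does
not emulate, and the numerical decisions a maintainer should know about.

## Copy-number recurrence

Inputs are gene-level discrete GISTIC calls: −2 deep deletion (below the
chromosome-arm minimum copy ratio), −1 shallow deletion, 0 neutral, +1 shallow
amplification, +2 deep amplification. Real-valued copy-ratio tables are
rejected rather than re-thresholded: thresholding is GISTIC's job and
re-doing it silently would change the analysis.

Per gene and cancer type we tally the fraction of samples altered, for "any"
(|call| ≥ 1) and "deep" (|call| = 2) events separately. A gene is recurrently
deleted when its deletion fraction is **≥ 0.20** in **≥ 7** cancer types;
amplification is symmetric and independent. Both comparisons are inclusive
("at least"), and both thresholds are config keys. The default counts shallow
plus deep events; `deletion_mode: deep_only` restricts to |call| = 2. With 21
cancer types the cancer-count threshold equals one-third of the cohorts; the
stated rule is ambiguous between "more than seven" and "at least one third",
and we implement ≥ 7 (the inclusive reading), configurable via
`min_cancers`.

## Moderated-t differential expression

Expression is consumed on the log₂ scale; no pseudocount or transform is
applied internally (`assume_log2: true` documents the contract — which
upstream normalisation produced the values is the caller's responsibility).
For a two-group contrast the statistic is the empirical-Bayes moderated t:

- per gene, log2FC = mean(group1) − mean(group2), pooled residual variance
  s²_g on d = n₁ + n₂ − 2 df;
- prior (d₀, s₀²) by method of moments on log s²_g: with
  e_g = log s²_g − ψ(d/2) + log(d/2), solve ψ′(d₀/2) = Var(e) − ψ′(d/2) via a
  Newton trigamma inverse and set s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2));
- posterior variance s̃²_g = (d₀s₀² + d s²_g)/(d₀ + d), t on d₀ + d df,
  Benjamini–Hochberg across genes.

If the observed variances are *under*-dispersed relative to chi-square
sampling noise the moment estimate of d₀ is non-finite; we fall back to
d₀ = ∞ (complete shrinkage to the common variance) and log the fallback.
Zero-variance genes are floored at 10⁻⁸ × the smallest positive variance in
the moment fit and never divide by zero as long as d₀ > 0. `prior_df=0`
recovers the classical pooled t exactly (used as a test oracle). The
implementation is cross-checked against Bioconductor limma (t, p, d₀, s₀²) in
the test suite.

Two fold-change filters coexist deliberately, mirroring how the two analyses
are specified:

- **cross-cancer concordance** (tumour vs normal): linear 1.5-fold, i.e.
  |log2FC| ≥ log₂ 1.5 ≈ 0.585, significance p < 0.05;
- **quartile DEG calling** (Q4 vs Q1 patients): literal log₂ threshold
  |log2FC| > 1.5, significance p < 0.01.

Both are config keys. Significance filters use BH-adjusted values by default
(`p_adjust_for_filters: bh`) with a `raw` option, since "P < 0.05" is
ambiguous about adjustment in the source analyses.

## Gene-set derivation and scoring

Clock^Loss = {recurrently deleted ∧ significantly down in ≥ `min_cancers`
cancers}; Clock^Gain = {amplified ∧ up}. The derivation universe is the
packaged 32-gene clock list intersected with the input tables. A gene
satisfying both criteria is kept in both sets and logged.

Scores are unweighted means of log₂ expression over the set genes present
(missing members dropped with one warning). Stratification:

- **quartiles**: rank-based near-equal split, Q1 lowest; boundary ties broken
  by stable sample order after ranking (deterministic; any rule is defensible
  and this one is reproducible);
- **median**: high iff score > median (a score equal to the median is low);
- **joint**: cross of the two median labels, reference group low/low.

Quartiles are computed per cohort (each survival panel is one cohort), not
pooled across cancer types.

## Survival models

Kaplan–Meier estimation and the k-group log-rank test come from lifelines;
Cox models use the partial likelihood with Efron tie handling (the standard
default). Multivariate models add TNM stage as a single ordinal 1–4
covariate; samples with missing stage are excluded from stage-adjusted
analyses only. Degenerate designs (constant covariates, fewer events than
parameters) raise before fitting.

The fixed-horizon ROC (default horizon 1825 days = 5 years, configurable)
classifies death on/before the horizon against survival beyond it; samples
censored before the horizon are excluded with a logged count. This is the
simplest defensible treatment of censoring; time-dependent ROC estimators
(e.g. inverse-censoring-weighted) are a documented non-default alternative
left unimplemented. The AUC is exactly the Mann–Whitney concordance with ties
counted ½, so it is invariant under monotone score transforms. The combined
model fits a bivariate Cox on (score, stage) and feeds its linear predictor
to the same ROC.

## Crosstalk statistics

- **Spearman**: rho on average ranks; exact permutation p (full n!
  enumeration, chunked) for n ≤ 10, t-approximation above.
- **Mann–Whitney**: exact null for min(n) ≤ 8 without ties, tie-corrected
  normal approximation otherwise; U counts (a > b) pairs.
- **PCoA**: classical metric scaling of Euclidean sample distances
  (scikit-bio), equivalent to metric MDS — non-metric MDS is out of scope.
- **PERMANOVA**: pseudo-F = (SS_between/(g−1))/(SS_within/(n−g)) on squared
  distances, free label permutations (no strata),
  p = (1 + #{F_perm ≥ F_obs})/(1 + N). Default N = 9999, seed mandatory and
  derived from the run seed. Cross-checked against
  `skbio.stats.distance.permanova` in the tests.
- **Over-representation**: upper-tail hypergeometric per GMT term with BH
  across terms. This is a local replacement for web-service enrichment
  tools; users supply their own GMT collections, none are bundled.

## Synthetic cohort generator

The generator is the pipeline's oracle: every downstream quantity has a
planted truth.

- **CNA**: per gene×cancer planted deletion/amplification fractions;
  mutually exclusive per sample; altered samples split 70/30 between shallow
  and deep calls (only the any/deep distinction matters downstream; the split
  is configurable). `exact_fraction_mode` assigns ⌈round⌉(f·n) samples
  exactly; sampling mode draws per-sample.
- **Expression**: tumour = baseline (8.0 log₂ units) + 0.5·call (dosage) +
  planted log2FC + N(0, 1); normal = baseline + noise. The gene-wise noise sd
  of 1 log₂ unit is typical of bulk tumour expression heterogeneity.
- **Clock–hypoxia coupling**: one latent factor h ~ N(0,1) per tumour sample
  is added to the loss-set genes (weight sign(ρ)·λ) and hypoxia genes
  (weight λ). λ solves λ²/√((λ²+v_c)(λ²+v_h)) = 2·sin(π|ρ|/6) with v_c, v_h
  the empirical score variances before coupling — the Pearson target implied
  by the Spearman target under approximate normality. Realised rank
  correlations land within ~0.05 of the target at large n.
- **Survival**: exponential proportional hazards
  h(t) = h₀·exp(β_clock·score + β_stage·stage), analytically checkable and
  sufficient for Cox recovery. Censoring is an independent exponential whose
  global rate is set so the expected censored fraction approximates
  `censor_rate` exactly at the mean linear predictor (censor_rate = 0 gives
  all events). Stages are drawn with probabilities (0.25, 0.35, 0.25, 0.15).

The **reference design** (`default_design`): 21 cancer types, 60 tumour / 30
normal samples each; the 11 published loss members planted at deletion
fraction 0.30 with log2FC −1.0 in 9 cancer types, the 2 gain members at
amplification 0.30 with +1.0; all other clock/filler genes at background
0.10 / −0.1 (below both thresholds everywhere); hypoxia genes mildly
up-regulated (+0.3) with coupling target ρ = −0.5 to the loss score;
β_clock = −0.7 (protective), β_stage = 0.7 (hazard roughly doubles per
stage), baseline hazard 8×10⁻⁵/day so 5-year survival sits near 50% at
typical stage, 30% censoring. These sizes keep the full pipeline to seconds
on one CPU while every planted effect is recovered with wide margins.

What the generator does **not** emulate: real gene–gene covariance beyond the
single latent factor, batch effects, chromosome-arm geometry, non-proportional
hazards, informative censoring, or cohort-size imbalance. Passing tests
therefore demonstrate correctness of the computations and recoverability of
planted effects under clean conditions — not robustness to the messiness of
real tumour data.

## Packaged gene lists

The 32-gene clock list is the KEGG circadian-rhythm panel (it contains all 13
derived-set members plus the other core oscillator and degradation-complex
genes). The 52-gene hypoxia signature is a Buffa-style metagene including the
canonical HIF-1A targets CA9, VEGFA and LDHA; its file header marks the
membership as reconstructed. No computation in the package depends on the
identity of signature members beyond their count and the three HIF targets.

## Determinism and degenerate inputs

All randomness flows from one config seed; stage seeds are
`seed XOR crc32(stage_name)` (mod 2³¹). Identical design + seed reproduce
bit-identical bundles and byte-identical output tables. Constant score
vectors refuse to stratify; constant covariates refuse to enter Cox models;
a cohort with zero samples, an empty gene universe, or out-of-range
copy-number codes fail loudly with the offending file/gene/sample named.
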