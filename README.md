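# panclock

Pan-cancer analysis of circadian clock gene dysregulation: from discrete
gene-level copy-number calls and tumour/normal expression to prognostic gene
sets, patient scores, survival models and hypoxia crosstalk — plus a synthetic
multi-cancer cohort generator so the entire pipeline can be exercised and
verified without any external download.

## The scientific problem

Somatic copy-number alteration (SCNA) of core circadian clock genes is
widespread across tumour types. When a recurrent deletion is accompanied by
transcript downregulation in tumours, the gene is a candidate
*loss-of-function* player (tumour suppressive); a recurrent amplification with
upregulation suggests *gain-of-function* (oncogenic). `panclock` implements
this derivation and its downstream clinical evaluation for the 32 core clock
genes (packaged), over any number of cancer cohorts:

1. **Recurrence.** From GISTIC-style discrete calls (−2 deep deletion … +2
   deep amplification), a gene is *recurrently deleted* (or amplified) when at
   least 20% of samples within a cancer type carry the alteration in at least
   7 cancer types (both thresholds configurable, comparisons inclusive).
2. **Differential expression.** Tumour-vs-normal contrasts per cancer use an
   empirical-Bayes moderated t: gene-wise variances s²_g (df d) are shrunk
   towards a moment-estimated prior (d₀, s₀²),
   s̃²_g = (d₀s₀² + d s²_g)/(d₀ + d), with t = Δ/(s̃_g·√(1/n₁+1/n₂)) on
   d₀ + d degrees of freedom and Benjamini–Hochberg FDR control.
3. **Gene sets.** Clock^Loss = recurrently deleted ∧ downregulated
   (|FC| > 1.5, p < 0.05) in ≥ 7 cancers; Clock^Gain = amplified ∧ upregulated.
4. **Scores.** Per patient, the Clock^Loss / Clock^Gain / hypoxia score is the
   unweighted mean log₂ expression over the set (the 52-gene hypoxia signature
   is packaged). Patients are stratified into score quartiles, median halves,
   and joint median clock×hypoxia groups.
5. **Survival.** Kaplan–Meier curves with k-group log-rank tests; Cox
   proportional-hazards quartile contrasts (Q4 vs Q1, Efron ties), with and
   without TNM stage; fixed-horizon (5-year) ROC where AUC is the
   Mann–Whitney concordance of the score for deaths-by-horizon versus
   survivors-past-horizon, and a combined score+stage Cox linear predictor.
6. **Crosstalk.** Spearman association between clock and hypoxia scores,
   Mann–Whitney tumour-vs-normal comparisons, PCoA ordination with a seeded
   PERMANOVA on Euclidean distances, ranked HIF-target (CA9/VEGFA/LDHA)
   correlation exports, and hypergeometric over-representation against GMT
   collections.

The synthetic generator plants every one of these effects (alteration
fractions, dosage coupling, fold changes, score-dependent exponential
proportional hazards, a calibrated clock–hypoxia latent factor) so each stage
can be checked against a known ground truth.

## Worked example

Run the reference synthetic study (21 cancer types, 60 tumour / 30 normal
samples each, the published 11 loss / 2 gain members planted) end to end:

```python
import panclock as pc

cfg = pc.AnalysisConfig(seed=1, n_permutations=999)
pc.run_pipeline(cfg, "demo_run", design=pc.default_design(seed=1))
print(pc.report_summary("demo_run"))
```

The derivation section of the report reads:

```
Clock^Loss members (11): CLOCK, CRY2, FBXL3, FBXW11, NR1D2, PER1, PER2, PER3, PRKAA2, RORA, RORB
Clock^Gain members (2): ARNTL2, NR1D1
```

i.e. the pipeline recovers exactly the planted loss-of-function and
gain-of-function memberships. For the first cohort the summary tables show
(seed 1): a protective Q4-vs-Q1 hazard ratio of 0.34 for the Clock^Loss score
(patients with the highest score fare best — the planted log-hazard per score
unit is −0.7), a 5-year combined score+TNM AUC of 0.76 versus 0.35/0.74 for
score and stage alone, a Clock^Loss-vs-hypoxia Spearman rho of −0.32
(p = 0.013; the design targets a cohort-level rank correlation of −0.5, and
the mean across the 21 cohorts is −0.48), and a tumour-vs-normal PERMANOVA on
the Clock^Loss genes of F = 24.8 with the permutation floor p = 0.001 at 999
permutations.

The same analyses run from the command line:

```bash
panclock run-all --seed 1 --out demo_run
panclock report --out demo_run
```

and each stage (`simulate`, `ingest`, `recurrence`, `de`, `derive`, `score`,
`survival`, `crosstalk`) is available as its own subcommand over the same
output directory. Real cohorts are supplied as per-cancer TSV tables
(`<ct>.cna.tsv`, `<ct>.tumour_expr.tsv`, `<ct>.normal_expr.tsv`,
`<ct>.clinical.tsv`); copy-number tables must contain discrete GISTIC codes
and expression is consumed already log₂-transformed.

## Layout

```
src/panclock/        io, config, simulate, recurrence, de, scoring,
                     survival, crosstalk, pipeline, cli
src/panclock/resources/  packaged clock gene list and hypoxia signature
docs/methods.md      model, assumptions, numerical choices, limitations
tests/               unit, property and end-to-end acceptance tests
```
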