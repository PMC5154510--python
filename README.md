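# tnbcsens

Integrated genomic analysis of chemosensitivity in triple negative
breast cancer (TNBC), for computational cancer-genomics researchers who
have somatic mutation tables, expression, methylation, and clinical
outcomes and want the pipeline from raw variant lists to response and
survival associations.

About one third of TNBC patients achieve pathologic complete response
(pCR) to standard anthracycline/taxane chemotherapy, and tumor genomics
can help say which ones. `tnbcsens` implements the analysis layer:

* **Somatic filtering** — germline removal by population-database
  flags, tumor/pooled-normal allele-frequency ratio < 5, and the
  heterozygous 0.45–0.55 MAF band, with COSMIC (n ≥ 5)/ClinVar
  whitelisting; high-functional-impact selection (≥ 3 of 5 deleterious
  predictor votes, plus all indels).
* **Burden and clonality** — mutation rate per Mb of ≥ 10×-covered
  exome; the MATH heterogeneity score
  100 · 1.4826 · MAD(VAF)/median(VAF) on VAF ≥ 0.075; clonal
  decomposition of (alt, depth) pairs with a binomial mixture fitted by
  EM and selected by BIC; the clonal mutation burden (CMB) category
  from cohort-median-dichotomized MR and MATH.
* **Mutational signatures** — 96-trinucleotide-context tallies
  deconvolved by non-negative least squares, min‖x − Lc‖₂ s.t. c ≥ 0,
  with normalized coefficients as signature proportions and the largest
  as the dominant signature.
* **BRCA deficiency** — wild-type transcript abundance
  Expr_WT = Expr_total · (1 − MAF); per-gene deficiency thresholds as
  the maximum carrier wild-type expression; calls by deleterious
  mutation or sub-threshold wild-type expression; BRCA1 promoter
  methylation (mean beta of four probes, > 0.2 methylated) as
  corroborating evidence.
* **Metagene signatures** — differential expression (Welch t on
  log2(x+1), p < 0.002, low-expression genes excluded), up-mean minus
  down-mean scoring, median dichotomization, sensitivity/specificity
  evaluation, and a six-gene immune metagene.
* **Pathway association** — binary mutation matrices vs response by
  two-sided Fisher exact test with Bonferroni adjustment, bootstrap
  robustness, and label-permutation significance.
* **Outcome statistics** — Fisher, Kaplan–Meier, log-rank, Wilcoxon,
  Spearman with pinned tie conventions.
* **Synthetic cohorts** — a seeded generator with ground-truth clone
  structure, signature mixtures, BRCA status, planted differential
  expression, and outcome models, used by the whole test suite.

## Worked example

Simulate a 29-sample cohort and run every stage:

```sh
tnbc-pipeline simulate --seed 7 --out cohort/
tnbc-pipeline run --config config.yaml --seed 7 --out run/
```

with `config.yaml`:

```yaml
inputs:
  mutations: cohort/mutations.tsv
  expression: cohort/expression.tsv
  methylation: cohort/methylation.tsv
  clinical: cohort/clinical.tsv
  pathways: cohort/pathways.gmt
  signature_reference: cohort/signature_reference.tsv
```

or equivalently from Python:

```python
from tnbcsens.simulate import SimulationConfig, simulate_cohort, write_cohort
from tnbcsens.pipeline import run_pipeline

paths = write_cohort(simulate_cohort(SimulationConfig(), seed=7), "cohort")
summary = run_pipeline(
    {"seed": 7, "inputs": {k: str(v) for k, v in paths.items() if k != "truth"}},
    outdir="run",
)
```

`run/summary.json` then reports (excerpt; this is the output the code
prints for seed 7):

```json
"brca": {"n_deficient": 14, "n_samples": 29,
         "thresholds": {"BRCA1": 307.48, "BRCA2": 256.52}},
"metagene": {"n_up": 25, "n_down": 26,
             "sensitivity_vs_brca": 1.0, "specificity_vs_brca": 1.0},
"survival": {"brca_deficient": {"chi2": 5.528, "p": 0.0187, "n": 29}}
```

Read: 14/29 samples (48%) are called BRCA-deficient; the metagene
derived from those calls re-identifies them perfectly in-cohort (the
generator plants 50 differentially expressed genes); and the planted
survival benefit of deficiency (hazard ratio 0.3) is detected by the
log-rank test at p = 0.019. Per-stage TSVs (`burden.tsv`,
`signatures.tsv`, `brca_calls.tsv`, `pathway_associations.tsv`, ...)
sit alongside; file formats are documented in `docs/formats.md` and the
model choices in `docs/methods.md`.

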