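# Methods

`tnbcsens` implements an integrated analysis of chemosensitivity in
triple negative breast cancer (TNBC): from somatic mutation tables,
gene expression, and promoter methylation to per-tumor burden and
clonality metrics, mutational-signature proportions, BRCA-deficiency
calls, metagene scores, pathway-level response association, and
survival comparisons. This note records the models, the defaults that
matter, and the choices made where the design was genuinely open.

## Somatic filtering

Variant calls arriving in the MAF-like table are assumed to be
caller-filtered but not germline-cleaned. Three rules remove putative
germline variants:

* membership in a population database (dbSNP-nonsomatic, ESP, 1000
  Genomes, ExAC), consumed as resolved boolean flags from annotation;
* tumor/pooled-normal allele-frequency ratio below 5. The pooled-normal
  MAF may be 0 (or absent), so the denominator is floored at 0.01; the
  floor makes the rule total while preserving its intent (tumor signal
  must greatly exceed normal noise);
* allele frequency inside the heterozygous germline band, 0.45–0.55
  inclusive at both ends.

Recurrent COSMIC variants (n ≥ 5) and ClinVar-annotated variants are
whitelisted and kept regardless. The decision is a pure function of the
record's flags, so rule order is irrelevant; this is property-tested.

High-functional-impact selection keeps SNVs called deleterious by at
least 3 of the 5 predictors (PhyloP, SIFT, PolyPhen2, MutationTaster,
LRT) plus every indel. Missing predictor calls count as non-deleterious
votes — the conservative reading when a predictor could not score a
variant. Silent variants are never high impact.

## Burden and clonality

**Mutation rate (MR)** is mutations per megabase of target exome
covered at ≥ 10×. All detected mutations (silent and non-silent) enter
the default MR.

**MATH** (mutant-allele tumor heterogeneity) is
100 × 1.4826 × MAD / median of per-mutation allele fractions, computed
on mutations with MAF ≥ 0.075. The 1.4826 consistency constant and the
×100 scaling follow the MATH literature; because every downstream use
median-dichotomizes MATH within a cohort, these constants cannot change
any category. Fewer than three qualifying mutations leaves the score
undefined and the sample excluded from MATH-based analyses.

**Clonal decomposition** clusters (alt_count, depth) pairs with a
maximum-likelihood binomial mixture fitted by EM. Mutations below 10×
depth or with MAF ≥ 0.6 are excluded (high-MAF variants may sit on
copy-number losses). For k = 1..6 components the EM runs 10 seeded
restarts with quantile (k-means-style) initialization on raw allele
fractions plus N(0, 0.02) jitter; convergence at relative log-likelihood
improvement < 1e-8 or 500 iterations; component probabilities clipped to
[1e-4, 1−1e-4]. Model selection minimizes BIC = −2 logL + (2k−1) ln n.
Assignments are maximum-posterior; empty components are removed and k
reported accordingly. This is a deliberately simple, testable engine for
clone-number and clone-mean recovery — it is not copy-number-aware and
does not estimate purity or cellular prevalence; accuracy is
demonstrated by parameter recovery on simulations with known truth
(two clones at allele fractions 0.45/0.12, depth 150, 60+60 mutations
are recovered in ≥ 95% of seeded runs).

**Average mutations per clone** is the clone-proportion-weighted mean
clone size, Σ_k n_k (n_k / N); it is bounded by N with equality only at
k = 1.

**CMB** (clonal mutation burden) median-dichotomizes MR and MATH within
the cohort (≤ median ⇒ "low", a total and deterministic tie rule):
high = high MR and low MATH; low = low MR and high MATH; all else
intermediate.

## Mutational signatures

Substitutions are tallied over the 96 pyrimidine-strand trinucleotide
contexts (purine-reference labels are reverse-complemented at load).
The count vector, normalized to a probability vector, is decomposed
over a 96 × K reference loading matrix by non-negative least squares
(Lawson–Hanson active set); normalizing the counts first makes the
coefficients interpretable as mixture weights, and normalized
coefficients are the reported proportions. The KKT conditions of the
NNLS solution are verified to 1e-10 in tests. The signature with the
greatest coefficient is dominant; exact ties break by reference column
order and are flagged. Samples with fewer than 20 contexted mutations
carry a low-confidence flag.

The package ships `synthetic_signature_reference()`, a deterministic,
synthetic four-signature reference whose columns emulate the
qualitative shapes of processes active in breast cancer (age-like CpG
C>T, APOBEC-like TpC C>T/C>G, a flat BRCA-like profile, an MMR-like
profile). It is a constructed stand-in, not a published catalog; any
96-row reference TSV can be supplied instead.

## BRCA deficiency

For each of BRCA1/BRCA2 per sample the pipeline assembles: deleterious
mutation status (non-silent and either ClinVar-annotated or of a
truncating class — nonsense, frameshift, splice), the representative
mutation (highest RNA allele fraction; DNA fraction as fallback and
tie-break, then position), total expression, and wild-type expression
Expr_WT = Expr_total × (1 − MAF). The per-gene deficiency threshold is
the maximum wild-type expression among that gene's mutation carriers in
the cohort; thresholds are strictly per-gene. A sample is
gene-deficient if it carries a deleterious mutation (rule 1) or, as a
non-carrier, falls strictly below the threshold (rule 2); the combined
call is the OR over genes. Rule 1 dominates, so every carrier is called
deficient by construction.

BRCA1 promoter methylation is the mean beta of four promoter probes
(cg19531713, cg19088651, cg08993267, cg04658354; ≥ 2 required), with
score > 0.2 read as methylated. Methylation and deep loss are reported
as corroborating evidence rather than forcing a call: both are expected
to manifest as low wild-type expression and hence be captured by
rule 2. If a cohort has no carriers of a gene, the expression rule for
that gene is unavailable and calls fall back to mutation evidence with
a logged warning.

## Metagene signatures

Differential expression between labeled groups uses a per-gene
two-sided Welch t-test on log2(x+1) with an unadjusted p < 0.002
cutoff, after excluding genes whose median expression is below 25% of
the overall median. The Welch test is a dependency-free choice; an
empirical-Bayes moderated test (limma-style) would shrink per-gene
variances and behave slightly better at very small group sizes, but at
the planted effect sizes used for validation the difference is
immaterial, and no moderated mode is currently implemented. The
expression scale for scoring is log2(x+1) of normalized counts.

The metagene score is the mean log-expression over up genes minus the
mean over down genes; calls dichotomize strictly above the cohort
median (ties ⇒ "low"). Classifier performance against labels is plain
sensitivity/specificity counting. The immune metagene is the mean
log-expression of GZMB, PRF1, CXCL13, IRF1, IKZF1, and HLA-E (≥ 4
required).

## Pathway association

High-impact mutations collapse to a binary sample × pathway matrix
(1 = any high-impact mutation in any pathway gene). Association with
pathologic complete response uses the two-sided Fisher exact test
(sum of hypergeometric point probabilities ≤ the observed table's), with
Bonferroni adjustment over tested pathways. Robustness is the fraction
of 100 unstratified patient bootstrap resamples with nominal p < 0.05
(single-class resamples count as p = 1). Significance is assessed by
label permutation with the add-one estimator
p = (1 + #{perm p ≤ observed p}) / (n_perm + 1), plus a family-wise
variant ranking the observed p against each permutation's minimum p
across pathways.

Because the Fisher statistic is discrete, the permutation p-value is
conservative in small cohorts: at ~30–40 samples many permutations tie
the observed table exactly and null permutation p-values sit visibly
above uniform. At ~200 samples the point masses are small and the null
distribution is indistinguishable from uniform; the calibration tests
run in that regime. Interpret small-cohort permutation p-values as
upper bounds.

## Statistical kernels

Fisher's exact test, the Kaplan–Meier estimator (events before
censoring at tied times), the two-group log-rank test, the Wilcoxon
rank-sum test (normal approximation with tie correction), and Spearman
correlation (average ranks for ties) delegate to scipy and lifelines;
the conventions above are pinned by tests against independent oracles
(full hypergeometric enumeration for every 2×2 table with total ≤ 40, a
hand-computed product-limit fixture, exact rank-permutation
enumeration at n ≤ 8). Degenerate inputs: a zero-margin table gives
p = 1; a constant vector makes Spearman undefined (error); survival
curves require at least one subject.

## Synthetic cohorts

The generator draws, per sample: a clone count on 1–4
(probabilities 0.35/0.30/0.20/0.15), per-clone mutation counts from a
negative binomial (mean 30, dispersion 5), a purity in [0.6, 0.95], and
a signature mixture from a Dirichlet prior that is BRCA-dominant for
deficient samples (α = (1.5, 1, 8, 1) over age/APOBEC/BRCA/MMR) and
age-dominant otherwise (α = (8, 2, 1, 1)). Reads are binomial at
success probability min(purity × clone fraction, 0.5) with Poisson
depth around 150×, emulating exome-scale sequencing. 47% of samples are
BRCA-deficient; 60% of those carry a deleterious BRCA1/2 mutation
(80% BRCA1). Carrier wild-type expression is depressed by an RNA
allele fraction drawn in [0.55, 0.9]; expression-only deficient samples
are planted below the carriers' maximum wild-type abundance and normals
above it, so truth is recoverable by construction. Expression is
log-normal (gene means 2^N(7, 1.5), per-sample noise 2^N(0, 0.5)) with
50 planted differentially expressed genes (25 up, 25 down in deficient
samples) at fold change 2 and fixed baseline 128 so they survive the
low-expression filter. Response is Bernoulli from a logistic model on a
standardized mutations-per-clone proxy (coefficient 1.0) and a planted
pathway-mutation flag (coefficient 3.0, intercept −1.5); survival is
exponential with baseline hazard 0.02/month and hazard ratio 0.3 for
deficiency, censored uniformly on [12, 60] months. The default cohort
size is 29 (18:11-scale discovery regime); `tcga_like_config()` gives
101.

One integer seed drives a single root generator; every emitted file
embeds the seed in a `# seed=` header comment, and identical seeds give
byte-identical outputs.

What the generator does **not** emulate — and hence what passing tests
cannot show about real data: realistic genomic positions and reference
alleles, copy-number variation and its effect on allele fractions,
purity/ploidy interplay, mechanistic methylation–expression coupling,
correlated gene–gene expression structure, batch effects, and the
selection biases of a retrospective cohort. Recovery rates on these
cohorts are upper bounds on real-data performance.

## Problem sizes

The validation suite uses the sizes its claims state: 100 seeded
two-clone decompositions; 200 signature-recovery samples at 1,000
mutations; one 200-sample end-to-end cohort plus 50 expression/outcome
replicates; 5 × 2,000 null genes for type-I calibration; 1,000 (tests)
or 500 (acceptance script) null log-rank replicates. These sizes give
binomial standard errors comfortably inside the asserted margins.

## Known limitations

* The clonal engine ignores copy number; clusters at fraction ~0.5 may
  merge clonal LOH and heterozygous events.
* The deficiency threshold is a cohort statistic: a cohort without
  carriers (or with an extreme carrier) shifts rule-2 calls.
* Wilcoxon p-values are asymptotic; for n ≤ 8 they deviate from the
  exact distribution by up to ~0.04.
* Permutation p-values are conservative in small cohorts (above).
* The deleterious-mutation rule treats missense variants as deleterious
  only when ClinVar-annotated; a configurable rule hook
  (`deleterious_rule`) is exposed for cohorts where hotspot missense
  variants should count.
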