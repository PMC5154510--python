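# File formats

All tables are UTF-8, tab-delimited, header row first. Lines starting
with `#` are comments (the simulator writes `# seed=<int>` as the first
line of every file it emits). Numeric fields use plain decimal
notation.

## Mutation table (MAF-like TSV)

One row per somatic variant. Coordinates are 1-based, fully closed
(VCF/MAF convention); indels are taken as provided (no left-alignment
renormalization).

Required columns:

| column | type | meaning |
| --- | --- | --- |
| `sample_id` | text | tumor sample identifier |
| `chrom` | text | chromosome |
| `pos` | integer ≥ 1 | position |
| `ref_allele`, `alt_allele` | text | alleles |
| `gene` | text | gene symbol |
| `variant_class` | enum | `silent`, `missense`, `nonsense`, `frameshift_indel`, `inframe_indel`, `splice`, `other_nonsilent` |
| `alt_count`, `ref_count` | integer ≥ 0 | supporting read counts |

Optional columns (missing values are `.` or empty):

| column | type | meaning |
| --- | --- | --- |
| `maf` | fraction | mutant allele frequency; computed from counts when absent |
| `trinucleotide_context` | label | e.g. `A[C>T]G`; purine-reference labels are reverse-complemented onto the pyrimidine strand at load |
| `phylop`, `sift`, `polyphen2`, `mutationtaster`, `lrt` | `D`/`T`/`.` | functional-impact predictor calls |
| `dbsnp`, `esp`, `thousand_genomes`, `exac` | 0/1 | population-database membership (resolved flags) |
| `cosmic_recurrence` | integer | COSMIC recurrence count |
| `clinvar_flag` | 0/1 | ClinVar annotated |
| `pooled_normal_maf` | fraction | allele frequency in the pooled normal |
| `rna_maf` | fraction | RNA-derived allele fraction at the variant position |

## Expression matrix

First column `gene` (unique symbols), one column per sample,
non-negative normalized counts.

## Methylation table

First column `probe`, one column per sample, beta values in [0, 1]
(missing allowed).

## Clinical table

Columns: `sample_id`, `response` (`pCR`, `RCB-I`, `RCB-II`, `RCB-III`,
or `RD`; any non-pCR class binarizes to RD), optional `os_time`
(months), `os_event` (0/1), `stage`, `grade`.

## Gene sets

Standard GMT: pathway name, description, then gene symbols,
tab-separated; genes are de-duplicated per set.

## Signature reference

First column `context` containing the canonical 96 labels, one column
per signature with non-negative loadings; columns are renormalized to
sum to 1 at load.
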