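"""Synthetic TNBC cohort generator with ground-truth labels.

Cohorts emulate the data regimes the pipeline targets: per-tumor clonal
structure (1-4 clones, binomial read sampling at exome-like depth around
150x), trinucleotide contexts drawn from per-sample signature mixtures
(BRCA-deficient tumors are BRCA-signature-dominant by prior), BRCA-status-
dependent wild-type transcript abundance (carriers' wild-type expression
is depressed by the mutant allele fraction; expression-only deficient
tumors are planted below the carriers' maximum), planted differential
expression between deficient and normal groups, and outcomes (binary
response from a logistic model on a clonal-mutation-burden proxy and a
pathway-mutation flag; exponential survival with a planted hazard ratio
for BRCA deficiency and uniform censoring).

Every draw flows from one root ``numpy`` generator seeded by a single
integer, so identical seeds give identical cohorts; the writers embed the
seed in a header comment of each emitted file.

Default cohort size is 29, mirroring a discovery cohort of 18 responders
and 11 non-responders at exome scale; ``tcga_like_config`` switches to a
101-sample validation-scale cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .contexts import CONTEXTS_96
from .metagene import IMMUNE_GENES
from .models import (
    ClinicalRecord,
    ExpressionMatrix,
    ImpactCall,
    MethylationTable,
    MutationRecord,
    PathwayCollection,
    Response,
    SignatureReference,
    VariantClass,
)
from .brca import BRCA1_PROMOTER_PROBES
from .signatures import synthetic_signature_reference


@dataclass(frozen=True)
class SimulationConfig:
    n_samples: int = 29
    # clonal architecture
    clone_count_probs: tuple[float, ...] = (0.35, 0.30, 0.20, 0.15)  # 1..4 clones
    mutations_per_clone_mean: float = 30.0
    mutations_per_clone_dispersion: float = 5.0
    depth_mean: float = 150.0
    purity_range: tuple[float, float] = (0.6, 0.95)
    covered_bases_10x: int = 30_000_000
    silent_fraction: float = 0.25
    deleterious_vote_prob: float = 0.75
    # BRCA status
    fraction_brca_deficient: float = 0.47
    fraction_deficient_with_mutation: float = 0.6
    fraction_carrier_brca1: float = 0.8
    # signature mixture Dirichlet priors over (age, APOBEC, BRCA, MMR)
    signature_alpha_deficient: tuple[float, ...] = (1.5, 1.0, 8.0, 1.0)
    signature_alpha_normal: tuple[float, ...] = (8.0, 2.0, 1.0, 1.0)
    # expression
    n_genes: int = 2000
    n_planted_de_genes: int = 50
    fold_change: float = 2.0
    expression_log2_sd: float = 0.5
    # response + survival
    pathway_mutation_prob: float = 0.4
    pcr_intercept: float = -1.5
    pcr_coef_cmb: float = 1.0
    pcr_coef_pathway: float = 3.0
    survival_hr_brca_d: float = 0.3
    baseline_hazard: float = 0.02  # events per month for BRCA-normal
    censoring_range: tuple[float, float] = (12.0, 60.0)


def tcga_like_config(**overrides) -> SimulationConfig:
    """A validation-scale preset (101 samples)."""
    return replace(SimulationConfig(n_samples=101), **overrides)


@dataclass
class SampleTruth:
    sample_id: str
    n_clones: int
    clone_fractions: tuple[float, ...]  # cellular allele fractions, descending
    clone_mutation_counts: tuple[int, ...]
    purity: float
    signature_mixture: tuple[float, ...]
    brca_deficient: bool
    carrier_gene: str | None  # BRCA1 / BRCA2 / None
    rna_maf: float | None
    pathway_mutated: bool
    pcr_prob: float | None = None

    @property
    def total_mutations(self) -> int:
        return int(sum(self.clone_mutation_counts))


@dataclass
class SyntheticTruth:
    samples: list[SampleTruth]
    planted_up_genes: tuple[str, ...]
    planted_down_genes: tuple[str, ...]
    pathway_genes: tuple[str, ...]
    config: SimulationConfig

    def frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": s.sample_id,
                "n_clones": s.n_clones,
                "clone_fractions": ",".join(f"{f:.4f}" for f in s.clone_fractions),
                "total_mutations": s.total_mutations,
                "purity": s.purity,
                "signature_mixture": ",".join(
                    f"{p:.4f}" for p in s.signature_mixture
                ),
                "brca_deficient": int(s.brca_deficient),
                "carrier_gene": s.carrier_gene or ".",
                "pathway_mutated": int(s.pathway_mutated),
                "pcr_prob": "." if s.pcr_prob is None else f"{s.pcr_prob:.4f}",
            }
            for s in self.samples
        ]
        return pd.DataFrame(rows)


@dataclass
class SyntheticCohort:
    mutations: dict[str, list[MutationRecord]]
    expression: ExpressionMatrix
    methylation: MethylationTable
    clinical: dict[str, ClinicalRecord]
    pathways: PathwayCollection
    reference: SignatureReference
    truth: SyntheticTruth
    seed: int | None = None


def _gene_symbols(config: SimulationConfig) -> list[str]:
    return [f"G{i:04d}" for i in range(config.n_genes)]


def _pathway_collection(config: SimulationConfig, rng: np.random.Generator):
    """A planted response pathway plus decoy pathways over the gene universe."""
    genes = _gene_symbols(config)
    planted = tuple(genes[-20:])
    collection = {"RESPONSE_PATHWAY": set(planted)}
    for i in range(9):
        members = rng.choice(config.n_genes - 20, size=25, replace=False)
        collection[f"DECOY_{i:02d}"] = {genes[j] for j in members}
    return PathwayCollection(collection), planted


def draw_truth(config: SimulationConfig, seed: int) -> tuple[SyntheticTruth, np.random.Generator]:
    """Draw all latent per-sample state; returns the truth and the advanced rng."""
    rng = np.random.default_rng(seed)
    genes = _gene_symbols(config)
    n_planted = config.n_planted_de_genes
    up = tuple(genes[: n_planted // 2])
    down = tuple(genes[n_planted // 2 : n_planted])
    _, pathway_genes = _pathway_collection(config, np.random.default_rng(seed + 1))

    n = config.n_samples
    n_def = int(round(config.fraction_brca_deficient * n))
    status = np.zeros(n, dtype=bool)
    status[rng.choice(n, size=n_def, replace=False)] = True
    nb_r = config.mutations_per_clone_dispersion
    nb_p = nb_r / (nb_r + config.mutations_per_clone_mean)
    samples: list[SampleTruth] = []
    carrier_flags = rng.random(n) < config.fraction_deficient_with_mutation
    for i in range(n):
        k = int(rng.choice(len(config.clone_count_probs), p=config.clone_count_probs)) + 1
        fracs = [0.5] + sorted(
            rng.uniform(0.08, 0.35, size=k - 1).tolist(), reverse=True
        )
        counts = tuple(int(max(1, c)) for c in rng.negative_binomial(nb_r, nb_p, size=k))
        mixture = rng.dirichlet(
            config.signature_alpha_deficient
            if status[i]
            else config.signature_alpha_normal
        )
        carrier = bool(status[i] and carrier_flags[i])
        gene = None
        if carrier:
            gene = "BRCA1" if rng.random() < config.fraction_carrier_brca1 else "BRCA2"
        samples.append(
            SampleTruth(
                sample_id=f"S{i:03d}",
                n_clones=k,
                clone_fractions=tuple(fracs),
                clone_mutation_counts=counts,
                purity=float(rng.uniform(*config.purity_range)),
                signature_mixture=tuple(float(x) for x in mixture),
                brca_deficient=bool(status[i]),
                carrier_gene=gene,
                rna_maf=float(rng.uniform(0.55, 0.9)) if carrier else None,
                pathway_mutated=bool(rng.random() < config.pathway_mutation_prob),
            )
        )
    # expression-rule calibration needs at least one BRCA1 carrier
    deficient = [s for s in samples if s.brca_deficient]
    if deficient and not any(s.carrier_gene == "BRCA1" for s in samples):
        s0 = deficient[0]
        s0.carrier_gene = "BRCA1"
        s0.rna_maf = float(rng.uniform(0.55, 0.9))
    truth = SyntheticTruth(
        samples=samples,
        planted_up_genes=up,
        planted_down_genes=down,
        pathway_genes=pathway_genes,
        config=config,
    )
    return truth, rng


def simulate_mutations(
    config: SimulationConfig,
    sample: SampleTruth,
    reference: SignatureReference,
    rng: np.random.Generator,
) -> list[MutationRecord]:
    """Binomial read sampling at clone-specific allele fractions.

    Each mutation's observed success probability is min(purity x clone
    fraction, 0.5); depth is Poisson around the configured mean; the
    trinucleotide context is drawn from the mixture-weighted signature
    multinomial.
    """
    loadings = reference.matrix
    mixture = np.asarray(sample.signature_mixture)
    records: list[MutationRecord] = []
    pos = 1
    class_choices = (
        VariantClass.MISSENSE,
        VariantClass.NONSENSE,
        VariantClass.FRAMESHIFT_INDEL,
        VariantClass.SPLICE,
    )
    class_probs = (0.80, 0.10, 0.05, 0.05)
    for frac, count in zip(sample.clone_fractions, sample.clone_mutation_counts):
        p = min(sample.purity * frac, 0.5)
        for _ in range(count):
            depth = max(20, int(rng.poisson(config.depth_mean)))
            alt = max(1, int(rng.binomial(depth, p)))
            sig = int(rng.choice(mixture.size, p=mixture))
            ctx = CONTEXTS_96[int(rng.choice(96, p=loadings[:, sig]))]
            silent = rng.random() < config.silent_fraction
            vclass = (
                VariantClass.SILENT
                if silent
                else class_choices[int(rng.choice(4, p=class_probs))]
            )
            if vclass.is_indel:
                context_label = None
                ref, altbase = "A", "AT"
            else:
                context_label = ctx
                ref, altbase = ctx[2], ctx[4]
            impact = {
                pred: (
                    ImpactCall.MISSING
                    if silent or vclass.is_indel
                    else (
                        ImpactCall.DELETERIOUS
                        if rng.random() < config.deleterious_vote_prob
                        else ImpactCall.TOLERATED
                    )
                )
                for pred in ("phylop", "sift", "polyphen2", "mutationtaster", "lrt")
            }
            records.append(
                MutationRecord(
                    sample_id=sample.sample_id,
                    chrom="1",
                    pos=pos,
                    ref_allele=ref,
                    alt_allele=altbase,
                    gene=f"G{int(rng.integers(config.n_genes - 20)):04d}",
                    variant_class=vclass,
                    alt_count=alt,
                    ref_count=depth - alt,
                    maf=alt / depth,
                    trinucleotide_context=context_label,
                    impact_calls=impact,
                )
            )
            pos += 100
    if sample.pathway_mutated:
        genes = _gene_symbols(config)
        gene = genes[config.n_genes - 20 + int(rng.integers(20))]
        depth = max(20, int(rng.poisson(config.depth_mean)))
        alt = max(1, int(rng.binomial(depth, min(sample.purity * 0.5, 0.5))))
        records.append(
            MutationRecord(
                sample_id=sample.sample_id,
                chrom="2",
                pos=pos,
                ref_allele="C",
                alt_allele="T",
                gene=gene,
                variant_class=VariantClass.MISSENSE,
                alt_count=alt,
                ref_count=depth - alt,
                maf=alt / depth,
                trinucleotide_context="A[C>T]G",
                impact_calls={
                    p: ImpactCall.DELETERIOUS
                    for p in ("phylop", "sift", "polyphen2", "mutationtaster", "lrt")
                },
            )
        )
        pos += 100
    if sample.carrier_gene is not None:
        depth = max(20, int(rng.poisson(config.depth_mean)))
        alt = max(1, int(rng.binomial(depth, min(sample.purity * 0.5, 0.5))))
        records.append(
            MutationRecord(
                sample_id=sample.sample_id,
                chrom="17" if sample.carrier_gene == "BRCA1" else "13",
                pos=pos,
                ref_allele="G",
                alt_allele="T",
                gene=sample.carrier_gene,
                variant_class=VariantClass.NONSENSE,
                alt_count=alt,
                ref_count=depth - alt,
                maf=alt / depth,
                trinucleotide_context="A[C>A]C",
                impact_calls={
                    p: ImpactCall.DELETERIOUS
                    for p in ("phylop", "sift", "polyphen2", "mutationtaster", "lrt")
                },
                clinvar_flag=True,
                rna_maf=sample.rna_maf,
            )
        )
    return records


def simulate_expression(
    config: SimulationConfig, truth: SyntheticTruth, rng: np.random.Generator
) -> ExpressionMatrix:
    """Log-normal baseline expression with planted group differences.

    Planted up genes are multiplied by the fold change in BRCA-deficient
    samples, planted down genes in BRCA-normal samples. BRCA1/2 rows are
    constructed so that every expression-only deficient sample falls below
    the carriers' maximum wild-type abundance and every normal sample
    falls above it.
    """
    genes = _gene_symbols(config)
    sample_ids = [s.sample_id for s in truth.samples]
    n = len(sample_ids)
    deficient = np.array([s.brca_deficient for s in truth.samples])

    gene_means = np.power(2.0, rng.normal(7.0, 1.5, size=config.n_genes))
    planted = set(truth.planted_up_genes) | set(truth.planted_down_genes)
    for i, g in enumerate(genes):
        if g in planted:
            gene_means[i] = 128.0
    noise = np.power(2.0, rng.normal(0.0, config.expression_log2_sd, size=(config.n_genes, n)))
    values = gene_means[:, None] * noise
    up_idx = [genes.index(g) for g in truth.planted_up_genes]
    down_idx = [genes.index(g) for g in truth.planted_down_genes]
    values[np.ix_(up_idx, np.where(deficient)[0])] *= config.fold_change
    values[np.ix_(down_idx, np.where(~deficient)[0])] *= config.fold_change

    frame = pd.DataFrame(values, index=genes, columns=sample_ids)

    # immune metagene genes: independent baseline
    for g in IMMUNE_GENES:
        frame.loc[g] = np.power(2.0, rng.normal(6.0, 1.0, size=n))

    # BRCA1/2 abundance by status
    for gene in ("BRCA1", "BRCA2"):
        carriers = [s for s in truth.samples if s.carrier_gene == gene]
        row = np.empty(n)
        carrier_wt = {}
        for s in carriers:
            total = float(rng.uniform(400.0, 800.0))
            carrier_wt[s.sample_id] = total * (1.0 - s.rna_maf)
            row[sample_ids.index(s.sample_id)] = total
        max_wt = max(carrier_wt.values()) if carrier_wt else 500.0
        for j, s in enumerate(truth.samples):
            if s.carrier_gene == gene:
                continue
            low_here = (
                gene == "BRCA1" and s.brca_deficient and s.carrier_gene is None
            )
            if low_here:
                row[j] = float(rng.uniform(0.1, 0.8)) * max_wt
            else:
                row[j] = float(rng.uniform(1.2, 3.0)) * max_wt
        frame.loc[gene] = row
    return ExpressionMatrix(frame)


def simulate_methylation(
    config: SimulationConfig, truth: SyntheticTruth, rng: np.random.Generator
) -> MethylationTable:
    """BRCA1 promoter probes: methylated in ~half the expression-only deficient."""
    sample_ids = [s.sample_id for s in truth.samples]
    betas = rng.uniform(0.01, 0.15, size=(len(BRCA1_PROMOTER_PROBES), len(sample_ids)))
    for j, s in enumerate(truth.samples):
        if s.brca_deficient and s.carrier_gene is None and rng.random() < 0.5:
            betas[:, j] = rng.uniform(0.3, 0.7, size=len(BRCA1_PROMOTER_PROBES))
    return MethylationTable(
        pd.DataFrame(betas, index=list(BRCA1_PROMOTER_PROBES), columns=sample_ids)
    )


def simulate_outcomes(
    config: SimulationConfig, truth: SyntheticTruth, rng: np.random.Generator
) -> dict[str, ClinicalRecord]:
    """Response from a logistic model; survival exponential with planted HR.

    The clonal-mutation-burden proxy is the cohort-standardized average
    number of mutations per clone (total / clone count).
    """
    per_clone = np.array([s.total_mutations / s.n_clones for s in truth.samples])
    z = (per_clone - per_clone.mean()) / (per_clone.std() or 1.0)
    records: dict[str, ClinicalRecord] = {}
    for s, zi in zip(truth.samples, z):
        eta = (
            config.pcr_intercept
            + config.pcr_coef_cmb * zi
            + config.pcr_coef_pathway * float(s.pathway_mutated)
        )
        prob = 1.0 / (1.0 + np.exp(-eta))
        s.pcr_prob = float(prob)
        pcr = bool(rng.random() < prob)
        hazard = config.baseline_hazard * (
            config.survival_hr_brca_d if s.brca_deficient else 1.0
        )
        event_time = float(rng.exponential(1.0 / hazard))
        censor_time = float(rng.uniform(*config.censoring_range))
        records[s.sample_id] = ClinicalRecord(
            sample_id=s.sample_id,
            response=Response.PCR if pcr else Response.RD,
            rcb_class="pCR" if pcr else "RD",
            os_time=min(event_time, censor_time),
            os_event=event_time <= censor_time,
        )
    return records


def simulate_cohort(
    config: SimulationConfig | None = None,
    seed: int = 0,
    include_mutations: bool = True,
) -> SyntheticCohort:
    """Generate a full cohort (mutations, expression, methylation, outcomes)."""
    config = config or SimulationConfig()
    truth, rng = draw_truth(config, seed)
    reference = synthetic_signature_reference()
    mutations: dict[str, list[MutationRecord]] = {}
    if include_mutations:
        for s in truth.samples:
            mutations[s.sample_id] = simulate_mutations(config, s, reference, rng)
    expression = simulate_expression(config, truth, rng)
    methylation = simulate_methylation(config, truth, rng)
    clinical = simulate_outcomes(config, truth, rng)
    pathway_collection, _ = _pathway_collection(config, np.random.default_rng(seed + 1))
    return SyntheticCohort(
        mutations=mutations,
        expression=expression,
        methylation=methylation,
        clinical=clinical,
        pathways=pathway_collection,
        reference=reference,
        truth=truth,
        seed=seed,
    )


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, Path]:
    """Write all standard-format inputs plus the truth table to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cohort.seed
    paths = {
        "mutations": outdir / "mutations.tsv",
        "expression": outdir / "expression.tsv",
        "methylation": outdir / "methylation.tsv",
        "clinical": outdir / "clinical.tsv",
        "pathways": outdir / "pathways.gmt",
        "signature_reference": outdir / "signature_reference.tsv",
        "truth": outdir / "truth.tsv",
    }
    tio.write_mutation_table(cohort.mutations, paths["mutations"], seed=seed)
    tio.write_expression_matrix(cohort.expression, paths["expression"], seed=seed)
    tio.write_methylation_table(cohort.methylation, paths["methylation"], seed=seed)
    tio.write_clinical_table(cohort.clinical, paths["clinical"], seed=seed)
    tio.write_gene_sets(cohort.pathways, paths["pathways"], seed=seed)
    tio.write_signature_reference(
        cohort.reference, paths["signature_reference"], seed=seed
    )
    tio._write_with_seed(cohort.truth.frame(), paths["truth"], seed, index=False)
    return paths
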