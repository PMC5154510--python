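"""BRCA1/2 deficiency calling from mutation, expression, and methylation.

Wild-type transcript abundance is estimated for mutation carriers as
``total_expression * (1 - MAF)``, with the representative mutation chosen
as the one with the highest RNA allele fraction (DNA fraction as
fallback/tie-break). The per-gene deficiency threshold is the maximum
wild-type expression observed among deleterious-mutation carriers in the
cohort; a sample is gene-deficient if it carries a deleterious mutation
(rule 1) or, for wild-type samples, its wild-type expression falls
strictly below the threshold (rule 2). BRCA1 promoter methylation is
scored as the mean beta of four promoter probes (> 0.2 = methylated) and
reported as corroborating evidence; methylated or deep-loss tumors are
expected to manifest as low wild-type expression rather than forcing a
call directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .models import (
    ExpressionMatrix,
    MethylationTable,
    MutationRecord,
    VariantClass,
)

logger = logging.getLogger(__name__)

BRCA_GENES = ("BRCA1", "BRCA2")

#: The four robust BRCA1 promoter probes on the 450K methylation array.
BRCA1_PROMOTER_PROBES = ("cg19531713", "cg19088651", "cg08993267", "cg04658354")

METHYLATION_CUTOFF = 0.2

#: Variant classes treated as deleterious for rule 1 (truncating classes).
DELETERIOUS_CLASSES = frozenset(
    {VariantClass.NONSENSE, VariantClass.FRAMESHIFT_INDEL, VariantClass.SPLICE}
)


class ThresholdUnavailableError(ValueError):
    pass


@dataclass
class BrcaGeneEvidence:
    sample_id: str
    gene: str
    has_deleterious_mutation: bool
    representative_maf: float | None
    total_expression: float
    wt_expression: float
    methylation_score: float | None = None
    methylation_status: str = "missing"  # methylated / unmethylated / missing
    deep_loss: bool | None = None


@dataclass
class BrcaCall:
    sample_id: str
    brca1_deficient: bool
    brca2_deficient: bool
    brca_deficient: bool
    threshold_brca1: float | None
    threshold_brca2: float | None
    rationale: dict[str, list[str]] = field(default_factory=dict)


def methylation_score(betas: dict[str, float]) -> tuple[float | None, str]:
    """Mean beta over the four BRCA1 promoter probes; > 0.2 is methylated.

    At least two of the four probes must be present; the score is the mean
    of the present probes. Fewer than two present -> (None, "missing").
    """
    unexpected = set(betas) - set(BRCA1_PROMOTER_PROBES)
    if unexpected:
        raise ValueError(f"unexpected methylation probes: {sorted(unexpected)}")
    values = [v for v in betas.values() if v is not None and not np.isnan(v)]
    if len(values) < 2:
        return None, "missing"
    if any(not 0.0 <= v <= 1.0 for v in values):
        raise ValueError("beta values must lie in [0, 1]")
    score = float(np.mean(values))
    return score, ("methylated" if score > METHYLATION_CUTOFF else "unmethylated")


def wt_expression(total_expression: float, maf: float) -> float:
    """Wild-type transcript abundance: total expression x (1 - MAF)."""
    if not 0.0 <= maf <= 1.0:
        raise ValueError(f"MAF must lie in [0, 1], got {maf}")
    if total_expression < 0:
        raise ValueError("expression must be non-negative")
    return total_expression * (1.0 - maf)


def is_deleterious_brca_mutation(record: MutationRecord) -> bool:
    """Rule-1 deleteriousness: truncating class or ClinVar-annotated, non-silent."""
    if record.is_silent:
        return False
    return record.clinvar_flag or record.variant_class in DELETERIOUS_CLASSES


def select_representative_mutation(
    gene_mutations: list[MutationRecord],
) -> MutationRecord:
    """The mutation with the highest RNA allele fraction.

    Falls back to the DNA allele fraction when no RNA fraction is
    recorded; exact ties break by DNA fraction, then first by position.
    """
    if not gene_mutations:
        raise ValueError("no mutations to select from")
    def key(m: MutationRecord):
        rna = m.rna_maf if m.rna_maf is not None else m.maf
        return (-rna, -m.maf, m.pos)
    return sorted(gene_mutations, key=key)[0]


def build_gene_evidence(
    sample_id: str,
    gene: str,
    mutations: list[MutationRecord],
    expression: ExpressionMatrix,
    methylation: MethylationTable | None = None,
    deleterious_rule=is_deleterious_brca_mutation,
) -> BrcaGeneEvidence:
    """Assemble per-sample evidence for one BRCA gene."""
    if gene not in expression.values.index:
        raise ValueError(f"{gene} absent from expression matrix")
    total = float(expression.values.loc[gene, sample_id])
    gene_muts = [
        m for m in mutations if m.gene == gene and deleterious_rule(m)
    ]
    if gene_muts:
        rep = select_representative_mutation(gene_muts)
        rep_maf = rep.rna_maf if rep.rna_maf is not None else rep.maf
        if rep.rna_maf is None:
            logger.info(
                "%s/%s: no RNA allele fraction; falling back to DNA MAF",
                sample_id, gene,
            )
        wt = wt_expression(total, rep_maf)
    else:
        rep_maf, wt = None, total
    score, status = None, "missing"
    if gene == "BRCA1" and methylation is not None and sample_id in methylation.samples:
        betas = {
            p: float(methylation.betas.loc[p, sample_id])
            for p in BRCA1_PROMOTER_PROBES
            if p in methylation.betas.index
        }
        score, status = methylation_score(betas)
    return BrcaGeneEvidence(
        sample_id=sample_id,
        gene=gene,
        has_deleterious_mutation=bool(gene_muts),
        representative_maf=rep_maf,
        total_expression=total,
        wt_expression=wt,
        methylation_score=score,
        methylation_status=status,
    )


def deficiency_threshold(cohort_evidence: list[BrcaGeneEvidence], gene: str) -> float:
    """Max wild-type expression over deleterious-mutation carriers of a gene."""
    carriers = [
        e for e in cohort_evidence if e.gene == gene and e.has_deleterious_mutation
    ]
    if not carriers:
        raise ThresholdUnavailableError(
            f"no {gene} mutation carriers in cohort; expression-based deficiency "
            "calling unavailable for this gene"
        )
    return max(e.wt_expression for e in carriers)


def call_brca_deficiency(
    evidence: dict[str, BrcaGeneEvidence],
    thresholds: dict[str, float | None],
) -> BrcaCall:
    """Combine per-gene evidence into the sample's deficiency call.

    Rule 1: any deleterious mutation in the gene. Rule 2 (non-carriers
    only): wild-type expression strictly below the per-gene threshold.
    The combined call is the OR over BRCA1 and BRCA2.
    """
    flags: dict[str, bool] = {}
    rationale: dict[str, list[str]] = {}
    sample_id = next(iter(evidence.values())).sample_id
    for gene in BRCA_GENES:
        ev = evidence.get(gene)
        if ev is None:
            flags[gene] = False
            continue
        reasons = []
        if ev.has_deleterious_mutation:
            reasons.append("mutation")
        else:
            thr = thresholds.get(gene)
            if thr is None:
                logger.warning(
                    "%s/%s: no deficiency threshold; expression rule skipped",
                    sample_id, gene,
                )
            elif ev.wt_expression < thr:
                reasons.append("low_wt_expression")
        flags[gene] = bool(reasons)
        rationale[gene] = reasons
    return BrcaCall(
        sample_id=sample_id,
        brca1_deficient=flags["BRCA1"],
        brca2_deficient=flags["BRCA2"],
        brca_deficient=flags["BRCA1"] or flags["BRCA2"],
        threshold_brca1=thresholds.get("BRCA1"),
        threshold_brca2=thresholds.get("BRCA2"),
        rationale=rationale,
    )


def call_cohort(
    mutations_by_sample: dict[str, list[MutationRecord]],
    expression: ExpressionMatrix,
    methylation: MethylationTable | None = None,
    deleterious_rule=is_deleterious_brca_mutation,
) -> tuple[list[BrcaCall], dict[str, float | None]]:
    """Build evidence, derive per-gene thresholds, and call every sample."""
    samples = expression.samples
    evidence: dict[str, dict[str, BrcaGeneEvidence]] = {}
    for s in samples:
        evidence[s] = {
            g: build_gene_evidence(
                s, g, mutations_by_sample.get(s, []), expression, methylation,
                deleterious_rule=deleterious_rule,
            )
            for g in BRCA_GENES
            if g in expression.values.index
        }
    thresholds: dict[str, float | None] = {}
    for g in BRCA_GENES:
        pool = [ev[g] for ev in evidence.values() if g in ev]
        try:
            thresholds[g] = deficiency_threshold(pool, g)
        except ThresholdUnavailableError:
            logger.warning("cohort has no %s carriers; threshold unavailable", g)
            thresholds[g] = None
    calls = [call_brca_deficiency(evidence[s], thresholds) for s in samples]
    return calls, thresholds
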