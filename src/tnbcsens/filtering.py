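"""Post-calling somatic filters and high-functional-impact selection.

Variants are removed when they look germline: present in a population
database, tumor/pooled-normal allele-frequency ratio below a minimum, or
allele frequency inside the heterozygous germline band (0.45-0.55,
inclusive). Recurrent COSMIC (n >= 5) or ClinVar-annotated variants are
whitelisted and kept regardless. High-functional-impact selection keeps
SNVs called deleterious by at least three of five predictors, plus every
indel; silent variants are never high impact.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .models import MutationRecord


class FilterReason(str, enum.Enum):
    POPULATION_DB = "population_db"
    LOW_TUMOR_NORMAL_RATIO = "low_tumor_normal_ratio"
    MAF_GERMLINE_BAND = "maf_germline_band"
    WHITELISTED = "whitelisted"
    PASSED = "passed"


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class FilterDecision:
    record: MutationRecord
    kept: bool
    reasons: tuple[FilterReason, ...]

    def __post_init__(self) -> None:
        if not self.kept and all(
            r in (FilterReason.PASSED, FilterReason.WHITELISTED) for r in self.reasons
        ):
            raise ValueError("dropped record must carry a drop reason")


def is_whitelisted(record: MutationRecord, min_cosmic: int = 5) -> bool:
    """Whitelist recurrent COSMIC (n >= 5) or ClinVar-annotated variants."""
    return record.cosmic_recurrence >= min_cosmic or record.clinvar_flag


def apply_somatic_filters(
    record: MutationRecord,
    min_ratio: float = 5.0,
    germline_band: tuple[float, float] = (0.45, 0.55),
    normal_maf_floor: float = 0.01,
) -> FilterDecision:
    """Decide whether one variant survives the germline filters.

    The tumor/normal ratio uses ``max(pooled_normal_maf, normal_maf_floor)``
    in the denominator so the rule is total when the pooled normal shows no
    variant reads; a missing pooled-normal MAF is treated as 0. The
    germline band is inclusive at both ends. A whitelisted variant is kept
    regardless of any drop reason.
    """
    if min_ratio <= 0:
        raise ConfigurationError(f"min_ratio must be positive, got {min_ratio}")
    lo, hi = germline_band
    reasons: list[FilterReason] = []
    if record.any_population_flag():
        reasons.append(FilterReason.POPULATION_DB)
    normal = max(record.pooled_normal_maf or 0.0, normal_maf_floor)
    if record.maf / normal < min_ratio:
        reasons.append(FilterReason.LOW_TUMOR_NORMAL_RATIO)
    if lo <= record.maf <= hi:
        reasons.append(FilterReason.MAF_GERMLINE_BAND)
    if reasons and is_whitelisted(record):
        return FilterDecision(record, kept=True, reasons=(FilterReason.WHITELISTED,))
    if reasons:
        return FilterDecision(record, kept=False, reasons=tuple(reasons))
    return FilterDecision(record, kept=True, reasons=(FilterReason.PASSED,))


def filter_mutations(
    records: list[MutationRecord], **kwargs
) -> tuple[list[MutationRecord], list[FilterDecision]]:
    """Apply the somatic filters to a record list; return survivors + audit."""
    decisions = [apply_somatic_filters(r, **kwargs) for r in records]
    kept = [d.record for d in decisions if d.kept]
    return kept, decisions


def select_high_impact(
    records: list[MutationRecord], min_deleterious_votes: int = 3
) -> list[MutationRecord]:
    """Keep SNVs with >= 3 deleterious predictor votes, plus all indels.

    Missing predictor calls count as non-deleterious votes. Silent
    variants are never selected. Idempotent; output is a subset of input.
    """
    out = []
    for r in records:
        if r.is_silent:
            continue
        if r.is_indel or r.n_deleterious_votes() >= min_deleterious_votes:
            out.append(r)
    return out
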