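"""Domain types for the TNBC chemosensitivity pipeline.

The atom of the pipeline is :class:`MutationRecord`, one somatic variant
with read counts and annotations. A :class:`TumorProfile` bundles one
sample's mutations with its adequately covered exome length and clinical
outcome. Expression, methylation, pathway, and signature-reference
containers wrap validated pandas/numpy structures.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .contexts import CONTEXTS_96, normalize_context


class VariantClass(str, enum.Enum):
    SILENT = "silent"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT_INDEL = "frameshift_indel"
    INFRAME_INDEL = "inframe_indel"
    SPLICE = "splice"
    OTHER_NONSILENT = "other_nonsilent"

    @property
    def is_silent(self) -> bool:
        return self is VariantClass.SILENT

    @property
    def is_indel(self) -> bool:
        return self in (VariantClass.FRAMESHIFT_INDEL, VariantClass.INFRAME_INDEL)


class ImpactCall(str, enum.Enum):
    """Ternary functional-impact prediction from one algorithm."""

    DELETERIOUS = "D"
    TOLERATED = "T"
    MISSING = "."


#: The five functional-impact predictors whose calls are consumed as input.
IMPACT_PREDICTORS: tuple[str, ...] = (
    "phylop",
    "sift",
    "polyphen2",
    "mutationtaster",
    "lrt",
)

#: Population databases whose membership flags a putative germline variant.
POPULATION_DBS: tuple[str, ...] = ("dbsnp", "esp", "thousand_genomes", "exac")


class ValidationError(ValueError):
    """An input violates a declared invariant."""


class FormatError(ValueError):
    """A file does not conform to its documented tabular format."""


@dataclass(frozen=True)
class MutationRecord:
    sample_id: str
    chrom: str
    pos: int  # 1-based, fully closed (VCF/MAF convention)
    ref_allele: str
    alt_allele: str
    gene: str
    variant_class: VariantClass
    alt_count: int
    ref_count: int
    maf: float
    trinucleotide_context: str | None = None
    impact_calls: dict[str, ImpactCall] = field(default_factory=dict)
    population_flags: dict[str, bool] = field(default_factory=dict)
    cosmic_recurrence: int = 0
    clinvar_flag: bool = False
    pooled_normal_maf: float | None = None
    rna_maf: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        if self.alt_count < 0 or self.ref_count < 0:
            raise ValidationError("read counts must be non-negative")
        if not 0.0 <= self.maf <= 1.0:
            raise ValidationError(f"MAF must lie in [0, 1], got {self.maf}")
        depth = self.alt_count + self.ref_count
        if depth > 0 and not math.isclose(
            self.maf, self.alt_count / depth, abs_tol=1e-6
        ):
            raise ValidationError(
                f"MAF {self.maf} inconsistent with counts "
                f"{self.alt_count}/{depth} for {self.sample_id}:{self.gene}"
            )
        if self.trinucleotide_context is not None:
            object.__setattr__(
                self,
                "trinucleotide_context",
                normalize_context(self.trinucleotide_context),
            )
        if self.cosmic_recurrence < 0:
            raise ValidationError("cosmic_recurrence must be non-negative")

    @property
    def depth(self) -> int:
        return self.alt_count + self.ref_count

    @property
    def is_silent(self) -> bool:
        return self.variant_class.is_silent

    @property
    def is_indel(self) -> bool:
        return self.variant_class.is_indel

    def n_deleterious_votes(self) -> int:
        """Count predictors voting deleterious; missing counts as non-deleterious."""
        return sum(
            1
            for p in IMPACT_PREDICTORS
            if self.impact_calls.get(p, ImpactCall.MISSING) is ImpactCall.DELETERIOUS
        )

    def any_population_flag(self) -> bool:
        return any(self.population_flags.get(db, False) for db in POPULATION_DBS)

    def with_(self, **changes) -> "MutationRecord":
        return replace(self, **changes)


class Response(str, enum.Enum):
    PCR = "pCR"
    RD = "RD"


#: Residual cancer burden classes; pCR means no residual invasive disease.
RCB_CLASSES: tuple[str, ...] = ("pCR", "RCB-I", "RCB-II", "RCB-III", "RD")


@dataclass(frozen=True)
class ClinicalRecord:
    sample_id: str
    response: Response | None = None
    rcb_class: str | None = None
    os_time: float | None = None  # months
    os_event: bool | None = None
    stage: str | None = None
    grade: str | None = None

    def __post_init__(self) -> None:
        if self.os_event is not None and self.os_time is None:
            raise ValidationError(
                f"{self.sample_id}: os_event present without os_time"
            )
        if self.os_time is not None and self.os_time < 0:
            raise ValidationError(f"{self.sample_id}: negative survival time")
        if self.rcb_class is not None and self.rcb_class not in RCB_CLASSES:
            raise ValidationError(
                f"{self.sample_id}: unknown RCB class {self.rcb_class!r}"
            )


@dataclass
class TumorProfile:
    sample_id: str
    mutations: list[MutationRecord]
    covered_bases_10x: int
    clinical: ClinicalRecord | None = None

    def require_coverage(self) -> None:
        if self.covered_bases_10x <= 0:
            raise ValidationError(
                f"{self.sample_id}: covered exome length must be positive "
                "before mutation-rate computation"
            )


class ExpressionMatrix:
    """Gene x sample matrix of non-negative normalized counts."""

    def __init__(self, values: pd.DataFrame):
        if values.index.duplicated().any():
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene symbols: {dups}")
        arr = values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValidationError("expression matrix contains missing values")
        if (arr < 0).any():
            raise ValidationError("expression values must be non-negative")
        self.values = values.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes) -> "ExpressionMatrix":
        present = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[present])

    def __eq__(self, other) -> bool:
        return isinstance(other, ExpressionMatrix) and self.values.equals(other.values)


class MethylationTable:
    """Probe x sample matrix of methylation beta values in [0, 1]."""

    def __init__(self, betas: pd.DataFrame):
        arr = betas.to_numpy(dtype=float)
        finite = arr[~np.isnan(arr)]
        if ((finite < 0) | (finite > 1)).any():
            raise ValidationError("beta values must lie in [0, 1]")
        self.betas = betas.astype(float)

    @property
    def probes(self) -> list[str]:
        return list(self.betas.index)

    @property
    def samples(self) -> list[str]:
        return list(self.betas.columns)


class PathwayCollection(dict):
    """Mapping of pathway name -> set of gene symbols (non-empty)."""

    def __init__(self, mapping: dict[str, set[str]]):
        for name, genes in mapping.items():
            if not genes:
                raise ValidationError(f"pathway {name!r} has an empty gene set")
        super().__init__({name: set(genes) for name, genes in mapping.items()})


class SignatureReference:
    """96-context loading matrix for K mutational signatures.

    Columns are renormalized to sum to one so that each signature is a
    probability distribution over the 96 contexts.
    """

    def __init__(self, loadings: pd.DataFrame):
        if list(loadings.index) != list(CONTEXTS_96):
            if set(loadings.index) == set(CONTEXTS_96):
                loadings = loadings.loc[list(CONTEXTS_96)]
            else:
                raise FormatError(
                    "signature reference must be indexed by the canonical "
                    f"96 contexts (got {len(loadings.index)} rows)"
                )
        arr = loadings.to_numpy(dtype=float)
        if (arr < 0).any():
            raise ValidationError("signature loadings must be non-negative")
        colsums = arr.sum(axis=0)
        if (colsums <= 0).any():
            raise ValidationError("every signature column must have positive mass")
        self.loadings = loadings.astype(float) / colsums

    @property
    def signatures(self) -> list[str]:
        return list(self.loadings.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.loadings.to_numpy(dtype=float)

    @property
    def n_signatures(self) -> int:
        return self.loadings.shape[1]
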