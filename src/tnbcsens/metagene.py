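"""Metagene signatures: derivation, scoring, and evaluation.

A deficiency signature is derived by per-gene differential expression
between labeled groups (Welch t-test on log2(x+1), unadjusted p < 0.002
by default) after excluding genes whose median expression is below 25% of
the overall median. The metagene score of a sample is the mean
log2-expression over the up-gene set minus the mean over the down-gene
set, and calls dichotomize at the cohort median (strictly greater =
high). An immune metagene averages six lymphocyte-specific genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .models import ExpressionMatrix

logger = logging.getLogger(__name__)

#: Lymphocyte-specific genes averaged into the immune metagene.
IMMUNE_GENES = ("GZMB", "PRF1", "CXCL13", "IRF1", "IKZF1", "HLA-E")


@dataclass(frozen=True)
class MetageneSignature:
    up_genes: frozenset[str]
    down_genes: frozenset[str]
    derivation_p_cutoff: float
    low_expression_fraction: float
    p_values: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.up_genes & self.down_genes:
            raise ValueError("up and down gene sets must be disjoint")


@dataclass(frozen=True)
class MetageneScores:
    scores: pd.Series  # per-sample score
    calls: pd.Series  # "high" / "low"
    cohort_median: float


def _log2p1(matrix: ExpressionMatrix) -> pd.DataFrame:
    return np.log2(matrix.values + 1.0)


def filter_low_expression(
    matrix: ExpressionMatrix, fraction: float = 0.25
) -> list[str]:
    """Genes whose per-gene median is >= fraction x the overall median."""
    values = matrix.values.to_numpy()
    overall = float(np.median(values))
    if overall == 0:
        raise ValueError("degenerate matrix: overall median expression is zero")
    gene_medians = np.median(values, axis=1)
    keep = gene_medians >= fraction * overall
    return [g for g, k in zip(matrix.genes, keep) if k]


def differential_expression(
    matrix: ExpressionMatrix,
    groups: pd.Series,
    p_cutoff: float = 0.002,
    low_expression_fraction: float = 0.25,
    apply_low_expression_filter: bool = True,
) -> MetageneSignature:
    """Two-group Welch t-test per gene on log2(x+1); split hits by direction.

    ``groups`` maps sample -> binary label (1 = deficient-like group whose
    overexpressed genes become ``up_genes``). Requires >= 3 samples per
    group.
    """
    groups = groups.loc[[s for s in matrix.samples if s in groups.index]]
    g1 = groups.index[groups.astype(bool)].tolist()
    g0 = groups.index[~groups.astype(bool)].tolist()
    if len(g1) < 3 or len(g0) < 3:
        raise ValueError(
            f"each group needs >= 3 samples, got {len(g1)} and {len(g0)}"
        )
    if apply_low_expression_filter:
        kept = filter_low_expression(matrix, low_expression_fraction)
        matrix = matrix.subset_genes(kept)
    log_expr = _log2p1(matrix)
    a = log_expr[g1].to_numpy()
    b = log_expr[g0].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sps.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    up, down, pvals = set(), set(), {}
    mean_diff = a.mean(axis=1) - b.mean(axis=1)
    for gene, pv, d in zip(matrix.genes, p, mean_diff):
        if pv < p_cutoff and d != 0:
            (up if d > 0 else down).add(gene)
            pvals[gene] = float(pv)
    return MetageneSignature(
        up_genes=frozenset(up),
        down_genes=frozenset(down),
        derivation_p_cutoff=p_cutoff,
        low_expression_fraction=low_expression_fraction,
        p_values=pvals,
    )


def metagene_score(
    matrix: ExpressionMatrix, signature: MetageneSignature
) -> MetageneScores:
    """Mean log2 expression over up genes minus mean over down genes.

    Signature genes absent from the matrix are dropped with a warning;
    calls are "high" iff score > cohort median.
    """
    log_expr = _log2p1(matrix)
    up = [g for g in signature.up_genes if g in log_expr.index]
    down = [g for g in signature.down_genes if g in log_expr.index]
    missing = (signature.up_genes | signature.down_genes) - set(up) - set(down)
    if missing:
        logger.warning("metagene_score: %d signature genes missing", len(missing))
    if not up or not down:
        raise ValueError("need >= 1 up gene and >= 1 down gene present in matrix")
    scores = log_expr.loc[up].mean(axis=0) - log_expr.loc[down].mean(axis=0)
    median = float(scores.median())
    calls = pd.Series(
        np.where(scores > median, "high", "low"), index=scores.index
    )
    return MetageneScores(scores=scores, calls=calls, cohort_median=median)


def immune_metagene(matrix: ExpressionMatrix) -> pd.Series:
    """Mean log2(x+1) over the six lymphocyte-specific genes (>= 4 required)."""
    present = [g for g in IMMUNE_GENES if g in matrix.values.index]
    missing = [g for g in IMMUNE_GENES if g not in matrix.values.index]
    if len(present) < 4:
        raise ValueError(
            f"immune metagene needs >= 4 of {IMMUNE_GENES}, missing {missing}"
        )
    if missing:
        logger.warning("immune_metagene: missing genes %s", missing)
    return _log2p1(matrix).loc[present].mean(axis=0)


def classifier_performance(calls: pd.Series, truth: pd.Series) -> tuple[float, float]:
    """(sensitivity, specificity) of binary calls against truth labels.

    Both inputs are boolean-like series indexed by sample (True =
    deficient/positive).
    """
    common = calls.index.intersection(truth.index)
    if len(common) != len(calls) or len(common) != len(truth):
        raise ValueError("calls and truth must cover the same samples")
    c = calls.loc[common].astype(bool)
    t = truth.loc[common].astype(bool)
    pos, neg = int(t.sum()), int((~t).sum())
    if pos == 0 or neg == 0:
        raise ValueError("sensitivity/specificity undefined without both classes")
    tp = int((c & t).sum())
    tn = int((~c & ~t).sum())
    return tp / pos, tn / neg
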