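"""Mutation burden, intratumor heterogeneity, and clonal decomposition.

Per tumor this module computes:

* mutation rate (MR): mutations per megabase of target exome covered at
  >= 10x;
* MATH score: 100 x 1.4826 x MAD / median of the per-mutation allele
  fractions at MAF >= 0.075 (the consistency constant makes the MAD an
  unbiased sigma estimate under normality, the convention of the MATH
  literature);
* a maximum-likelihood binomial-mixture clonal decomposition of
  (alt_count, depth) pairs, fitted by EM over k = 1..k_max with BIC model
  selection — each component is read as one clone;
* the average number of mutations per clone, the clone-size-weighted mean
  of the per-clone mutation counts;
* the clonal mutation burden (CMB) category from cohort-median
  dichotomized MR and MATH: high = (high MR, low MATH), low = (low MR,
  high MATH), intermediate otherwise.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .models import MutationRecord

logger = logging.getLogger(__name__)


class UndefinedScoreError(ValueError):
    """Too few qualifying mutations to compute the statistic."""


class DecompositionUnavailableError(ValueError):
    pass


class CmbCategory(str, enum.Enum):
    LOW = "low"
    INTERMEDIATE = "intermediate"
    HIGH = "high"


@dataclass
class BurdenMetrics:
    sample_id: str
    mutation_rate: float
    math_score: float | None
    cmb: CmbCategory | None = None
    n_mutations_used_math: int = 0


@dataclass(frozen=True)
class ClonalDecomposition:
    k: int
    cluster_means: tuple[float, ...]
    cluster_sizes: tuple[int, ...]
    assignments: tuple[int, ...]
    avg_mutations_per_clone: float
    log_likelihood: float
    bic: float
    seed: int

    def __post_init__(self) -> None:
        if sum(self.cluster_sizes) != len(self.assignments):
            raise ValueError("cluster sizes must sum to the number of mutations used")


def mutation_rate(n_mutations: int, covered_bases_10x: int) -> float:
    """Mutations per megabase of adequately covered exome."""
    if covered_bases_10x <= 0:
        raise ValueError(
            f"covered exome length must be positive, got {covered_bases_10x}"
        )
    return n_mutations / (covered_bases_10x / 1e6)


def math_score(mafs, min_maf: float = 0.075) -> float:
    """MATH = 100 * 1.4826 * MAD(maf) / median(maf), on MAFs >= min_maf."""
    mafs = np.asarray([m for m in np.asarray(mafs, dtype=float) if m >= min_maf])
    if mafs.size < 3:
        raise UndefinedScoreError(
            f"MATH needs >= 3 mutations with MAF >= {min_maf}, got {mafs.size}"
        )
    med = float(np.median(mafs))
    mad = float(np.median(np.abs(mafs - med)))
    return 100.0 * 1.4826 * mad / med


def _binom_mixture_em(
    alt: np.ndarray,
    depth: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int = 500,
    tol: float = 1e-8,
):
    """One EM run for a k-component binomial mixture; returns (logL, p, w, resp)."""
    n = alt.size
    maf = alt / depth
    # binomial coefficient term is parameter-free: precompute once
    log_coef = (
        gammaln(depth + 1) - gammaln(alt + 1) - gammaln(depth - alt + 1)
    )[:, None]

    def logpmf(p):
        return log_coef + alt[:, None] * np.log(p)[None, :] + (
            depth - alt
        )[:, None] * np.log1p(-p)[None, :]

    # quantile (k-means-style) initialization on raw MAFs with seeded jitter
    order = np.argsort(maf)
    groups = np.array_split(order, k)
    p = np.array([maf[g].mean() if g.size else rng.uniform(0.05, 0.5) for g in groups])
    p = np.clip(p + rng.normal(0.0, 0.02, size=k), 1e-4, 1 - 1e-4)
    w = np.full(k, 1.0 / k)
    prev_ll = -np.inf
    log_binom = logpmf(p)
    for _ in range(max_iter):
        log_comp = np.log(w)[None, :] + log_binom
        ll_i = np.logaddexp.reduce(log_comp, axis=1)
        ll = float(ll_i.sum())
        resp = np.exp(log_comp - ll_i[:, None])
        if ll - prev_ll < tol * max(1.0, abs(ll)) and ll >= prev_ll:
            return ll, p, w, resp
        prev_ll = ll
        nk = resp.sum(axis=0)
        w = nk / n
        p = np.clip((resp * alt[:, None]).sum(axis=0) /
                    np.maximum((resp * depth[:, None]).sum(axis=0), 1e-12),
                    1e-4, 1 - 1e-4)
        log_binom = logpmf(p)
    return prev_ll, p, w, resp


def decompose_clones(
    mutations: list[MutationRecord],
    min_depth: int = 10,
    max_maf: float = 0.6,
    k_max: int = 6,
    n_restarts: int = 10,
    seed: int = 0,
) -> ClonalDecomposition:
    """Cluster allele fractions into clones with a binomial mixture model.

    Mutations with depth < ``min_depth`` or MAF >= ``max_maf`` are excluded
    (high-MAF variants may sit on copy-number losses). Mixtures with
    k = 1..k_max components are fitted by EM with ``n_restarts`` seeded
    restarts each; the model minimizing BIC = -2 logL + (2k-1) ln n is
    selected. Mutations are assigned to their maximum-posterior component;
    components left empty are removed.
    """
    used_idx = [
        i
        for i, m in enumerate(mutations)
        if m.depth >= min_depth and m.maf < max_maf
    ]
    if len(used_idx) < 5:
        raise DecompositionUnavailableError(
            f"clonal decomposition needs >= 5 qualifying mutations, "
            f"got {len(used_idx)}"
        )
    alt = np.array([mutations[i].alt_count for i in used_idx], dtype=float)
    depth = np.array([mutations[i].depth for i in used_idx], dtype=float)
    n = alt.size
    rng = np.random.default_rng(seed)
    best = None
    for k in range(1, k_max + 1):
        best_k = None
        for _ in range(n_restarts):
            ll, p, w, resp = _binom_mixture_em(alt, depth, k, rng)
            if not np.isfinite(ll):
                continue
            if best_k is None or ll > best_k[0]:
                best_k = (ll, p, w, resp)
        if best_k is None:
            continue
        ll, p, w, resp = best_k
        bic = -2.0 * ll + (2 * k - 1) * np.log(n)
        if best is None or bic < best[0]:
            best = (bic, ll, p, w, resp)
    if best is None:
        raise DecompositionUnavailableError("EM failed to converge in all restarts")
    bic, ll, p, w, resp = best
    assign = resp.argmax(axis=1)
    occupied = np.unique(assign)
    p = p[occupied]
    order = np.argsort(p)
    remap = {int(occupied[j]): int(np.where(order == j)[0][0]) for j in range(occupied.size)}
    assignments = tuple(remap[int(a)] for a in assign)
    means = tuple(float(x) for x in p[order])
    sizes = tuple(int(np.sum(np.array(assignments) == j)) for j in range(len(means)))
    decomp = ClonalDecomposition(
        k=len(means),
        cluster_means=means,
        cluster_sizes=sizes,
        assignments=assignments,
        avg_mutations_per_clone=0.0,
        log_likelihood=float(ll),
        bic=float(bic),
        seed=seed,
    )
    return dataclasses.replace(
        decomp, avg_mutations_per_clone=avg_mutations_per_clone(decomp)
    )


def avg_mutations_per_clone(decomposition: ClonalDecomposition) -> float:
    """Clone-proportion-weighted mean clone size: sum_k n_k * (n_k / N)."""
    sizes = np.asarray(decomposition.cluster_sizes, dtype=float)
    total = sizes.sum()
    return float((sizes * (sizes / total)).sum())


def assign_cmb(cohort: list[BurdenMetrics]) -> list[BurdenMetrics]:
    """Fill CMB categories by cohort-median dichotomization of MR and MATH.

    A value <= the cohort median is "low". CMB is low for (low MR, high
    MATH), high for (high MR, low MATH), intermediate otherwise. Samples
    without a MATH score stay uncategorized.
    """
    scored = [b for b in cohort if b.math_score is not None]
    if len(scored) < 2:
        raise ValueError("CMB requires >= 2 samples with defined MR and MATH")
    mr_median = float(np.median([b.mutation_rate for b in scored]))
    math_median = float(np.median([b.math_score for b in scored]))
    if all(b.mutation_rate == scored[0].mutation_rate for b in scored) and all(
        b.math_score == scored[0].math_score for b in scored
    ):
        logger.warning(
            "degenerate cohort: identical MR and MATH everywhere; "
            "all samples dichotomize low and CMB is intermediate"
        )
    for b in cohort:
        if b.math_score is None:
            b.cmb = None
            continue
        mr_low = b.mutation_rate <= mr_median
        math_low = b.math_score <= math_median
        if mr_low and not math_low:
            b.cmb = CmbCategory.LOW
        elif not mr_low and math_low:
            b.cmb = CmbCategory.HIGH
        else:
            b.cmb = CmbCategory.INTERMEDIATE
    return cohort


def burden_metrics(
    sample_id: str,
    mutations: list[MutationRecord],
    covered_bases_10x: int,
    min_maf: float = 0.075,
) -> BurdenMetrics:
    """MR (all detected mutations) and MATH for one tumor."""
    if covered_bases_10x <= 0:
        raise ValueError(f"{sample_id}: covered exome length must be positive")
    mr = mutation_rate(len(mutations), covered_bases_10x)
    mafs = [m.maf for m in mutations]
    try:
        score = math_score(mafs, min_maf=min_maf)
        n_used = int(sum(1 for m in mafs if m >= min_maf))
    except UndefinedScoreError:
        logger.info("%s: MATH undefined (too few mutations above %.3f)", sample_id, min_maf)
        score, n_used = None, 0
    return BurdenMetrics(
        sample_id=sample_id,
        mutation_rate=mr,
        math_score=score,
        n_mutations_used_math=n_used,
    )
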