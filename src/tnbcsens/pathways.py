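"""Pathway-level mutation aggregation and response association.

High-functional-impact mutations are collapsed to a binary sample x
pathway matrix (1 = any high-impact mutation in any pathway gene), tested
for association with pathologic complete response by a two-sided Fisher
exact test with Bonferroni adjustment, and accompanied by two resampling
assessments: the frequency of nominal significance under bootstrap
resampling of patients (robustness) and a label-permutation p-value with
the add-one estimator (significance). The bootstrap is unstratified, so
resampled cohorts have varying responder counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .models import MutationRecord, PathwayCollection
from .stats import fisher_exact_2x2


@dataclass
class AssociationResult:
    pathway: str
    table: tuple[tuple[int, int], tuple[int, int]]  # (mut, wt) x (pCR, no-pCR)
    p_fisher: float
    p_bonferroni: float
    bootstrap_frequency: float | None = None
    p_permutation: float | None = None
    p_permutation_fwer: float | None = None
    n_boot: int | None = None
    n_perm: int | None = None
    seed: int | None = None


@lru_cache(maxsize=200_000)
def _cached_fisher(a: int, b: int, c: int, d: int) -> float:
    return fisher_exact_2x2(((a, b), (c, d)))


def pathway_mutation_matrix(
    high_impact: dict[str, list[MutationRecord]],
    pathways: PathwayCollection,
) -> pd.DataFrame:
    """Binary samples x pathways matrix of high-impact pathway mutation."""
    samples = list(high_impact)
    data = np.zeros((len(samples), len(pathways)), dtype=int)
    for i, s in enumerate(samples):
        genes = {m.gene for m in high_impact[s]}
        for j, name in enumerate(pathways):
            if genes & pathways[name]:
                data[i, j] = 1
    return pd.DataFrame(data, index=samples, columns=list(pathways))


def merge_pathways(
    collection: PathwayCollection, names: list[str], merged_name: str
) -> PathwayCollection:
    """Add the union of named gene sets under ``merged_name`` (originals kept)."""
    unknown = [n for n in names if n not in collection]
    if unknown:
        raise KeyError(f"unknown pathway name(s): {unknown}")
    merged = set().union(*(collection[n] for n in names))
    out = dict(collection)
    out[merged_name] = merged
    return PathwayCollection(out)


def _tables(matrix: pd.DataFrame, response: np.ndarray) -> np.ndarray:
    """Per-pathway 2x2 tables [[mut&pCR, mut&RD], [wt&pCR, wt&RD]]."""
    m = matrix.to_numpy(dtype=bool)
    r = response.astype(bool)
    a = (m & r[:, None]).sum(axis=0)
    b = (m & ~r[:, None]).sum(axis=0)
    c = (~m & r[:, None]).sum(axis=0)
    d = (~m & ~r[:, None]).sum(axis=0)
    return np.stack([a, b, c, d], axis=1)


def _fisher_ps(tables: np.ndarray) -> np.ndarray:
    return np.array([_cached_fisher(*map(int, t)) for t in tables])


def associate_response(
    matrix: pd.DataFrame, response: pd.Series
) -> list[AssociationResult]:
    """Fisher exact association of each pathway with response, Bonferroni-adjusted."""
    response = response.loc[matrix.index]
    r = response.to_numpy(dtype=bool)
    if r.all() or not r.any():
        raise ValueError("both response classes must be present")
    tables = _tables(matrix, r)
    ps = _fisher_ps(tables)
    n = len(matrix.columns)
    return [
        AssociationResult(
            pathway=name,
            table=((int(t[0]), int(t[1])), (int(t[2]), int(t[3]))),
            p_fisher=float(p),
            p_bonferroni=float(min(1.0, p * n)),
        )
        for name, t, p in zip(matrix.columns, tables, ps)
    ]


def bootstrap_robustness(
    matrix: pd.DataFrame,
    response: pd.Series,
    n_boot: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Fraction of patient bootstrap resamples with Fisher p < 0.05 per pathway.

    Resampling is with replacement and unstratified; a resample with a
    single response class yields p = 1 for every pathway.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    response = response.loc[matrix.index].to_numpy(dtype=bool)
    m = matrix.to_numpy(dtype=bool)
    n_samples = m.shape[0]
    rng = np.random.default_rng(seed)
    hits = np.zeros(m.shape[1])
    for _ in range(n_boot):
        idx = rng.integers(0, n_samples, size=n_samples)
        r = response[idx]
        if r.all() or not r.any():
            continue  # degenerate resample: p = 1 everywhere
        tables = _tables(pd.DataFrame(m[idx]), r)
        hits += _fisher_ps(tables) < 0.05
    return pd.Series(hits / n_boot, index=matrix.columns)


def permutation_significance(
    matrix: pd.DataFrame,
    response: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Label-permutation p-values per pathway (add-one estimator).

    Returns a DataFrame with ``p_permutation`` (per-pathway) and
    ``p_permutation_fwer`` (family-wise: rank of the observed p against
    the per-permutation minimum p across pathways).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    response = response.loc[matrix.index].to_numpy(dtype=bool)
    m = matrix.to_numpy(dtype=bool)
    obs = _fisher_ps(_tables(pd.DataFrame(m), response))
    rng = np.random.default_rng(seed)
    count = np.zeros(m.shape[1])
    count_fwer = np.zeros(m.shape[1])
    for _ in range(n_perm):
        r = rng.permutation(response)
        ps = _fisher_ps(_tables(pd.DataFrame(m), r))
        count += ps <= obs + 1e-12
        count_fwer += ps.min() <= obs + 1e-12
    return pd.DataFrame(
        {
            "p_permutation": (1.0 + count) / (n_perm + 1.0),
            "p_permutation_fwer": (1.0 + count_fwer) / (n_perm + 1.0),
        },
        index=matrix.columns,
    )


def association_table(results: list[AssociationResult]) -> pd.DataFrame:
    rows = [
        {
            "pathway": r.pathway,
            "mut_pcr": r.table[0][0],
            "mut_rd": r.table[0][1],
            "wt_pcr": r.table[1][0],
            "wt_rd": r.table[1][1],
            "p_fisher": r.p_fisher,
            "p_bonferroni": r.p_bonferroni,
            "bootstrap_frequency": r.bootstrap_frequency,
            "p_permutation": r.p_permutation,
            "p_permutation_fwer": r.p_permutation_fwer,
        }
        for r in results
    ]
    return pd.DataFrame(rows).sort_values("p_fisher", kind="stable").reset_index(
        drop=True
    )
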