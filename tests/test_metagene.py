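"""Metagene derivation, scoring, dichotomization, and evaluation."""

import numpy as np
import pandas as pd
import pytest

from tnbcsens.metagene import (
    IMMUNE_GENES,
    MetageneSignature,
    classifier_performance,
    differential_expression,
    filter_low_expression,
    immune_metagene,
    metagene_score,
)
from tnbcsens.models import ExpressionMatrix


def _matrix(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


def test_low_expression_filter_rules(rng):
    m = _matrix(
        np.vstack(
            [
                np.zeros(4),  # excluded
                np.full(4, 10.0),
                np.full(4, 2.5),  # exactly 0.25 x overall median -> kept
                np.full(4, 30.0),
            ]
        )
    )
    overall = np.median(m.values.to_numpy())
    kept = filter_low_expression(m)
    assert "G0" not in kept
    assert "G2" in kept  # boundary >= rule
    # brute-force re-evaluation
    expected = [
        g
        for g in m.genes
        if np.median(m.values.loc[g].to_numpy()) >= 0.25 * overall
    ]
    assert kept == expected


def test_low_expression_filter_random_matches_bruteforce(rng):
    m = _matrix(rng.uniform(0, 50, size=(100, 12)))
    overall = np.median(m.values.to_numpy())
    expected = [
        g for g in m.genes if np.median(m.values.loc[g].to_numpy()) >= 0.25 * overall
    ]
    assert filter_low_expression(m) == expected


def test_degenerate_all_zero_matrix():
    with pytest.raises(ValueError):
        filter_low_expression(_matrix(np.zeros((3, 3))))


def test_differential_expression_null_and_planted(rng):
    n = 20
    base = rng.lognormal(5, 0.3, size=(50, 2 * n))
    base[0, :] = 100.0  # identical in both groups
    base[1, :n] *= 4.0  # planted 4-fold up in group 1
    m = _matrix(base)
    groups = pd.Series([1] * n + [0] * n, index=m.samples)
    sig = differential_expression(m, groups, apply_low_expression_filter=False)
    assert "G0" not in sig.up_genes | sig.down_genes
    assert "G1" in sig.up_genes


def test_differential_expression_group_size():
    m = _matrix(np.ones((5, 5)) * 10)
    groups = pd.Series([1, 1, 0, 0, 0], index=m.samples)
    with pytest.raises(ValueError):
        differential_expression(m, groups)


def test_metagene_score_cancellation_and_shift_invariance(rng):
    vals = rng.uniform(1, 100, size=(4, 10))
    vals[2:] = vals[:2]  # down genes identical to up genes per sample
    m = _matrix(vals)
    sig = MetageneSignature(
        up_genes=frozenset(["G0", "G1"]),
        down_genes=frozenset(["G2", "G3"]),
        derivation_p_cutoff=0.002,
        low_expression_fraction=0.25,
    )
    scores = metagene_score(m, sig)
    assert np.allclose(scores.scores.to_numpy(), 0.0)

    # adding a constant in log space (x -> 2^c (x+1) - 1) leaves scores unchanged
    vals2 = rng.uniform(1, 100, size=(4, 10))
    m2 = _matrix(vals2)
    shifted = _matrix(np.power(2.0, 1.7) * (vals2 + 1.0) - 1.0)
    s1 = metagene_score(m2, sig).scores.to_numpy()
    s2 = metagene_score(shifted, sig).scores.to_numpy()
    assert np.allclose(s1, s2, atol=1e-9)


def test_metagene_median_dichotomy(rng):
    m = _matrix(rng.uniform(1, 100, size=(6, 40)))
    sig = MetageneSignature(
        up_genes=frozenset(["G0", "G1", "G2"]),
        down_genes=frozenset(["G3", "G4", "G5"]),
        derivation_p_cutoff=0.002,
        low_expression_fraction=0.25,
    )
    scores = metagene_score(m, sig)
    assert (scores.calls == "high").sum() == 20  # floor(40/2) for distinct scores
    assert ((scores.scores > scores.cohort_median) == (scores.calls == "high")).all()


def test_metagene_requires_signature_genes():
    m = _matrix(np.ones((2, 4)))
    sig = MetageneSignature(
        up_genes=frozenset(["ABSENT1"]),
        down_genes=frozenset(["ABSENT2"]),
        derivation_p_cutoff=0.002,
        low_expression_fraction=0.25,
    )
    with pytest.raises(ValueError):
        metagene_score(m, sig)


def test_up_down_disjoint_enforced():
    with pytest.raises(ValueError):
        MetageneSignature(
            up_genes=frozenset(["A"]),
            down_genes=frozenset(["A"]),
            derivation_p_cutoff=0.002,
            low_expression_fraction=0.25,
        )


def test_immune_metagene_value_and_monotonicity(rng):
    v = 7.0
    vals = np.full((6, 3), v)
    m = _matrix(vals, genes=list(IMMUNE_GENES))
    scores = immune_metagene(m)
    assert np.allclose(scores.to_numpy(), np.log2(v + 1))

    vals2 = vals.copy()
    vals2[0, 0] *= 2  # doubling one gene raises that sample's score
    m2 = _matrix(vals2, genes=list(IMMUNE_GENES))
    assert immune_metagene(m2).iloc[0] > scores.iloc[0]


def test_immune_metagene_bruteforce(rng):
    vals = rng.uniform(1, 50, size=(6, 8))
    m = _matrix(vals, genes=list(IMMUNE_GENES))
    expected = np.log2(vals + 1).mean(axis=0)
    assert np.allclose(immune_metagene(m).to_numpy(), expected)


def test_immune_metagene_requires_four_genes():
    m = _matrix(np.ones((3, 2)), genes=list(IMMUNE_GENES[:3]))
    with pytest.raises(ValueError):
        immune_metagene(m)


def test_classifier_performance_counting(rng):
    idx = [f"s{i}" for i in range(50)]
    truth = pd.Series(rng.random(50) < 0.5, index=idx)
    calls = pd.Series(rng.random(50) < 0.5, index=idx)
    if truth.all() or not truth.any():
        truth.iloc[0] = not truth.iloc[0]
    sens, spec = classifier_performance(calls, truth)
    tp = int((calls & truth).sum())
    fn = int((~calls & truth).sum())
    tn = int((~calls & ~truth).sum())
    fp = int((calls & ~truth).sum())
    assert sens == pytest.approx(tp / (tp + fn))
    assert spec == pytest.approx(tn / (tn + fp))

    perfect = classifier_performance(truth, truth)
    assert perfect == (1.0, 1.0)
    assert classifier_performance(~truth, truth) == (0.0, 0.0)
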