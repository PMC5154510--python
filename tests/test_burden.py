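"""Mutation rate, MATH, clonal decomposition, and CMB categories."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tnbcsens.burden import (
    BurdenMetrics,
    ClonalDecomposition,
    CmbCategory,
    DecompositionUnavailableError,
    UndefinedScoreError,
    assign_cmb,
    avg_mutations_per_clone,
    decompose_clones,
    math_score,
    mutation_rate,
)
from tnbcsens.stats import spearman_corr

from conftest import make_record


@pytest.mark.parametrize(
    "n,bases,expected",
    [(30, 30_000_000, 1.0), (0, 30_000_000, 0.0), (45, 33_000_000, 45 / 33)],
)
def test_mutation_rate_per_megabase(n, bases, expected):
    assert mutation_rate(n, bases) == pytest.approx(expected)


def test_mutation_rate_requires_positive_coverage():
    with pytest.raises(ValueError):
        mutation_rate(10, 0)


def test_math_zero_dispersion():
    assert math_score([0.3, 0.3, 0.3, 0.3]) == 0.0


def test_math_hand_computed():
    # MAFs [0.10, 0.20, 0.40, 0.50]: median 0.30, |dev| [.2,.1,.1,.2],
    # MAD 0.15 -> 100 * 1.4826 * 0.15 / 0.30 = 74.13
    assert math_score([0.10, 0.20, 0.40, 0.50]) == pytest.approx(74.13)


def test_math_applies_min_maf_filter():
    # values below 0.075 are discarded before the score
    with_low = math_score([0.01, 0.02, 0.10, 0.20, 0.40, 0.50])
    assert with_low == pytest.approx(math_score([0.10, 0.20, 0.40, 0.50]))


def test_math_too_few_values():
    with pytest.raises(UndefinedScoreError):
        math_score([0.01, 0.02, 0.3, 0.4])  # only 2 survive the filter


@given(
    st.lists(st.floats(0.08, 0.3), min_size=3, max_size=30),
    st.floats(1.01, 2.0),
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_math_scale_and_permutation_invariance(mafs, c):
    base = math_score(mafs)
    scaled = math_score([min(m * c, 1.0) for m in mafs]) if max(mafs) * c <= 1 else None
    if scaled is not None:
        assert scaled == pytest.approx(base, abs=1e-9)
    assert math_score(list(reversed(mafs))) == pytest.approx(base, abs=1e-12)


def _simulate_clones(rng, fractions, n_per_clone, depth):
    recs = []
    pos = 1
    for f in fractions:
        for _ in range(n_per_clone):
            a = max(1, rng.binomial(depth, f))
            recs.append(make_record(alt=int(a), depth=depth, pos=pos))
            pos += 1
    return recs


def test_single_clone_recovery(rng):
    recs = _simulate_clones(rng, [0.4], 100, 100)
    d = decompose_clones(recs, seed=1)
    assert d.k == 1
    assert d.cluster_means[0] == pytest.approx(0.4, abs=0.03)
    assert d.avg_mutations_per_clone == len(recs)


def test_two_clone_recovery(rng):
    recs = _simulate_clones(rng, [0.45, 0.12], 60, 150)
    d = decompose_clones(recs, seed=2)
    assert d.k == 2
    assert sorted(d.cluster_means)[0] == pytest.approx(0.12, abs=0.03)
    assert sorted(d.cluster_means)[1] == pytest.approx(0.45, abs=0.03)
    assert sum(d.cluster_sizes) == len(d.assignments) == 120


def test_decomposition_needs_five_mutations(rng):
    recs = _simulate_clones(rng, [0.3], 4, 100)
    with pytest.raises(DecompositionUnavailableError):
        decompose_clones(recs, seed=1)


def test_decomposition_excludes_low_depth_and_high_maf(rng):
    good = _simulate_clones(rng, [0.3], 20, 150)
    excluded = [
        make_record(alt=2, depth=8, pos=1000),  # below 10x
        make_record(alt=90, depth=100, pos=1001),  # MAF 0.9 >= 0.6
    ]
    d = decompose_clones(good + excluded, seed=3)
    assert len(d.assignments) == 20


def test_decomposition_seed_reproducible(rng):
    recs = _simulate_clones(rng, [0.45, 0.12], 40, 150)
    d1 = decompose_clones(recs, seed=9)
    d2 = decompose_clones(recs, seed=9)
    assert d1 == d2


def _decomp(sizes):
    n = sum(sizes)
    assigns = [i for i, s in enumerate(sizes) for _ in range(s)]
    return ClonalDecomposition(
        k=len(sizes),
        cluster_means=tuple(0.1 * (i + 1) for i in range(len(sizes))),
        cluster_sizes=tuple(sizes),
        assignments=tuple(assigns),
        avg_mutations_per_clone=0.0,
        log_likelihood=0.0,
        bic=0.0,
        seed=0,
    )


@pytest.mark.parametrize(
    "sizes,expected", [([80], 80.0), ([50, 50], 50.0), ([30, 10], 25.0)]
)
def test_avg_mutations_per_clone(sizes, expected):
    assert avg_mutations_per_clone(_decomp(sizes)) == pytest.approx(expected)


@given(st.lists(st.integers(1, 50), min_size=1, max_size=5))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_avg_mutations_per_clone_bounded(sizes):
    val = avg_mutations_per_clone(_decomp(sizes))
    total = sum(sizes)
    assert val <= total + 1e-9
    assert (val == pytest.approx(total)) == (len(sizes) == 1)


def _metrics(mrs, maths):
    return [
        BurdenMetrics(sample_id=f"s{i}", mutation_rate=mr, math_score=ma)
        for i, (mr, ma) in enumerate(zip(mrs, maths))
    ]


def test_cmb_hand_evaluated():
    cohort = assign_cmb(_metrics([1, 2, 10, 20], [50, 40, 10, 5]))
    assert [b.cmb for b in cohort] == [
        CmbCategory.LOW,
        CmbCategory.LOW,
        CmbCategory.HIGH,
        CmbCategory.HIGH,
    ]


def test_cmb_degenerate_cohort_all_intermediate():
    cohort = assign_cmb(_metrics([3, 3, 3, 3], [20, 20, 20, 20]))
    assert all(b.cmb == CmbCategory.INTERMEDIATE for b in cohort)


@given(
    st.lists(
        st.tuples(st.floats(0.1, 30), st.floats(1, 100)), min_size=2, max_size=30
    )
)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_cmb_partitions_cohort(pairs):
    cohort = assign_cmb(_metrics([p[0] for p in pairs], [p[1] for p in pairs]))
    assert all(b.cmb is not None for b in cohort)
    assert len(cohort) == len(pairs)


def test_math_correlates_with_clone_count(rng):
    """More clones -> higher allele-fraction dispersion -> higher MATH."""
    maths, ks = [], []
    for i in range(50):
        n_clones = 1 + i % 4
        fractions = [0.45] + list(rng.uniform(0.08, 0.3, size=n_clones - 1))
        recs = _simulate_clones(rng, fractions, 25, 150)
        d = decompose_clones(recs, k_max=5, n_restarts=4, seed=100 + i)
        maths.append(math_score([r.maf for r in recs]))
        ks.append(d.k)
    assert spearman_corr(maths, ks) > 0
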