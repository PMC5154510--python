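"""Wild-type BRCA abundance, thresholds, and deficiency calls."""

import numpy as np
import pytest

from tnbcsens.brca import (
    BRCA1_PROMOTER_PROBES,
    BrcaGeneEvidence,
    ThresholdUnavailableError,
    call_brca_deficiency,
    call_cohort,
    deficiency_threshold,
    methylation_score,
    select_representative_mutation,
    wt_expression,
)
from tnbcsens.simulate import SimulationConfig, simulate_cohort

from conftest import make_record


def _betas(values):
    return dict(zip(BRCA1_PROMOTER_PROBES, values))


@pytest.mark.parametrize(
    "values,score,status",
    [
        ((0.1, 0.1, 0.1, 0.1), 0.1, "unmethylated"),
        ((0.5, 0.3, 0.4, 0.2), 0.35, "methylated"),
        ((0.2, 0.2, 0.2, 0.2), 0.2, "unmethylated"),  # boundary: > 0.2 strict
    ],
)
def test_methylation_score(values, score, status):
    s, st_ = methylation_score(_betas(values))
    assert s == pytest.approx(score) and st_ == status


def test_methylation_missing_probes():
    s, status = methylation_score(_betas((0.4, np.nan, np.nan, np.nan)))
    assert s is None and status == "missing"
    s, status = methylation_score(_betas((0.4, 0.2, np.nan, np.nan)))
    assert s == pytest.approx(0.3) and status == "methylated"


def test_methylation_rejects_unknown_probe():
    with pytest.raises(ValueError):
        methylation_score({"cg000": 0.5, BRCA1_PROMOTER_PROBES[0]: 0.5})


@pytest.mark.parametrize("total,maf,expected", [(100, 0, 100), (100, 1, 0), (80, 0.25, 60)])
def test_wt_expression(total, maf, expected):
    assert wt_expression(total, maf) == pytest.approx(expected)


def test_wt_expression_maf_domain():
    with pytest.raises(ValueError):
        wt_expression(100, 1.5)


def test_representative_mutation_highest_rna_maf():
    a = make_record(maf=0.3, pos=1, rna_maf=0.2)
    b = make_record(maf=0.3, pos=2, rna_maf=0.7)
    assert select_representative_mutation([a, b]) is b
    assert select_representative_mutation([a]) is a


def test_representative_mutation_tie_breaks_on_dna_maf():
    a = make_record(alt=30, depth=100, pos=1, rna_maf=0.5)
    b = make_record(alt=40, depth=100, pos=2, rna_maf=0.5)
    assert select_representative_mutation([a, b]) is b


def _evidence(sample_id, gene, carrier, wt):
    return BrcaGeneEvidence(
        sample_id=sample_id,
        gene=gene,
        has_deleterious_mutation=carrier,
        representative_maf=0.5 if carrier else None,
        total_expression=wt * 2 if carrier else wt,
        wt_expression=wt,
    )


def test_threshold_is_max_over_carriers():
    cohort = [_evidence(f"s{i}", "BRCA1", True, w) for i, w in enumerate([12, 40, 25])]
    cohort += [_evidence("n1", "BRCA1", False, 500)]
    assert deficiency_threshold(cohort, "BRCA1") == 40
    assert deficiency_threshold([_evidence("s", "BRCA1", True, 7)], "BRCA1") == 7


def test_threshold_brute_force_on_random_cohorts(rng):
    for _ in range(20):
        cohort = [
            _evidence(f"s{i}", "BRCA2", bool(rng.random() < 0.4), float(w))
            for i, w in enumerate(rng.uniform(1, 100, size=15))
        ]
        carriers = [e.wt_expression for e in cohort if e.has_deleterious_mutation]
        if not carriers:
            with pytest.raises(ThresholdUnavailableError):
                deficiency_threshold(cohort, "BRCA2")
        else:
            assert deficiency_threshold(cohort, "BRCA2") == max(carriers)


def _call(b1, thresholds):
    ev = {"BRCA1": b1, "BRCA2": _evidence(b1.sample_id, "BRCA2", False, 1000)}
    return call_brca_deficiency(ev, thresholds)


def test_carrier_deficient_regardless_of_expression():
    call = _call(_evidence("s", "BRCA1", True, 9999), {"BRCA1": 40, "BRCA2": None})
    assert call.brca1_deficient and call.brca_deficient
    assert call.rationale["BRCA1"] == ["mutation"]


def test_noncarrier_below_threshold_deficient():
    call = _call(_evidence("s", "BRCA1", False, 30), {"BRCA1": 40, "BRCA2": None})
    assert call.brca1_deficient
    assert call.rationale["BRCA1"] == ["low_wt_expression"]


def test_threshold_boundary_strict():
    call = _call(_evidence("s", "BRCA1", False, 40), {"BRCA1": 40, "BRCA2": None})
    assert not call.brca1_deficient


def test_monotonicity_in_wt_expression():
    thresholds = {"BRCA1": 40, "BRCA2": None}
    deficient_at = [
        _call(_evidence("s", "BRCA1", False, w), thresholds).brca1_deficient
        for w in np.linspace(0, 80, 30)
    ]
    # once normal, stays normal as expression rises
    assert deficient_at == sorted(deficient_at, reverse=True)


def test_cohort_calls_recover_truth():
    cohort = simulate_cohort(SimulationConfig(n_samples=60), seed=21)
    calls, thresholds = call_cohort(
        cohort.mutations, cohort.expression, cohort.methylation
    )
    truth = {s.sample_id: s.brca_deficient for s in cohort.truth.samples}
    carriers = {s.sample_id for s in cohort.truth.samples if s.carrier_gene}
    acc = np.mean([c.brca_deficient == truth[c.sample_id] for c in calls])
    assert acc >= 0.95
    # every mutation carrier is called deficient (rule 1 dominates)
    assert all(c.brca_deficient for c in calls if c.sample_id in carriers)
    assert thresholds["BRCA1"] is not None
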