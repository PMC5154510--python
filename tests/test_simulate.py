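"""The synthetic cohort generator: determinism and planted-effect regimes."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from tnbcsens.metagene import differential_expression
from tnbcsens.signatures import synthetic_signature_reference
from tnbcsens.simulate import (
    SampleTruth,
    SimulationConfig,
    draw_truth,
    simulate_cohort,
    simulate_expression,
    simulate_mutations,
    simulate_outcomes,
    tcga_like_config,
)
from tnbcsens.stats import fisher_exact_2x2


def _truth(**kwargs):
    defaults = dict(
        sample_id="s0",
        n_clones=1,
        clone_fractions=(0.5,),
        clone_mutation_counts=(200,),
        purity=0.8,
        signature_mixture=(0.25, 0.25, 0.25, 0.25),
        brca_deficient=False,
        carrier_gene=None,
        rna_maf=None,
        pathway_mutated=False,
    )
    defaults.update(kwargs)
    return SampleTruth(**defaults)


def test_single_clone_mean_maf(rng):
    config = SimulationConfig(depth_mean=1000.0)
    recs = simulate_mutations(
        config, _truth(), synthetic_signature_reference(), rng
    )
    mafs = [r.maf for r in recs]
    assert np.mean(mafs) == pytest.approx(0.4, abs=0.02)  # purity 0.8 x fraction 0.5


def test_zero_mutations_empty(rng):
    truth = _truth(clone_mutation_counts=(0,))
    recs = simulate_mutations(
        SimulationConfig(), truth, synthetic_signature_reference(), rng
    )
    assert recs == []


def test_cohort_seed_determinism():
    c1 = simulate_cohort(SimulationConfig(n_samples=5), seed=42)
    c2 = simulate_cohort(SimulationConfig(n_samples=5), seed=42)
    assert c1.mutations == c2.mutations
    assert c1.expression == c2.expression
    assert c1.clinical == c2.clinical


def test_contexts_follow_signature_mixture(rng):
    """A pure-signature sample's context histogram matches the loading."""
    reference = synthetic_signature_reference()
    truth = _truth(signature_mixture=(0.0, 0.0, 1.0, 0.0),
                   clone_mutation_counts=(3000,))
    config = SimulationConfig(silent_fraction=0.0)
    recs = simulate_mutations(config, truth, reference, rng)
    labels = [r.trinucleotide_context for r in recs if r.trinucleotide_context]
    # the BRCA-like column is near-uniform: expected count ~ n/96 everywhere
    counts = pd.Series(labels).value_counts()
    assert counts.max() < 3 * len(labels) / 96


def test_null_fold_change_yields_type_i_rate():
    config = SimulationConfig(n_samples=60, fold_change=1.0, n_genes=1500)
    truth, rng = draw_truth(config, seed=3)
    expr = simulate_expression(config, truth, rng)
    labels = pd.Series(
        {s.sample_id: int(s.brca_deficient) for s in truth.samples}
    )
    sig = differential_expression(expr, labels, apply_low_expression_filter=False)
    rate = (len(sig.up_genes) + len(sig.down_genes)) / 1500
    assert rate < 0.01  # ~ the 0.002 nominal rate, allowing binomial noise


def test_planted_genes_recovered_at_high_fold_change():
    config = SimulationConfig(n_samples=60, fold_change=4.0)
    truth, rng = draw_truth(config, seed=4)
    expr = simulate_expression(config, truth, rng)
    labels = pd.Series(
        {s.sample_id: int(s.brca_deficient) for s in truth.samples}
    )
    sig = differential_expression(expr, labels)
    planted_up = set(truth.planted_up_genes)
    planted_down = set(truth.planted_down_genes)
    recovered = len(planted_up & sig.up_genes) + len(planted_down & sig.down_genes)
    assert recovered >= 0.9 * (len(planted_up) + len(planted_down))


def test_pathway_effect_detectable_at_discovery_scale():
    """Strong response coefficient on the pathway flag is detectable by
    Fisher in a 29-sample cohort."""
    config = SimulationConfig(pcr_coef_pathway=6.0, pcr_intercept=-3.0)
    detected = 0
    for seed in range(20):
        truth, rng = draw_truth(config, seed=200 + seed)
        clinical = simulate_outcomes(config, truth, rng)
        a = b = c = d = 0
        for s in truth.samples:
            pcr = clinical[s.sample_id].response.value == "pCR"
            if s.pathway_mutated:
                a, b = a + pcr, b + (not pcr)
            else:
                c, d = c + pcr, d + (not pcr)
        detected += fisher_exact_2x2(((a, b), (c, d))) < 0.05
    assert detected >= 19  # >= 95% of cohorts


def test_tcga_like_preset():
    config = tcga_like_config()
    assert config.n_samples == 101
    assert dataclasses.replace(config, n_samples=29) == SimulationConfig()


def test_expression_construction_separates_brca_groups(default_cohort):
    """Expression-only deficient samples sit below the carriers' max
    wild-type abundance; normals sit above it."""
    truth = default_cohort.truth
    expr = default_cohort.expression.values
    carrier_wt = [
        expr.loc["BRCA1", s.sample_id] * (1 - s.rna_maf)
        for s in truth.samples
        if s.carrier_gene == "BRCA1"
    ]
    max_wt = max(carrier_wt)
    for s in truth.samples:
        if s.carrier_gene is not None:
            continue
        val = expr.loc["BRCA1", s.sample_id]
        if s.brca_deficient:
            assert val < max_wt
        else:
            assert val > max_wt
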