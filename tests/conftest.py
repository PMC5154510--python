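import numpy as np
import pytest

from tnbcsens.models import MutationRecord, VariantClass
from tnbcsens.signatures import synthetic_signature_reference
from tnbcsens.simulate import SimulationConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def reference():
    return synthetic_signature_reference()


@pytest.fixture(scope="session")
def default_cohort():
    """One default 29-sample synthetic cohort, shared across tests."""
    return simulate_cohort(SimulationConfig(), seed=1)


def make_record(
    maf=None,
    alt=None,
    depth=100,
    sample_id="s1",
    gene="G0001",
    variant_class=VariantClass.MISSENSE,
    pos=1,
    **kwargs,
):
    """Build a consistent MutationRecord from either a MAF or counts."""
    if alt is None:
        alt = int(round((maf or 0.0) * depth))
    maf = alt / depth
    return MutationRecord(
        sample_id=sample_id,
        chrom="1",
        pos=pos,
        ref_allele="C",
        alt_allele="T",
        gene=gene,
        variant_class=variant_class,
        alt_count=alt,
        ref_count=depth - alt,
        maf=maf,
        **kwargs,
    )


@pytest.fixture
def record_factory():
    return make_record
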