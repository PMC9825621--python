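import numpy as np
import pytest

from somaclass.simulate import (
    AncestryGroup,
    CohortConfig,
    SubtypeSpec,
    simulate_cohort,
)
from somaclass.variant_io import NON_SBS, CopyNumberSegment, VariantCall


def make_variant(**overrides) -> VariantCall:
    """A valid SNV VariantCall with overridable fields (test helper)."""
    base = dict(
        sample_id="S1",
        chrom="chr1",
        pos=100,
        ref="C",
        alt="T",
        variant_class="SNV",
        t_alt_freq=0.4,
        t_maj_allele=0.6,
        depth=100,
        caller_filter="PASS",
        fpfilter="PASS",
        ontology="missense",
        db_freqs={},
        cosmic_count=0,
        tri_context="ACG",
        truth_label=None,
    )
    base.update(overrides)
    if base["variant_class"] != "SNV":
        base["tri_context"] = NON_SBS
    return VariantCall(**base)


@pytest.fixture
def variant_factory():
    return make_variant


@pytest.fixture
def diploid_segment():
    return CopyNumberSegment(sample_id="S1", chrom="chr1", start=0, end=1_000_000, log2_ratio=0.0)


@pytest.fixture(scope="session")
def tiny_cohort_config():
    """A fast 9-patient cohort exercising all simulator machinery."""
    return CohortConfig(
        subtypes={
            "low": SubtypeSpec(5, (1.0, 4.0)),
            "high": SubtypeSpec(4, (5.0, 12.0)),
        },
        ancestry_groups={
            "grpA": AncestryGroup(fraction=0.6, r_db=0.995),
            "grpB": AncestryGroup(fraction=0.4, r_db=0.85),
        },
        exome_mb=10.0,
        rare_germline_range=(50, 150),
        ancestry_site_mean=150,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_cohort_config):
    return simulate_cohort(tiny_cohort_config, seed=42)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
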