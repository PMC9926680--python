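import pytest

from nephrotriage import pipeline, synthetic_cohort


@pytest.fixture(scope="session")
def fixture_artifacts():
    """The deterministic 191-patient study cohort (in memory)."""
    return synthetic_cohort.build_study_fixture()


@pytest.fixture(scope="session")
def fixture_outcomes(fixture_artifacts):
    return pipeline.run_cohort(fixture_artifacts.data)


@pytest.fixture(scope="session")
def demo_panels():
    return synthetic_cohort.demo_registry()


def make_call(**kw):
    """A VariantCall with innocuous defaults, overridable per test."""
    from nephrotriage.types import Consequence, Genotype, VariantCall

    defaults = dict(
        patient_id="P1",
        chrom="1",
        pos=1000,
        ref="A",
        alt="G",
        gene="NPHS2",
        consequence=Consequence.missense,
        splice_region=False,
        pop_af=0.0,
        vaf=0.5,
        depth=60,
        genotype=Genotype.het,
    )
    defaults.update(kw)
    return VariantCall(**defaults)
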