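"""Filtering cascade: boundary semantics, oracle equivalence, invariances."""

import random

import pytest

from conftest import make_call
from nephrotriage.types import Consequence, FilterConfig, GenePanel, Genotype, PanelEntry, Moi
from nephrotriage.variant_filtering import (
    consequence_filter,
    quality_frequency_filter,
    run_filter_cascade,
)

CFG = FilterConfig()


@pytest.mark.parametrize(
    "consequence,splice,expected",
    [
        (Consequence.synonymous, False, False),
        (Consequence.synonymous, True, True),
        (Consequence.intronic, False, False),
        (Consequence.intronic, True, True),
        (Consequence.missense, False, True),
        (Consequence.nonsense, False, True),
        (Consequence.frameshift, False, True),
        (Consequence.splicing, True, True),
        (Consequence.other, False, False),
    ],
)
def test_consequence_filter(consequence, splice, expected):
    call = make_call(consequence=consequence, splice_region=splice)
    assert consequence_filter(call, CFG) is expected


@pytest.mark.parametrize(
    "pop_af,vaf,depth,expected",
    [
        (0.02, 0.5, 60, False),   # common variant fails the <1% rule
        (0.01, 0.5, 60, False),   # boundary: "less than 1%" is strict
        (0.0, 0.19, 100, False),  # VAF below 0.2
        (0.0, 0.2, 100, True),    # VAF boundary is inclusive
        (0.005, 0.5, 20, True),   # depth boundary is inclusive
        (0.0, 0.5, 19, False),    # depth below 20
    ],
)
def test_quality_frequency_boundaries(pop_af, vaf, depth, expected):
    call = make_call(pop_af=pop_af, vaf=vaf, depth=depth)
    assert quality_frequency_filter(call, CFG) is expected


def test_homozygous_gets_no_vaf_exemption():
    call = make_call(genotype=Genotype.hom_alt, vaf=0.15, depth=80)
    assert quality_frequency_filter(call, CFG) is False


def test_cnv_records_skip_vaf_depth_but_not_frequency():
    cnv = make_call(
        consequence=Consequence.cnv_del, alt="<DEL>", ref="N", vaf=None, depth=None
    )
    assert quality_frequency_filter(cnv, CFG) is True
    common_cnv = make_call(
        consequence=Consequence.cnv_del, alt="<DEL>", ref="N",
        vaf=None, depth=None, pop_af=0.05,
    )
    assert quality_frequency_filter(common_cnv, CFG) is False


PANEL = GenePanel(
    name="t",
    category="t",
    entries=[PanelEntry("NPHS2", Moi.AR, "1"), PanelEntry("PKD1", Moi.AD, "16")],
)


def _random_call(rng, i):
    return make_call(
        pos=1000 + i,
        gene=rng.choice(["NPHS2", "PKD1", "TTN"]),
        consequence=rng.choice(list(Consequence)),
        splice_region=rng.random() < 0.3,
        pop_af=rng.choice([0.0, 0.001, 0.009, 0.01, 0.02, 0.2]),
        vaf=rng.choice([0.05, 0.19, 0.2, 0.45, 1.0]),
        depth=rng.choice([5, 19, 20, 60, 200]),
    )


def test_cascade_equals_conjunction_of_predicates():
    """Oracle equivalence: the cascade must keep exactly the calls that
    pass each predicate evaluated independently, over 1000 random calls."""
    rng = random.Random(20240917)
    calls = [_random_call(rng, i) for i in range(1000)]
    survivors, trace = run_filter_cascade(calls, PANEL, CFG)
    expected = [
        c
        for c in calls
        if c.gene in PANEL.genes
        and consequence_filter(c, CFG)
        and quality_frequency_filter(c, CFG)
    ]
    assert [c.key for c in survivors] == [c.key for c in expected]
    # every call has a trace; failures name exactly one first-failing filter
    for c in calls:
        steps = trace.steps[c.key]
        fails = [name for name, ok in steps if not ok]
        assert len(fails) <= 1
        if fails:
            assert steps[-1] == (fails[0], False)


def test_survivors_invariant_under_permutation():
    rng = random.Random(7)
    calls = [_random_call(rng, i) for i in range(200)]
    base = {c.key for c in run_filter_cascade(calls, PANEL, CFG)[0]}
    shuffled = calls[:]
    rng.shuffle(shuffled)
    assert {c.key for c in run_filter_cascade(shuffled, PANEL, CFG)[0]} == base


def test_relaxing_thresholds_never_shrinks_survivors():
    """Monotonicity over randomized configurations: any relaxation of
    (max_pop_af up, min_vaf down, min_depth down) can only add survivors."""
    rng = random.Random(99)
    calls = [_random_call(rng, i) for i in range(300)]
    for _ in range(25):
        tight = FilterConfig(
            max_pop_af=rng.uniform(0.001, 0.05),
            min_vaf=rng.uniform(0.05, 0.5),
            min_depth=rng.randint(5, 50),
        )
        relaxed = FilterConfig(
            max_pop_af=min(1.0, tight.max_pop_af * rng.uniform(1.0, 3.0)),
            min_vaf=tight.min_vaf * rng.uniform(0.3, 1.0),
            min_depth=rng.randint(0, tight.min_depth),
        )
        s_tight = {c.key for c in run_filter_cascade(calls, PANEL, tight)[0]}
        s_relax = {c.key for c in run_filter_cascade(calls, PANEL, relaxed)[0]}
        assert s_tight <= s_relax


def test_cascade_idempotent_and_empty_input():
    assert run_filter_cascade([], PANEL, CFG)[0] == []
    rng = random.Random(3)
    calls = [_random_call(rng, i) for i in range(50)]
    once, _ = run_filter_cascade(calls, PANEL, CFG)
    twice, _ = run_filter_cascade(once, PANEL, CFG)
    assert [c.key for c in twice] == [c.key for c in once]
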