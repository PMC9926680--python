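"""Report decision logic vs an independent brute-force re-implementation."""

import random

import pytest

from conftest import make_call
from nephrotriage.report_classifier import classify_report, outcome_reasons
from nephrotriage.types import (
    AcmgClass,
    CandidateBundle,
    ClassifiedVariant,
    GeneGroup,
    Genotype,
    Moi,
    MoiAssessment,
    MoiReason,
    Outcome,
    PhenotypeFit,
    SegregationResult,
    SegStatus,
)

REASON_OK = {
    MoiReason.ad_het_ok: True,
    MoiReason.ar_hom_ok: True,
    MoiReason.ar_comphet_ok: True,
    MoiReason.xl_hemi_ok: True,
    MoiReason.xld_het_ok: True,
    MoiReason.ar_single_het: False,
    MoiReason.incompatible: False,
}


def _group(
    cls=AcmgClass.C5,
    fit=PhenotypeFit.full,
    moi_reason=MoiReason.ad_het_ok,
    seg=SegStatus.unavailable,
    via="subpanel",
    n_variants=1,
    gene="PKD1",
    pos0=1000,
):
    variants = [
        ClassifiedVariant(
            call=make_call(gene=gene, pos=pos0 + i, genotype=Genotype.het),
            acmg_class=cls,
            computed_class=AcmgClass.C3 if cls is AcmgClass.C3_C4 else cls,
            manual_class=AcmgClass.C3_C4 if cls is AcmgClass.C3_C4 else None,
        )
        for i in range(n_variants)
    ]
    return GeneGroup(
        gene=gene,
        variants=variants,
        moi=MoiAssessment(REASON_OK[moi_reason], moi_reason, Moi.AD),
        segregation=SegregationResult(seg),
        phenotype_fit=fit,
        found_via=via,
    )


def _bundle(*groups):
    return CandidateBundle(patient_id="P1", groups=list(groups))


# --- worked single-group examples ----------------------------------------


@pytest.mark.parametrize(
    "group,expected,reason",
    [
        # pathogenic, full fit, satisfied model -> conclusive
        (_group(AcmgClass.C5, seg=SegStatus.confirmed), Outcome.conclusive, "pathogenic_full_match"),
        # curated C3_C4 gets C4-like weight
        (_group(AcmgClass.C3_C4), Outcome.conclusive, "pathogenic_full_match"),
        # VUS + confirmed segregation + full fit -> conclusive
        (_group(AcmgClass.C3, seg=SegStatus.confirmed), Outcome.conclusive, "c3_segregation_confirmed"),
        # VUS awaiting/lacking segregation -> uncertain
        (_group(AcmgClass.C3, seg=SegStatus.pending), Outcome.uncertain, "c3_segregation_pending"),
        (_group(AcmgClass.C3, seg=SegStatus.unavailable), Outcome.uncertain, "c3_segregation_pending"),
        # pathogenic but only partially matching the phenotype -> uncertain
        (_group(AcmgClass.C4, fit=PhenotypeFit.partial), Outcome.uncertain, "pathogenic_partial_phenotype"),
        # single het in a recessive gene -> inconclusive
        (
            _group(AcmgClass.C4, moi_reason=MoiReason.ar_single_het),
            Outcome.inconclusive,
            "single_het_recessive",
        ),
        # off-phenotype VUS found via the kidneyome -> inconclusive
        (
            _group(AcmgClass.C3, fit=PhenotypeFit.none, via="kidneyome"),
            Outcome.inconclusive,
            "c3_off_phenotype",
        ),
        # refuted segregation sinks the group
        (_group(AcmgClass.C5, seg=SegStatus.refuted), Outcome.inconclusive, "segregation_refuted"),
    ],
)
def test_single_group_rules(group, expected, reason):
    out = classify_report(_bundle(group))
    assert out.outcome is expected
    assert out.reasons == [reason]


def test_empty_bundle_is_negative_exome():
    out = classify_report(_bundle())
    assert out.outcome is Outcome.inconclusive
    assert out.reasons == ["no_variants"]
    assert out.reported_variants == []
    assert not out.variant_positive


def test_conclusive_group_dominates_and_reports_only_its_variants():
    conclusive = _group(AcmgClass.C5, gene="PKD1", pos0=1000)
    vus = _group(AcmgClass.C3, seg=SegStatus.pending, gene="PKD2", pos0=2000)
    out = classify_report(_bundle(conclusive, vus))
    assert out.outcome is Outcome.conclusive
    assert out.reasons == ["pathogenic_full_match"]
    assert out.secondary_reasons == ["c3_segregation_pending"]
    assert {v.call.gene for v in out.reported_variants} == {"PKD1"}


def test_adding_conclusive_group_never_downgrades():
    """Precedence: appending a conclusive-qualifying group to any bundle
    keeps or raises the patient outcome (never lowers it)."""
    rank = {Outcome.inconclusive: 0, Outcome.uncertain: 1, Outcome.conclusive: 2}
    rng = random.Random(5)
    for _ in range(200):
        base_groups = [_random_group(rng, i) for i in range(rng.randint(0, 3))]
        before = classify_report(_bundle(*base_groups)).outcome
        winner = _group(AcmgClass.C5, gene="WT1", pos0=9000)
        after = classify_report(_bundle(*base_groups, winner)).outcome
        assert rank[after] >= rank[before]
        assert after is Outcome.conclusive


# --- brute-force oracle over randomized bundles ---------------------------


def _oracle_group(group):
    """Independent re-statement of the decision rules (a)-(h)."""
    lead = max(
        (v.acmg_class for v in group.variants),
        key=lambda c: ["C1", "C2", "C3", "C3_C4", "C4", "C5"].index(c.value),
    )
    weight = "C4" if lead is AcmgClass.C3_C4 else lead.value
    if group.segregation.status is SegStatus.refuted:  # (h)
        return Outcome.inconclusive
    if group.moi.reason is MoiReason.ar_single_het:  # (e)
        return Outcome.inconclusive
    if weight in ("C4", "C5"):
        if group.phenotype_fit is PhenotypeFit.full and group.moi.satisfied:  # (a)
            return Outcome.conclusive
        if group.phenotype_fit is PhenotypeFit.partial:  # (d)
            return Outcome.uncertain
        return Outcome.inconclusive  # off-phenotype suppressed / model unmet
    if weight == "C3":
        if not group.moi.satisfied:
            return Outcome.inconclusive
        if group.phenotype_fit is PhenotypeFit.full:
            if group.segregation.status is SegStatus.confirmed:  # (b)
                return Outcome.conclusive
            return Outcome.uncertain  # (c)
        if group.phenotype_fit is PhenotypeFit.partial:
            return Outcome.uncertain
        return Outcome.inconclusive  # (f)
    return Outcome.inconclusive  # benign classes


def _oracle_bundle(bundle):
    if not bundle.groups:
        return Outcome.inconclusive
    rank = {Outcome.inconclusive: 0, Outcome.uncertain: 1, Outcome.conclusive: 2}
    return max((_oracle_group(g) for g in bundle.groups), key=rank.get)


def _random_group(rng, i):
    return _group(
        cls=rng.choice(list(AcmgClass)),
        fit=rng.choice(list(PhenotypeFit)),
        moi_reason=rng.choice(list(MoiReason)),
        seg=rng.choice(list(SegStatus)),
        via=rng.choice(["subpanel", "kidneyome"]),
        n_variants=rng.randint(1, 2),
        gene=f"G{i}",
        pos0=1000 * (i + 1),
    )


def test_classifier_matches_brute_force_on_randomized_bundles():
    """2000 randomized bundles: the classifier must agree with the
    independently coded brute-force rules on every one."""
    rng = random.Random(20230213)
    for _ in range(2000):
        bundle = _bundle(*[_random_group(rng, i) for i in range(rng.randint(0, 4))])
        assert classify_report(bundle).outcome is _oracle_bundle(bundle)


def test_classifier_is_deterministic():
    rng = random.Random(11)
    bundle = _bundle(*[_random_group(rng, i) for i in range(3)])
    first = classify_report(bundle)
    assert all(classify_report(bundle) == first for _ in range(5))
    assert outcome_reasons(bundle) == first.reasons
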