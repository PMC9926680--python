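"""MOI assessment truth table, de novo detection, compound-het phasing,
and trio segregation judgments."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_call
from nephrotriage.segregation import (
    assess_moi,
    detect_de_novo,
    evaluate_segregation,
    phase_compound_het,
)
from nephrotriage.types import (
    Genotype,
    Moi,
    MoiReason,
    Phase,
    SegStatus,
    Sex,
    TrioGenotypes,
)


# Hand-coded oracle: (moi, genotype multiset, sex) -> (satisfied, reason).
def _oracle(moi, genotypes, sex):
    het = genotypes.count(Genotype.het)
    hom = genotypes.count(Genotype.hom_alt)
    hemi = genotypes.count(Genotype.hemizygous)
    any_alt = het + hom + hemi
    if moi is Moi.AD:
        return (True, MoiReason.ad_het_ok) if any_alt else (False, MoiReason.incompatible)
    if moi is Moi.AR:
        if hom:
            return (True, MoiReason.ar_hom_ok)
        if het >= 2:
            return (True, MoiReason.ar_comphet_ok)
        if het == 1:
            return (False, MoiReason.ar_single_het)
        return (False, MoiReason.incompatible)
    if moi is Moi.XLR:
        if sex is Sex.M and hemi:
            return (True, MoiReason.xl_hemi_ok)
        if sex is Sex.F and (hom or hemi):
            return (True, MoiReason.xl_hemi_ok)
        return (False, MoiReason.incompatible)
    if moi is Moi.XLD:
        return (True, MoiReason.xld_het_ok) if any_alt else (False, MoiReason.incompatible)
    return (False, MoiReason.incompatible)


GENOTYPE_POOL = [Genotype.het, Genotype.hom_alt, Genotype.hemizygous, Genotype.hom_ref]


def test_moi_truth_table_exhaustive():
    """assess_moi equals the hand-coded oracle over every MOI x genotype
    multiset (sizes 1-2) x sex combination."""
    multisets = [list(c) for n in (1, 2) for c in itertools.combinations_with_replacement(GENOTYPE_POOL, n)]
    for moi in (Moi.AD, Moi.AR, Moi.XLD, Moi.XLR, Moi.NA):
        for genotypes in multisets:
            for sex in (Sex.F, Sex.M):
                variants = [
                    make_call(pos=1000 + i, genotype=g) for i, g in enumerate(genotypes)
                ]
                got = assess_moi(variants, moi, sex)
                want_sat, want_reason = _oracle(moi, genotypes, sex)
                assert (got.satisfied, got.reason) == (want_sat, want_reason), (
                    moi,
                    genotypes,
                    sex,
                )


def test_single_het_in_recessive_gene_is_not_causative():
    a = assess_moi([make_call(genotype=Genotype.het)], Moi.AR, Sex.F)
    assert not a.satisfied and a.reason is MoiReason.ar_single_het


def _trio(father_data=None, mother_data=None, keys=()):
    trio = TrioGenotypes(proband_id="P", father_id="F", mother_id="M")
    for key in keys:
        site = {}
        if father_data is not None:
            site["F"] = father_data
        if mother_data is not None:
            site["M"] = mother_data
        trio.genotypes[key] = site
    return trio


def test_de_novo_detection():
    v = make_call(genotype=Genotype.het)
    ok = _trio((Genotype.hom_ref, 50), (Genotype.hom_ref, 50), keys=[v.key])
    assert detect_de_novo(v, ok) is True
    inherited = _trio((Genotype.het, 50), (Genotype.hom_ref, 50), keys=[v.key])
    assert detect_de_novo(v, inherited) is False
    shallow = _trio((Genotype.hom_ref, 50), (Genotype.hom_ref, 5), keys=[v.key])
    assert detect_de_novo(v, shallow) is None  # depth gate -> unavailable
    no_father = TrioGenotypes(proband_id="P", mother_id="M")
    no_father.genotypes[v.key] = {"M": (Genotype.hom_ref, 50)}
    assert detect_de_novo(v, no_father) is None


PARENT_STATES = [None, (Genotype.hom_ref, 60), (Genotype.het, 60)]


def test_de_novo_never_true_when_a_parent_carries():
    """Over all parental genotype combinations, de novo is only declared
    when both parents are confirmed hom-ref at depth."""
    v = make_call(genotype=Genotype.het)
    for fa, mo in itertools.product(PARENT_STATES, repeat=2):
        trio = _trio(fa, mo, keys=[v.key])
        got = detect_de_novo(v, trio)
        if fa is not None and fa[0].carries_alt:
            assert got is False
        elif mo is not None and mo[0].carries_alt:
            assert got is False
        elif fa is None or mo is None:
            assert got is None
        else:
            assert got is True


def _phase_pair(fa1, mo1, fa2, mo2):
    v1, v2 = make_call(pos=100), make_call(pos=200)
    trio = TrioGenotypes(proband_id="P", father_id="F", mother_id="M")
    trio.genotypes[v1.key] = {"F": fa1, "M": mo1}
    trio.genotypes[v2.key] = {"F": fa2, "M": mo2}
    return v1, v2, trio


REF, HET = (Genotype.hom_ref, 60), (Genotype.het, 60)


def test_phase_enumeration_of_parental_carriage():
    """All 3x3 combinations of (father-only / mother-only / both) carriage
    for the two variants, checked against the definitional phase."""
    def carrier_state(code):
        return {"f": (HET, REF), "m": (REF, HET), "b": (HET, HET)}[code]

    for c1, c2 in itertools.product("fmb", repeat=2):
        fa1, mo1 = carrier_state(c1)
        fa2, mo2 = carrier_state(c2)
        v1, v2, trio = _phase_pair(fa1, mo1, fa2, mo2)
        got = phase_compound_het(v1, v2, trio)
        if "b" in (c1, c2):
            assert got is Phase.unknown
        elif c1 == c2:
            assert got is Phase.cis
        else:
            assert got is Phase.trans


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    st.sampled_from([REF, HET, None]),
    st.sampled_from([REF, HET, None]),
    st.sampled_from([REF, HET, None]),
    st.sampled_from([REF, HET, None]),
)
def test_phase_is_symmetric(fa1, mo1, fa2, mo2):
    v1, v2, trio = _phase_pair(fa1, mo1, fa2, mo2)
    assert phase_compound_het(v1, v2, trio) is phase_compound_het(v2, v1, trio)


def test_ar_hom_with_carrier_parents_confirmed():
    v = make_call(genotype=Genotype.hom_alt)
    trio = _trio(HET, HET, keys=[v.key])
    assert evaluate_segregation([v], trio, Moi.AR).status is SegStatus.confirmed


def test_ar_hom_with_homref_parent_refuted():
    v = make_call(genotype=Genotype.hom_alt)
    trio = _trio(HET, REF, keys=[v.key])
    assert evaluate_segregation([v], trio, Moi.AR).status is SegStatus.refuted


def test_comphet_cis_refuted_trans_confirmed():
    v1, v2, trio = _phase_pair(HET, REF, HET, REF)  # both paternal -> cis
    assert evaluate_segregation([v1, v2], trio, Moi.AR).status is SegStatus.refuted
    v1, v2, trio = _phase_pair(HET, REF, REF, HET)  # one from each -> trans
    res = evaluate_segregation([v1, v2], trio, Moi.AR)
    assert res.status is SegStatus.confirmed and res.phase is Phase.trans


def test_no_parental_samples_pending_vs_unavailable():
    v = make_call(genotype=Genotype.het)
    listed_no_data = TrioGenotypes(proband_id="P", father_id="F", mother_id="M")
    assert evaluate_segregation([v], listed_no_data, Moi.AD).status is SegStatus.pending
    no_parents = TrioGenotypes(proband_id="P")
    assert evaluate_segregation([v], no_parents, Moi.AD).status is SegStatus.unavailable
    assert evaluate_segregation([v], None, Moi.AD).status is SegStatus.unavailable


def test_ad_de_novo_confirmed_with_flag():
    v = make_call(genotype=Genotype.het)
    trio = _trio(REF, REF, keys=[v.key])
    res = evaluate_segregation([v], trio, Moi.AD)
    assert res.status is SegStatus.confirmed and res.de_novo


def test_xl_variant_carried_by_unaffected_father_refuted():
    v = make_call(chrom="X", genotype=Genotype.het)
    trio = _trio((Genotype.hemizygous, 50), REF, keys=[v.key])
    assert evaluate_segregation([v], trio, Moi.XLD).status is SegStatus.refuted
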