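"""Mode-of-inheritance assessment and trio segregation.

Family segregation serves two purposes: confirming variants in the
proband and including/excluding candidate variants based on their
segregation in the family.  Penetrance is assumed complete for
refutation logic; an unaffected carrier parent under AD therefore counts
as confirmed transmission, not as a refutation (incomplete penetrance,
common in real dominant kidney disease, is deliberately not modeled).
Parental mosaicism is likewise not modeled.
"""

from __future__ import annotations

from typing import Optional

from .types import (
    Genotype,
    Moi,
    MoiAssessment,
    MoiReason,
    Phase,
    SegregationResult,
    SegStatus,
    Sex,
    TrioGenotypes,
    VariantCall,
)

DEFAULT_MIN_PARENT_DEPTH = 20  # mirrors the proband coverage rule


def assess_moi(variants_in_gene: list, moi: Moi, sex: Sex) -> MoiAssessment:
    """Can this gene's genotype configuration be causative under ``moi``?

    ``variants_in_gene`` are the candidate variants of one patient in one
    gene (ClassifiedVariant or VariantCall).  AR needs two hits (hom or
    >=2 het, a candidate compound het); a single het in a recessive gene
    is explicitly unsatisfied.  X-linked recessive needs a hemizygous
    male or homozygous female; X-linked dominant is satisfied by het or
    hemizygous carriers.
    """
    genotypes = [
        (v.call.genotype if hasattr(v, "call") else v.genotype) for v in variants_in_gene
    ]
    n_het = sum(1 for g in genotypes if g is Genotype.het)
    n_hom = sum(1 for g in genotypes if g is Genotype.hom_alt)
    n_hemi = sum(1 for g in genotypes if g is Genotype.hemizygous)

    if moi is Moi.AD:
        if n_het + n_hom + n_hemi >= 1:
            return MoiAssessment(True, MoiReason.ad_het_ok, moi)
        return MoiAssessment(False, MoiReason.incompatible, moi)
    if moi is Moi.AR:
        if n_hom >= 1:
            return MoiAssessment(True, MoiReason.ar_hom_ok, moi)
        if n_het >= 2:
            return MoiAssessment(True, MoiReason.ar_comphet_ok, moi)
        if n_het == 1:
            return MoiAssessment(False, MoiReason.ar_single_het, moi)
        return MoiAssessment(False, MoiReason.incompatible, moi)
    if moi is Moi.XLR:
        if (sex is Sex.M and n_hemi >= 1) or (sex is Sex.F and (n_hom >= 1 or n_hemi >= 1)):
            return MoiAssessment(True, MoiReason.xl_hemi_ok, moi)
        return MoiAssessment(False, MoiReason.incompatible, moi)
    if moi is Moi.XLD:
        if n_het + n_hom + n_hemi >= 1:
            return MoiAssessment(True, MoiReason.xld_het_ok, moi)
        return MoiAssessment(False, MoiReason.incompatible, moi)
    # moi NA: no inheritance model to satisfy
    return MoiAssessment(False, MoiReason.incompatible, moi)


def _parent_state(trio: TrioGenotypes, key: tuple, parent_id: Optional[str]):
    """(carries_alt, genotype, depth) or None when no data."""
    entry = trio.member_genotype(key, parent_id)
    if entry is None:
        return None
    gt, depth = entry
    if gt is Genotype.missing:
        return None
    return (gt.carries_alt, gt, depth)


def detect_de_novo(
    v: VariantCall,
    trio: TrioGenotypes,
    min_parent_depth: int = DEFAULT_MIN_PARENT_DEPTH,
) -> Optional[bool]:
    """True iff the proband carries the alt and both parents are
    homozygous reference with adequate coverage at the site.

    Returns None ("unavailable") when a parent is missing or a parental
    genotype is unusable (missing call or depth below the gate) — an
    unverifiable site is never reported as inherited or de novo.
    """
    if not v.genotype.carries_alt:
        return False
    if not trio.has_parents:
        return None
    states = [_parent_state(trio, v.key, p) for p in (trio.father_id, trio.mother_id)]
    # a carrier parent settles the question even if the other parent is
    # unavailable: the variant is inherited
    if any(s is not None and s[0] for s in states):
        return False
    if any(s is None for s in states):
        return None
    for carries, gt, depth in states:
        if gt is not Genotype.hom_ref:
            return None
        if depth is None or depth < min_parent_depth:
            return None
    return True


def phase_compound_het(v1: VariantCall, v2: VariantCall, trio: TrioGenotypes) -> Phase:
    """Phase two proband-het variants in one gene from parental carriage.

    trans: one variant traces exclusively to each parent.  cis: both
    trace exclusively to the same parent.  unknown: anything
    indeterminate — a variant carried by both parents, by neither
    (possible de novo), or a parent without data.
    """
    if not trio.has_parents:
        return Phase.unknown
    carriage = []
    for v in (v1, v2):
        states = [_parent_state(trio, v.key, p) for p in (trio.father_id, trio.mother_id)]
        if any(s is None for s in states):
            return Phase.unknown
        in_father, in_mother = states[0][0], states[1][0]
        if in_father == in_mother:  # both or neither: indeterminate origin
            return Phase.unknown
        carriage.append("father" if in_father else "mother")
    return Phase.trans if carriage[0] != carriage[1] else Phase.cis


def evaluate_segregation(
    variants: list,
    trio: Optional[TrioGenotypes],
    moi: Moi,
    min_parent_depth: int = DEFAULT_MIN_PARENT_DEPTH,
) -> SegregationResult:
    """Judge parental consistency of a gene's candidate variants.

    confirmed: parental genotypes consistent with the proband genotype
    under ``moi`` (AR hom with both parents het; AR compound het in
    trans; AD/XL inherited from a carrier parent or arisen de novo).
    refuted: inconsistent (compound het phased cis; AR hom with a
    well-covered hom-ref parent; an unaffected father carrying an
    X-linked variant).  pending: parents known but their data absent or
    indeterminate.  unavailable: no parents at all.
    """
    calls = [(v.call if hasattr(v, "call") else v) for v in variants]
    if trio is None or not (trio.father_id or trio.mother_id):
        return SegregationResult(SegStatus.unavailable)
    if not trio.has_parent_data():
        return SegregationResult(SegStatus.pending)

    # X-linked: an unaffected father carrying the variant refutes it
    # under the complete-penetrance assumption.
    if moi in (Moi.XLR, Moi.XLD):
        for c in calls:
            st = _parent_state(trio, c.key, trio.father_id)
            if st is not None and st[0]:
                return SegregationResult(SegStatus.refuted)

    if moi is Moi.AR:
        homs = [c for c in calls if c.genotype is Genotype.hom_alt]
        hets = [c for c in calls if c.genotype is Genotype.het]
        if homs:
            c = homs[0]
            states = [
                _parent_state(trio, c.key, p) for p in (trio.father_id, trio.mother_id)
            ]
            if any(s is None for s in states):
                return SegregationResult(SegStatus.pending)
            if all(s[0] for s in states):
                return SegregationResult(SegStatus.confirmed)
            # a well-covered hom-ref parent contradicts a homozygous child
            for carries, gt, depth in states:
                if (
                    not carries
                    and gt is Genotype.hom_ref
                    and depth is not None
                    and depth >= min_parent_depth
                ):
                    return SegregationResult(SegStatus.refuted)
            return SegregationResult(SegStatus.pending)
        if len(hets) >= 2:
            phase = phase_compound_het(hets[0], hets[1], trio)
            if phase is Phase.trans:
                return SegregationResult(SegStatus.confirmed, phase=phase)
            if phase is Phase.cis:
                return SegregationResult(SegStatus.refuted, phase=phase)
            return SegregationResult(SegStatus.pending, phase=phase)
        return SegregationResult(SegStatus.pending)

    # AD / XLD / XLR carrier logic: de novo or transmission both confirm.
    for c in calls:
        if not c.genotype.carries_alt:
            continue
        dn = detect_de_novo(c, trio, min_parent_depth)
        if dn is True:
            return SegregationResult(SegStatus.confirmed, de_novo=True)
        if dn is False:  # inherited from a carrier parent
            return SegregationResult(SegStatus.confirmed)
    return SegregationResult(SegStatus.pending)
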