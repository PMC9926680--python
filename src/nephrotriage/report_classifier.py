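"""Per-patient report classification: conclusive / uncertain / inconclusive.

The decision logic works per gene group and then takes the best group
outcome for the patient (a patient with one conclusive finding has a
conclusive report regardless of extra VUS):

(a) C5/C4 (or curated C3_C4) with full phenotype fit and a satisfied
    inheritance model -> conclusive;
(b) C3 with full phenotype fit and confirmed family segregation ->
    conclusive;
(c) C3 with full phenotype fit whose segregation is pending or cannot
    be obtained -> uncertain;
(d) C4/C5 not fully in line with the phenotype (partial fit) ->
    uncertain;
(e) a single heterozygous variant in a recessive gene -> inconclusive;
(f) C3 not in line with the phenotype, found when analysis was extended
    to the kidneyome -> inconclusive;
(g) no surviving variants -> inconclusive with reason ``no_variants``;
(h) refuted segregation -> that group is inconclusive.

C3_C4 is given C4-like weight in rules (a)/(d) but tallied as its own
class in the statistics.  A C4/C5 variant with *no* phenotype fit is
suppressed (logged, not reported) rather than assigned an invented
outcome; a C3 with partial fit can at most be uncertain, because
conclusive VUS calls require full clinical compatibility.
"""

from __future__ import annotations

from .types import (
    AcmgClass,
    CandidateBundle,
    CLASS_RANK,
    GeneGroup,
    MoiReason,
    Outcome,
    OUTCOME_RANK,
    PhenotypeFit,
    ReportOutcome,
    SegStatus,
)

# reason codes are machine-readable rule identifiers
R_PATHOGENIC_FULL = "pathogenic_full_match"          # rule (a)
R_C3_CONFIRMED = "c3_segregation_confirmed"          # rule (b)
R_C3_PENDING = "c3_segregation_pending"              # rule (c)
R_PATHOGENIC_PARTIAL = "pathogenic_partial_phenotype"  # rule (d)
R_SINGLE_HET_AR = "single_het_recessive"             # rule (e)
R_C3_OFF_PHENOTYPE = "c3_off_phenotype"              # rule (f)
R_NO_VARIANTS = "no_variants"                        # rule (g)
R_REFUTED = "segregation_refuted"                    # rule (h)
R_C3_PARTIAL = "c3_partial_phenotype"
R_OFF_PHENOTYPE_SUPPRESSED = "off_phenotype_suppressed"
R_MOI_INCOMPATIBLE = "moi_incompatible"
R_BENIGN = "benign_class"


def _lead_class(group: GeneGroup) -> AcmgClass:
    return max((v.acmg_class for v in group.variants), key=CLASS_RANK.get)


def _effective_weight(cls: AcmgClass) -> AcmgClass:
    """C3_C4 is handled with C4 weight by the decision rules."""
    return AcmgClass.C4 if cls is AcmgClass.C3_C4 else cls


def group_outcome(group: GeneGroup) -> tuple:
    """(Outcome, reason, reportable) for one gene group."""
    if group.segregation.status is SegStatus.refuted:
        return (Outcome.inconclusive, R_REFUTED, False)
    if group.moi.reason is MoiReason.ar_single_het:
        return (Outcome.inconclusive, R_SINGLE_HET_AR, False)
    cls = _effective_weight(_lead_class(group))
    fit = group.phenotype_fit
    if cls in (AcmgClass.C4, AcmgClass.C5):
        if fit is PhenotypeFit.full and group.moi.satisfied:
            return (Outcome.conclusive, R_PATHOGENIC_FULL, True)
        if fit is PhenotypeFit.partial:
            return (Outcome.uncertain, R_PATHOGENIC_PARTIAL, True)
        if fit is PhenotypeFit.none:
            return (Outcome.inconclusive, R_OFF_PHENOTYPE_SUPPRESSED, False)
        return (Outcome.inconclusive, R_MOI_INCOMPATIBLE, False)
    if cls is AcmgClass.C3:
        if not group.moi.satisfied:
            return (Outcome.inconclusive, R_MOI_INCOMPATIBLE, False)
        if fit is PhenotypeFit.full:
            if group.segregation.status is SegStatus.confirmed:
                return (Outcome.conclusive, R_C3_CONFIRMED, True)
            return (Outcome.uncertain, R_C3_PENDING, True)
        if fit is PhenotypeFit.partial:
            return (Outcome.uncertain, R_C3_PARTIAL, True)
        return (Outcome.inconclusive, R_C3_OFF_PHENOTYPE, False)
    return (Outcome.inconclusive, R_BENIGN, False)


def classify_report(bundle: CandidateBundle) -> ReportOutcome:
    """Patient outcome = best group outcome; conclusive > uncertain >
    inconclusive.  Reasons of best-outcome groups become the primary
    reasons; the rest are recorded as secondary.  Variants are reported
    from best-outcome groups only, and only when the rules deem the
    group reportable (suppressed or excluded variants stay out of the
    report)."""
    if not bundle.groups:
        return ReportOutcome(
            patient_id=bundle.patient_id,
            outcome=Outcome.inconclusive,
            reasons=[R_NO_VARIANTS],
        )
    judged = [(g, *group_outcome(g)) for g in bundle.groups]
    best = max((o for _, o, _, _ in judged), key=OUTCOME_RANK.get)
    reasons, secondary, reported = [], [], []
    for g, outcome, reason, reportable in judged:
        if outcome is best:
            if reason not in reasons:
                reasons.append(reason)
            if reportable:
                reported.extend(g.variants)
        elif reason not in secondary:
            secondary.append(reason)
    return ReportOutcome(
        patient_id=bundle.patient_id,
        outcome=best,
        reasons=reasons,
        reported_variants=reported,
        secondary_reasons=secondary,
    )


def outcome_reasons(bundle: CandidateBundle) -> list:
    """Machine-readable reasons justifying the patient outcome."""
    return classify_report(bundle).reasons
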