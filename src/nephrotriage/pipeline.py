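"""End-to-end orchestration: cohort files -> filtered candidates ->
classified variants -> segregation -> per-patient report outcomes.

A cohort on disk is a directory with::

    patients.tsv   patient metadata and clinician phenotype flags
    panels.tsv     gene-panel registry (one row per gene x inheritance mode)
    clinical.tsv   per (patient, gene): phenotype fit, optional manual class
    cohort.ped     pedigree; '0' marks unavailable parents
    vcf/<id>.vcf   one VCF per family (proband plus genotyped parents)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import io_formats
from .acmg import classify_with_override, combine_evidence
from .gene_panels import (
    build_kidneyome,
    restrict_to_panel,
    select_panel,
    should_escalate,
)
from .report_classifier import classify_report
from .segregation import assess_moi, evaluate_segregation
from .types import (
    AcmgClass,
    CandidateBundle,
    ClassifiedVariant,
    Consequence,
    EscalationContext,
    EvidenceProfile,
    FilterConfig,
    GeneGroup,
    Genotype,
    MoiReason,
    PatientRecord,
    PhenotypeFit,
    ReportOutcome,
    Sex,
    TrioGenotypes,
)
from .variant_filtering import run_filter_cascade


@dataclass
class CohortData:
    """In-memory cohort: the unit the pipeline runs on, whether loaded
    from disk or produced directly by the simulator."""

    patients: list = field(default_factory=list)  # list[PatientRecord]
    calls: dict = field(default_factory=dict)  # patient_id -> list[VariantCall]
    trios: dict = field(default_factory=dict)  # patient_id -> TrioGenotypes
    clinical: dict = field(default_factory=dict)  # (pid, gene) -> (fit, manual)
    panels: list = field(default_factory=list)  # subpanel registry


def load_cohort(cohort_dir) -> CohortData:
    cohort_dir = Path(cohort_dir)
    patients = io_formats.read_patients(cohort_dir / "patients.tsv")
    panels = io_formats.read_panels(cohort_dir / "panels.tsv")
    clinical = io_formats.read_clinical(cohort_dir / "clinical.tsv")
    ped = io_formats.read_ped(cohort_dir / "cohort.ped")
    ped_by_id = {r.individual_id: r for r in ped}

    data = CohortData(patients=patients, panels=panels, clinical=clinical)
    for p in patients:
        vcf_path = cohort_dir / "vcf" / f"{p.patient_id}.vcf"
        rec = ped_by_id.get(p.patient_id)
        father = rec.father_id if rec else None
        mother = rec.mother_id if rec else None
        trio = TrioGenotypes(proband_id=p.patient_id, father_id=father, mother_id=mother)
        if vcf_path.exists():
            sex_map = {p.patient_id: p.sex}
            if father:
                sex_map[father] = Sex.M
            if mother:
                sex_map[mother] = Sex.F
            all_calls = io_formats.read_vcf(vcf_path, sex_map=sex_map)
            proband_calls = []
            for c in all_calls:
                trio.genotypes.setdefault(c.key, {})[c.patient_id] = (c.genotype, c.depth)
                if c.patient_id == p.patient_id:
                    proband_calls.append(c)
            data.calls[p.patient_id] = proband_calls
        else:
            data.calls[p.patient_id] = []
        data.trios[p.patient_id] = trio
    return data


def _choose_moi(variants, moi_options, sex):
    """Assess every registered inheritance mode for the gene and keep the
    most informative result: satisfied beats unsatisfied, and the
    single-het-in-recessive-gene reason beats a bare incompatibility
    because it drives its own report rule."""
    assessments = [assess_moi(variants, m, sex) for m in moi_options]
    for a in assessments:
        if a.satisfied:
            return a
    for a in assessments:
        if a.reason is MoiReason.ar_single_het:
            return a
    return assessments[0]


def _mode_label(cv: ClassifiedVariant, moi_reason: MoiReason) -> str:
    if cv.call.consequence.is_cnv:
        return "cnv"
    if cv.call.genotype is Genotype.hemizygous:
        return "hemi"
    if cv.call.genotype is Genotype.hom_alt:
        return "hom"
    if moi_reason is MoiReason.ar_comphet_ok:
        return "comphet"
    return "het"


def analyze_patient(
    patient: PatientRecord,
    calls: list,
    panels: list,
    clinical: dict,
    trio: Optional[TrioGenotypes] = None,
    cfg: FilterConfig = FilterConfig(),
    kidneyome=None,
) -> tuple:
    """Run the full triage for one patient.

    Returns (ReportOutcome, CandidateBundle, FilterTrace).  The filtering
    cascade runs once against the clinical-suspicion subpanel; only a
    negative subpanel result with an unclear or overlapping phenotype
    escalates to the kidneyome (filtered calls are reused — the
    thresholds are panel-independent, so filtering is a single pass).
    """
    candidates = [c for c in calls if c.genotype.carries_alt]
    subpanel = select_panel(patient, panels)
    survivors, trace = run_filter_cascade(candidates, subpanel, cfg)
    found_via = "subpanel"
    panel_used = subpanel
    if not survivors:
        ctx = EscalationContext(
            subpanel_negative=True,
            phenotype_unclear=patient.phenotype_unclear,
            phenotype_overlapping=patient.phenotype_overlapping,
        )
        if should_escalate(ctx):
            if kidneyome is None:
                kidneyome = build_kidneyome(panels)
            survivors, trace = run_filter_cascade(candidates, kidneyome, cfg)
            found_via = "kidneyome"
            panel_used = kidneyome

    by_gene: dict = {}
    for call in survivors:
        by_gene.setdefault(call.gene, []).append(call)

    groups = []
    for gene, gene_calls in by_gene.items():
        classified = []
        for call in gene_calls:
            evidence = call.evidence or EvidenceProfile()
            computed = combine_evidence(evidence)
            _, manual = clinical.get((patient.patient_id, gene), (None, None))
            classified.append(
                ClassifiedVariant(
                    call=call,
                    acmg_class=classify_with_override(evidence, manual),
                    computed_class=computed,
                    manual_class=manual,
                )
            )
        moi_options = panel_used.moi_for(gene) or [None]
        moi = _choose_moi(classified, [m for m in moi_options if m], patient.sex)
        seg = evaluate_segregation(classified, trio, moi.moi)
        for cv in classified:
            cv.mode = _mode_label(cv, moi.reason)
        fit, _ = clinical.get((patient.patient_id, gene), (PhenotypeFit.none, None))
        groups.append(
            GeneGroup(
                gene=gene,
                variants=classified,
                moi=moi,
                segregation=seg,
                phenotype_fit=fit,
                found_via=found_via,
            )
        )
    bundle = CandidateBundle(patient_id=patient.patient_id, groups=groups)
    return classify_report(bundle), bundle, trace


def run_cohort(data: CohortData, cfg: FilterConfig = FilterConfig()) -> list:
    """Analyze every patient; returns ReportOutcome list in patient order."""
    kidneyome = build_kidneyome(data.panels)
    outcomes = []
    for p in data.patients:
        outcome, _, _ = analyze_patient(
            p,
            data.calls.get(p.patient_id, []),
            data.panels,
            data.clinical,
            trio=data.trios.get(p.patient_id),
            cfg=cfg,
            kidneyome=kidneyome,
        )
        outcomes.append(outcome)
    return outcomes
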