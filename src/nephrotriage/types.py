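"""Core domain types for the kidney-disease variant triage pipeline.

The pipeline moves small-variant calls through a fixed sequence of stages:
panel restriction, a filtering cascade (consequence, population frequency,
in-patient allele fraction, coverage), ACMG evidence combination, trio
segregation, and finally per-patient report classification into
conclusive / uncertain / inconclusive.  The dataclasses here are the
contracts between those stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class Consequence(str, Enum):
    missense = "missense"
    nonsense = "nonsense"
    frameshift = "frameshift"
    splicing = "splicing"
    synonymous = "synonymous"
    intronic = "intronic"
    inframe_indel = "inframe_indel"
    cnv_del = "cnv_del"
    cnv_dup = "cnv_dup"
    other = "other"

    @property
    def is_cnv(self) -> bool:
        return self in (Consequence.cnv_del, Consequence.cnv_dup)


class Genotype(str, Enum):
    het = "het"
    hom_alt = "hom_alt"
    hemizygous = "hemizygous"
    hom_ref = "hom_ref"
    missing = "missing"

    @property
    def carries_alt(self) -> bool:
        return self in (Genotype.het, Genotype.hom_alt, Genotype.hemizygous)


class Sex(str, Enum):
    F = "F"
    M = "M"


class MacroCategory(str, Enum):
    """The six clinical-suspicion macro-categories the cohort is split into."""

    CAKUT = "CAKUT"
    ciliopathy = "ciliopathy"
    glomerulopathy = "glomerulopathy"
    nephrolithiasis = "nephrolithiasis"
    tubulopathy = "tubulopathy"
    other = "other"


class Ethnicity(str, Enum):
    European = "European"
    African = "African"
    Asian = "Asian"
    LatinAmerican = "LatinAmerican"
    mixed = "mixed"


class Moi(str, Enum):
    """Mode of inheritance attached to a gene in a panel."""

    AD = "AD"
    AR = "AR"
    XLD = "XLD"
    XLR = "XLR"
    NA = "NA"


class AcmgClass(str, Enum):
    """Five-tier ACMG class; C3_C4 is a curated intermediate assigned only
    by manual override (it never falls out of the combining rules)."""

    C1 = "C1"  # benign
    C2 = "C2"  # likely benign
    C3 = "C3"  # VUS
    C4 = "C4"  # likely pathogenic
    C5 = "C5"  # pathogenic
    C3_C4 = "C3_C4"  # curated intermediate


# Rank for choosing the "leading" class of a report; C3_C4 sits between
# C3 and C4 (it is reported with C4-like weight but tallied separately).
CLASS_RANK = {
    AcmgClass.C1: 0,
    AcmgClass.C2: 1,
    AcmgClass.C3: 2,
    AcmgClass.C3_C4: 3,
    AcmgClass.C4: 4,
    AcmgClass.C5: 5,
}


class Outcome(str, Enum):
    conclusive = "conclusive"
    uncertain = "uncertain"
    inconclusive = "inconclusive"


OUTCOME_RANK = {
    Outcome.inconclusive: 0,
    Outcome.uncertain: 1,
    Outcome.conclusive: 2,
}


class PhenotypeFit(str, Enum):
    """Clinician-supplied compatibility of a candidate gene with the
    patient's clinical picture.  Never inferred by the pipeline."""

    full = "full"
    partial = "partial"
    none = "none"


class SegStatus(str, Enum):
    confirmed = "confirmed"
    refuted = "refuted"
    pending = "pending"
    unavailable = "unavailable"


class Phase(str, Enum):
    trans = "trans"
    cis = "cis"
    unknown = "unknown"


class MoiReason(str, Enum):
    ad_het_ok = "ad_het_ok"
    ar_hom_ok = "ar_hom_ok"
    ar_comphet_ok = "ar_comphet_ok"
    ar_single_het = "ar_single_het"
    xl_hemi_ok = "xl_hemi_ok"
    xld_het_ok = "xld_het_ok"
    incompatible = "incompatible"


SEX_CHROMOSOMES = {"X", "Y", "chrX", "chrY"}


@dataclass
class VariantCall:
    """One annotated alternate allele observed in one patient.

    ``vaf`` is the in-patient alternate-read fraction (alt reads / total
    reads); ``pop_af`` is the external population frequency.  CNV records
    (consequence ``cnv_del``/``cnv_dup``) carry ``vaf``/``depth`` as None —
    a per-site allele fraction is not meaningful for a multi-exon event.
    """

    patient_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: Consequence
    splice_region: bool = False
    pop_af: float = 0.0
    vaf: Optional[float] = None
    depth: Optional[int] = None
    genotype: Genotype = Genotype.missing
    evidence: Optional["EvidenceProfile"] = None
    published: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.vaf is not None and not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"vaf out of [0,1]: {self.vaf}")
        if self.depth is not None and self.depth < 0:
            raise ValueError(f"negative depth: {self.depth}")
        if not (0.0 <= self.pop_af <= 1.0):
            raise ValueError(f"pop_af out of [0,1]: {self.pop_af}")

    @property
    def key(self) -> tuple:
        """Site identity within a call set: (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def on_sex_chromosome(self) -> bool:
        return self.chrom in SEX_CHROMOSOMES


@dataclass
class EvidenceProfile:
    """Counts of invoked ACMG evidence codes, bucketed by strength."""

    pvs: int = 0
    ps: int = 0
    pm: int = 0
    pp: int = 0
    ba: int = 0
    bs: int = 0
    bp: int = 0

    def __post_init__(self) -> None:
        for name in ("pvs", "ps", "pm", "pp", "ba", "bs", "bp"):
            if getattr(self, name) < 0:
                raise ValueError(f"evidence count {name} must be >= 0")


@dataclass
class ClassifiedVariant:
    """A VariantCall plus its ACMG class and bookkeeping set during
    bundling (zygosity mode used in cohort tallies)."""

    call: VariantCall
    acmg_class: AcmgClass
    computed_class: AcmgClass
    manual_class: Optional[AcmgClass] = None
    mode: Optional[str] = None  # het | hom | comphet | hemi | cnv


@dataclass
class PatientRecord:
    patient_id: str
    sex: Sex
    age_years: float
    macro_category: MacroCategory
    primary_disease: str = ""
    family_history: bool = False
    ethnicity: Ethnicity = Ethnicity.European
    consanguinity: bool = False
    # Clinician-supplied flags feeding the super-panel escalation rule.
    phenotype_unclear: bool = False
    phenotype_overlapping: bool = False

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise ValueError("age_years must be non-negative")


@dataclass
class TrioGenotypes:
    """Genotypes of a proband and (optionally) its parents at the
    proband's candidate sites.  An absent parent is None, never imputed."""

    proband_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    # (chrom, pos, ref, alt) -> member_id -> (Genotype, depth or None)
    genotypes: dict = field(default_factory=dict)

    @property
    def has_parents(self) -> bool:
        return self.father_id is not None and self.mother_id is not None

    def member_genotype(self, key: tuple, member_id: Optional[str]):
        """(Genotype, depth) for one member at a site, or None if the
        member is absent or has no data at the site."""
        if member_id is None:
            return None
        site = self.genotypes.get(key)
        if site is None:
            return None
        return site.get(member_id)

    def has_parent_data(self) -> bool:
        members = {m for site in self.genotypes.values() for m in site}
        return any(p in members for p in (self.father_id, self.mother_id) if p)


@dataclass
class MoiAssessment:
    satisfied: bool
    reason: MoiReason
    moi: Moi = Moi.NA

    def __post_init__(self) -> None:
        if self.reason is MoiReason.ar_single_het and self.satisfied:
            raise ValueError("a single het in a recessive gene cannot satisfy AR")


@dataclass
class SegregationResult:
    status: SegStatus
    de_novo: bool = False
    phase: Phase = Phase.unknown


@dataclass
class GeneGroup:
    """All candidate variants of one patient in one gene, with the
    per-group annotations the report classifier consumes."""

    gene: str
    variants: list  # list[ClassifiedVariant]
    moi: MoiAssessment
    segregation: SegregationResult
    phenotype_fit: PhenotypeFit
    found_via: str = "subpanel"  # "subpanel" | "kidneyome"


@dataclass
class CandidateBundle:
    patient_id: str
    groups: list = field(default_factory=list)  # list[GeneGroup]


@dataclass
class ReportOutcome:
    patient_id: str
    outcome: Outcome
    reasons: list = field(default_factory=list)
    reported_variants: list = field(default_factory=list)  # list[ClassifiedVariant]
    secondary_reasons: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if (
            self.outcome is Outcome.inconclusive
            and "no_variants" in self.reasons
            and self.reported_variants
        ):
            raise ValueError("no_variants outcome cannot carry reported variants")
        if self.outcome is Outcome.conclusive and not self.reported_variants:
            raise ValueError("a conclusive report must list at least one variant")

    @property
    def variant_positive(self) -> bool:
        """True when at least one variant survived filtering for this
        patient (a negative exome is flagged by reason ``no_variants``)."""
        return "no_variants" not in self.reasons


@dataclass(frozen=True)
class PanelEntry:
    gene: str
    moi: Moi
    chromosome: str


@dataclass
class GenePanel:
    name: str
    category: str  # MacroCategory value or "kidneyome"
    entries: list = field(default_factory=list)  # list[PanelEntry]

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            k = (e.gene, e.moi)
            if k in seen:
                raise ValueError(f"duplicate panel entry {k} in panel {self.name}")
            seen.add(k)

    @property
    def genes(self) -> set:
        return {e.gene for e in self.entries}

    def moi_for(self, gene: str) -> list:
        """All inheritance modes registered for a gene (dual-inheritance
        genes are entered once per mode)."""
        return [e.moi for e in self.entries if e.gene == gene]


@dataclass
class EscalationContext:
    """Explicit flags governing escalation from a disease subpanel to the
    kidneyome super-panel; never inferred from data."""

    subpanel_negative: bool
    phenotype_unclear: bool
    phenotype_overlapping: bool


@dataclass
class FilterConfig:
    """Thresholds of the filtering cascade.  Defaults are the clinical
    rule set: population frequency strictly below 1%, in-patient allele
    fraction at least 0.2, coverage at least 20 reads."""

    max_pop_af: float = 0.01
    min_vaf: float = 0.2
    min_depth: int = 20
    retained_consequences: frozenset = frozenset(
        {
            Consequence.missense,
            Consequence.nonsense,
            Consequence.frameshift,
            Consequence.splicing,
            Consequence.inframe_indel,
            Consequence.cnv_del,
            Consequence.cnv_dup,
        }
    )

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_pop_af <= 1.0):
            raise ValueError("max_pop_af out of [0,1]")
        if not (0.0 <= self.min_vaf <= 1.0):
            raise ValueError("min_vaf out of [0,1]")
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")


@dataclass
class FilterTrace:
    """Ordered (filter name, passed) record per input variant; a failed
    variant carries exactly one first-failing filter."""

    steps: dict = field(default_factory=dict)  # variant key -> list[(str, bool)]

    def record(self, key: tuple, filter_name: str, passed: bool) -> None:
        self.steps.setdefault(key, []).append((filter_name, passed))

    def first_failure(self, key: tuple) -> Optional[str]:
        for name, ok in self.steps.get(key, []):
            if not ok:
                return name
        return None
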