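"""Synthetic cohort generation with per-patient ground truth.

Two entry points:

* :func:`simulate_cohort` draws randomized cohorts from a
  :class:`SimConfig` — every patient gets an intended report outcome,
  causative variants engineered to reach exactly that outcome through
  the real pipeline, and decoy variants each constructed to fail exactly
  one named filter.  The accompanying :class:`GroundTruthLedger` is the
  oracle for pipeline-vs-ledger agreement tests.

* :func:`build_study_fixture` builds a deterministic 191-patient cohort
  whose structure mirrors the published pediatric kidney-disease study
  population: category sizes 34/39/62/22/20/14, 47 family-history
  positive patients (28 of them diagnosed), 154 variant-positive
  patients, report split 71 conclusive / 22 uncertain / 61 inconclusive,
  and 96 reported variants in 32 genes across the conclusive reports
  (53 missense, 15 frameshift, 14 nonsense, 9 splicing, 5 CNV; leading
  classes 17 C5 / 34 C4 / 16 C3 / 4 C3_C4).  The joint distribution of
  family history x category x diagnosis is under-determined by the
  published marginals; the fixture fixes one deterministic completion
  consistent with all of them.  Every record is engineered so that the
  pipeline — not the ledger — produces these outcomes.

No read-level simulation: depth and allele fraction are emitted as
summary FORMAT fields, which is the granularity the filters consume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from . import io_formats
from .pipeline import CohortData
from .types import (
    AcmgClass,
    Consequence,
    Ethnicity,
    EvidenceProfile,
    GenePanel,
    Genotype,
    MacroCategory,
    Moi,
    Outcome,
    PanelEntry,
    PatientRecord,
    PhenotypeFit,
    Sex,
    TrioGenotypes,
    VariantCall,
)

# ---------------------------------------------------------------------------
# Demonstration gene registry.  Genes named in the disease literature for
# each macro-category; the production >400-gene list is curated externally
# and is not part of this package.

_CAT = MacroCategory
# gene -> (chromosome, moi, category); order fixes base coordinates
GENE_TABLE = [
    # CAKUT
    ("PAX2", "10", Moi.AD, _CAT.CAKUT),
    ("HNF1B", "17", Moi.AD, _CAT.CAKUT),
    ("EYA1", "8", Moi.AD, _CAT.CAKUT),
    ("GATA3", "10", Moi.AD, _CAT.CAKUT),
    ("SALL1", "16", Moi.AD, _CAT.CAKUT),
    ("FRAS1", "4", Moi.AR, _CAT.CAKUT),
    ("ROBO2", "3", Moi.AD, _CAT.CAKUT),
    # ciliopathies
    ("PKD1", "16", Moi.AD, _CAT.ciliopathy),
    ("PKD2", "4", Moi.AD, _CAT.ciliopathy),
    ("PKHD1", "6", Moi.AR, _CAT.ciliopathy),
    ("NPHP1", "2", Moi.AR, _CAT.ciliopathy),
    ("CEP290", "12", Moi.AR, _CAT.ciliopathy),
    ("TMEM67", "8", Moi.AR, _CAT.ciliopathy),
    ("BBS1", "11", Moi.AR, _CAT.ciliopathy),
    ("IFT140", "16", Moi.AR, _CAT.ciliopathy),
    ("NPHP4", "1", Moi.AR, _CAT.ciliopathy),
    # glomerulopathies
    ("COL4A5", "X", Moi.XLD, _CAT.glomerulopathy),
    ("COL4A3", "2", Moi.AR, _CAT.glomerulopathy),
    ("COL4A4", "2", Moi.AR, _CAT.glomerulopathy),
    ("NPHS1", "19", Moi.AR, _CAT.glomerulopathy),
    ("NPHS2", "1", Moi.AR, _CAT.glomerulopathy),
    ("WT1", "11", Moi.AD, _CAT.glomerulopathy),
    ("TRPC6", "11", Moi.AD, _CAT.glomerulopathy),
    ("CFH", "1", Moi.AD, _CAT.glomerulopathy),
    ("LMX1B", "9", Moi.AD, _CAT.glomerulopathy),
    ("INF2", "14", Moi.AD, _CAT.glomerulopathy),
    ("PTPRO", "12", Moi.AR, _CAT.glomerulopathy),
    # nephrolithiasis
    ("AGXT", "2", Moi.AR, _CAT.nephrolithiasis),
    ("SLC3A1", "2", Moi.AR, _CAT.nephrolithiasis),
    ("SLC7A9", "19", Moi.AR, _CAT.nephrolithiasis),
    ("CYP24A1", "20", Moi.AR, _CAT.nephrolithiasis),
    ("SLC34A1", "5", Moi.AR, _CAT.nephrolithiasis),
    ("ADCY10", "1", Moi.AD, _CAT.nephrolithiasis),
    ("CLDN19", "1", Moi.AR, _CAT.nephrolithiasis),
    # tubulopathies
    ("SLC12A3", "16", Moi.AR, _CAT.tubulopathy),
    ("CLCNKB", "1", Moi.AR, _CAT.tubulopathy),
    ("CLDN16", "3", Moi.AR, _CAT.tubulopathy),
    ("OCRL", "X", Moi.XLR, _CAT.tubulopathy),
    ("UMOD", "16", Moi.AD, _CAT.tubulopathy),
    ("BSND", "1", Moi.AR, _CAT.tubulopathy),
    # other / syndromic
    ("TSC2", "16", Moi.AD, _CAT.other),
    ("TSC1", "9", Moi.AD, _CAT.other),
    ("WDR19", "4", Moi.AR, _CAT.other),
    ("ZEB2", "2", Moi.AD, _CAT.other),
]

# genes outside every kidney panel; used for off-panel decoys
OFF_PANEL_GENES = [("TTN", "2"), ("BRCA2", "13")]

GENE_CHROM = {g: c for g, c, _, _ in GENE_TABLE}
GENE_CHROM.update({g: c for g, c in OFF_PANEL_GENES})
GENE_MOI = {g: m for g, _, m, _ in GENE_TABLE}
# distinct base coordinate per gene, clash-free also within a chromosome
GENE_BASE = {g: (i + 1) * 1_000_000 for i, (g, _, _, _) in enumerate(GENE_TABLE)}
GENE_BASE.update(
    {g: (len(GENE_TABLE) + i + 1) * 1_000_000 for i, (g, _) in enumerate(OFF_PANEL_GENES)}
)


def demo_registry() -> list:
    """One GenePanel per macro-category from the demonstration table."""
    panels = {}
    for gene, chrom, moi, cat in GENE_TABLE:
        panels.setdefault(cat.value, []).append(
            PanelEntry(gene=gene, moi=moi, chromosome=chrom)
        )
    return [
        GenePanel(name=cat, category=cat, entries=entries)
        for cat, entries in panels.items()
    ]


# ---------------------------------------------------------------------------
# Plans


@dataclass
class VariantPlan:
    gene: str
    cls: AcmgClass  # intended reported class (C3_C4 implies manual override)
    zygosity: str  # het | hom | hemi
    consequence: Optional[Consequence] = None  # filled from pools if None
    phenotype_fit: PhenotypeFit = PhenotypeFit.full
    published: bool = True


@dataclass
class PatientPlan:
    category: MacroCategory
    intended: Outcome
    variants: list = field(default_factory=list)  # list[VariantPlan]
    # trio scenario applied to the causal gene group:
    # None | denovo | parents_het | trans | carrier
    trio: Optional[str] = None
    decoys: list = field(default_factory=list)  # filter names to fail
    sex: Optional[Sex] = None
    family_history: bool = False
    phenotype_unclear: bool = False
    consanguinity: bool = False


class InfeasiblePlanError(ValueError):
    """A requested plant cannot be realized with the given panels."""


def genes_with_mode(panel: GenePanel, modes) -> list:
    """Genes of a panel carrying one of the requested inheritance modes;
    an empty pool makes the requested plant infeasible (e.g. a compound
    het cannot be planted into a panel without a recessive gene)."""
    pool = sorted(e.gene for e in panel.entries if e.moi in modes)
    if not pool:
        raise InfeasiblePlanError(
            f"no gene with mode in {sorted(m.value for m in modes)} "
            f"in panel {panel.name}"
        )
    return pool


# -- plan constructors -------------------------------------------------------


def _p(cat, variants, *, intended=Outcome.conclusive, **kw) -> PatientPlan:
    return PatientPlan(category=cat, intended=intended, variants=variants, **kw)


def k_ad_het(cat, gene, cls, n=1):
    return _p(cat, [VariantPlan(gene, cls, "het") for _ in range(n)])


def k_ad_denovo(cat, gene):
    return _p(cat, [VariantPlan(gene, AcmgClass.C3, "het")], trio="denovo")


def k_ar_hom(cat, gene, cls, trio=None):
    return _p(cat, [VariantPlan(gene, cls, "hom")], trio=trio)


def k_comphet(cat, gene, cls, trio=None):
    return _p(cat, [VariantPlan(gene, cls, "het"), VariantPlan(gene, cls, "het")], trio=trio)


def k_xld_het(cat, gene, cls):
    return _p(cat, [VariantPlan(gene, cls, "het")], sex=Sex.F)


def k_hemi(cat, gene, cls):
    return _p(cat, [VariantPlan(gene, cls, "hemi")], sex=Sex.M)


def k_cnv(cat, gene, cls, dup=False, zygosity="het"):
    csq = Consequence.cnv_dup if dup else Consequence.cnv_del
    return _p(cat, [VariantPlan(gene, cls, zygosity, consequence=csq)])


def k_c3_pending(cat, gene):
    return _p(cat, [VariantPlan(gene, AcmgClass.C3, "het")], intended=Outcome.uncertain)


def k_c4_partial(cat, gene):
    return _p(
        cat,
        [VariantPlan(gene, AcmgClass.C4, "het", phenotype_fit=PhenotypeFit.partial)],
        intended=Outcome.uncertain,
    )


def k_ar_single(cat, gene):
    return _p(
        cat,
        [VariantPlan(gene, AcmgClass.C4, "het")],
        intended=Outcome.inconclusive,
    )


def k_offtarget(cat, gene):
    """C3 in a gene outside the patient's subpanel, found only after
    kidneyome escalation, not in line with the phenotype."""
    return _p(
        cat,
        [VariantPlan(gene, AcmgClass.C3, "het", phenotype_fit=PhenotypeFit.none)],
        intended=Outcome.inconclusive,
        phenotype_unclear=True,
    )


def k_negative(cat):
    return _p(cat, [], intended=Outcome.inconclusive)


# ---------------------------------------------------------------------------
# The deterministic study fixture


# per category: (size, n_conclusive, fh_diagnosed, fh_nondiagnosed)
FIXTURE_MARGINALS = {
    _CAT.CAKUT: (34, 7, 1, 2),
    _CAT.ciliopathy: (39, 29, 16, 6),
    _CAT.glomerulopathy: (62, 15, 2, 4),
    _CAT.nephrolithiasis: (22, 10, 8, 4),
    _CAT.tubulopathy: (20, 9, 1, 2),
    _CAT.other: (14, 1, 0, 1),
}

# consequence pools for the primary causative variant per intended class;
# secondary variants (compound-het partners, additional same-gene hits)
# are all missense, reproducing 53/15/14/9 missense/frameshift/nonsense/
# splicing plus 5 CNVs = 96 reported variants.
_C5_POOL = [Consequence.nonsense] * 8 + [Consequence.frameshift] * 8
_C4_POOL = (
    [Consequence.nonsense] * 6
    + [Consequence.frameshift] * 7
    + [Consequence.splicing] * 9
    + [Consequence.missense] * 8
)

DECOY_KINDS = ["common", "low_vaf", "low_depth", "synonymous", "intronic", "off_panel"]


def _fixture_conclusive_plans() -> dict:
    C3, C4, C5, C34 = AcmgClass.C3, AcmgClass.C4, AcmgClass.C5, AcmgClass.C3_C4
    cak, cil, glo, nep, tub, oth = (
        _CAT.CAKUT,
        _CAT.ciliopathy,
        _CAT.glomerulopathy,
        _CAT.nephrolithiasis,
        _CAT.tubulopathy,
        _CAT.other,
    )
    plans = {
        cak: [
            k_cnv(cak, "HNF1B", C5),
            k_cnv(cak, "EYA1", C4),
            k_ad_het(cak, "PAX2", C4),
            k_ad_het(cak, "GATA3", C4),
            k_ad_het(cak, "SALL1", C4),
            k_ad_het(cak, "HNF1B", C4),
            k_ad_denovo(cak, "PAX2"),
        ],
        cil: (
            [k_comphet(cil, "PKHD1", C5) for _ in range(2)]
            + [k_ar_hom(cil, "NPHP1", C5), k_ar_hom(cil, "CEP290", C5)]
            + [k_ad_het(cil, "PKD1", C4, n=2) for _ in range(8)]
            + [
                k_comphet(cil, "PKHD1", C4),
                k_comphet(cil, "TMEM67", C4),
                k_comphet(cil, "CEP290", C4),
                k_comphet(cil, "NPHP1", C4),
                k_comphet(cil, "TMEM67", C4),
            ]
            + [
                k_comphet(cil, "PKHD1", C3, trio="trans"),
                k_comphet(cil, "TMEM67", C3, trio="trans"),
                k_comphet(cil, "NPHP1", C3, trio="trans"),
            ]
            + [k_ad_denovo(cil, "PKD2") for _ in range(3)]
            + [k_ad_denovo(cil, "PKD1") for _ in range(2)]
            + [
                k_ar_hom(cil, "BBS1", C3, trio="parents_het"),
                k_ar_hom(cil, "IFT140", C3, trio="parents_het"),
            ]
            + [k_ad_het(cil, "PKD1", C34), k_ad_het(cil, "PKD2", C34)]
        ),
        glo: [
            k_hemi(glo, "COL4A5", C5),
            k_ar_hom(glo, "NPHS2", C5),
            k_ad_het(glo, "WT1", C5),
            k_cnv(glo, "NPHS1", C4, zygosity="hom"),
            k_cnv(glo, "COL4A4", C4, zygosity="hom"),
            k_cnv(glo, "WT1", C4, dup=True),
            k_xld_het(glo, "COL4A5", C4),
            k_xld_het(glo, "COL4A5", C4),
            k_comphet(glo, "NPHS1", C4),
            k_comphet(glo, "NPHS2", C4),
            k_comphet(glo, "COL4A3", C4),
            k_ad_denovo(glo, "LMX1B"),
            k_ad_denovo(glo, "CFH"),
            k_ar_hom(glo, "COL4A3", C3, trio="parents_het"),
            k_ad_het(glo, "TRPC6", C34),
        ],
        nep: [
            k_ar_hom(nep, "AGXT", C5),
            k_ar_hom(nep, "AGXT", C5),
            k_ar_hom(nep, "SLC3A1", C5),
            k_ar_hom(nep, "SLC7A9", C5),
            k_comphet(nep, "AGXT", C5),
            k_comphet(nep, "SLC7A9", C4),
            k_ar_hom(nep, "CYP24A1", C4),
            k_ar_hom(nep, "SLC34A1", C4),
            k_ar_hom(nep, "SLC3A1", C4),
            k_ar_hom(nep, "CYP24A1", C3, trio="parents_het"),
        ],
        tub: [
            k_hemi(tub, "OCRL", C5),
            k_ar_hom(tub, "SLC12A3", C5),
            k_ar_hom(tub, "SLC12A3", C5),
            k_ar_hom(tub, "CLCNKB", C5),
            k_comphet(tub, "SLC12A3", C4),
            k_comphet(tub, "CLCNKB", C4),
            k_ar_hom(tub, "CLDN16", C4),
            k_ar_hom(tub, "CLDN16", C3, trio="parents_het"),
            k_ar_hom(tub, "SLC12A3", C34),
        ],
        oth: [k_ad_het(oth, "TSC2", C4)],
    }
    return plans


def _fixture_other_plans() -> dict:
    """Uncertain, variant-positive inconclusive, and negative plans."""
    cak, cil, glo, nep, tub, oth = (
        _CAT.CAKUT,
        _CAT.ciliopathy,
        _CAT.glomerulopathy,
        _CAT.nephrolithiasis,
        _CAT.tubulopathy,
        _CAT.other,
    )
    uncertain = {
        cak: [
            k_c3_pending(cak, "PAX2"),
            k_c3_pending(cak, "HNF1B"),
            k_c4_partial(cak, "GATA3"),
            k_c4_partial(cak, "EYA1"),
        ],
        cil: [k_c3_pending(cil, "PKD1"), k_c3_pending(cil, "PKD2"), k_c4_partial(cil, "PKD1")],
        glo: [
            k_c3_pending(glo, "WT1"),
            k_c3_pending(glo, "TRPC6"),
            k_c3_pending(glo, "CFH"),
            k_c3_pending(glo, "LMX1B"),
            k_c3_pending(glo, "INF2"),
            k_c4_partial(glo, "WT1"),
            k_c4_partial(glo, "CFH"),
            k_c4_partial(glo, "INF2"),
        ],
        nep: [
            k_c3_pending(nep, "ADCY10"),
            k_c3_pending(nep, "ADCY10"),
            k_c4_partial(nep, "ADCY10"),
        ],
        tub: [k_c3_pending(tub, "UMOD"), k_c4_partial(tub, "UMOD")],
        oth: [k_c3_pending(oth, "TSC1"), k_c3_pending(oth, "ZEB2")],
    }
    inconclusive = {
        cak: [k_ar_single(cak, "FRAS1") for _ in range(9)]
        + [k_offtarget(cak, "PKD2") for _ in range(5)],
        cil: [k_ar_single(cil, "PKHD1") for _ in range(3)] + [k_offtarget(cil, "NPHS2")],
        glo: [k_ar_single(glo, "NPHS1") for _ in range(8)]
        + [k_ar_single(glo, "COL4A3") for _ in range(8)]
        + [k_offtarget(glo, "PKD1") for _ in range(8)],
        nep: [k_ar_single(nep, "AGXT") for _ in range(3)]
        + [k_offtarget(nep, "COL4A3") for _ in range(2)],
        tub: [k_ar_single(tub, "CLCNKB") for _ in range(4)]
        + [k_offtarget(tub, "NPHP1") for _ in range(2)],
        oth: [k_ar_single(oth, "WDR19") for _ in range(5)]
        + [k_offtarget(oth, "SLC12A3") for _ in range(3)],
    }
    negative = {cak: 9, cil: 3, glo: 15, nep: 4, tub: 3, oth: 3}
    return {
        cat: uncertain[cat] + inconclusive[cat] + [k_negative(cat) for _ in range(negative[cat])]
        for cat in uncertain
    }


def build_fixture_plans() -> list:
    """All 191 patient plans, category-ordered, with consequences drawn
    from the class pools, decoys attached, and family history assigned to
    match the published marginals."""
    conclusive = _fixture_conclusive_plans()
    others = _fixture_other_plans()
    c5_pool, c4_pool = list(_C5_POOL), list(_C4_POOL)

    plans: list[PatientPlan] = []
    decoy_i = 0
    for cat, (size, n_conc, fh_diag, fh_nondiag) in FIXTURE_MARGINALS.items():
        cat_conc = conclusive[cat]
        cat_rest = others[cat]
        if len(cat_conc) != n_conc or len(cat_conc) + len(cat_rest) != size:
            raise InfeasiblePlanError(
                f"{cat.value}: planned {len(cat_conc)}+{len(cat_rest)} patients, "
                f"expected {n_conc}+{size - n_conc}"
            )
        for i, plan in enumerate(cat_conc):
            plan.family_history = i < fh_diag
        for i, plan in enumerate(cat_rest):
            plan.family_history = i < fh_nondiag
        for plan in cat_conc + cat_rest:
            # primary consequence from the class pool, partners missense
            for j, vp in enumerate(plan.variants):
                if vp.consequence is not None:
                    continue
                if j > 0 or plan.intended is not Outcome.conclusive:
                    vp.consequence = Consequence.missense
                elif vp.cls is AcmgClass.C5:
                    vp.consequence = c5_pool.pop(0)
                elif vp.cls is AcmgClass.C4:
                    vp.consequence = c4_pool.pop(0)
                else:
                    vp.consequence = Consequence.missense
            n_decoys = 2 if not plan.variants else 1
            for _ in range(n_decoys):
                plan.decoys.append(DECOY_KINDS[decoy_i % len(DECOY_KINDS)])
                decoy_i += 1
            plans.append(plan)
    if c5_pool or c4_pool:
        raise InfeasiblePlanError("consequence pools not exhausted by the plan")

    # a minority of ciliopathy variants are unpublished
    n_unpub = 0
    for plan in plans:
        if plan.category is _CAT.ciliopathy and plan.intended is Outcome.conclusive:
            for vp in plan.variants:
                if n_unpub < 13:
                    vp.published = False
                    n_unpub += 1

    # eight consanguineous families, drawn from recessive-homozygous cases
    n_consang = 0
    for plan in plans:
        if n_consang >= 8:
            break
        if plan.intended is Outcome.conclusive and any(
            vp.zygosity == "hom" for vp in plan.variants
        ):
            plan.consanguinity = True
            n_consang += 1
    return plans


# ---------------------------------------------------------------------------
# Materialization


@dataclass
class GroundTruthLedger:
    """Per patient: intended outcome, planted causative variants, and the
    decoys with the filter each one must fail."""

    patients: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.patients, indent=1, sort_keys=True)


@dataclass
class CohortArtifacts:
    data: CohortData
    ledger: GroundTruthLedger
    clinical_rows: list = field(default_factory=list)


_EVIDENCE_BY_CLASS = {
    AcmgClass.C5: EvidenceProfile(pvs=1, ps=1),
    AcmgClass.C4: EvidenceProfile(ps=1, pm=1),
    AcmgClass.C3: EvidenceProfile(pm=1, pp=1),
    AcmgClass.C3_C4: EvidenceProfile(pm=1, pp=2),  # computes to C3; curated up
}

_REF_ALT = {
    Consequence.missense: ("A", "G"),
    Consequence.nonsense: ("C", "T"),
    Consequence.splicing: ("G", "A"),
    Consequence.frameshift: ("AT", "A"),
    Consequence.synonymous: ("A", "G"),
    Consequence.intronic: ("T", "C"),
}

_ETHNICITIES = [Ethnicity.European] * 10 + [Ethnicity.African] * 2 + [
    Ethnicity.Asian,
    Ethnicity.LatinAmerican,
    Ethnicity.mixed,
]


class _PositionAllocator:
    def __init__(self):
        self.counts: dict = {}

    def next(self, gene: str) -> int:
        k = self.counts.get(gene, 0)
        self.counts[gene] = k + 1
        return GENE_BASE[gene] + 97 * k


def _genotype_fields(zygosity: str, chrom: str):
    """(gt, ad, dp, Genotype) for the proband."""
    if zygosity == "hom":
        return ("1/1", "0,72", 72, Genotype.hom_alt)
    if zygosity == "hemi":
        return ("1", "0,45", 45, Genotype.hemizygous)
    return ("0/1", "30,30", 60, Genotype.het)


def _decoy_spec(kind: str, panel_gene: str):
    """(gene, consequence, splice_region, pop_af, gt, ad, dp)."""
    if kind == "common":
        return (panel_gene, Consequence.missense, False, 0.05, "0/1", "30,30", 60)
    if kind == "low_vaf":
        return (panel_gene, Consequence.missense, False, 0.0, "0/1", "54,6", 60)
    if kind == "low_depth":
        return (panel_gene, Consequence.missense, False, 0.0, "0/1", "5,5", 10)
    if kind == "synonymous":
        return (panel_gene, Consequence.synonymous, False, 0.0, "0/1", "30,30", 60)
    if kind == "intronic":
        return (panel_gene, Consequence.intronic, False, 0.0, "0/1", "30,30", 60)
    if kind == "off_panel":
        return ("TTN", Consequence.missense, False, 0.0, "0/1", "30,30", 60)
    raise ValueError(f"unknown decoy kind {kind}")


# the cascade filter a decoy kind is constructed to fail first
DECOY_FAILS = {
    "common": "quality_frequency",
    "low_vaf": "quality_frequency",
    "low_depth": "quality_frequency",
    "synonymous": "consequence",
    "intronic": "consequence",
    "off_panel": "panel",
}


def materialize(plans: list, id_prefix: str = "P") -> CohortArtifacts:
    """Turn patient plans into a concrete cohort: records, calls, trios,
    clinical annotations, panels, and the ground-truth ledger."""
    panels = demo_registry()
    panel_genes = {p.category: sorted(p.genes) for p in panels}
    alloc = _PositionAllocator()
    data = CohortData(panels=panels)
    ledger = GroundTruthLedger()
    clinical_rows: list = []
    sex_cycle = [Sex.M, Sex.F]

    for i, plan in enumerate(plans):
        pid = f"{id_prefix}{i + 1:03d}"
        sex = plan.sex
        if sex is None:
            # hemizygous plants force male; otherwise alternate
            if any(vp.zygosity == "hemi" for vp in plan.variants):
                sex = Sex.M
            else:
                sex = sex_cycle[i % 2]
        own_panel = plan.category.value
        primary = plan.variants[0].gene if plan.variants else plan.category.value
        patient = PatientRecord(
            patient_id=pid,
            sex=sex,
            age_years=float(1 + (i * 37) % 17),
            macro_category=plan.category,
            primary_disease=f"{primary}-related nephropathy"
            if plan.variants
            else f"{own_panel} (unresolved)",
            family_history=plan.family_history,
            ethnicity=_ETHNICITIES[i % len(_ETHNICITIES)],
            consanguinity=plan.consanguinity,
            phenotype_unclear=plan.phenotype_unclear,
        )
        data.patients.append(patient)

        trio = TrioGenotypes(proband_id=pid)
        if plan.trio is not None:
            trio.father_id, trio.mother_id = f"{pid}-F", f"{pid}-M"

        calls: list[VariantCall] = []
        planted_log, decoy_log = [], []
        for v_i, vp in enumerate(plan.variants):
            chrom = GENE_CHROM[vp.gene]
            pos = alloc.next(vp.gene)
            csq = vp.consequence
            if csq.is_cnv:
                ref, alt = "N", ("<DUP>" if csq is Consequence.cnv_dup else "<DEL>")
                gt_enum = Genotype.hom_alt if vp.zygosity == "hom" else Genotype.het
                vaf, depth = None, None
            else:
                ref, alt = _REF_ALT[csq]
                _, ad, depth, gt_enum = _genotype_fields(vp.zygosity, chrom)
                alt_reads = int(ad.split(",")[1])
                vaf = alt_reads / depth
            evidence = _EVIDENCE_BY_CLASS[
                AcmgClass.C3 if vp.cls is AcmgClass.C3_C4 else vp.cls
            ]
            if vp.cls is AcmgClass.C3_C4:
                evidence = _EVIDENCE_BY_CLASS[AcmgClass.C3_C4]
            call = VariantCall(
                patient_id=pid,
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                gene=vp.gene,
                consequence=csq,
                splice_region=csq is Consequence.splicing,
                pop_af=0.0005 if vp.published else 0.0,
                vaf=vaf,
                depth=depth,
                genotype=gt_enum,
                evidence=evidence,
                published=vp.published,
            )
            calls.append(call)
            planted_log.append(
                {
                    "gene": vp.gene,
                    "class": vp.cls.value,
                    "zygosity": vp.zygosity,
                    "consequence": csq.value,
                    "phenotype_fit": vp.phenotype_fit.value,
                    "chrom": chrom,
                    "pos": pos,
                }
            )
            # parental genotypes according to the trio scenario
            if plan.trio is not None:
                fa, mo = trio.father_id, trio.mother_id
                if plan.trio == "denovo":
                    parent_gt = {fa: (Genotype.hom_ref, 60), mo: (Genotype.hom_ref, 60)}
                elif plan.trio == "parents_het":
                    parent_gt = {fa: (Genotype.het, 60), mo: (Genotype.het, 60)}
                elif plan.trio == "trans":
                    carrier, clear = (mo, fa) if v_i == 0 else (fa, mo)
                    parent_gt = {carrier: (Genotype.het, 60), clear: (Genotype.hom_ref, 60)}
                elif plan.trio == "carrier":
                    parent_gt = {fa: (Genotype.het, 60), mo: (Genotype.hom_ref, 60)}
                else:
                    raise ValueError(f"unknown trio scenario {plan.trio}")
                site = trio.genotypes.setdefault(call.key, {})
                site[pid] = (gt_enum, depth)
                site.update(parent_gt)

        # one clinical row per causal gene
        seen_genes = set()
        for vp in plan.variants:
            if vp.gene in seen_genes:
                continue
            seen_genes.add(vp.gene)
            clinical_rows.append(
                {
                    "patient_id": pid,
                    "gene": vp.gene,
                    "phenotype_fit": vp.phenotype_fit.value,
                    "manual_class": vp.cls.value if vp.cls is AcmgClass.C3_C4 else None,
                }
            )

        for kind in plan.decoys:
            gene, csq, splice, pop_af, gt, ad, dp = _decoy_spec(
                kind, panel_genes[own_panel][0]
            )
            pos = alloc.next(gene)
            alt_reads = int(ad.split(",")[1])
            calls.append(
                VariantCall(
                    patient_id=pid,
                    chrom=GENE_CHROM[gene],
                    pos=pos,
                    ref=_REF_ALT[csq][0],
                    alt=_REF_ALT[csq][1],
                    gene=gene,
                    consequence=csq,
                    splice_region=splice,
                    pop_af=pop_af,
                    vaf=alt_reads / dp,
                    depth=dp,
                    genotype=Genotype.het,
                    published=True,
                )
            )
            decoy_log.append({"gene": gene, "kind": kind, "fails": DECOY_FAILS[kind], "pos": pos})
            if plan.trio is not None:
                site = trio.genotypes.setdefault(calls[-1].key, {})
                site[pid] = (Genotype.het, dp)
                site[trio.father_id] = (Genotype.hom_ref, 60)
                site[trio.mother_id] = (Genotype.hom_ref, 60)

        data.calls[pid] = calls
        data.trios[pid] = trio
        ledger.patients[pid] = {
            "intended_outcome": plan.intended.value,
            "planted": planted_log,
            "decoys": decoy_log,
        }

    data.clinical = {
        (r["patient_id"], r["gene"]): (
            PhenotypeFit(r["phenotype_fit"]),
            AcmgClass(r["manual_class"]) if r["manual_class"] else None,
        )
        for r in clinical_rows
    }
    return CohortArtifacts(data=data, ledger=ledger, clinical_rows=clinical_rows)


# ---------------------------------------------------------------------------
# Writing a cohort to disk


def _gt_string(gt: Genotype, chrom: str, member_sex: Sex) -> str:
    haploid = chrom in ("X", "Y") and member_sex is Sex.M
    if gt is Genotype.hom_ref:
        return "0" if haploid else "0/0"
    if gt is Genotype.het:
        return "0/1"
    if gt is Genotype.hom_alt:
        return "1/1"
    if gt is Genotype.hemizygous:
        return "1"
    return "./."


def write_cohort(artifacts: CohortArtifacts, outdir) -> None:
    """Persist a cohort as patients.tsv / panels.tsv / clinical.tsv /
    cohort.ped / vcf/<id>.vcf / ledger.json."""
    outdir = Path(outdir)
    (outdir / "vcf").mkdir(parents=True, exist_ok=True)
    data = artifacts.data
    io_formats.write_patients(data.patients, outdir / "patients.tsv")
    io_formats.write_panels(data.panels, outdir / "panels.tsv")
    io_formats.write_clinical(artifacts.clinical_rows, outdir / "clinical.tsv")
    (outdir / "ledger.json").write_text(artifacts.ledger.to_json())

    ped_lines = []
    by_id = {p.patient_id: p for p in data.patients}
    for p in data.patients:
        trio = data.trios[p.patient_id]
        fa, mo = trio.father_id or "0", trio.mother_id or "0"
        sex_code = "1" if p.sex is Sex.M else "2"
        ped_lines.append(f"{p.patient_id}\t{p.patient_id}\t{fa}\t{mo}\t{sex_code}\t2")
        if trio.father_id:
            ped_lines.append(f"{p.patient_id}\t{trio.father_id}\t0\t0\t1\t1")
        if trio.mother_id:
            ped_lines.append(f"{p.patient_id}\t{trio.mother_id}\t0\t0\t2\t1")
    (outdir / "cohort.ped").write_text("\n".join(ped_lines) + "\n")

    for p in data.patients:
        pid = p.patient_id
        trio = data.trios[pid]
        samples = [pid] + [s for s in (trio.father_id, trio.mother_id) if s]
        member_sex = {pid: by_id[pid].sex}
        if trio.father_id:
            member_sex[trio.father_id] = Sex.M
        if trio.mother_id:
            member_sex[trio.mother_id] = Sex.F
        records = []
        for call in data.calls[pid]:
            info = {
                "GENE": call.gene,
                "CSQ": call.consequence.value,
                "SPLICE_REGION": call.splice_region,
                "PUBLISHED": int(call.published) if call.published is not None else None,
            }
            if call.pop_af:
                info["POP_AF"] = call.pop_af
            if call.evidence:
                for f_name, key in io_formats.EVIDENCE_INFO_KEYS.items():
                    n = getattr(call.evidence, f_name)
                    if n:
                        info[key] = n
            if call.consequence.is_cnv:
                info["SVTYPE"] = "DEL" if call.consequence is Consequence.cnv_del else "DUP"
                info["END"] = call.pos + 5000
            sample_fields = {}
            site = trio.genotypes.get(call.key, {})
            for s in samples:
                if s == pid:
                    gt_enum, depth = call.genotype, call.depth
                elif s in site:
                    gt_enum, depth = site[s]
                else:
                    gt_enum, depth = Genotype.hom_ref, 60
                gt = _gt_string(gt_enum, call.chrom, member_sex[s])
                if call.consequence.is_cnv:
                    sample_fields[s] = (gt, None, None)
                elif s == pid:
                    alt_reads = (
                        int(round((call.vaf or 0) * depth)) if depth is not None else 0
                    )
                    ref_reads = (depth or 0) - alt_reads
                    sample_fields[s] = (gt, f"{ref_reads},{alt_reads}", depth)
                else:
                    alt_reads = {
                        Genotype.hom_ref: 0,
                        Genotype.het: depth // 2 if depth else 0,
                        Genotype.hom_alt: depth or 0,
                        Genotype.hemizygous: depth or 0,
                    }.get(gt_enum, 0)
                    sample_fields[s] = (
                        gt,
                        f"{(depth or 0) - alt_reads},{alt_reads}",
                        depth,
                    )
            records.append(
                {
                    "chrom": call.chrom,
                    "pos": call.pos,
                    "ref": call.ref,
                    "alt": call.alt,
                    "info": info,
                    "samples": sample_fields,
                }
            )
        io_formats.write_vcf(outdir / "vcf" / f"{pid}.vcf", records, samples)


# ---------------------------------------------------------------------------
# Fixture entry point with self-checks


def build_study_fixture(outdir=None) -> CohortArtifacts:
    """The deterministic 191-patient cohort; every published marginal it
    encodes is re-checked at build time and any mismatch is a build
    error."""
    plans = build_fixture_plans()
    _check_fixture_plans(plans)
    artifacts = materialize(plans)
    if outdir is not None:
        write_cohort(artifacts, outdir)
    return artifacts


def _check_fixture_plans(plans: list) -> None:
    if len(plans) != 191:
        raise InfeasiblePlanError(f"cohort size {len(plans)} != 191")
    conc = [p for p in plans if p.intended is Outcome.conclusive]
    if len(conc) != 71:
        raise InfeasiblePlanError("conclusive patients != 71")
    n_fh = sum(1 for p in plans if p.family_history)
    n_fh_diag = sum(1 for p in conc if p.family_history)
    if (n_fh, n_fh_diag) != (47, 28):
        raise InfeasiblePlanError("family-history marginals off")
    n_vp = sum(1 for p in plans if p.variants)
    if n_vp != 154:
        raise InfeasiblePlanError("variant-positive patients != 154")
    uncertain = sum(1 for p in plans if p.intended is Outcome.uncertain)
    inconc_vp = sum(
        1 for p in plans if p.intended is Outcome.inconclusive and p.variants
    )
    if (uncertain, inconc_vp) != (22, 61):
        raise InfeasiblePlanError("report split != 71/22/61")
    variants = [vp for p in conc for vp in p.variants]
    if len(variants) != 96:
        raise InfeasiblePlanError("reported variants != 96")
    csq = {}
    for vp in variants:
        k = "cnv" if vp.consequence.is_cnv else vp.consequence.value
        csq[k] = csq.get(k, 0) + 1
    if csq != {"missense": 53, "frameshift": 15, "nonsense": 14, "splicing": 9, "cnv": 5}:
        raise InfeasiblePlanError(f"consequence tallies off: {csq}")
    genes = {vp.gene for vp in variants}
    if len(genes) != 32:
        raise InfeasiblePlanError(f"distinct genes {len(genes)} != 32")
    classes = {}
    for p in conc:
        lead = p.variants[0].cls
        classes[lead.value] = classes.get(lead.value, 0) + 1
    if classes != {"C5": 17, "C4": 34, "C3": 16, "C3_C4": 4}:
        raise InfeasiblePlanError(f"leading classes off: {classes}")
    per_cat = {}
    for p in conc:
        per_cat[p.category] = per_cat.get(p.category, 0) + 1
    expected = {c: m[1] for c, m in FIXTURE_MARGINALS.items()}
    if per_cat != expected:
        raise InfeasiblePlanError("per-category diagnostic counts off")


# ---------------------------------------------------------------------------
# Randomized simulation


@dataclass
class SimConfig:
    """Study conditions for randomized synthetic cohorts.  Default rates
    follow the clinical cohort the fixture mirrors: ~37% of patients
    reach a conclusive report, ~12% stay uncertain, ~31% are
    variant-positive but inconclusive, the rest are negative exomes."""

    seed: int = 0
    n_patients: int = 40
    category_proportions: dict = field(
        default_factory=lambda: {
            _CAT.CAKUT: 34 / 191,
            _CAT.ciliopathy: 39 / 191,
            _CAT.glomerulopathy: 62 / 191,
            _CAT.nephrolithiasis: 22 / 191,
            _CAT.tubulopathy: 20 / 191,
            _CAT.other: 14 / 191,
        }
    )
    family_history_rate: float = 47 / 191
    conclusive_rate: float = 71 / 191
    uncertain_rate: float = 22 / 191
    inconclusive_variant_rate: float = 61 / 191
    decoys_per_patient: int = 2
    trio_rate: float = 0.5

    def __post_init__(self) -> None:
        total = sum(self.category_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("category proportions must sum to 1")
        for r in (
            self.family_history_rate,
            self.conclusive_rate,
            self.uncertain_rate,
            self.inconclusive_variant_rate,
            self.trio_rate,
        ):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.conclusive_rate + self.uncertain_rate + self.inconclusive_variant_rate > 1.0:
            raise ValueError("outcome rates exceed 1")


_OFFTARGET_SOURCE = {
    _CAT.CAKUT: "PKD2",
    _CAT.ciliopathy: "NPHS2",
    _CAT.glomerulopathy: "PKD1",
    _CAT.nephrolithiasis: "COL4A3",
    _CAT.tubulopathy: "NPHP1",
    _CAT.other: "SLC12A3",
}


def simulate_cohort(cfg: SimConfig) -> CohortArtifacts:
    """Draw a randomized cohort from the configured study conditions.

    Reproducible: the same config (including seed) yields an identical
    cohort.  Conclusive patients whose plant is a VUS always come with a
    segregation-confirming trio; pathogenic/likely-pathogenic plants get
    a trio at ``trio_rate`` (it never changes their outcome).
    """
    rng = np.random.default_rng(cfg.seed)
    panels = {p.category: p for p in demo_registry()}
    cats = list(cfg.category_proportions)
    probs = np.array([cfg.category_proportions[c] for c in cats], dtype=float)

    def genes_of(cat, modes):
        return genes_with_mode(panels[cat.value], modes)

    plans = []
    for _ in range(cfg.n_patients):
        cat = cats[int(rng.choice(len(cats), p=probs))]
        u = rng.random()
        if u < cfg.conclusive_rate:
            with_trio = rng.random() < cfg.trio_rate
            kinds = ["ad_het", "ar_hom", "comphet"]
            if with_trio:
                kinds += ["ad_denovo", "ar_hom_trio", "comphet_trans"]
            kind = kinds[int(rng.choice(len(kinds)))]
            cls = [AcmgClass.C4, AcmgClass.C4, AcmgClass.C5][int(rng.choice(3))]
            if kind == "ad_het":
                gene = _pick(rng, genes_of(cat, {Moi.AD}))
                plan = k_ad_het(cat, gene, cls)
                if with_trio:
                    plan.trio = "carrier"
            elif kind == "ar_hom":
                plan = k_ar_hom(cat, _pick(rng, genes_of(cat, {Moi.AR})), cls)
                if with_trio:
                    plan.trio = "parents_het"
            elif kind == "comphet":
                plan = k_comphet(cat, _pick(rng, genes_of(cat, {Moi.AR})), cls)
                if with_trio:
                    plan.trio = "trans"
            elif kind == "ad_denovo":
                plan = k_ad_denovo(cat, _pick(rng, genes_of(cat, {Moi.AD})))
            elif kind == "ar_hom_trio":
                plan = k_ar_hom(
                    cat, _pick(rng, genes_of(cat, {Moi.AR})), AcmgClass.C3, trio="parents_het"
                )
            else:
                plan = k_comphet(
                    cat, _pick(rng, genes_of(cat, {Moi.AR})), AcmgClass.C3, trio="trans"
                )
        elif u < cfg.conclusive_rate + cfg.uncertain_rate:
            if rng.random() < 0.5:
                plan = k_c3_pending(cat, _pick(rng, genes_of(cat, {Moi.AD})))
            else:
                plan = k_c4_partial(cat, _pick(rng, genes_of(cat, {Moi.AD})))
        elif u < cfg.conclusive_rate + cfg.uncertain_rate + cfg.inconclusive_variant_rate:
            if rng.random() < 0.6:
                plan = k_ar_single(cat, _pick(rng, genes_of(cat, {Moi.AR})))
            else:
                plan = k_offtarget(cat, _OFFTARGET_SOURCE[cat])
        else:
            plan = k_negative(cat)
        plan.family_history = bool(rng.random() < cfg.family_history_rate)
        for vp in plan.variants:
            if vp.consequence is None:
                vp.consequence = [
                    Consequence.missense,
                    Consequence.missense,
                    Consequence.frameshift,
                    Consequence.nonsense,
                    Consequence.splicing,
                ][int(rng.choice(5))]
        n_decoys = cfg.decoys_per_patient
        for _ in range(n_decoys):
            plan.decoys.append(DECOY_KINDS[int(rng.choice(len(DECOY_KINDS)))])
        plans.append(plan)
    return materialize(plans, id_prefix="S")


def _pick(rng, pool):
    return pool[int(rng.choice(len(pool)))]
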