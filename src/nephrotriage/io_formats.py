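"""Readers and writers for the on-disk formats the pipeline touches.

VCF (via cyvcf2), 6-column PED, TSV panel / patient / clinical-annotation
tables, and the JSON report schema.  All coordinates are 1-based, fully
closed, as in VCF; no translation layer exists anywhere in the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
from cyvcf2 import VCF

from .types import (
    AcmgClass,
    ClassifiedVariant,
    Consequence,
    Ethnicity,
    EvidenceProfile,
    Genotype,
    MacroCategory,
    Moi,
    Outcome,
    PanelEntry,
    GenePanel,
    PatientRecord,
    ReportOutcome,
    SEX_CHROMOSOMES,
    Sex,
    VariantCall,
)

EVIDENCE_INFO_KEYS = {
    "pvs": "ACMG_PVS",
    "ps": "ACMG_PS",
    "pm": "ACMG_PM",
    "pp": "ACMG_PP",
    "ba": "ACMG_BA",
    "bs": "ACMG_BS",
    "bp": "ACMG_BP",
}


@dataclass
class VcfInfoKeys:
    """Names of the INFO annotations the reader expects.  Population AF
    and consequence are inputs to this pipeline, not computed by it, so
    the key names are configurable to match the upstream annotator."""

    gene: str = "GENE"
    consequence: str = "CSQ"
    splice_region: str = "SPLICE_REGION"
    pop_af: str = "POP_AF"
    published: str = "PUBLISHED"


class VcfConfigError(ValueError):
    """A required annotation key is missing from a VCF record."""


def _genotype_from_alleles(alleles, alt_index, chrom, sex: Optional[Sex]) -> Genotype:
    """Map a per-sample allele vector to the genotype enum.

    Haploid calls and any alt-carrying male call on X/Y map to
    hemizygous; otherwise the mapping is by alt-allele count.
    """
    known = [a for a in alleles if a >= 0]
    if not known:
        return Genotype.missing
    n_alt = sum(1 for a in known if a == alt_index)
    on_sex = chrom in SEX_CHROMOSOMES
    if len(known) == 1:  # haploid GT
        if n_alt == 0:
            return Genotype.hom_ref
        return Genotype.hemizygous if on_sex else Genotype.het
    if n_alt == 0:
        return Genotype.hom_ref
    if on_sex and sex is Sex.M:
        return Genotype.hemizygous
    if n_alt >= 2:
        return Genotype.hom_alt
    return Genotype.het


def read_vcf(
    path,
    sample_map: Optional[Mapping[str, str]] = None,
    sex_map: Optional[Mapping[str, Sex]] = None,
    info_keys: VcfInfoKeys = VcfInfoKeys(),
) -> list:
    """Read a VCF into VariantCall records, one per alternate allele per
    sample (multi-allelic records are decomposed).

    ``sample_map`` maps VCF sample names to patient ids (identity when
    omitted); ``sex_map`` supplies each patient's sex for the hemizygosity
    rule on X/Y.  Samples that are homozygous reference at a site still
    yield a record (genotype ``hom_ref``) — parental reference genotypes
    carry the depth evidence de novo detection needs.
    """
    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises plain OSError on bad files
        raise ValueError(f"malformed or unreadable VCF {path}: {exc}") from exc
    samples = vcf.samples
    sample_map = dict(sample_map or {s: s for s in samples})
    calls: list[VariantCall] = []
    for rec in vcf:
        info = dict(rec.INFO)
        gene = info.get(info_keys.gene)
        if gene is None:
            raise VcfConfigError(
                f"{path}:{rec.CHROM}:{rec.POS}: missing INFO key "
                f"{info_keys.gene!r} (gene symbol)"
            )
        csq_raw = info.get(info_keys.consequence)
        if csq_raw is None:
            raise VcfConfigError(
                f"{path}:{rec.CHROM}:{rec.POS}: missing INFO key "
                f"{info_keys.consequence!r} (consequence)"
            )
        splice = bool(info.get(info_keys.splice_region, False))
        # Absent population AF means the variant is novel: treat as 0 so
        # it passes the rarity filter.
        pop_af = float(info.get(info_keys.pop_af, 0.0) or 0.0)
        published = info.get(info_keys.published)
        if published is not None:
            published = bool(int(published))
        evidence = None
        if any(info.get(k) is not None for k in EVIDENCE_INFO_KEYS.values()):
            evidence = EvidenceProfile(
                **{f: int(info.get(k, 0) or 0) for f, k in EVIDENCE_INFO_KEYS.items()}
            )
        ad = rec.format("AD")
        dp = rec.format("DP")
        genotypes = rec.genotypes
        for alt_i, alt in enumerate(rec.ALT, start=1):
            try:
                consequence = Consequence(csq_raw)
            except ValueError:
                consequence = Consequence.other
            is_cnv = alt in ("<DEL>", "<DUP>") or consequence.is_cnv
            if alt == "<DEL>":
                consequence = Consequence.cnv_del
            elif alt == "<DUP>":
                consequence = Consequence.cnv_dup
            for s_i, sample in enumerate(samples):
                if sample not in sample_map:
                    continue
                patient_id = sample_map[sample]
                sex = (sex_map or {}).get(patient_id)
                alleles = genotypes[s_i][:-1]  # last element is phased flag
                gt = _genotype_from_alleles(alleles, alt_i, rec.CHROM, sex)
                vaf = depth = None
                if not is_cnv:
                    if dp is not None and dp[s_i][0] >= 0:
                        depth = int(dp[s_i][0])
                    if ad is not None and depth:
                        alt_reads = int(ad[s_i][alt_i])
                        if alt_reads >= 0:
                            vaf = alt_reads / depth
                calls.append(
                    VariantCall(
                        patient_id=patient_id,
                        chrom=rec.CHROM,
                        pos=rec.POS,
                        ref=rec.REF,
                        alt=alt,
                        gene=gene,
                        consequence=consequence,
                        splice_region=splice,
                        pop_af=pop_af,
                        vaf=vaf,
                        depth=depth,
                        genotype=gt,
                        evidence=evidence,
                        published=published,
                    )
                )
    return calls


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Molecular consequence">
##INFO=<ID=SPLICE_REGION,Number=0,Type=Flag,Description="Maps within a splice region">
##INFO=<ID=POP_AF,Number=1,Type=Float,Description="Population allele frequency">
##INFO=<ID=PUBLISHED,Number=1,Type=Integer,Description="1 if previously published">
##INFO=<ID=ACMG_PVS,Number=1,Type=Integer,Description="Very strong pathogenic evidence count">
##INFO=<ID=ACMG_PS,Number=1,Type=Integer,Description="Strong pathogenic evidence count">
##INFO=<ID=ACMG_PM,Number=1,Type=Integer,Description="Moderate pathogenic evidence count">
##INFO=<ID=ACMG_PP,Number=1,Type=Integer,Description="Supporting pathogenic evidence count">
##INFO=<ID=ACMG_BA,Number=1,Type=Integer,Description="Stand-alone benign evidence count">
##INFO=<ID=ACMG_BS,Number=1,Type=Integer,Description="Strong benign evidence count">
##INFO=<ID=ACMG_BP,Number=1,Type=Integer,Description="Supporting benign evidence count">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant type">
##INFO=<ID=END,Number=1,Type=Integer,Description="End of structural variant">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""

_CONTIG_ORDER = [str(i) for i in range(1, 23)] + ["X", "Y"]


def write_vcf(path, records: list, samples: list) -> None:
    """Write VCF rows described by plain dicts.

    Each record: chrom, pos, ref, alt, info (dict), and per-sample
    ``samples`` dict mapping sample name -> (gt_string, ad_string or None,
    dp or None).  Used by the cohort simulator; records are sorted into
    karyotype order before writing.
    """
    lines = [_VCF_HEADER]
    for c in _CONTIG_ORDER:
        lines.append(f"##contig=<ID={c}>\n")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")

    def sort_key(r):
        chrom = r["chrom"]
        order = _CONTIG_ORDER.index(chrom) if chrom in _CONTIG_ORDER else 99
        return (order, r["pos"])

    for r in sorted(records, key=sort_key):
        info_parts = []
        for k, v in r["info"].items():
            if v is True:
                info_parts.append(k)
            elif v is not None and v is not False:
                info_parts.append(f"{k}={v}")
        fields = [
            r["chrom"],
            str(r["pos"]),
            ".",
            r["ref"],
            r["alt"],
            ".",
            ".",
            ";".join(info_parts) or ".",
            "GT:AD:DP",
        ]
        for s in samples:
            gt, ad, dp = r["samples"].get(s, ("./.", None, None))
            fields.append(f"{gt}:{ad if ad is not None else '.'}:{dp if dp is not None else '.'}")
        lines.append("\t".join(fields) + "\n")
    Path(path).write_text("".join(lines))


@dataclass
class PedRecord:
    family_id: str
    individual_id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    sex: Optional[Sex]
    phenotype: int


def read_ped(path) -> list:
    """Read a 6-column PED file; '0' marks an unavailable parent.

    Returns PedRecord rows; trio assembly happens downstream so that
    singletons remain first-class.  Cyclic parentage is rejected.
    """
    rows = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 6:
            raise ValueError(f"{path}:{ln}: expected 6 PED columns, got {len(parts)}")
        fam, ind, fa, mo, sex, pheno = parts[:6]
        rows.append(
            PedRecord(
                family_id=fam,
                individual_id=ind,
                father_id=None if fa == "0" else fa,
                mother_id=None if mo == "0" else mo,
                sex={"1": Sex.M, "2": Sex.F}.get(sex),
                phenotype=int(pheno) if pheno.isdigit() else 0,
            )
        )
    parents = {r.individual_id: [p for p in (r.father_id, r.mother_id) if p] for r in rows}
    for start in parents:  # reject cyclic parentage by walking ancestors
        stack, seen = [start], set()
        while stack:
            node = stack.pop()
            for p in parents.get(node, []):
                if p == start:
                    raise ValueError(f"cyclic parentage involving {start}")
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
    return rows


# ---------------------------------------------------------------------------
# JSON report


def _variant_to_dict(cv: ClassifiedVariant) -> dict:
    call = cv.call
    return {
        "patient_id": call.patient_id,
        "chrom": call.chrom,
        "pos": call.pos,
        "ref": call.ref,
        "alt": call.alt,
        "gene": call.gene,
        "consequence": call.consequence.value,
        "splice_region": call.splice_region,
        "pop_af": call.pop_af,
        "vaf": call.vaf,
        "depth": call.depth,
        "genotype": call.genotype.value,
        "published": call.published,
        "evidence": asdict(call.evidence) if call.evidence else None,
        "acmg_class": cv.acmg_class.value,
        "computed_class": cv.computed_class.value,
        "manual_class": cv.manual_class.value if cv.manual_class else None,
        "mode": cv.mode,
    }


def _variant_from_dict(d: dict) -> ClassifiedVariant:
    call = VariantCall(
        patient_id=d["patient_id"],
        chrom=d["chrom"],
        pos=d["pos"],
        ref=d["ref"],
        alt=d["alt"],
        gene=d["gene"],
        consequence=Consequence(d["consequence"]),
        splice_region=d["splice_region"],
        pop_af=d["pop_af"],
        vaf=d["vaf"],
        depth=d["depth"],
        genotype=Genotype(d["genotype"]),
        evidence=EvidenceProfile(**d["evidence"]) if d.get("evidence") else None,
        published=d.get("published"),
    )
    return ClassifiedVariant(
        call=call,
        acmg_class=AcmgClass(d["acmg_class"]),
        computed_class=AcmgClass(d["computed_class"]),
        manual_class=AcmgClass(d["manual_class"]) if d.get("manual_class") else None,
        mode=d.get("mode"),
    )


def write_report(outcomes: list, path) -> None:
    """Serialize ReportOutcome records to the JSON report schema.

    One object per patient; duplicate patient ids are rejected because a
    genetic report is issued per patient, not per finding.
    """
    seen = set()
    payload = []
    for o in outcomes:
        if o.patient_id in seen:
            raise ValueError(f"duplicate patient_id in report: {o.patient_id}")
        seen.add(o.patient_id)
        payload.append(
            {
                "patient_id": o.patient_id,
                "outcome": o.outcome.value,
                "reasons": list(o.reasons),
                "secondary_reasons": list(o.secondary_reasons),
                "reported_variants": [_variant_to_dict(v) for v in o.reported_variants],
            }
        )
    try:
        Path(path).write_text(json.dumps({"patients": payload}, indent=1))
    except OSError as exc:
        raise OSError(f"cannot write report to {path}: {exc}") from exc


def read_report(path) -> list:
    data = json.loads(Path(path).read_text())
    outcomes = []
    for d in data["patients"]:
        outcomes.append(
            ReportOutcome(
                patient_id=d["patient_id"],
                outcome=Outcome(d["outcome"]),
                reasons=list(d["reasons"]),
                secondary_reasons=list(d.get("secondary_reasons", [])),
                reported_variants=[_variant_from_dict(v) for v in d["reported_variants"]],
            )
        )
    return outcomes


# ---------------------------------------------------------------------------
# TSV tables


def read_panels(path) -> list:
    """Read the panel registry TSV (columns: gene, moi, chromosome,
    category, panel_version) into one GenePanel per category."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "moi", "chromosome", "category"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"panel table {path} lacks columns: {sorted(missing)}")
    panels = []
    for category, sub in df.groupby("category", sort=True):
        entries = [
            PanelEntry(gene=r.gene, moi=Moi(r.moi), chromosome=r.chromosome)
            for r in sub.itertuples()
        ]
        panels.append(GenePanel(name=str(category), category=str(category), entries=entries))
    return panels


def write_panels(panels: list, path, version: str = "demo-1") -> None:
    rows = []
    for p in panels:
        if p.category == "kidneyome":  # derived, never persisted
            continue
        for e in p.entries:
            rows.append(
                {
                    "gene": e.gene,
                    "moi": e.moi.value,
                    "chromosome": e.chromosome,
                    "category": p.category,
                    "panel_version": version,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


_BOOL = {"True": True, "False": False, "1": True, "0": False,
         "true": True, "false": False}


def read_patients(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype=str)
    patients = []
    for r in df.itertuples():
        patients.append(
            PatientRecord(
                patient_id=r.patient_id,
                sex=Sex(r.sex),
                age_years=float(r.age_years),
                macro_category=MacroCategory(r.macro_category),
                primary_disease=getattr(r, "primary_disease", "") or "",
                family_history=_BOOL[r.family_history],
                ethnicity=Ethnicity(r.ethnicity),
                consanguinity=_BOOL[r.consanguinity],
                phenotype_unclear=_BOOL[getattr(r, "phenotype_unclear", "0")],
                phenotype_overlapping=_BOOL[getattr(r, "phenotype_overlapping", "0")],
            )
        )
    return patients


def write_patients(patients: list, path) -> None:
    rows = [
        {
            "patient_id": p.patient_id,
            "sex": p.sex.value,
            "age_years": p.age_years,
            "macro_category": p.macro_category.value,
            "primary_disease": p.primary_disease,
            "family_history": p.family_history,
            "ethnicity": p.ethnicity.value,
            "consanguinity": p.consanguinity,
            "phenotype_unclear": p.phenotype_unclear,
            "phenotype_overlapping": p.phenotype_overlapping,
        }
        for p in patients
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_clinical(path) -> dict:
    """Clinician annotations per (patient, gene): phenotype fit and an
    optional manual ACMG class override.  Returns
    {(patient_id, gene): (PhenotypeFit value, AcmgClass or None)}."""
    from .types import PhenotypeFit

    df = pd.read_csv(path, sep="\t", dtype=str)
    out = {}
    for r in df.itertuples():
        manual = getattr(r, "manual_class", None)
        if isinstance(manual, float) or manual in (None, "", "nan"):
            manual = None
        out[(r.patient_id, r.gene)] = (
            PhenotypeFit(r.phenotype_fit),
            AcmgClass(manual) if manual else None,
        )
    return out


def write_clinical(rows: list, path) -> None:
    """rows: dicts with patient_id, gene, phenotype_fit, manual_class."""
    pd.DataFrame(rows, columns=["patient_id", "gene", "phenotype_fit", "manual_class"]).to_csv(
        path, sep="\t", index=False
    )
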