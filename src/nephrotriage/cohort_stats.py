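"""Cohort-level diagnostic-yield statistics and variant tallies.

"Diagnostic" means a conclusive report; an uncertain report is not
counted as a diagnosis.  All percentages are rounded half-up to one
decimal, and every denominator stays explicit in the output so any
printed percentage can be recomputed from its two counts.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import pandas as pd

from .types import (
    AcmgClass,
    CLASS_RANK,
    Outcome,
    PatientRecord,
    ReportOutcome,
)


def percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """100 * numerator / denominator, rounded half-up."""
    if denominator == 0:
        return 0.0
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(numerator) * 100 / Decimal(denominator)).quantize(q, rounding=ROUND_HALF_UP)
    )


def _match(outcomes: list, patients: list) -> dict:
    by_id = {p.patient_id: p for p in patients}
    unmatched = [o.patient_id for o in outcomes if o.patient_id not in by_id]
    if unmatched:
        raise ValueError(f"outcomes without a patient record: {unmatched}")
    return by_id


def diagnostic_yield(
    outcomes: list, patients: list, stratify_by: str = "macro_category"
) -> pd.DataFrame:
    """Per-stratum diagnostic yield table.

    ``stratify_by`` is "macro_category" or "family_history".  Yield is
    100 * conclusive / cases in the stratum, half-up to one decimal.
    """
    by_id = _match(outcomes, patients)
    rows: dict = {}
    for o in outcomes:
        p = by_id[o.patient_id]
        if stratify_by == "macro_category":
            stratum = p.macro_category.value
        elif stratify_by == "family_history":
            stratum = "positive" if p.family_history else "negative"
        else:
            raise ValueError(f"unknown stratifier {stratify_by!r}")
        r = rows.setdefault(stratum, {"n_cases": 0, "n_diagnostic": 0})
        r["n_cases"] += 1
        if o.outcome is Outcome.conclusive:
            r["n_diagnostic"] += 1
    table = pd.DataFrame(
        [
            {
                "stratum": s,
                "n_cases": r["n_cases"],
                "n_diagnostic": r["n_diagnostic"],
                "yield_percent": percent(r["n_diagnostic"], r["n_cases"]),
            }
            for s, r in sorted(rows.items())
        ]
    )
    return table


def report_split(outcomes: list) -> dict:
    """Overall report-category counts.  Conclusive/uncertain/inconclusive
    shares are expressed over the variant-positive patients, as the
    clinical workflow does; variant-negative exomes are tracked as
    ``n_no_variants``."""
    n = len(outcomes)
    vp = [o for o in outcomes if o.variant_positive]
    n_vp = len(vp)
    counts = {
        Outcome.conclusive: 0,
        Outcome.uncertain: 0,
        Outcome.inconclusive: 0,
    }
    for o in vp:
        counts[o.outcome] += 1
    return {
        "n_patients": n,
        "n_variant_positive": n_vp,
        "pct_variant_positive": percent(n_vp, n),
        "n_no_variants": n - n_vp,
        "pct_no_variants": percent(n - n_vp, n),
        "n_conclusive": counts[Outcome.conclusive],
        "pct_conclusive_of_variant_positive": percent(counts[Outcome.conclusive], n_vp),
        "n_uncertain": counts[Outcome.uncertain],
        "pct_uncertain_of_variant_positive": percent(counts[Outcome.uncertain], n_vp),
        "n_inconclusive": counts[Outcome.inconclusive],
        "pct_inconclusive_of_variant_positive": percent(counts[Outcome.inconclusive], n_vp),
        "pct_conclusive_of_cohort": percent(counts[Outcome.conclusive], n),
    }


def variant_tallies(outcomes: list) -> dict:
    """Tallies over the variants listed in conclusive reports: counts and
    percentages by consequence, leading ACMG class per patient, zygosity
    mode per variant, published/novel status, plus distinct variant and
    gene counts."""
    conclusive = [o for o in outcomes if o.outcome is Outcome.conclusive]
    variants = [v for o in conclusive for v in o.reported_variants]
    distinct = {v.call.key for v in variants}
    genes = {v.call.gene for v in variants}
    n_var = len(variants)

    def tally(keys) -> dict:
        counts: dict = {}
        for k in keys:
            counts[k] = counts.get(k, 0) + 1
        return counts

    csq_counts = tally(v.call.consequence.value for v in variants)
    mode_counts = tally(v.mode or "unknown" for v in variants)
    pub_counts = tally(
        ("published" if v.call.published else "novel")
        for v in variants
        if v.call.published is not None
    )
    lead_class_counts = tally(
        max((v.acmg_class for v in o.reported_variants), key=CLASS_RANK.get).value
        for o in conclusive
    )
    n_cnv = sum(csq_counts.get(c, 0) for c in ("cnv_del", "cnv_dup"))
    return {
        "n_conclusive_patients": len(conclusive),
        "n_reported_variants": n_var,
        "n_distinct_variants": len(distinct),
        "n_distinct_genes": len(genes),
        "n_cnv": n_cnv,
        "by_consequence": csq_counts,
        "pct_by_consequence": {k: percent(c, n_var) for k, c in csq_counts.items()},
        "by_mode": mode_counts,
        "by_published": pub_counts,
        "lead_class_by_patient": lead_class_counts,
        "pct_lead_class_by_patient": {
            k: percent(c, len(conclusive)) for k, c in lead_class_counts.items()
        },
    }


def sankey_counts(outcomes: list, patients: list) -> pd.DataFrame:
    """Edge table of the cohort flow: macro-category -> variants-found /
    no-variants -> report category.  Patient counts are conserved along
    every path (checked by the caller via the node sums)."""
    by_id = _match(outcomes, patients)
    edges: dict = {}
    for o in outcomes:
        p = by_id[o.patient_id]
        mid = "variants_found" if o.variant_positive else "no_variants"
        for src, dst in (
            (p.macro_category.value, mid),
            (mid, o.outcome.value),
        ):
            edges[(src, dst)] = edges.get((src, dst), 0) + 1
    return pd.DataFrame(
        [{"source": s, "target": t, "n": n} for (s, t), n in sorted(edges.items())]
    )


def cohort_summary(outcomes: list, patients: list) -> dict:
    """The full cohort summary: per-category and per-family-history yield
    tables, the overall report split, and the conclusive-report variant
    tallies, with internal consistency enforced."""
    split = report_split(outcomes)
    tallies = variant_tallies(outcomes)
    if (
        split["n_conclusive"] + split["n_uncertain"] + split["n_inconclusive"]
        != split["n_variant_positive"]
    ):
        raise AssertionError("report split does not partition variant-positive patients")
    if split["n_variant_positive"] + split["n_no_variants"] != split["n_patients"]:
        raise AssertionError("variant-positive + negative != cohort size")
    by_cat = diagnostic_yield(outcomes, patients, "macro_category")
    if int(by_cat["n_diagnostic"].sum()) != split["n_conclusive"]:
        raise AssertionError("per-category diagnostic counts do not sum to conclusive count")
    return {
        "by_category": by_cat,
        "by_family_history": diagnostic_yield(outcomes, patients, "family_history"),
        "report_split": split,
        "variant_tallies": tallies,
    }
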