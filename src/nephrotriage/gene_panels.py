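"""Category-specific in-silico gene panels and the kidneyome super-panel.

Analysis is first restricted to the subpanel matching the patient's
clinical suspicion.  Only when that analysis is negative *and* the
phenotype is either not clearly indicated or overlaps several disease
categories does it escalate to the kidneyome, the exact union of all
subpanels.
"""

from __future__ import annotations

from .types import EscalationContext, GenePanel, PatientRecord

KIDNEYOME = "kidneyome"


class PanelRegistryError(ValueError):
    """The registry does not cover a requested category."""


def build_kidneyome(panels: list) -> GenePanel:
    """Union of all subpanel entries (gene, moi, chromosome), deduplicated."""
    seen = set()
    entries = []
    for p in panels:
        if p.category == KIDNEYOME:
            continue
        for e in p.entries:
            k = (e.gene, e.moi)
            if k not in seen:
                seen.add(k)
                entries.append(e)
    return GenePanel(name=KIDNEYOME, category=KIDNEYOME, entries=entries)


def select_panel(patient: PatientRecord, registry: list) -> GenePanel:
    """The subpanel whose category equals the patient's macro-category."""
    for p in registry:
        if p.category == patient.macro_category.value:
            return p
    raise PanelRegistryError(
        f"no panel registered for category {patient.macro_category.value!r}"
    )


def should_escalate(ctx: EscalationContext) -> bool:
    """Escalate to the kidneyome iff the subpanel result was negative and
    the phenotype is unclear or overlapping."""
    return ctx.subpanel_negative and (ctx.phenotype_unclear or ctx.phenotype_overlapping)


def restrict_to_panel(calls: list, panel: GenePanel) -> list:
    """Keep only calls whose gene is a panel entry; order preserved."""
    genes = panel.genes
    return [c for c in calls if c.gene in genes]


def validate_registry(panels: list, categories: list) -> None:
    """Check one panel per requested category; raise naming the gaps."""
    have = {p.category for p in panels}
    missing = [c for c in categories if c not in have]
    if missing:
        raise PanelRegistryError(f"registry lacks panels for: {missing}")
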