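"""The variant filtering cascade.

Raw calls become candidate variants by passing, in order: panel
restriction, the consequence filter (synonymous variants not impacting
splicing and intronic variants outside splice regions are excluded), and
the quality/frequency filter (population frequency strictly below 1%,
in-patient allele fraction of at least 0.2, coverage of at least 20
reads).  CNV records are exempt from the VAF/depth tests — a single-site
allele fraction is not meaningful for a depth-based event — but still
obey panel restriction and the rarity rule when an AF is available.
"""

from __future__ import annotations

from .gene_panels import restrict_to_panel
from .types import Consequence, FilterConfig, FilterTrace, GenePanel, VariantCall


def consequence_filter(call: VariantCall, cfg: FilterConfig = FilterConfig()) -> bool:
    """True when the consequence class is retained.

    A variant outside the retained set still passes when it maps within a
    splice region (the "not impacting on the splicing mechanism"
    exception for synonymous/intronic variants).
    """
    if call.consequence in cfg.retained_consequences:
        return True
    return call.splice_region


def quality_frequency_filter(call: VariantCall, cfg: FilterConfig = FilterConfig()) -> bool:
    """pop_af < max_pop_af AND vaf >= min_vaf AND depth >= min_depth.

    Boundary semantics are literal: "less than 1%" is strict, "at least
    0.2 / 20 reads" are inclusive.  Homozygous calls get no VAF
    exemption.  CNVs skip the VAF/depth clauses.
    """
    if call.depth is not None and call.depth < 0:
        raise ValueError(f"negative depth on {call.key}")
    if not call.pop_af < cfg.max_pop_af:
        return False
    if call.consequence.is_cnv:
        return True
    if call.vaf is None or call.depth is None:
        return False
    return call.vaf >= cfg.min_vaf and call.depth >= cfg.min_depth


def run_filter_cascade(
    calls: list,
    panel: GenePanel,
    cfg: FilterConfig = FilterConfig(),
) -> tuple:
    """Apply panel restriction, consequence filter, and quality/frequency
    filter in order.  Returns (survivors, FilterTrace); every input call
    gets a trace and a failed call carries exactly one first-failing
    filter.
    """
    trace = FilterTrace()
    panel_genes = panel.genes
    survivors = []
    for call in calls:
        in_panel = call.gene in panel_genes
        trace.record(call.key, "panel", in_panel)
        if not in_panel:
            continue
        csq_ok = consequence_filter(call, cfg)
        trace.record(call.key, "consequence", csq_ok)
        if not csq_ok:
            continue
        qf_ok = quality_frequency_filter(call, cfg)
        trace.record(call.key, "quality_frequency", qf_ok)
        if not qf_ok:
            continue
        survivors.append(call)
    return survivors, trace
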