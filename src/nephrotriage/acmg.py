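"""ACMG/AMP evidence combination into the C1-C5 classes.

The engine implements the combining rules of the original 2015 ACMG/AMP
sequence-variant interpretation standard (Richards et al.), taking
evidence codes pre-bucketed by strength: PVS (very strong), PS (strong),
PM (moderate), PP (supporting) on the pathogenic side; BA (stand-alone),
BS (strong), BP (supporting) on the benign side.  The 28-criterion
catalog itself is not re-derived here — which codes apply to a variant
is an input, as in a clinical laboratory where evidence assignment is a
curation step.

When both a pathogenic-direction and a benign-direction rule fire, the
evidence is contradictory and the variant is classified C3 (VUS), per
the standard.  The intermediate C3_C4 class can only be set by manual
override — it models geneticist curation and never falls out of the
combining rules.
"""

from __future__ import annotations

from typing import Optional

from .types import AcmgClass, EvidenceProfile


def _pathogenic(e: EvidenceProfile) -> bool:
    if e.pvs >= 1 and (
        e.ps >= 1 or e.pm >= 2 or (e.pm >= 1 and e.pp >= 1) or e.pp >= 2
    ):
        return True
    if e.ps >= 2:
        return True
    if e.ps >= 1 and (
        e.pm >= 3 or (e.pm >= 2 and e.pp >= 2) or (e.pm >= 1 and e.pp >= 4)
    ):
        return True
    return False


def _likely_pathogenic(e: EvidenceProfile) -> bool:
    return (
        (e.pvs >= 1 and e.pm >= 1)
        or (e.ps >= 1 and e.pm >= 1)
        or (e.ps >= 1 and e.pp >= 2)
        or e.pm >= 3
        or (e.pm >= 2 and e.pp >= 2)
        or (e.pm >= 1 and e.pp >= 4)
    )


def _benign(e: EvidenceProfile) -> bool:
    return e.ba >= 1 or e.bs >= 2


def _likely_benign(e: EvidenceProfile) -> bool:
    return (e.bs >= 1 and e.bp >= 1) or e.bp >= 2


def combine_evidence(e: EvidenceProfile) -> AcmgClass:
    """Deterministic, total mapping from an evidence profile to a class.

    Pathogenic-side and benign-side rules are evaluated independently;
    if both sides fire the evidence conflicts and the result is C3.
    """
    path_side = _pathogenic(e) or _likely_pathogenic(e)
    benign_side = _benign(e) or _likely_benign(e)
    if path_side and benign_side:
        return AcmgClass.C3
    if _pathogenic(e):
        return AcmgClass.C5
    if _likely_pathogenic(e):
        return AcmgClass.C4
    if _benign(e):
        return AcmgClass.C1
    if _likely_benign(e):
        return AcmgClass.C2
    return AcmgClass.C3


def classify_with_override(
    e: EvidenceProfile, manual: Optional[AcmgClass] = None
) -> AcmgClass:
    """Computed class, unless a geneticist's manual class overrides it.

    The override models report curation — including the intermediate
    C3_C4 calls that exist only as curated assignments.
    """
    if manual is not None:
        return manual
    return combine_evidence(e)
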