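"""Synthetic cohorts: determinism, ledger agreement, decoy construction,
and the deterministic study fixture's engineered marginals."""

import filecmp
from pathlib import Path

import pytest

from nephrotriage import pipeline, synthetic_cohort as sc
from nephrotriage.types import MacroCategory, Moi, Outcome
from nephrotriage.variant_filtering import run_filter_cascade


def test_fixture_plans_pass_internal_checks(fixture_artifacts):
    data = fixture_artifacts.data
    assert len(data.patients) == 191
    sizes = {}
    for p in data.patients:
        sizes[p.macro_category] = sizes.get(p.macro_category, 0) + 1
    assert sizes == {
        MacroCategory.CAKUT: 34,
        MacroCategory.ciliopathy: 39,
        MacroCategory.glomerulopathy: 62,
        MacroCategory.nephrolithiasis: 22,
        MacroCategory.tubulopathy: 20,
        MacroCategory.other: 14,
    }
    assert sum(1 for p in data.patients if p.family_history) == 47


def test_fixture_is_deterministic(tmp_path):
    d1, d2 = tmp_path / "a", tmp_path / "b"
    sc.build_study_fixture(d1)
    sc.build_study_fixture(d2)
    files = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
    assert files == sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
    for f in files:
        assert filecmp.cmp(d1 / f, d2 / f, shallow=False), f


def test_simulated_cohort_is_deterministic_and_seed_sensitive():
    cfg = sc.SimConfig(seed=42, n_patients=30)
    a = sc.simulate_cohort(cfg)
    b = sc.simulate_cohort(sc.SimConfig(seed=42, n_patients=30))
    assert a.ledger.to_json() == b.ledger.to_json()
    c = sc.simulate_cohort(sc.SimConfig(seed=43, n_patients=30))
    assert a.ledger.to_json() != c.ledger.to_json()


@pytest.mark.parametrize("seed", [1, 7, 123])
def test_pipeline_agrees_with_ledger_on_simulated_cohorts(seed):
    """On noise-free configs the pipeline must reproduce the intended
    outcome for every simulated patient — exact agreement is the
    contract; any disagreement is a generator or pipeline bug."""
    art = sc.simulate_cohort(sc.SimConfig(seed=seed, n_patients=50))
    outcomes = pipeline.run_cohort(art.data)
    for o in outcomes:
        assert o.outcome.value == art.ledger.patients[o.patient_id]["intended_outcome"], (
            o.patient_id,
            o.reasons,
        )


def test_decoys_fail_exactly_the_named_filter(fixture_artifacts):
    """Every decoy's first failing cascade filter equals the one the
    ledger says it was constructed to fail."""
    data = fixture_artifacts.data
    panels = {p.category: p for p in data.panels}
    checked = 0
    for pid, entry in fixture_artifacts.ledger.patients.items():
        if not entry["decoys"]:
            continue
        patient = next(p for p in data.patients if p.patient_id == pid)
        candidates = [c for c in data.calls[pid] if c.genotype.carries_alt]
        _, trace = run_filter_cascade(candidates, panels[patient.macro_category.value])
        decoy_pos = {d["pos"]: d["fails"] for d in entry["decoys"]}
        for c in candidates:
            if c.pos in decoy_pos:
                assert trace.first_failure(c.key) == decoy_pos[c.pos], (pid, c.pos)
                checked += 1
    assert checked > 150


def test_causative_variants_survive_filters(fixture_artifacts):
    """Planted causative variants pass the full cascade of the panel
    context they are meant to be found in."""
    data = fixture_artifacts.data
    from nephrotriage.gene_panels import build_kidneyome

    panels = {p.category: p for p in data.panels}
    kidneyome = build_kidneyome(data.panels)
    for pid, entry in fixture_artifacts.ledger.patients.items():
        if not entry["planted"]:
            continue
        patient = next(p for p in data.patients if p.patient_id == pid)
        candidates = [c for c in data.calls[pid] if c.genotype.carries_alt]
        sub, _ = run_filter_cascade(candidates, panels[patient.macro_category.value])
        full, _ = run_filter_cascade(candidates, kidneyome)
        survivor_pos = {c.pos for c in sub} | {c.pos for c in full}
        for v in entry["planted"]:
            assert v["pos"] in survivor_pos, (pid, v)


def test_infeasible_plant_raises_before_emission():
    """A compound het cannot be planted when the panel has no recessive
    gene: the generator refuses before emitting anything."""
    from nephrotriage.types import GenePanel, PanelEntry

    dominant_only = GenePanel(
        name="d", category="d", entries=[PanelEntry("WT1", Moi.AD, "11")]
    )
    with pytest.raises(sc.InfeasiblePlanError):
        sc.genes_with_mode(dominant_only, {Moi.AR})
    assert sc.genes_with_mode(dominant_only, {Moi.AD}) == ["WT1"]


def test_cohort_round_trips_through_disk(tmp_path):
    """write_cohort -> load_cohort preserves what the pipeline consumes:
    same outcomes from files as from memory."""
    art = sc.simulate_cohort(sc.SimConfig(seed=9, n_patients=25))
    mem = pipeline.run_cohort(art.data)
    sc.write_cohort(art, tmp_path)
    disk = pipeline.run_cohort(pipeline.load_cohort(tmp_path))
    assert [(o.patient_id, o.outcome) for o in disk] == [
        (o.patient_id, o.outcome) for o in mem
    ]
    assert Path(tmp_path, "ledger.json").exists()
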