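"""Knowledge-base loading, evidence queries, and filtering."""

import logging

import pytest

from diaet import (
    FilterSpec,
    KBSpec,
    EndpointSpec,
    TrialRecord,
    apply_filters,
    generate_kb,
    load_kb,
)
from diaet.errors import DataError, KBLoadError, UsageError, ValidationError
from diaet.kb import KnowledgeBase
from diaet.rdf import parse_turtle


def test_load_glaucoma_fixture(glaucoma):
    assert glaucoma.kb.trial_count == 11
    assert glaucoma.kb.triple_count == len(parse_turtle(glaucoma.path.read_text()))
    record = glaucoma.kb.trials["CT_01"]
    assert record.publication_year is not None
    assert record.total_participants > 0


def test_empty_graph_yields_zero_trials_with_warning(tmp_path, caplog):
    path = tmp_path / "empty.ttl"
    path.write_text("@prefix ctro: <https://w3id.org/diaet/ctro#> .\n")
    with caplog.at_level(logging.WARNING):
        kb = load_kb(path)
    assert kb.trial_count == 0
    assert any("no clinical trials" in r.message for r in caplog.records)


def test_load_errors(tmp_path):
    with pytest.raises(KBLoadError):
        load_kb(tmp_path / "missing.ttl")
    with pytest.raises(UsageError):
        load_kb(tmp_path / "whatever.rdf", format="rdfxml")


@pytest.mark.parametrize(
    "drug1, drug2, endpoint, expected",
    [
        ("latanoprost", "timolol", "diurnal_IOP", 11),
        ("  LATANOPROST ", "Timolol", "DIURNAL_iop", 11),  # normalized matching
        ("latanoprost", "timolol", "unknown_endpoint", 0),
        ("drugX", "timolol", "diurnal_IOP", 0),
    ],
)
def test_query_endpoint_evidence(glaucoma, drug1, drug2, endpoint, expected):
    pairs = glaucoma.kb.query_endpoint_evidence(drug1, drug2, endpoint)
    assert len(pairs) == expected
    assert [p.study_id for p in pairs] == sorted(p.study_id for p in pairs)
    for p in pairs:
        assert p.unit == "mmHg" and p.drug2_unit is None


def test_query_adverse_evidence(glaucoma):
    pairs = glaucoma.kb.query_adverse_evidence(
        "latanoprost", "timolol", "conjunctival_hyperemia"
    )
    assert len(pairs) == 6
    assert glaucoma.kb.query_adverse_evidence("latanoprost", "timolol", "absent") == []
    for p in pairs:
        assert 0 <= p.drug1_affected <= p.drug1_arm_size
        assert 0 <= p.drug2_affected <= p.drug2_arm_size


def test_empty_names_rejected(glaucoma):
    with pytest.raises(UsageError):
        glaucoma.kb.query_endpoint_evidence("", "timolol", "diurnal_IOP")


def test_change_derived_from_baseline_and_final(tmp_path):
    spec = KBSpec(
        drug1="a", drug2="b",
        endpoints=(EndpointSpec("ep", n_supporting=2, n_contradicting=1),),
        seed=7,
    )
    direct = KnowledgeBase(parse_turtle(generate_kb(spec)))
    from dataclasses import replace

    derived = KnowledgeBase(
        parse_turtle(generate_kb(replace(spec, emit_final_values=True)))
    )
    p1 = direct.query_endpoint_evidence("a", "b", "ep")
    p2 = derived.query_endpoint_evidence("a", "b", "ep")
    assert len(p1) == len(p2) == 3
    for x, y in zip(p1, p2):
        # final - baseline reproduces the stored change up to float noise
        assert x.drug1_change == pytest.approx(y.drug1_change, abs=1e-9)
        assert x.drug2_change == pytest.approx(y.drug2_change, abs=1e-9)


ONE_SIDED_KB = """
@prefix ctro: <https://w3id.org/diaet/ctro#> .
@prefix kb: <https://w3id.org/diaet/kb#> .

kb:CT_01 a ctro:ClinicalTrial ;
    ctro:hasArm kb:a1, kb:a2 .
kb:a1 ctro:hasDrugName "drugA" ;
    ctro:hasEndpointResult kb:r1 .
kb:a2 ctro:hasDrugName "drugB" .
kb:r1 ctro:hasEndpointId "ep" ;
    ctro:hasChangeValue -1.0 ;
    ctro:hasUnit "u" .
"""


def test_one_sided_endpoint_reports_are_dropped_with_warning(caplog):
    kb = KnowledgeBase(parse_turtle(ONE_SIDED_KB))
    with caplog.at_level(logging.WARNING):
        pairs = kb.query_endpoint_evidence("drugA", "drugB", "ep")
    assert pairs == []
    assert any("only one arm" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def test_apply_filters_identity_and_exclusion(glaucoma):
    pairs = glaucoma.kb.query_endpoint_evidence("latanoprost", "timolol", "diurnal_IOP")
    assert apply_filters(pairs, glaucoma.kb.trials, FilterSpec()) == pairs

    spec = FilterSpec(excluded_study_ids={"CT_03", "CT_07"})
    kept = apply_filters(pairs, glaucoma.kb.trials, spec)
    assert {p.study_id for p in pairs} - {p.study_id for p in kept} == {"CT_03", "CT_07"}
    # idempotent and order preserving
    assert apply_filters(kept, glaucoma.kb.trials, spec) == kept
    assert [p.study_id for p in kept] == [
        p.study_id for p in pairs if p.study_id not in {"CT_03", "CT_07"}
    ]


def test_apply_filters_metadata_bounds(glaucoma):
    pairs = glaucoma.kb.query_endpoint_evidence("latanoprost", "timolol", "diurnal_IOP")
    years = [glaucoma.kb.trials[p.study_id].publication_year for p in pairs]
    assert apply_filters(pairs, glaucoma.kb.trials, FilterSpec(year_min=max(years) + 1)) == []
    kept = apply_filters(pairs, glaucoma.kb.trials, FilterSpec(year_min=min(years)))
    assert kept == pairs


def test_apply_filters_validation_and_missing_metadata(glaucoma):
    pairs = glaucoma.kb.query_endpoint_evidence("latanoprost", "timolol", "diurnal_IOP")
    with pytest.raises(ValidationError):
        apply_filters(pairs, glaucoma.kb.trials, FilterSpec(year_min=2000, year_max=1999))
    # a bound on unreported metadata excludes the trial
    trials = {
        p.study_id: TrialRecord(study_id=p.study_id, label=p.study_id) for p in pairs
    }
    assert apply_filters(pairs, trials, FilterSpec(age_min=18)) == []
    with pytest.raises(DataError):
        apply_filters(pairs, {}, FilterSpec())


def test_trial_record_rejects_negative_metadata():
    with pytest.raises(DataError):
        TrialRecord(study_id="x", label="x", duration_weeks=-1)
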