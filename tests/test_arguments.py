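"""Superiority criteria, aggregation, acceptance and tree construction."""

from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diaet import (
    AdverseEventPair,
    AggregatedArgument,
    AtomicArgument,
    BuildConfig,
    EndpointResultPair,
    FilterSpec,
    KBSpec,
    aggregate_confidence,
    build_diaet,
    evaluate_efficacy_superiority,
    evaluate_safety_superiority,
    generate_kb,
    is_accepted,
    make_atomic_argument,
    reported_confidence,
)
from diaet.dimensions import LeafBinding
from diaet.errors import (
    DataError,
    DegenerateWeightsError,
    NoEvidenceError,
    ValidationError,
)
from diaet.kb import KnowledgeBase
from diaet.rdf import parse_turtle

DECREASE = LeafBinding("efficacy", "HbA1c", "decrease")
INCREASE = LeafBinding("efficacy", "HbA1c", "increase")


def endpoint_pair(change1, change2, unit="%", drug2_unit=None, endpoint="HbA1c"):
    return EndpointResultPair(
        study_id="CT_x", endpoint_id=endpoint, drug1_name="IGlar",
        drug2_name="NPH insulin", drug1_change=change1, drug2_change=change2,
        unit=unit, drug2_unit=drug2_unit,
    )


def event_pair(a1, a2, s1=None, s2=None):
    return AdverseEventPair(
        study_id="CT_x", event_id="ev", drug1_name="d1", drug2_name="d2",
        drug1_affected=a1, drug2_affected=a2, drug1_arm_size=s1, drug2_arm_size=s2,
    )


@pytest.mark.parametrize(
    "change1, change2, binding, expected",
    [
        (-0.46, -0.38, DECREASE, True),   # larger reduction supports
        (-0.5, -0.5, DECREASE, False),    # tie is not superiority
        (-0.30, -0.40, DECREASE, False),  # smaller reduction contradicts
        (0.2, -0.1, DECREASE, False),     # wrong direction contradicts
        (0.8, 0.3, INCREASE, True),
        (0.3, 0.8, INCREASE, False),
    ],
)
def test_efficacy_superiority(change1, change2, binding, expected):
    assert evaluate_efficacy_superiority(endpoint_pair(change1, change2), binding) is expected


def test_efficacy_unit_and_binding_mismatches():
    with pytest.raises(DataError, match="unit mismatch"):
        evaluate_efficacy_superiority(
            endpoint_pair(-1, -2, unit="%", drug2_unit="mmol/mol"), DECREASE
        )
    with pytest.raises(DataError, match="does not match"):
        evaluate_efficacy_superiority(endpoint_pair(-1, -2, endpoint="other"), DECREASE)


@pytest.mark.parametrize(
    "pair, expected",
    [
        (event_pair(1, 5), True),               # fewer incidences support
        (event_pair(5, 5), False),              # equal counts contradict
        (event_pair(2, 1), False),
        (event_pair(2, 1, 100, 50), False),     # 2/100 == 1/50: tie on proportion
        (event_pair(3, 2, 300, 100), True),     # 1% < 2% despite higher count
        (event_pair(0, 0, 50, 50), False),
    ],
)
def test_safety_superiority(pair, expected):
    assert evaluate_safety_superiority(pair) is expected


def test_safety_count_exceeding_arm_size_is_a_data_error():
    with pytest.raises(DataError):
        evaluate_safety_superiority(event_pair(51, 1, 50, 50))


def test_make_atomic_argument_confidence():
    supporting = make_atomic_argument(endpoint_pair(-0.46, -0.38), DECREASE,
                                      "IGlar", "NPH insulin", "hba1c")
    contradicting = make_atomic_argument(endpoint_pair(-0.30, -0.40), DECREASE,
                                         "IGlar", "NPH insulin", "hba1c")
    tie = make_atomic_argument(endpoint_pair(-0.5, -0.5), DECREASE,
                               "IGlar", "NPH insulin", "hba1c")
    assert supporting.confidence == 1 and supporting.supports
    assert contradicting.confidence == 0
    assert tie.confidence == 0
    assert supporting.facts is not None and supporting.weight == 1


def test_aggregate_confidence_examples():
    assert aggregate_confidence([(1, 1)] * 11) == 1
    assert aggregate_confidence([(1, 1)] + [(1, 0)] * 5) == Fraction(1, 6)
    mixed = aggregate_confidence([(0.5, 1), (0.5, 0.17)])
    assert mixed == Fraction(585, 1000)
    assert aggregate_confidence([(2, Fraction(1, 3)), (0, 1)]) == Fraction(1, 3)


def test_aggregate_confidence_errors():
    with pytest.raises(NoEvidenceError):
        aggregate_confidence([])
    with pytest.raises(DegenerateWeightsError):
        aggregate_confidence([(0, 1), (0, 0)])
    with pytest.raises(ValidationError):
        aggregate_confidence([(1, 2)])  # confidence outside [0, 1]
    with pytest.raises(ValidationError):
        aggregate_confidence([(-1, 0.5)])


@settings(max_examples=80, derandomize=True, deadline=None)
@given(
    entries=st.lists(
        st.tuples(
            st.fractions(min_value=0, max_value=5),
            st.fractions(min_value=0, max_value=1),
        ),
        min_size=1,
        max_size=8,
    )
)
def test_aggregate_confidence_bounds_and_mean_reduction(entries):
    """The weighted mean stays in [0,1]; equal weights give the plain mean."""
    if sum(w for w, _ in entries) == 0:
        entries[0] = (Fraction(1), entries[0][1])
    value = aggregate_confidence(entries)
    assert 0 <= value <= 1
    confs = [c for _, c in entries]
    assert aggregate_confidence([(1, c) for c in confs]) == sum(confs) / len(confs)


@pytest.mark.parametrize(
    "confidence, tau, expected",
    [(Fraction(59, 100), Fraction(1, 2), True),
     (Fraction(42, 100), Fraction(1, 2), False),
     (Fraction(1, 2), Fraction(1, 2), True),  # 'not less than' boundary
     (0, 0, True), (1, 1, True)],
)
def test_is_accepted(confidence, tau, expected):
    assert is_accepted(confidence, tau) is expected


def test_build_config_validation():
    with pytest.raises(ValidationError):
        BuildConfig(tau=Fraction(3, 2))
    with pytest.raises(ValidationError):
        BuildConfig(reporting_mode="fancy")


# ---------------------------------------------------------------------------
# Tree construction
# ---------------------------------------------------------------------------


def aggregated(root):
    return {n.dimension_id: n for n in root.walk() if isinstance(n, AggregatedArgument)}


def test_build_glaucoma_tree(glaucoma):
    root = build_diaet(glaucoma.kb, glaucoma.tree, "latanoprost", "timolol")
    nodes = aggregated(root)
    assert nodes["iop_reduction"].confidence == 1
    assert nodes["conjunctival_hyperemia"].confidence == Fraction(1, 6)
    assert nodes["efficacy"].confidence == 1  # single child of weight 1
    assert nodes["safety"].confidence == Fraction(1, 6)
    assert root.confidence == Fraction(7, 12)
    assert root.status == "accepted"
    assert nodes["efficacy"].status == "accepted"
    assert nodes["safety"].status == "rejected"
    assert root.evidence_count == 11
    assert nodes["safety"].evidence_count == 6
    atoms = [n for n in root.walk() if isinstance(n, AtomicArgument)]
    assert len(atoms) == 17  # 11 endpoint + 6 adverse-event studies


def test_build_zero_trial_kb_yields_no_evidence(glaucoma, tmp_path):
    path = tmp_path / "empty.ttl"
    path.write_text("@prefix ctro: <https://w3id.org/diaet/ctro#> .\n")
    from diaet import load_kb

    root = build_diaet(load_kb(path), glaucoma.tree, "a", "b")
    assert root.status == "no_evidence"
    assert root.confidence is None
    assert reported_confidence(root) == "n/a"


def test_build_unknown_drug_is_no_evidence_not_error(glaucoma):
    root = build_diaet(glaucoma.kb, glaucoma.tree, "drugX", "timolol")
    assert root.status == "no_evidence"


def test_no_evidence_leaf_renormalizes_parent(t2dm):
    """A leaf without data drops out of the sum and out of Z: with safety
    evidence absent, the overall conclusion equals the efficacy branch."""
    kb = KnowledgeBase(
        parse_turtle(
            generate_kb(
                KBSpec(
                    drug1="insulin glargine", drug2="NPH insulin",
                    endpoints=t2dm.spec.endpoints, events=(), n_trials=9, seed=3,
                )
            )
        )
    )
    root = build_diaet(kb, t2dm.tree, "insulin glargine", "NPH insulin")
    nodes = aggregated(root)
    assert nodes["safety"].status == "no_evidence"
    assert root.confidence == nodes["efficacy"].confidence == Fraction(4, 9)


def test_exclusion_keeps_reporting_denominator(glaucoma):
    """Excluding one of 11 supporting studies gives 10/11, not 10/10: the
    reference count of a leaf is the number of studies reporting it."""
    config = BuildConfig(filter=FilterSpec(excluded_study_ids={"CT_01"}))
    nodes = aggregated(build_diaet(glaucoma.kb, glaucoma.tree,
                                   "latanoprost", "timolol", config))
    assert nodes["iop_reduction"].confidence == Fraction(10, 11)
    assert nodes["iop_reduction"].evidence_count == 10


def test_reported_confidence_modes(glaucoma):
    root = build_diaet(glaucoma.kb, glaucoma.tree, "latanoprost", "timolol")
    nodes = aggregated(root)
    assert reported_confidence(root, "exact") == "0.58"  # 7/12 = 0.5833...
    assert reported_confidence(root, "paper_rounded") == "0.59"  # 0.5*1 + 0.5*0.17
    assert reported_confidence(nodes["efficacy"], "exact") == "1.00"
    assert reported_confidence(nodes["efficacy"], "paper_rounded") == "1.00"
    assert reported_confidence(nodes["conjunctival_hyperemia"], "exact") == "0.17"
    with pytest.raises(Exception):
        reported_confidence(root, "bogus")


def test_recursion_call_count_equals_node_count(glaucoma):
    root = build_diaet(glaucoma.kb, glaucoma.tree, "latanoprost", "timolol")
    assert root.meta["recursive_calls"] == glaucoma.tree.size == 5
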