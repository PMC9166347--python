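"""Scenario tables, threshold sweeps and tree diffs."""

from fractions import Fraction

import pytest

from diaet import (
    BuildConfig,
    FilterSpec,
    Scenario,
    build_diaet,
    diff_trees,
    run_scenarios,
    sweep_thresholds,
)
from diaet.errors import StructuralError, ValidationError
from diaet.sensitivity import partition_to_frame


def test_default_scenario_row_matches_plain_build(glaucoma):
    frame = run_scenarios(glaucoma.kb, glaucoma.tree, "latanoprost", "timolol",
                          [Scenario("defaults")])
    root = build_diaet(glaucoma.kb, glaucoma.tree, "latanoprost", "timolol")
    row = frame.iloc[0]
    assert row["scenario"] == "defaults"
    assert row["n_studies"] == root.evidence_count == 11
    assert row["overall"] == ">" and row["efficacy"] == ">" and row["safety"] == "≯"


def test_scenario_excluding_all_studies_is_no_evidence(glaucoma):
    all_ids = frozenset(glaucoma.kb.trials)
    frame = run_scenarios(
        glaucoma.kb, glaucoma.tree, "latanoprost", "timolol",
        [Scenario("none", filter=FilterSpec(excluded_study_ids=all_ids))],
    )
    row = frame.iloc[0]
    assert all(row[dim] == "n/a" for dim in
               ("overall", "efficacy", "safety", "iop_reduction"))


def test_scenarios_require_at_least_one(glaucoma):
    with pytest.raises(ValidationError):
        run_scenarios(glaucoma.kb, glaucoma.tree, "latanoprost", "timolol", [])


def test_sweep_glaucoma_partition(glaucoma):
    """On the 0.01 grid the outcome pattern flips where the exact confidences
    1/6 (safety) and 7/12 (root) fall; three maximal ranges result."""
    partition = sweep_thresholds(glaucoma.kb, glaucoma.tree,
                                 "latanoprost", "timolol")
    assert len(partition.intervals) == 3
    # independent boundary computation from the exact rationals
    step = Fraction(1, 100)
    safety_flip = Fraction(1, 6)  # accepted while tau <= 1/6
    root_flip = Fraction(7, 12)
    last_safety_ok = (safety_flip / step).__floor__() * step
    last_root_ok = (root_flip / step).__floor__() * step
    (lo1, hi1, p1), (lo2, hi2, p2), (lo3, hi3, p3) = partition.intervals
    assert (lo1, hi1) == (0, last_safety_ok)
    assert (lo2, hi2) == (last_safety_ok + step, last_root_ok)
    assert (lo3, hi3) == (last_root_ok + step, 1)
    assert p1["safety"] == "accepted" and p2["safety"] == "rejected"
    assert p2["overall"] == "accepted" and p3["overall"] == "rejected"
    assert p3["efficacy"] == "accepted"  # confidence 1 accepted everywhere
    assert partition.exact_breakpoints == (Fraction(1, 6), Fraction(7, 12), 1)


def test_sweep_interval_patterns_reproduced_at_midpoints(glaucoma):
    partition = sweep_thresholds(glaucoma.kb, glaucoma.tree,
                                 "latanoprost", "timolol")
    for low, high, pattern in partition.intervals:
        mid = (low + high) / 2
        root = build_diaet(glaucoma.kb, glaucoma.tree, "latanoprost", "timolol",
                           BuildConfig(tau=mid))
        from diaet import AggregatedArgument

        statuses = {n.dimension_id: n.status for n in root.walk()
                    if isinstance(n, AggregatedArgument)}
        assert statuses == pattern


def test_sweep_accepted_sets_are_antitone(glaucoma):
    partition = sweep_thresholds(glaucoma.kb, glaucoma.tree,
                                 "latanoprost", "timolol")
    accepted_sets = [
        {d for d, s in pattern.items() if s == "accepted"}
        for _, _, pattern in partition.intervals
    ]
    for earlier, later in zip(accepted_sets, accepted_sets[1:]):
        assert later <= earlier


def test_sweep_grid_step_edge_cases(glaucoma):
    partition = sweep_thresholds(glaucoma.kb, glaucoma.tree,
                                 "latanoprost", "timolol",
                                 grid_step=Fraction(1, 2))
    covered = {partition.intervals[0][0]}
    for lo, hi, _ in partition.intervals:
        covered.update({lo, hi})
    assert covered <= {0, Fraction(1, 2), 1}  # grid {0, 0.5, 1}
    assert partition.pattern_at(Fraction(1, 4)) == partition.intervals[0][2]
    with pytest.raises(ValidationError):
        sweep_thresholds(glaucoma.kb, glaucoma.tree, "latanoprost", "timolol",
                         grid_step=Fraction(3, 5))
    frame = partition_to_frame(partition)
    assert list(frame["tau_low"]) == [float(lo) for lo, _, _ in partition.intervals]


def test_sweep_all_accepted_single_interval(glaucoma):
    """A tree whose every confidence is 1 stays accepted on the whole grid."""
    from diaet import DimensionTree

    efficacy_tree = DimensionTree(glaucoma.tree.root.children[0])
    partition = sweep_thresholds(glaucoma.kb, efficacy_tree,
                                 "latanoprost", "timolol")
    assert len(partition.intervals) == 1
    (lo, hi, pattern) = partition.intervals[0]
    assert (lo, hi) == (0, 1)
    assert set(pattern.values()) == {"accepted"}


def test_diff_trees(glaucoma):
    base = build_diaet(glaucoma.kb, glaucoma.tree, "latanoprost", "timolol")
    assert diff_trees(base, base) == []

    reweighted = build_diaet(
        glaucoma.kb, glaucoma.tree, "latanoprost", "timolol",
        BuildConfig(weight_overrides={"efficacy": 0.3, "safety": 0.7}),
    )
    deltas = {d.dimension_id: d for d in diff_trees(base, reweighted)}
    assert deltas["overall"].status_before == "accepted"
    assert deltas["overall"].status_after == "rejected"

    excluded = build_diaet(
        glaucoma.kb, glaucoma.tree, "latanoprost", "timolol",
        BuildConfig(filter=FilterSpec(excluded_study_ids={"CT_02"})),
    )
    deltas = {d.dimension_id: d for d in diff_trees(base, excluded)}
    assert deltas["iop_reduction"].confidence_delta == Fraction(-1, 11)

    with pytest.raises(StructuralError):
        from diaet import DimensionTree

        diff_trees(base, build_diaet(glaucoma.kb,
                                     DimensionTree(glaucoma.tree.root.children[0]),
                                     "latanoprost", "timolol"))
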