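"""What-if exploration: scenario tables, acceptance-threshold sweeps, and
per-node diffs between argument trees.

Scenario rows report, per dimension, whether the candidate treatment came out
superior (``>``), not concludably superior (``≯``), or without evidence
(``n/a``) — the presentation style of published sensitivity tables. Threshold
sweeps evaluate acceptance on a decimal grid against the *exact* confidences
(the tree is built once; only the comparison is repeated) and merge grid
points with identical per-dimension outcomes into maximal closed ranges; the
exact rational breakpoints are exposed alongside for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Sequence

import pandas as pd

from .arguments import (
    ACCEPTED,
    NO_EVIDENCE,
    REJECTED,
    AggregatedArgument,
    BuildConfig,
    build_diaet,
    is_accepted,
)
from .dimensions import DimensionTree, to_fraction
from .errors import StructuralError, ValidationError
from .kb import FilterSpec, KnowledgeBase

SUPERIOR = ">"
NOT_SUPERIOR = "≯"  # ≯
NO_DATA = "n/a"

_STATUS_SYMBOL = {ACCEPTED: SUPERIOR, REJECTED: NOT_SUPERIOR, NO_EVIDENCE: NO_DATA}


@dataclass(frozen=True)
class Scenario:
    """One named what-if setting (weight overrides, filter, threshold)."""

    name: str
    weight_overrides: dict = field(default_factory=dict)
    filter: FilterSpec = field(default_factory=FilterSpec)
    tau: Fraction = Fraction(1, 2)

    def to_config(self, base: BuildConfig | None = None) -> BuildConfig:
        base = base or BuildConfig()
        return replace(
            base,
            tau=to_fraction(self.tau, "tau"),
            weight_overrides=dict(self.weight_overrides),
            filter=self.filter,
        )


@dataclass(frozen=True)
class ThresholdPartition:
    """Maximal closed grid ranges of tau with a constant outcome pattern."""

    intervals: tuple[tuple[Fraction, Fraction, dict[str, str]], ...]
    grid_step: Fraction
    #: distinct exact confidences in the tree — the true flip points.
    exact_breakpoints: tuple[Fraction, ...] = ()

    def pattern_at(self, tau) -> dict[str, str]:
        """Pattern of the interval containing tau (a tau between grid points
        belongs to the interval of the largest grid point not above it)."""
        tau = to_fraction(tau, "tau")
        match = None
        for low, _, pattern in self.intervals:
            if low <= tau:
                match = pattern
        if match is None:
            raise KeyError(f"tau {tau} outside the swept range")
        return match


def _aggregated_nodes(root: AggregatedArgument) -> list[AggregatedArgument]:
    return [n for n in root.walk() if isinstance(n, AggregatedArgument)]


def run_scenarios(
    kb: KnowledgeBase,
    tree: DimensionTree,
    t: str,
    t_prime: str,
    scenarios: Sequence[Scenario],
) -> pd.DataFrame:
    """One row per scenario: evidence count and a superiority symbol per
    dimension (``>`` accepted / ``≯`` rejected / ``n/a`` no evidence)."""
    if not scenarios:
        raise ValidationError("at least one scenario is required")
    dimension_ids = [node.id for node in tree.nodes()]
    rows = []
    for scenario in scenarios:
        root = build_diaet(kb, tree, t, t_prime, scenario.to_config())
        by_id = {n.dimension_id: n for n in _aggregated_nodes(root)}
        row: dict[str, object] = {
            "scenario": scenario.name,
            "n_studies": root.evidence_count,
        }
        for dim in dimension_ids:
            node = by_id.get(dim)
            row[dim] = _STATUS_SYMBOL[node.status] if node else NO_DATA
        rows.append(row)
    return pd.DataFrame(rows)


def sweep_thresholds(
    kb: KnowledgeBase,
    tree: DimensionTree,
    t: str,
    t_prime: str,
    config: BuildConfig | None = None,
    grid_step=Fraction(1, 100),
) -> ThresholdPartition:
    """Evaluate acceptance at tau in {0, step, 2*step, ..., 1} and merge
    consecutive grid points with identical per-dimension patterns."""
    step = to_fraction(grid_step, "grid_step")
    if not 0 < step <= Fraction(1, 2):
        raise ValidationError(f"grid_step must be in (0, 0.5], got {step}")
    config = config or BuildConfig()
    root = build_diaet(kb, tree, t, t_prime, config)
    nodes = _aggregated_nodes(root)

    taus = [k * step for k in range(int(1 / step) + 1)]
    if taus[-1] != 1:
        taus.append(Fraction(1))

    def pattern(tau: Fraction) -> dict[str, str]:
        out = {}
        for node in nodes:
            if node.status == NO_EVIDENCE:
                out[node.dimension_id] = NO_EVIDENCE
            else:
                out[node.dimension_id] = (
                    ACCEPTED if is_accepted(node.confidence, tau) else REJECTED
                )
        return out

    intervals: list[tuple[Fraction, Fraction, dict[str, str]]] = []
    for tau in taus:
        p = pattern(tau)
        if intervals and intervals[-1][2] == p:
            low, _, _ = intervals[-1]
            intervals[-1] = (low, tau, p)
        else:
            intervals.append((tau, tau, p))
    breakpoints = sorted(
        {n.confidence for n in nodes if n.confidence is not None}
    )
    return ThresholdPartition(
        intervals=tuple(intervals),
        grid_step=step,
        exact_breakpoints=tuple(breakpoints),
    )


def partition_to_frame(partition: ThresholdPartition) -> pd.DataFrame:
    """Tabular view of a sweep, one row per interval."""
    rows = []
    for low, high, pattern in partition.intervals:
        row: dict[str, object] = {
            "tau_low": float(low),
            "tau_high": float(high),
        }
        row.update({dim: _STATUS_SYMBOL.get(status, status) for dim, status in pattern.items()})
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class NodeDelta:
    dimension_id: str
    status_before: str
    status_after: str
    confidence_before: Fraction | None
    confidence_after: Fraction | None

    @property
    def confidence_delta(self) -> Fraction | None:
        if self.confidence_before is None or self.confidence_after is None:
            return None
        return self.confidence_after - self.confidence_before


def diff_trees(a: AggregatedArgument, b: AggregatedArgument) -> list[NodeDelta]:
    """Per-dimension deltas between two trees built from the same dimension
    tree; empty when nothing changed. Structure mismatch raises."""
    nodes_a = _aggregated_nodes(a)
    nodes_b = _aggregated_nodes(b)
    if [n.dimension_id for n in nodes_a] != [n.dimension_id for n in nodes_b]:
        raise StructuralError("argument trees come from different dimension trees")
    deltas = []
    for na, nb in zip(nodes_a, nodes_b):
        if na.status != nb.status or na.confidence != nb.confidence:
            deltas.append(
                NodeDelta(
                    dimension_id=na.dimension_id,
                    status_before=na.status,
                    status_after=nb.status,
                    confidence_before=na.confidence,
                    confidence_after=nb.confidence,
                )
            )
    return deltas
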