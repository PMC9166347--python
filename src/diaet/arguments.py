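"""Core argument calculus: superiority criteria, confidence aggregation,
threshold acceptance, and construction of the full argument tree.

The model
---------
For a treatment pair (t, t') and a leaf dimension, every trial that reports
the dimension for both drugs yields one *atomic argument* whose confidence is
1 when the trial's evidence satisfies the leaf's superiority criterion and 0
when it contradicts it. Every dimension-tree node then yields one *aggregated
argument* whose degree of confidence is the weight-normalized mean of its
premises' confidences,

    [[AgA]] = (1/Z) * sum_i  w_i * [[A_i]],     Z = sum_i w_i ,

with the weights taken from the dimension tree (atomic arguments all have
weight 1, so a leaf's confidence is simply the fraction of reporting studies
that support the claim). An aggregated argument is *accepted* when its
confidence is not less than the acceptance threshold tau (default 0.5, i.e.
a majority of the weighted evidence).

All arithmetic is exact rational; acceptance compares exact values, and only
the display layer rounds. Two reporting modes exist because published
summaries often round child confidences before summing: ``exact`` renders the
exact value to two decimals (half-up), ``paper_rounded`` re-evaluates each
node's weighted sum over its children's 2-decimal rounded reported values
before rendering.

Ties (equal change magnitudes, equal incidences) contradict superiority:
"no worse" is not "better". Leaves left without evidence after filtering are
marked ``no_evidence`` and are excluded from their parent's sum *and* from Z,
so missing data is never conflated with contradiction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal, localcontext
from fractions import Fraction
from typing import Iterator, Sequence, Union

from .dimensions import (
    EFFICACY,
    DECREASE,
    DimensionNode,
    DimensionTree,
    LeafBinding,
    reweight,
    to_fraction,
)
from .errors import (
    DataError,
    DegenerateWeightsError,
    NoEvidenceError,
    UsageError,
    ValidationError,
)
from .kb import (
    AdverseEventPair,
    EndpointResultPair,
    EvidencePair,
    FilterSpec,
    KnowledgeBase,
    apply_filters,
)
from .rdf import normalize_name

logger = logging.getLogger(__name__)

ACCEPTED = "accepted"
REJECTED = "rejected"
NO_EVIDENCE = "no_evidence"

EXACT = "exact"
PAPER_ROUNDED = "paper_rounded"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AtomicArgument:
    """A single study's superiority claim for one dimension; confidence 0/1."""

    t: str
    t_prime: str
    dimension_id: str
    study_id: str
    confidence: int
    facts: EvidencePair
    study_label: str = ""
    weight: Fraction = Fraction(1)

    @property
    def supports(self) -> bool:
        return self.confidence == 1

    @property
    def status(self) -> str:  # uniform surface with AggregatedArgument
        return ACCEPTED if self.supports else REJECTED


@dataclass(frozen=True)
class AggregatedArgument:
    """An inner conclusion: confidence aggregated from its premises."""

    t: str
    t_prime: str
    dimension_id: str
    label: str
    role: str  # "root", "inner" or "leaf" (leaf of the dimension tree)
    weight: Fraction
    premises: tuple[Union["AggregatedArgument", AtomicArgument], ...]
    confidence: Fraction | None
    status: str
    evidence_count: int
    meta: dict = field(default_factory=dict, compare=False, repr=False)

    @property
    def claims_superiority(self) -> bool:
        return self.status == ACCEPTED

    def walk(self) -> Iterator[Union["AggregatedArgument", AtomicArgument]]:
        yield self
        for premise in self.premises:
            if isinstance(premise, AggregatedArgument):
                yield from premise.walk()
            else:
                yield premise


@dataclass(frozen=True)
class BuildConfig:
    """Run configuration: threshold, evidence filter, weight overrides."""

    tau: Fraction = Fraction(1, 2)
    filter: FilterSpec = field(default_factory=FilterSpec)
    weight_overrides: dict = field(default_factory=dict)
    reporting_mode: str = EXACT

    def __post_init__(self) -> None:
        object.__setattr__(self, "tau", to_fraction(self.tau, "tau"))
        if not 0 <= self.tau <= 1:
            raise ValidationError(f"tau must be in [0, 1], got {self.tau}")
        if self.reporting_mode not in (EXACT, PAPER_ROUNDED):
            raise ValidationError(f"unknown reporting mode {self.reporting_mode!r}")
        self.filter.validate()


# ---------------------------------------------------------------------------
# Superiority criteria
# ---------------------------------------------------------------------------


def evaluate_efficacy_superiority(pair: EndpointResultPair, binding: LeafBinding) -> bool:
    """True (supports) iff drug1's change from baseline is strictly larger in
    the desired direction than drug2's; ties and wrong direction contradict."""
    if binding.criterion_kind != EFFICACY:
        raise UsageError("efficacy criterion applied with a non-efficacy binding")
    if normalize_name(pair.endpoint_id) != normalize_name(binding.target_id):
        raise DataError(
            f"{pair.study_id}: endpoint {pair.endpoint_id!r} does not match "
            f"binding target {binding.target_id!r}"
        )
    if pair.drug2_unit is not None:
        raise DataError(
            f"{pair.study_id}: unit mismatch between arms "
            f"({pair.unit!r} vs {pair.drug2_unit!r})"
        )
    if binding.desired_direction == DECREASE:
        return pair.drug1_change < pair.drug2_change
    return pair.drug1_change > pair.drug2_change


def evaluate_safety_superiority(pair: AdverseEventPair) -> bool:
    """True iff drug1 led to strictly fewer incidences of the adverse event:
    by incidence proportion when both arm sizes are known, by raw count
    otherwise. Equal incidence contradicts (drug1 is not *superior*)."""
    for affected, size, arm in (
        (pair.drug1_affected, pair.drug1_arm_size, "drug1"),
        (pair.drug2_affected, pair.drug2_arm_size, "drug2"),
    ):
        if affected < 0:
            raise DataError(f"{pair.study_id}: negative affected count in {arm} arm")
        if size is not None and (size <= 0 or affected > size):
            raise DataError(
                f"{pair.study_id}: affected {affected} exceeds {arm} arm size {size}"
            )
    if pair.drug1_arm_size is not None and pair.drug2_arm_size is not None:
        return (
            Fraction(pair.drug1_affected, pair.drug1_arm_size)
            < Fraction(pair.drug2_affected, pair.drug2_arm_size)
        )
    return pair.drug1_affected < pair.drug2_affected


def make_atomic_argument(
    pair: EvidencePair,
    binding: LeafBinding,
    t: str,
    t_prime: str,
    dimension_id: str,
    study_label: str = "",
) -> AtomicArgument:
    """Instantiate one study's atomic argument under the leaf's criterion."""
    if binding.criterion_kind == EFFICACY:
        if not isinstance(pair, EndpointResultPair):
            raise DataError(f"{pair.study_id}: efficacy binding needs endpoint evidence")
        supports = evaluate_efficacy_superiority(pair, binding)
    else:
        if not isinstance(pair, AdverseEventPair):
            raise DataError(f"{pair.study_id}: safety binding needs adverse-event evidence")
        if normalize_name(pair.event_id) != normalize_name(binding.target_id):
            raise DataError(
                f"{pair.study_id}: event {pair.event_id!r} does not match "
                f"binding target {binding.target_id!r}"
            )
        supports = evaluate_safety_superiority(pair)
    return AtomicArgument(
        t=t,
        t_prime=t_prime,
        dimension_id=dimension_id,
        study_id=pair.study_id,
        confidence=1 if supports else 0,
        facts=pair,
        study_label=study_label or pair.study_id,
    )


# ---------------------------------------------------------------------------
# Aggregation and acceptance
# ---------------------------------------------------------------------------


def aggregate_confidence(
    weighted_children: Sequence[tuple[object, object]]
) -> Fraction:
    """Weight-normalized mean  sum(w_i * c_i) / sum(w_i)  in exact rationals."""
    if not weighted_children:
        raise NoEvidenceError("nothing to aggregate")
    pairs = [
        (to_fraction(w, "weight"), to_fraction(c, "confidence"))
        for w, c in weighted_children
    ]
    for w, c in pairs:
        if w < 0:
            raise ValidationError(f"negative weight {w}")
        if not 0 <= c <= 1:
            raise ValidationError(f"confidence {c} outside [0, 1]")
    total = sum(w for w, _ in pairs)
    if total == 0:
        raise DegenerateWeightsError("all weights are zero")
    return sum(w * c for w, c in pairs) / total


def is_accepted(confidence, tau) -> bool:
    """Exact 'not less than' comparison; no rounding is involved."""
    conf = to_fraction(confidence, "confidence")
    threshold = to_fraction(tau, "tau")
    if not 0 <= conf <= 1 or not 0 <= threshold <= 1:
        raise ValidationError("confidence and tau must lie in [0, 1]")
    return conf >= threshold


# ---------------------------------------------------------------------------
# Tree construction
# ---------------------------------------------------------------------------


def build_diaet(
    kb: KnowledgeBase,
    tree: DimensionTree,
    t: str,
    t_prime: str,
    config: BuildConfig | None = None,
) -> AggregatedArgument:
    """Build the full argument tree for treatment ``t`` versus ``t_prime``.

    The recursion mirrors the dimension tree exactly (one call per dimension
    node, so it terminates by construction). Leaves turn filtered evidence
    into atomic arguments; inner nodes aggregate their evidenced children.
    A root with no evidence anywhere comes back with status ``no_evidence``
    — an explicit "no conclusion possible" outcome, not an exception.
    """
    config = config or BuildConfig()
    if config.weight_overrides:
        tree = reweight(tree, config.weight_overrides)
    calls = 0

    def build(node: DimensionNode, depth: int) -> AggregatedArgument:
        nonlocal calls
        calls += 1
        role = "root" if depth == 0 else ("leaf" if node.is_leaf else "inner")
        if node.is_leaf:
            return build_leaf(node, role)
        children = tuple(build(child, depth + 1) for child in node.children)
        evidenced = [c for c in children if c.status != NO_EVIDENCE]
        studies = {
            p.study_id for c in children for p in c.walk() if isinstance(p, AtomicArgument)
        }
        if not evidenced:
            return AggregatedArgument(
                t=t, t_prime=t_prime, dimension_id=node.id, label=node.label,
                role=role, weight=node.weight, premises=children,
                confidence=None, status=NO_EVIDENCE, evidence_count=0,
            )
        confidence = aggregate_confidence(
            [(c.weight, c.confidence) for c in evidenced]
        )
        return AggregatedArgument(
            t=t, t_prime=t_prime, dimension_id=node.id, label=node.label,
            role=role, weight=node.weight, premises=children,
            confidence=confidence,
            status=ACCEPTED if is_accepted(confidence, config.tau) else REJECTED,
            evidence_count=len(studies),
        )

    def build_leaf(node: DimensionNode, role: str) -> AggregatedArgument:
        binding = node.binding
        assert binding is not None
        if binding.criterion_kind == EFFICACY:
            evidence: Sequence[EvidencePair] = kb.query_endpoint_evidence(
                t, t_prime, binding.target_id
            )
        else:
            evidence = kb.query_adverse_evidence(t, t_prime, binding.target_id)
        kept = apply_filters(evidence, kb.trials, config.filter)
        atoms = tuple(
            make_atomic_argument(
                pair, binding, t, t_prime, node.id,
                study_label=kb.trials[pair.study_id].label,
            )
            for pair in kept
        )
        if not atoms:
            logger.info("dimension %s: no evidence after filtering", node.id)
            return AggregatedArgument(
                t=t, t_prime=t_prime, dimension_id=node.id, label=node.label,
                role=role, weight=node.weight, premises=(),
                confidence=None, status=NO_EVIDENCE, evidence_count=0,
            )
        # The reference count of a leaf stays the number of studies that
        # report the dimension in the KB: filtering a study out removes its
        # support but not its place in the denominator (an excluded trial
        # from 11 leaves 10/11, not 10/10), matching published tool output.
        reporting = len({p.study_id for p in evidence})
        confidence = Fraction(sum(a.confidence for a in atoms), reporting)
        return AggregatedArgument(
            t=t, t_prime=t_prime, dimension_id=node.id, label=node.label,
            role=role, weight=node.weight, premises=atoms,
            confidence=confidence,
            status=ACCEPTED if is_accepted(confidence, config.tau) else REJECTED,
            evidence_count=len({a.study_id for a in atoms}),
        )

    root = build(tree.root, 0)
    root.meta["recursive_calls"] = calls
    root.meta["tau"] = config.tau
    return root


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


def round_half_up(value: Fraction, places: int = 2) -> Decimal:
    """Round an exact rational half-up to ``places`` decimals."""
    with localcontext() as ctx:
        ctx.prec = 50
        quantum = Decimal(1).scaleb(-places)
        return (Decimal(value.numerator) / Decimal(value.denominator)).quantize(
            quantum, rounding=ROUND_HALF_UP
        )


def _paper_rounded_value(node: Union[AggregatedArgument, AtomicArgument]) -> Fraction:
    """Bottom-up 2-decimal-rounded confidence, mimicking printed arithmetic."""
    if isinstance(node, AtomicArgument):
        return Fraction(node.confidence)
    if all(isinstance(p, AtomicArgument) for p in node.premises):
        # leaf aggregate: its exact confidence already carries the
        # reporting-study denominator (see build_diaet)
        assert node.confidence is not None
        return Fraction(round_half_up(node.confidence, 2))
    evidenced = [p for p in node.premises
                 if isinstance(p, AtomicArgument) or p.status != NO_EVIDENCE]
    value = aggregate_confidence(
        [(p.weight, _paper_rounded_value(p)) for p in evidenced]
    )
    return Fraction(round_half_up(value, 2))


def reported_confidence(node: AggregatedArgument, mode: str = EXACT) -> str:
    """Two-decimal display string of a node's confidence.

    ``exact``: the exact rational, rounded half-up once at the end.
    ``paper_rounded``: children's reported (2-decimal) values are re-summed
    at every level before the final rounding, reproducing arithmetic done on
    already-rounded printed figures. Nodes without evidence report ``"n/a"``.
    """
    if mode not in (EXACT, PAPER_ROUNDED):
        raise UsageError(f"unknown reporting mode {mode!r}")
    if isinstance(node, AtomicArgument):
        return f"{node.confidence}.00"
    if node.status == NO_EVIDENCE or node.confidence is None:
        return "n/a"
    if mode == EXACT:
        return f"{round_half_up(node.confidence, 2):.2f}"
    return f"{round_half_up(_paper_rounded_value(node), 2):.2f}"
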