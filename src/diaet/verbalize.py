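"""Template-based verbalization of argument trees, plus structured exports
(JSON round-trip, Graphviz DOT, plain text)."""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from typing import Mapping, Union

import yaml

from .arguments import (
    ACCEPTED,
    EXACT,
    NO_EVIDENCE,
    PAPER_ROUNDED,
    REJECTED,
    AggregatedArgument,
    AtomicArgument,
    reported_confidence,
)
from .dimensions import format_number
from .errors import TemplateError, UsageError, ValidationError
from .kb import AdverseEventPair, EndpointResultPair

_ROLES = (
    "root_accepted", "root_rejected",
    "inner_accepted", "inner_rejected",
    "leaf_accepted", "leaf_rejected",
    "atomic_support", "atomic_contradict",
    "no_evidence",
)


@dataclass(frozen=True)
class TemplateSet:
    """Sentence templates keyed by argument role and outcome.

    Templates are plain ``str.format`` strings; the default set reproduces
    the wording of published tool output ("The evidence in N clinical studies
    shows that X is superior to Y in terms of D...").
    """

    templates: Mapping[str, str]

    def __post_init__(self) -> None:
        missing = [r for r in _ROLES if r not in self.templates]
        if missing:
            raise ValidationError(f"template set lacks roles: {missing}")

    @classmethod
    def default(cls) -> "TemplateSet":
        text = (resources.files("diaet") / "resources/templates/default.yaml").read_text(
            encoding="utf-8"
        )
        return cls.from_text(text)

    @classmethod
    def from_text(cls, text: str) -> "TemplateSet":
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValidationError("template document must be a mapping role -> sentence")
        return cls(templates=dict(data))

    def render(self, role: str, values: Mapping[str, object]) -> str:
        template = self.templates[role]
        try:
            return template.format(**values)
        except (KeyError, IndexError) as exc:
            raise TemplateError(f"template {role!r}: unresolved placeholder {exc}") from exc


def _weights_phrase(node: AggregatedArgument) -> str:
    """'weight of <child>: <w>' for each aggregated child, raw (configured)
    weights, matching the printed style of tool conclusions."""
    parts = [
        f"weight of {p.label}: {format_number(p.weight)}"
        for p in node.premises
        if isinstance(p, AggregatedArgument)
    ]
    return "; ".join(parts)


def _role_of(node: Union[AggregatedArgument, AtomicArgument]) -> str:
    if isinstance(node, AtomicArgument):
        return "atomic_support" if node.supports else "atomic_contradict"
    if node.status == NO_EVIDENCE:
        return "no_evidence"
    outcome = "accepted" if node.status == ACCEPTED else "rejected"
    return f"{node.role}_{outcome}"


def verbalize_node(
    node: Union[AggregatedArgument, AtomicArgument],
    templates: TemplateSet | None = None,
    reporting_mode: str = EXACT,
) -> str:
    """One conclusion sentence for a single argument node."""
    templates = templates or TemplateSet.default()
    if isinstance(node, AtomicArgument):
        values: dict[str, object] = {
            "t": node.t,
            "t_prime": node.t_prime,
            "study": node.study_label or node.study_id,
            "label": node.dimension_id,
        }
        facts = node.facts
        if isinstance(facts, EndpointResultPair):
            values["label"] = facts.endpoint_id
        elif isinstance(facts, AdverseEventPair):
            values["label"] = facts.event_id
        return templates.render(_role_of(node), values)
    values = {
        "t": node.t,
        "t_prime": node.t_prime,
        "n": node.evidence_count,
        "label": node.label,
        "weights": _weights_phrase(node),
        "confidence": reported_confidence(node, reporting_mode)
        if node.status != NO_EVIDENCE
        else "n/a",
    }
    return templates.render(_role_of(node), values)


def verbalize_tree(
    root: AggregatedArgument,
    templates: TemplateSet | None = None,
    reporting_mode: str = EXACT,
) -> str:
    """Depth-first, indented rendering: one sentence per node, atomic
    arguments grouped under their leaf with supporters before contradictors."""
    templates = templates or TemplateSet.default()
    lines: list[str] = []

    def walk(node, depth: int) -> None:
        marker = "↦" if depth == 0 else ("→" if isinstance(node, AtomicArgument) else "⇒")
        lines.append(
            "  " * depth + f"{marker} " + verbalize_node(node, templates, reporting_mode)
        )
        if isinstance(node, AggregatedArgument):
            atoms = [p for p in node.premises if isinstance(p, AtomicArgument)]
            aggs = [p for p in node.premises if isinstance(p, AggregatedArgument)]
            for child in aggs:
                walk(child, depth + 1)
            for atom in sorted(atoms, key=lambda a: (-a.confidence, a.study_id)):
                walk(atom, depth + 1)

    walk(root, 0)
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Structured exports
# ---------------------------------------------------------------------------


def _frac_str(value: Fraction | None) -> str | None:
    return None if value is None else str(value)


def _facts_to_dict(facts) -> dict:
    if isinstance(facts, EndpointResultPair):
        return {
            "kind": "endpoint",
            "study_id": facts.study_id,
            "endpoint_id": facts.endpoint_id,
            "drug1_name": facts.drug1_name,
            "drug2_name": facts.drug2_name,
            "drug1_change": facts.drug1_change,
            "drug2_change": facts.drug2_change,
            "unit": facts.unit,
            "significant": facts.significant,
            "drug2_unit": facts.drug2_unit,
        }
    return {
        "kind": "adverse_event",
        "study_id": facts.study_id,
        "event_id": facts.event_id,
        "drug1_name": facts.drug1_name,
        "drug2_name": facts.drug2_name,
        "drug1_affected": facts.drug1_affected,
        "drug2_affected": facts.drug2_affected,
        "drug1_arm_size": facts.drug1_arm_size,
        "drug2_arm_size": facts.drug2_arm_size,
    }


def _facts_from_dict(data: dict):
    data = dict(data)
    kind = data.pop("kind")
    if kind == "endpoint":
        return EndpointResultPair(**data)
    if kind == "adverse_event":
        return AdverseEventPair(**data)
    raise ValidationError(f"unknown facts kind {kind!r}")


def tree_to_dict(node: Union[AggregatedArgument, AtomicArgument]) -> dict:
    if isinstance(node, AtomicArgument):
        return {
            "kind": "atomic",
            "t": node.t,
            "t_prime": node.t_prime,
            "dimension_id": node.dimension_id,
            "study_id": node.study_id,
            "study_label": node.study_label,
            "confidence": node.confidence,
            "weight": str(node.weight),
            "facts": _facts_to_dict(node.facts),
        }
    return {
        "kind": "aggregated",
        "t": node.t,
        "t_prime": node.t_prime,
        "dimension_id": node.dimension_id,
        "label": node.label,
        "role": node.role,
        "weight": str(node.weight),
        "status": node.status,
        "confidence_exact": _frac_str(node.confidence),
        "confidence_reported": None
        if node.status == NO_EVIDENCE
        else {
            "exact": reported_confidence(node, EXACT),
            "paper_rounded": reported_confidence(node, PAPER_ROUNDED),
        },
        "evidence_count": node.evidence_count,
        "premises": [tree_to_dict(p) for p in node.premises],
    }


def tree_from_dict(data: dict) -> Union[AggregatedArgument, AtomicArgument]:
    if data["kind"] == "atomic":
        return AtomicArgument(
            t=data["t"],
            t_prime=data["t_prime"],
            dimension_id=data["dimension_id"],
            study_id=data["study_id"],
            study_label=data["study_label"],
            confidence=data["confidence"],
            weight=Fraction(data["weight"]),
            facts=_facts_from_dict(data["facts"]),
        )
    conf = data["confidence_exact"]
    return AggregatedArgument(
        t=data["t"],
        t_prime=data["t_prime"],
        dimension_id=data["dimension_id"],
        label=data["label"],
        role=data["role"],
        weight=Fraction(data["weight"]),
        status=data["status"],
        confidence=None if conf is None else Fraction(conf),
        evidence_count=data["evidence_count"],
        premises=tuple(tree_from_dict(p) for p in data["premises"]),
    )


def tree_from_json(text: str) -> Union[AggregatedArgument, AtomicArgument]:
    return tree_from_dict(json.loads(text))


_DOT_FILL = {ACCEPTED: "palegreen", REJECTED: "lightcoral", NO_EVIDENCE: "lightgray"}


def _dot_escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"')


def export(root: AggregatedArgument, format: str = "json") -> str:
    """Export an argument tree.

    ``json`` round-trips losslessly via :func:`tree_from_json`; ``dot`` emits
    Graphviz source with accepted nodes green, rejected red, evidence-free
    gray (supporting atoms green, contradicting orange); ``text`` is the
    verbalized tree with the default templates.
    """
    if format == "json":
        return json.dumps(tree_to_dict(root), indent=2)
    if format == "text":
        return verbalize_tree(root)
    if format != "dot":
        raise UsageError(f"unknown export format {format!r}")
    lines = [
        "digraph diaet {",
        '  node [shape=box, style=filled, fontname="Helvetica"];',
    ]
    counter = 0

    def emit(node) -> str:
        nonlocal counter
        name = f"n{counter}"
        counter += 1
        if isinstance(node, AtomicArgument):
            fill = "palegreen" if node.supports else "orange"
            label = f"{node.study_label or node.study_id}\\n[[AtA]] = {node.confidence}"
        else:
            fill = _DOT_FILL[node.status]
            conf = "n/a" if node.status == NO_EVIDENCE else reported_confidence(node)
            label = f"{node.label}\\n[[AgA]] = {conf}"
        lines.append(f'  {name} [label="{_dot_escape(label)}", fillcolor="{fill}"];')
        if isinstance(node, AggregatedArgument):
            for premise in node.premises:
                child = emit(premise)
                lines.append(f"  {name} -> {child};")
        return name

    emit(root)
    lines.append("}")
    return "\n".join(lines) + "\n"
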