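"""Weighted dimension trees.

A dimension tree is the clinical backbone of an argument tree: a hierarchy of
comparison dimensions (efficacy, safety, individual endpoints and adverse
effects), each carrying a non-negative weight that expresses its relative
importance among its siblings. Leaves bind a superiority criterion: an
efficacy leaf targets an endpoint and a desired direction of change, a safety
leaf targets an adverse event. Weights are kept verbatim as exact rationals;
normalization (dividing by the sum of sibling weights) happens only during
aggregation, so sibling weights need not sum to 1.

Configuration documents are YAML (hence also JSON) with the shape::

    id: overall
    label: Overall
    weight: 1
    children:
      - id: efficacy
        weight: 0.5
        children:
          - {id: iop, label: diurnal IOP, weight: 1,
             criterion: efficacy, target: diurnal_IOP, direction: decrease}
      - id: safety
        weight: 0.5
        children:
          - {id: hyperemia, label: conjunctival hyperemia, weight: 1,
             criterion: safety, target: conjunctival_hyperemia}
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Iterator, Mapping, Union

import yaml

from .errors import DegenerateWeightsError, ValidationError

EFFICACY = "efficacy"
SAFETY = "safety"
DECREASE = "decrease"
INCREASE = "increase"


def to_fraction(value: Union[int, float, str, Fraction], what: str = "value") -> Fraction:
    """Exact rational from a config scalar; floats go through their decimal
    string so 0.3 means 3/10, not the binary double."""
    try:
        if isinstance(value, Fraction):
            return value
        if isinstance(value, float):
            return Fraction(str(value))
        return Fraction(value)
    except (ValueError, ZeroDivisionError, TypeError) as exc:
        raise ValidationError(f"{what} is not a number: {value!r}") from exc


def format_number(value: Fraction) -> str:
    """Render an exact rational the way a config would write it: integer,
    terminating decimal, or num/den as a last resort."""
    if value.denominator == 1:
        return str(value.numerator)
    den = value.denominator
    while den % 2 == 0:
        den //= 2
    while den % 5 == 0:
        den //= 5
    if den == 1:  # terminating decimal
        scaled = value
        digits = 0
        while scaled.denominator != 1:
            scaled *= 10
            digits += 1
        text = str(scaled.numerator).rjust(digits + 1, "0")
        sign = "-" if value < 0 else ""
        return f"{sign}{text[:-digits].lstrip('-') or '0'}.{text[-digits:]}"
    return f"{value.numerator}/{value.denominator}"


@dataclass(frozen=True)
class LeafBinding:
    """Superiority-criterion binding of a leaf dimension."""

    criterion_kind: str  # EFFICACY or SAFETY
    target_id: str  # endpoint_id or event_id
    desired_direction: str | None = None  # DECREASE/INCREASE, efficacy only

    def __post_init__(self) -> None:
        if self.criterion_kind not in (EFFICACY, SAFETY):
            raise ValidationError(f"unknown criterion kind {self.criterion_kind!r}")
        if not self.target_id:
            raise ValidationError("leaf binding needs a target endpoint/event id")
        if self.criterion_kind == EFFICACY:
            if self.desired_direction not in (DECREASE, INCREASE):
                raise ValidationError(
                    "efficacy bindings need direction 'decrease' or 'increase', "
                    f"got {self.desired_direction!r}"
                )
        elif self.desired_direction is not None:
            raise ValidationError("safety bindings do not take a direction")


@dataclass(frozen=True)
class DimensionNode:
    id: str
    label: str
    weight: Fraction
    children: tuple["DimensionNode", ...] = ()
    binding: LeafBinding | None = None

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValidationError(f"dimension {self.id!r}: weight must be non-negative")
        if self.children and self.binding is not None:
            raise ValidationError(f"dimension {self.id!r}: children and binding are exclusive")
        if not self.children and self.binding is None:
            raise ValidationError(f"dimension {self.id!r}: leaf without a criterion binding")

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass(frozen=True)
class DimensionTree:
    root: DimensionNode

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for node in self.nodes():
            if node.id in seen:
                raise ValidationError(f"duplicate dimension id {node.id!r}")
            seen.add(node.id)

    def nodes(self) -> Iterator[DimensionNode]:
        """Depth-first preorder."""

        def walk(node: DimensionNode) -> Iterator[DimensionNode]:
            yield node
            for child in node.children:
                yield from walk(child)

        return walk(self.root)

    def find(self, dimension_id: str) -> DimensionNode:
        for node in self.nodes():
            if node.id == dimension_id:
                return node
        raise KeyError(dimension_id)

    @property
    def depth(self) -> int:
        def d(node: DimensionNode) -> int:
            return 1 + max((d(c) for c in node.children), default=0)

        return d(self.root)

    @property
    def size(self) -> int:
        return sum(1 for _ in self.nodes())


# ---------------------------------------------------------------------------
# Parsing / serialization
# ---------------------------------------------------------------------------


def _node_from_dict(data, path: str) -> DimensionNode:
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: expected a mapping, got {type(data).__name__}")
    unknown = set(data) - {"id", "label", "weight", "children", "criterion", "target", "direction"}
    if unknown:
        raise ValidationError(f"{path}: unknown keys {sorted(unknown)}")
    node_id = data.get("id")
    if not node_id or not isinstance(node_id, str):
        raise ValidationError(f"{path}: every dimension needs a string 'id'")
    weight = to_fraction(data.get("weight", 1), f"{path}: weight")
    label = data.get("label", node_id)
    children_spec = data.get("children")
    if children_spec is not None:
        if not isinstance(children_spec, list) or not children_spec:
            raise ValidationError(f"{node_id}: inner node needs a non-empty child list")
        if any(k in data for k in ("criterion", "target", "direction")):
            raise ValidationError(f"{node_id}: a node has either children or a criterion")
        children = tuple(
            _node_from_dict(c, f"{node_id}.children[{i}]") for i, c in enumerate(children_spec)
        )
        return DimensionNode(node_id, label, weight, children=children)
    if "criterion" not in data or "target" not in data:
        raise ValidationError(f"{node_id}: leaf without 'criterion'/'target' binding")
    binding = LeafBinding(data["criterion"], data["target"], data.get("direction"))
    return DimensionNode(node_id, label, weight, binding=binding)


def parse_dimension_config(document: Union[str, Mapping]) -> DimensionTree:
    """Parse and validate a YAML/JSON dimension-tree document (text or an
    already-loaded mapping). Weights are preserved verbatim."""
    if isinstance(document, str):
        try:
            data = yaml.safe_load(document)
        except yaml.YAMLError as exc:
            raise ValidationError(f"malformed dimension config: {exc}") from exc
    else:
        data = document
    return DimensionTree(_node_from_dict(data, "root"))


def node_to_dict(node: DimensionNode) -> dict:
    out: dict = {"id": node.id, "label": node.label}
    weight = format_number(node.weight)
    out["weight"] = float(weight) if "." in weight else (
        int(weight) if "/" not in weight else weight
    )
    if node.children:
        out["children"] = [node_to_dict(c) for c in node.children]
    else:
        assert node.binding is not None
        out["criterion"] = node.binding.criterion_kind
        out["target"] = node.binding.target_id
        if node.binding.desired_direction is not None:
            out["direction"] = node.binding.desired_direction
    return out


def serialize_dimension_config(tree: DimensionTree) -> str:
    return yaml.safe_dump(node_to_dict(tree.root), sort_keys=False)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def normalized_child_weights(node: DimensionNode) -> dict[str, Fraction]:
    """Sibling weights divided by their sum (the normalization constant of the
    aggregation rule); exact rationals that sum to 1."""
    if node.is_leaf:
        raise ValidationError(f"dimension {node.id!r} is a leaf; no child weights")
    total = sum(child.weight for child in node.children)
    if total == 0:
        raise DegenerateWeightsError(f"dimension {node.id!r}: all child weights are zero")
    return {child.id: child.weight / total for child in node.children}


def reweight(tree: DimensionTree, overrides: Mapping[str, object]) -> DimensionTree:
    """Return a new tree with the weights of the named dimensions replaced.

    Unknown ids raise ``KeyError``; negative weights are rejected. The input
    tree is unmodified and the structure is preserved.
    """
    new_weights: dict[str, Fraction] = {}
    for key, value in overrides.items():
        weight = to_fraction(value, f"weight override {key!r}")
        if weight < 0:
            raise ValidationError(f"weight override {key!r} must be non-negative")
        new_weights[key] = weight
    known = {node.id for node in tree.nodes()}
    missing = set(new_weights) - known
    if missing:
        raise KeyError(f"unknown dimension id(s): {sorted(missing)}")

    def rebuild(node: DimensionNode) -> DimensionNode:
        return replace(
            node,
            weight=new_weights.get(node.id, node.weight),
            children=tuple(rebuild(c) for c in node.children),
        )

    return DimensionTree(rebuild(tree.root))
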