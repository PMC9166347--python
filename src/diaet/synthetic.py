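"""Synthetic knowledge-base generator.

Builds Turtle KBs with a prescribed evidence structure: for every endpoint or
adverse event, exactly the requested numbers of trials support, contradict
(including explicit ties) or do not report the dimension, so the argument
calculus can be exercised end to end with known leaf confidences
(supporting / (supporting + contradicting + ties)).

Numeric effect values are drawn with a minimum margin (0.1 endpoint units;
two percentage points of incidence) so that float comparisons can never blur
support into contradiction; exact ties occur only where requested. Generation
is fully deterministic for a fixed spec and seed.

The built-in fixtures mirror the package's two reference comparisons:
``glaucoma`` (11 trials, latanoprost vs timolol: all 11 support superiority on
diurnal IOP reduction, 1 of the 6 trials reporting conjunctival hyperemia
supports it) and ``t2dm`` (9 trials, insulin glargine vs NPH insulin: all 9
support superiority on nocturnal hypoglycemia, 4 of 9 on HbA1c reduction by
default; both counts are parameterizable).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace
from typing import Mapping

from . import rdf
from .errors import ValidationError
from .kb import CTRO, RDFS_LABEL
from .rdf import IRI, Literal

DATA_NS = "https://w3id.org/diaet/kb#"

SUPPORTING = "supporting"
CONTRADICTING = "contradicting"
TIE = "tie"
NONREPORTING = "nonreporting"

_SURNAMES = (
    "Alm", "Camras", "Watson", "Mishima", "Diestelhorst", "Rulo", "Aquino",
    "Suzuki", "Nordmann", "Hedman", "Bron", "Benedetti", "Hsia", "Rosenstock",
    "Fritsche", "Massi", "Yki", "Eliaschewitz", "Pan",
)


@dataclass(frozen=True)
class EndpointSpec:
    """Prescribed evidence structure for one efficacy endpoint."""

    endpoint_id: str
    direction: str = "decrease"
    n_supporting: int = 0
    n_contradicting: int = 0
    n_nonreporting: int = 0
    n_ties: int = 0  # exact ties; they contradict superiority
    unit: str = "units"

    @property
    def n_reporting(self) -> int:
        return self.n_supporting + self.n_contradicting + self.n_ties

    @property
    def n_total(self) -> int:
        return self.n_reporting + self.n_nonreporting


@dataclass(frozen=True)
class EventSpec:
    """Prescribed evidence structure for one adverse event."""

    event_id: str
    n_supporting: int = 0
    n_contradicting: int = 0
    n_nonreporting: int = 0
    n_ties: int = 0

    @property
    def n_reporting(self) -> int:
        return self.n_supporting + self.n_contradicting + self.n_ties

    @property
    def n_total(self) -> int:
        return self.n_reporting + self.n_nonreporting


@dataclass(frozen=True)
class KBSpec:
    drug1: str
    drug2: str
    endpoints: tuple[EndpointSpec, ...] = ()
    events: tuple[EventSpec, ...] = ()
    n_trials: int | None = None  # default: max dimension total
    year_range: tuple[int, int] = (1995, 2005)
    duration_range: tuple[int, int] = (4, 52)
    participants_range: tuple[int, int] = (50, 400)
    age_range: tuple[float, float] = (55.0, 70.0)
    seed: int = 0
    #: when set, endpoint results carry baseline+final values and the loader
    #: derives the change; otherwise the change is stored directly.
    emit_final_values: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "endpoints", tuple(self.endpoints))
        object.__setattr__(self, "events", tuple(self.events))

    def validate(self) -> None:
        if not self.drug1 or not self.drug2:
            raise ValidationError("both drug names are required")
        for dim in (*self.endpoints, *self.events):
            for name in ("n_supporting", "n_contradicting", "n_nonreporting", "n_ties"):
                if getattr(dim, name) < 0:
                    raise ValidationError(f"{_dim_id(dim)}: {name} must be non-negative")
        needed = max((d.n_total for d in (*self.endpoints, *self.events)), default=0)
        if self.n_trials is not None and self.n_trials < needed:
            raise ValidationError(
                f"n_trials={self.n_trials} is below the {needed} trials required "
                "by the per-dimension counts"
            )
        for lo, hi in (self.year_range, self.duration_range,
                       self.participants_range, self.age_range):
            if lo > hi:
                raise ValidationError(f"range ({lo}, {hi}) has min > max")

    @property
    def total_trials(self) -> int:
        needed = max((d.n_total for d in (*self.endpoints, *self.events)), default=0)
        return self.n_trials if self.n_trials is not None else needed


def _dim_id(dim) -> str:
    return dim.endpoint_id if isinstance(dim, EndpointSpec) else dim.event_id


def study_ids(spec: KBSpec) -> list[str]:
    return [f"CT_{i + 1:02d}" for i in range(spec.total_trials)]


def role_assignment(spec: KBSpec) -> dict[str, dict[str, str]]:
    """Per dimension, the role of every trial: trials take roles in id order
    (supporting first, then contradicting, ties, non-reporting); trials beyond
    a dimension's total never report it."""
    ids = study_ids(spec)
    out: dict[str, dict[str, str]] = {}
    for dim in (*spec.endpoints, *spec.events):
        roles: dict[str, str] = {}
        cursor = 0
        for role, count in (
            (SUPPORTING, dim.n_supporting),
            (CONTRADICTING, dim.n_contradicting),
            (TIE, dim.n_ties),
        ):
            for sid in ids[cursor:cursor + count]:
                roles[sid] = role
            cursor += count
        for sid in ids[cursor:]:
            roles[sid] = NONREPORTING
        out[_dim_id(dim)] = roles
    return out


def nonreporting_studies(spec: KBSpec, dimension_id: str) -> list[str]:
    """Study ids that do not report the given endpoint/event (sorted)."""
    roles = role_assignment(spec)[dimension_id]
    return sorted(sid for sid, role in roles.items() if role == NONREPORTING)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

_MIN_EFFECT_MARGIN = 0.1  # endpoint units
_MIN_INCIDENCE_MARGIN = 0.02  # proportion of the arm


def build_graph(spec: KBSpec) -> rdf.Graph:
    """Materialize the spec as an RDF graph (see :func:`generate_kb`)."""
    spec.validate()
    rng = random.Random(spec.seed)
    graph = rdf.Graph()
    graph.bind("ctro", CTRO)
    graph.bind("kb", DATA_NS)
    graph.bind("rdfs", "http://www.w3.org/2000/01/rdf-schema#")

    ids = study_ids(spec)
    roles = role_assignment(spec)
    participants: dict[str, int] = {}

    for sid in ids:
        trial = IRI(DATA_NS + sid)
        year = rng.randint(*spec.year_range)
        participants[sid] = rng.randint(*spec.participants_range)
        graph.add(trial, IRI(rdf.RDF_TYPE), IRI(CTRO + "ClinicalTrial"))
        graph.add(trial, RDFS_LABEL, Literal(f"{rng.choice(_SURNAMES)} {year}"))
        graph.add(trial, IRI(CTRO + "hasPublicationYear"), Literal(year))
        graph.add(trial, IRI(CTRO + "hasDurationWeeks"),
                  Literal(rng.randint(*spec.duration_range)))
        graph.add(trial, IRI(CTRO + "hasNumberOfParticipants"),
                  Literal(participants[sid]))
        graph.add(trial, IRI(CTRO + "hasMeanAge"),
                  Literal(round(rng.uniform(*spec.age_range), 1)))
        for arm_no, drug in ((1, spec.drug1), (2, spec.drug2)):
            arm = IRI(DATA_NS + f"{sid}_arm{arm_no}")
            graph.add(trial, IRI(CTRO + "hasArm"), arm)
            graph.add(arm, IRI(CTRO + "hasDrugName"), Literal(drug))

    for endpoint in spec.endpoints:
        for sid in ids:
            role = roles[endpoint.endpoint_id][sid]
            if role == NONREPORTING:
                continue
            _add_endpoint_results(graph, rng, spec, sid, endpoint, role)

    for event in spec.events:
        for sid in ids:
            role = roles[event.event_id][sid]
            if role == NONREPORTING:
                continue
            _add_event_counts(graph, rng, sid, event, role, participants[sid])

    return graph


def _add_endpoint_results(graph, rng, spec, sid, endpoint, role) -> None:
    sign = -1.0 if endpoint.direction == "decrease" else 1.0
    baseline = round(rng.uniform(10.0, 30.0), 1)
    change2 = round(sign * rng.uniform(0.5, 3.0), 2)
    delta = round(rng.uniform(_MIN_EFFECT_MARGIN, 1.2), 2)
    if role == SUPPORTING:
        change1 = round(change2 + sign * delta, 2)
    elif role == CONTRADICTING:
        change1 = round(change2 - sign * delta, 2)
    else:  # exact tie
        change1 = change2
    significant = role == SUPPORTING and rng.random() < 0.8
    for arm_no, change in ((1, change1), (2, change2)):
        node = IRI(DATA_NS + f"{sid}_arm{arm_no}_{endpoint.endpoint_id}")
        graph.add(IRI(DATA_NS + f"{sid}_arm{arm_no}"),
                  IRI(CTRO + "hasEndpointResult"), node)
        graph.add(node, IRI(CTRO + "hasEndpointId"), Literal(endpoint.endpoint_id))
        graph.add(node, IRI(CTRO + "hasBaselineValue"), Literal(baseline))
        if spec.emit_final_values:
            graph.add(node, IRI(CTRO + "hasFinalValue"),
                      Literal(round(baseline + change, 2)))
        else:
            graph.add(node, IRI(CTRO + "hasChangeValue"), Literal(change))
        graph.add(node, IRI(CTRO + "hasUnit"), Literal(endpoint.unit))
        if arm_no == 1:
            graph.add(node, IRI(CTRO + "isSignificant"), Literal(significant))


def _add_event_counts(graph, rng, sid, event, role, total_participants) -> None:
    size = max(2, total_participants // 2)  # equal arms: proportion == count order
    margin = max(1, -(-size * 2 // 100))  # ceil(0.02 * size) incidences
    low = rng.randint(0, size // 3)
    gap = margin + rng.randint(0, max(1, size // 10))
    high = min(size, low + gap)
    if high <= low:  # can only happen at tiny arm sizes
        low, high = 0, margin
    if role == SUPPORTING:
        affected1, affected2 = low, high
    elif role == CONTRADICTING:
        affected1, affected2 = high, low
    else:
        affected1 = affected2 = low
    for arm_no, affected in ((1, affected1), (2, affected2)):
        node = IRI(DATA_NS + f"{sid}_arm{arm_no}_{event.event_id}")
        graph.add(IRI(DATA_NS + f"{sid}_arm{arm_no}"),
                  IRI(CTRO + "hasAdverseEvent"), node)
        graph.add(node, IRI(CTRO + "hasEventId"), Literal(event.event_id))
        graph.add(node, IRI(CTRO + "hasNumberAffected"), Literal(affected))
        graph.add(node, IRI(CTRO + "hasArmSize"), Literal(size))


def generate_kb(spec: KBSpec) -> str:
    """Serialize the spec as a Turtle document (deterministic per seed)."""
    return rdf.serialize_turtle(build_graph(spec))


def write_kb(spec: KBSpec, path) -> None:
    from pathlib import Path

    Path(path).write_text(generate_kb(spec), encoding="utf-8")


# ---------------------------------------------------------------------------
# Built-in fixtures
# ---------------------------------------------------------------------------


def glaucoma_spec(seed: int = 0) -> KBSpec:
    """11 trials of latanoprost vs timolol: 11/11 support on diurnal IOP
    reduction; 6 report conjunctival hyperemia, 1 of them supporting."""
    return KBSpec(
        drug1="latanoprost",
        drug2="timolol",
        endpoints=(
            EndpointSpec("diurnal_IOP", direction="decrease",
                         n_supporting=11, unit="mmHg"),
        ),
        events=(
            EventSpec("conjunctival_hyperemia",
                      n_supporting=1, n_contradicting=5, n_nonreporting=5),
        ),
        seed=seed,
    )


def t2dm_spec(
    efficacy_supporting: int = 4,
    safety_supporting: int = 9,
    n_trials: int = 9,
    seed: int = 0,
) -> KBSpec:
    """9 trials of insulin glargine vs NPH insulin; support counts are
    parameterizable (defaults: 9/9 on nocturnal hypoglycemia, 4/9 on HbA1c)."""
    if not 0 <= efficacy_supporting <= n_trials or not 0 <= safety_supporting <= n_trials:
        raise ValidationError("support counts must lie within the number of trials")
    return KBSpec(
        drug1="insulin glargine",
        drug2="NPH insulin",
        endpoints=(
            EndpointSpec("HbA1c", direction="decrease",
                         n_supporting=efficacy_supporting,
                         n_contradicting=n_trials - efficacy_supporting,
                         unit="%"),
        ),
        events=(
            EventSpec("nocturnal_hypoglycemia",
                      n_supporting=safety_supporting,
                      n_contradicting=n_trials - safety_supporting),
        ),
        n_trials=n_trials,
        duration_range=(12, 52),
        seed=seed,
    )


def builtin_fixtures() -> dict[str, KBSpec]:
    """Named fixture specs; unknown names raise ``KeyError`` on lookup."""
    return {"glaucoma": glaucoma_spec(), "t2dm": t2dm_spec()}


# ---------------------------------------------------------------------------
# Spec (de)serialization for CLI use
# ---------------------------------------------------------------------------


def spec_from_dict(data: Mapping) -> KBSpec:
    data = dict(data)
    endpoints = tuple(EndpointSpec(**e) for e in data.pop("endpoints", []))
    events = tuple(EventSpec(**e) for e in data.pop("events", []))
    for key in ("year_range", "duration_range", "participants_range", "age_range"):
        if key in data:
            data[key] = tuple(data[key])
    try:
        spec = KBSpec(endpoints=endpoints, events=events, **data)
    except TypeError as exc:
        raise ValidationError(f"bad KB spec: {exc}") from exc
    spec.validate()
    return spec


def spec_with_seed(spec: KBSpec, seed: int) -> KBSpec:
    return replace(spec, seed=seed)
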