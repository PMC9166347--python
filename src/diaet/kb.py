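"""Evidence knowledge base: load a Turtle KB of randomized controlled trials
and answer arm-level evidence queries for a treatment pair.

The vocabulary is a small, documented subset of a clinical-trial ontology
(prefix ``ctro:``, see ``resources/schema.ttl``): a trial has arms, an arm
carries a drug name, endpoint results (change from baseline, or baseline and
final values, with a unit) and adverse-event counts, and the trial itself
carries the metadata used for evidence filtering (publication year, duration,
participant count, mean age).

Retrieval runs the query templates in ``resources/queries/`` through the
in-package BGP engine; drug, endpoint and event names are matched
case-insensitively after whitespace normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence, Union

from . import rdf
from .errors import DataError, KBLoadError, UsageError, ValidationError
from .rdf import IRI, Literal, normalize_name

logger = logging.getLogger(__name__)

#: Namespace of the shipped clinical-trial vocabulary subset.
CTRO = "https://w3id.org/diaet/ctro#"
RDFS_LABEL = IRI("http://www.w3.org/2000/01/rdf-schema#label")

_CLINICAL_TRIAL = IRI(CTRO + "ClinicalTrial")
_HAS_ARM = IRI(CTRO + "hasArm")
_HAS_DRUG_NAME = IRI(CTRO + "hasDrugName")
_HAS_ENDPOINT_RESULT = IRI(CTRO + "hasEndpointResult")
_HAS_ENDPOINT_ID = IRI(CTRO + "hasEndpointId")
_HAS_BASELINE = IRI(CTRO + "hasBaselineValue")
_HAS_CHANGE = IRI(CTRO + "hasChangeValue")
_HAS_FINAL = IRI(CTRO + "hasFinalValue")
_HAS_UNIT = IRI(CTRO + "hasUnit")
_IS_SIGNIFICANT = IRI(CTRO + "isSignificant")
_HAS_ADVERSE_EVENT = IRI(CTRO + "hasAdverseEvent")
_HAS_EVENT_ID = IRI(CTRO + "hasEventId")
_HAS_AFFECTED = IRI(CTRO + "hasNumberAffected")
_HAS_ARM_SIZE = IRI(CTRO + "hasArmSize")
_HAS_YEAR = IRI(CTRO + "hasPublicationYear")
_HAS_DURATION = IRI(CTRO + "hasDurationWeeks")
_HAS_PARTICIPANTS = IRI(CTRO + "hasNumberOfParticipants")
_HAS_MEAN_AGE = IRI(CTRO + "hasMeanAge")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrialRecord:
    """Metadata of one randomized controlled trial."""

    study_id: str
    label: str
    publication_year: int | None = None
    duration_weeks: float | None = None
    total_participants: int | None = None
    mean_age: float | None = None

    def __post_init__(self) -> None:
        for name in ("duration_weeks", "total_participants", "mean_age"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise DataError(f"{self.study_id}: {name} must be non-negative, got {value}")


@dataclass(frozen=True)
class EndpointResultPair:
    """One trial's paired endpoint evidence: change from baseline per arm."""

    study_id: str
    endpoint_id: str
    drug1_name: str
    drug2_name: str
    drug1_change: float
    drug2_change: float
    unit: str
    significant: bool | None = None
    #: unit reported for the second arm when it differs textually; the
    #: superiority criterion rejects pairs whose units do not agree.
    drug2_unit: str | None = None


@dataclass(frozen=True)
class AdverseEventPair:
    """One trial's paired adverse-event counts for a single event."""

    study_id: str
    event_id: str
    drug1_name: str
    drug2_name: str
    drug1_affected: int
    drug2_affected: int
    drug1_arm_size: int | None = None
    drug2_arm_size: int | None = None


EvidencePair = Union[EndpointResultPair, AdverseEventPair]

_BOUNDED_FIELDS = (
    ("year_min", "year_max", "publication_year"),
    ("duration_min", "duration_max", "duration_weeks"),
    ("participants_min", "participants_max", "total_participants"),
    ("age_min", "age_max", "mean_age"),
)


@dataclass(frozen=True)
class FilterSpec:
    """Evidence filter: trial-metadata bounds plus explicit study exclusions.

    A bound on a metadata field that a trial does not report excludes that
    trial (the bound cannot be verified).
    """

    year_min: int | None = None
    year_max: int | None = None
    duration_min: float | None = None
    duration_max: float | None = None
    participants_min: int | None = None
    participants_max: int | None = None
    age_min: float | None = None
    age_max: float | None = None
    excluded_study_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "excluded_study_ids", frozenset(self.excluded_study_ids))

    def validate(self) -> None:
        for lo_name, hi_name, _ in _BOUNDED_FIELDS:
            lo, hi = getattr(self, lo_name), getattr(self, hi_name)
            if lo is not None and hi is not None and lo > hi:
                raise ValidationError(f"{lo_name} > {hi_name} ({lo} > {hi})")

    def admits(self, trial: TrialRecord) -> bool:
        if trial.study_id in self.excluded_study_ids:
            return False
        for lo_name, hi_name, attr in _BOUNDED_FIELDS:
            lo, hi = getattr(self, lo_name), getattr(self, hi_name)
            if lo is None and hi is None:
                continue
            value = getattr(trial, attr)
            if value is None:
                return False
            if (lo is not None and value < lo) or (hi is not None and value > hi):
                return False
        return True


def _read_resource(name: str) -> str:
    return (resources.files("diaet") / "resources" / name).read_text(encoding="utf-8")


# ---------------------------------------------------------------------------
# Knowledge base
# ---------------------------------------------------------------------------


class KnowledgeBase:
    """A loaded trial KB: the RDF graph plus an index of trial records."""

    def __init__(self, graph: rdf.Graph, source: str | None = None) -> None:
        self.graph = graph
        self.source = source
        self.trials: dict[str, TrialRecord] = {}
        for subject in graph.subjects(IRI(rdf.RDF_TYPE), _CLINICAL_TRIAL):
            record = self._trial_record(subject)
            if record.study_id in self.trials:
                raise DataError(f"duplicate study_id {record.study_id!r}")
            self.trials[record.study_id] = record
        if not self.trials:
            logger.warning("knowledge base %s contains no clinical trials", source or "<graph>")

    def _trial_record(self, subject: IRI) -> TrialRecord:
        def lit(pred, cast):
            obj = self.graph.value(subject, pred)
            if obj is None:
                return None
            if not isinstance(obj, Literal):
                raise DataError(f"{subject.local_name}: expected literal for {pred.local_name}")
            return cast(obj.value)

        label = lit(RDFS_LABEL, str) or subject.local_name
        return TrialRecord(
            study_id=subject.local_name,
            label=label,
            publication_year=lit(_HAS_YEAR, int),
            duration_weeks=lit(_HAS_DURATION, float),
            total_participants=lit(_HAS_PARTICIPANTS, int),
            mean_age=lit(_HAS_MEAN_AGE, float),
        )

    @property
    def trial_count(self) -> int:
        return len(self.trials)

    @property
    def triple_count(self) -> int:
        return len(self.graph)

    # -- evidence retrieval ---------------------------------------------

    def query_endpoint_evidence(
        self, drug1: str, drug2: str, endpoint_id: str
    ) -> list[EndpointResultPair]:
        """One :class:`EndpointResultPair` per trial that reports ``endpoint_id``
        for both drugs, ordered by study_id. Trials lacking either arm or the
        endpoint in either arm are omitted (one-sided reports with a warning)."""
        _require_names(drug1, drug2, endpoint_id)
        template = _read_resource("queries/endpoint_evidence.rq")
        bindings = rdf.run_query(
            self.graph,
            template,
            {"drug1": drug1, "drug2": drug2, "endpoint_id": endpoint_id},
        )
        pairs: list[EndpointResultPair] = []
        for trial, rows in _group_by_trial(bindings):
            row = rows[0]
            values1 = self._endpoint_values(row["res1"], trial)
            values2 = self._endpoint_values(row["res2"], trial)
            if values1 is None or values2 is None:
                continue
            change1, unit1, sig1 = values1
            change2, unit2, _ = values2
            pairs.append(
                EndpointResultPair(
                    study_id=trial,
                    endpoint_id=_str(row["endpoint1"]),
                    drug1_name=_str(row["drug1Name"]),
                    drug2_name=_str(row["drug2Name"]),
                    drug1_change=change1,
                    drug2_change=change2,
                    unit=unit1,
                    significant=sig1,
                    drug2_unit=unit2 if normalize_name(unit2) != normalize_name(unit1) else None,
                )
            )
        self._warn_one_sided(drug1, drug2, endpoint_id, {p.study_id for p in pairs}, "endpoint")
        return sorted(pairs, key=lambda p: p.study_id)

    def query_adverse_evidence(
        self, drug1: str, drug2: str, event_id: str
    ) -> list[AdverseEventPair]:
        """Paired adverse-event counts, one per trial reporting the event for
        both drugs; same matching and ordering rules as endpoint evidence."""
        _require_names(drug1, drug2, event_id)
        template = _read_resource("queries/adverse_evidence.rq")
        bindings = rdf.run_query(
            self.graph,
            template,
            {"drug1": drug1, "drug2": drug2, "event_id": event_id},
        )
        pairs: list[AdverseEventPair] = []
        for trial, rows in _group_by_trial(bindings):
            row = rows[0]
            counts1 = self._event_values(row["ae1"], trial)
            counts2 = self._event_values(row["ae2"], trial)
            if counts1 is None or counts2 is None:
                continue
            pairs.append(
                AdverseEventPair(
                    study_id=trial,
                    event_id=_str(row["event1"]),
                    drug1_name=_str(row["drug1Name"]),
                    drug2_name=_str(row["drug2Name"]),
                    drug1_affected=counts1[0],
                    drug2_affected=counts2[0],
                    drug1_arm_size=counts1[1],
                    drug2_arm_size=counts2[1],
                )
            )
        self._warn_one_sided(drug1, drug2, event_id, {p.study_id for p in pairs}, "event")
        return sorted(pairs, key=lambda p: p.study_id)

    # -- value extraction -------------------------------------------------

    def _endpoint_values(self, result: IRI, trial: str):
        change = self.graph.value(result, _HAS_CHANGE)
        if change is None:
            baseline = self.graph.value(result, _HAS_BASELINE)
            final = self.graph.value(result, _HAS_FINAL)
            if baseline is None or final is None:
                logger.warning("%s: endpoint result without change or final value", trial)
                return None
            change_value = float(_num(final)) - float(_num(baseline))
        else:
            change_value = float(_num(change))
        unit = self.graph.value(result, _HAS_UNIT)
        sig = self.graph.value(result, _IS_SIGNIFICANT)
        return (
            change_value,
            _str(unit) if unit is not None else "",
            bool(sig.value) if isinstance(sig, Literal) else None,
        )

    def _event_values(self, node: IRI, trial: str):
        affected = self.graph.value(node, _HAS_AFFECTED)
        if affected is None:
            logger.warning("%s: adverse event without affected count", trial)
            return None
        size = self.graph.value(node, _HAS_ARM_SIZE)
        return int(_num(affected)), (int(_num(size)) if size is not None else None)

    def _warn_one_sided(self, drug1, drug2, target, paired_ids, kind) -> None:
        """Log trials comparing both drugs but reporting the target in one arm only."""
        pred, idp = (
            (_HAS_ENDPOINT_RESULT, _HAS_ENDPOINT_ID)
            if kind == "endpoint"
            else (_HAS_ADVERSE_EVENT, _HAS_EVENT_ID)
        )
        want = normalize_name(target)
        for subject in self.graph.subjects(IRI(rdf.RDF_TYPE), _CLINICAL_TRIAL):
            study_id = subject.local_name
            if study_id in paired_ids:
                continue
            reporting = set()
            for arm in self.graph.objects(subject, _HAS_ARM):
                name = self.graph.value(arm, _HAS_DRUG_NAME)
                if name is None:
                    continue
                name = normalize_name(_str(name))
                if name not in (normalize_name(drug1), normalize_name(drug2)):
                    continue
                for node in self.graph.objects(arm, pred):
                    tid = self.graph.value(node, idp)
                    if tid is not None and normalize_name(_str(tid)) == want:
                        reporting.add(name)
            if len(reporting) == 1:
                logger.warning(
                    "%s reports %s %r in only one arm; dropped from this dimension",
                    study_id, kind, target,
                )


def _require_names(*names: str) -> None:
    if any(not n or not n.strip() for n in names):
        raise UsageError("drug and endpoint/event names must be non-empty")


def _group_by_trial(bindings):
    groups: dict[str, list] = {}
    for b in bindings:
        groups.setdefault(b["trial"].local_name, []).append(b)
    for trial in sorted(groups):
        yield trial, groups[trial]


def _str(term) -> str:
    return str(term.value) if isinstance(term, Literal) else term.local_name


def _num(term):
    if not isinstance(term, Literal) or isinstance(term.value, str):
        raise DataError(f"expected a numeric literal, got {term!r}")
    return term.value


# ---------------------------------------------------------------------------
# Module operations
# ---------------------------------------------------------------------------


def load_kb(path: str | Path, format: str = "turtle") -> KnowledgeBase:
    """Load a Turtle KB file. ``format`` must name a supported serialization
    (only Turtle is; RDF/XML is not implemented)."""
    if format.lower() not in ("turtle", "ttl"):
        raise UsageError(f"unsupported RDF serialization {format!r} (only Turtle)")
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise KBLoadError(f"cannot read knowledge base {path}: {exc}") from exc
    graph = rdf.parse_turtle(text)
    return KnowledgeBase(graph, source=str(path))


def apply_filters(
    evidence: Sequence[EvidencePair],
    trials: Mapping[str, TrialRecord],
    filter_spec: FilterSpec,
) -> list[EvidencePair]:
    """Keep exactly the pairs whose trial satisfies every bound of
    ``filter_spec`` and is not excluded; order preserved, input unmodified."""
    filter_spec.validate()
    out: list[EvidencePair] = []
    for pair in evidence:
        if pair.study_id not in trials:
            raise DataError(f"no TrialRecord for study {pair.study_id!r}")
        if filter_spec.admits(trials[pair.study_id]):
            out.append(pair)
    return out
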