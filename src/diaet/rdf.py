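"""Minimal RDF triple store with a Turtle-subset parser/serializer and a
basic-graph-pattern (BGP) query engine.

The knowledge bases consumed by this package use a small, documented
vocabulary (named IRIs only, plain/typed literals, ``@prefix`` declarations).
This module implements exactly that subset of RDF 1.1 Turtle plus the BGP
fragment of SPARQL needed to evaluate the shipped query templates: triple
patterns with variables and ``FILTER(LCASE(STR(?v)) = "...")`` clauses.
Blank nodes, collections, language tags and OPTIONAL are not supported and
raise a parse error.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Union

from .errors import TurtleParseError, UsageError

RDF_TYPE = "http://www.w3.org/1999/02/22-rdf-syntax-ns#type"
XSD = "http://www.w3.org/2001/XMLSchema#"


@dataclass(frozen=True)
class IRI:
    """An IRI reference (absolute; this package never resolves relative IRIs)."""

    value: str

    @property
    def local_name(self) -> str:
        return re.split(r"[#/]", self.value)[-1]

    def __repr__(self) -> str:  # keeps sort keys readable in tests
        return f"<{self.value}>"


@dataclass(frozen=True)
class Literal:
    """A literal with its value mapped to a Python type (str/int/float/bool)."""

    value: Union[str, int, float, bool]

    def __repr__(self) -> str:
        return f"Literal({self.value!r})"


Term = Union[IRI, Literal]
Triple = tuple[IRI, IRI, Term]


@dataclass(frozen=True)
class Var:
    """A query variable (``?name``)."""

    name: str


class Graph:
    """An insertion-ordered, duplicate-free set of triples with prefix table."""

    def __init__(self) -> None:
        self._triples: list[Triple] = []
        self._seen: set[Triple] = set()
        self.namespaces: dict[str, str] = {}

    def __len__(self) -> int:
        return len(self._triples)

    def bind(self, prefix: str, namespace: str) -> None:
        self.namespaces[prefix] = namespace

    def add(self, s: IRI, p: IRI, o: Term) -> None:
        t = (s, p, o)
        if t not in self._seen:
            self._seen.add(t)
            self._triples.append(t)

    def triples(
        self, s: IRI | None = None, p: IRI | None = None, o: Term | None = None
    ) -> Iterator[Triple]:
        for ts, tp, to in self._triples:
            if (s is None or ts == s) and (p is None or tp == p) and (o is None or to == o):
                yield (ts, tp, to)

    def value(self, s: IRI, p: IRI):
        """First object for (s, p), by sorted term repr; None when absent."""
        objs = sorted((t[2] for t in self.triples(s, p)), key=repr)
        return objs[0] if objs else None

    def subjects(self, p: IRI | None = None, o: Term | None = None) -> list[IRI]:
        out: list[IRI] = []
        for ts, _, _ in self.triples(None, p, o):
            if ts not in out:
                out.append(ts)
        return out

    def objects(self, s: IRI, p: IRI) -> list[Term]:
        return [t[2] for t in self.triples(s, p)]


# ---------------------------------------------------------------------------
# Turtle tokenizer / parser
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""
      (?P<WS>[ \t\r]+)
    | (?P<COMMENT>\#[^\n]*)
    | (?P<NL>\n)
    | (?P<IRIREF><[^<>"{}|^`\\\x00-\x20]*>)
    | (?P<STRING>"(?:[^"\\\n]|\\.)*")
    | (?P<PREFIXDECL>@prefix\b)
    | (?P<PNAME>(?:[A-Za-z_][\w-]*)?:(?:\w(?:[\w.-]*[\w-])?)?)
    | (?P<BOOLEAN>\b(?:true|false)\b)
    | (?P<A>\ba\b)
    | (?P<DOUBLE>[+-]?(?:\d+\.\d*|\.?\d+)[eE][+-]?\d+)
    | (?P<DECIMAL>[+-]?\d*\.\d+)
    | (?P<INTEGER>[+-]?\d+)
    | (?P<DTYPE>\^\^)
    | (?P<PUNCT>[;,.\[\]\(\)])
    """,
    re.X,
)

_STRING_ESCAPES = {"\\": "\\", '"': '"', "n": "\n", "r": "\r", "t": "\t"}


def _unescape(raw: str, line: int) -> str:
    out: list[str] = []
    i = 0
    while i < len(raw):
        ch = raw[i]
        if ch == "\\":
            i += 1
            esc = raw[i]
            if esc not in _STRING_ESCAPES:
                raise TurtleParseError(f"unsupported string escape '\\{esc}'", line)
            out.append(_STRING_ESCAPES[esc])
        else:
            out.append(ch)
        i += 1
    return "".join(out)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    line = 1
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise TurtleParseError(f"unexpected character {text[pos]!r}", line)
        kind = m.lastgroup
        assert kind is not None
        if kind == "NL":
            line += 1
        elif kind not in ("WS", "COMMENT"):
            tokens.append((kind, m.group(), line))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, text: str) -> None:
        self.tokens = _tokenize(text)
        self.pos = 0
        self.graph = Graph()

    # -- token helpers ---------------------------------------------------
    def _peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def _next(self):
        tok = self._peek()
        if tok is None:
            last_line = self.tokens[-1][2] if self.tokens else 1
            raise TurtleParseError("unexpected end of input", last_line)
        self.pos += 1
        return tok

    def _expect(self, kind: str, text: str | None = None):
        tok = self._next()
        if tok[0] != kind or (text is not None and tok[1] != text):
            raise TurtleParseError(f"expected {text or kind}, found {tok[1]!r}", tok[2])
        return tok

    # -- grammar ---------------------------------------------------------
    def parse(self) -> Graph:
        while self._peek() is not None:
            if self._peek()[0] == "PREFIXDECL":
                self._prefix_decl()
            else:
                self._statement()
        return self.graph

    def _prefix_decl(self) -> None:
        self._expect("PREFIXDECL")
        kind, text, line = self._next()
        if kind != "PNAME" or not text.endswith(":") or text.count(":") != 1:
            raise TurtleParseError(f"expected prefix name, found {text!r}", line)
        prefix = text[:-1]
        _, iri, _ = self._expect("IRIREF")
        self.graph.bind(prefix, iri[1:-1])
        self._expect("PUNCT", ".")

    def _statement(self) -> None:
        subject = self._resource()
        while True:
            predicate = self._predicate()
            while True:
                obj = self._object()
                self.graph.add(subject, predicate, obj)
                if self._peek() and self._peek()[:2] == ("PUNCT", ","):
                    self._next()
                    continue
                break
            tok = self._next()
            if tok[:2] == ("PUNCT", ";"):
                # tolerate a trailing ';' before the closing '.'
                if self._peek() and self._peek()[:2] == ("PUNCT", "."):
                    self._next()
                    return
                continue
            if tok[:2] == ("PUNCT", "."):
                return
            raise TurtleParseError(f"expected ';' or '.', found {tok[1]!r}", tok[2])

    def _resource(self) -> IRI:
        kind, text, line = self._next()
        if kind == "IRIREF":
            return IRI(text[1:-1])
        if kind == "PNAME":
            return self._resolve_pname(text, line)
        if kind == "PUNCT" and text == "[":
            raise TurtleParseError("blank nodes are not supported", line)
        raise TurtleParseError(f"expected an IRI, found {text!r}", line)

    def _predicate(self) -> IRI:
        if self._peek() and self._peek()[0] == "A":
            self._next()
            return IRI(RDF_TYPE)
        return self._resource()

    def _object(self) -> Term:
        kind, text, line = self._next()
        if kind == "IRIREF":
            return IRI(text[1:-1])
        if kind == "PNAME":
            return self._resolve_pname(text, line)
        if kind == "STRING":
            value = _unescape(text[1:-1], line)
            if self._peek() and self._peek()[0] == "DTYPE":
                self._next()
                dtype = self._resource()
                return _typed_literal(value, dtype, line)
            return Literal(value)
        if kind == "INTEGER":
            return Literal(int(text))
        if kind in ("DECIMAL", "DOUBLE"):
            return Literal(float(text))
        if kind == "BOOLEAN":
            return Literal(text == "true")
        if kind == "PUNCT" and text in "[(":
            raise TurtleParseError("blank nodes / collections are not supported", line)
        raise TurtleParseError(f"expected an object term, found {text!r}", line)

    def _resolve_pname(self, text: str, line: int) -> IRI:
        prefix, _, local = text.partition(":")
        if prefix not in self.graph.namespaces:
            raise TurtleParseError(f"undeclared prefix '{prefix}:'", line)
        return IRI(self.graph.namespaces[prefix] + local)


def _typed_literal(value: str, dtype: IRI, line: int) -> Literal:
    name = dtype.value
    try:
        if name == XSD + "integer":
            return Literal(int(value))
        if name in (XSD + "decimal", XSD + "double", XSD + "float"):
            return Literal(float(value))
        if name == XSD + "boolean":
            return Literal(value == "true")
    except ValueError:
        raise TurtleParseError(f"malformed {name.split('#')[-1]} literal {value!r}", line)
    return Literal(value)  # unknown datatypes kept as strings


def parse_turtle(text: str) -> Graph:
    """Parse a Turtle document (the supported subset) into a :class:`Graph`."""
    return _Parser(text).parse()


# ---------------------------------------------------------------------------
# Turtle serializer
# ---------------------------------------------------------------------------

_LOCAL_RE = re.compile(r"^\w(?:[\w.-]*[\w-])?$|^$")


def _qname(iri: IRI, namespaces: dict[str, str]) -> str | None:
    for prefix, ns in sorted(namespaces.items()):
        if iri.value.startswith(ns):
            local = iri.value[len(ns):]
            if _LOCAL_RE.match(local):
                return f"{prefix}:{local}"
    return None


def _term_text(term: Term, namespaces: dict[str, str]) -> str:
    if isinstance(term, IRI):
        if term.value == RDF_TYPE:
            return "a"
        return _qname(term, namespaces) or f"<{term.value}>"
    v = term.value
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, int):
        return str(v)
    if isinstance(v, float):
        text = repr(v)
        return text if ("." in text or "e" in text or "E" in text) else text + ".0"
    escaped = v.replace("\\", "\\\\").replace('"', '\\"')
    escaped = escaped.replace("\n", "\\n").replace("\r", "\\r").replace("\t", "\\t")
    return f'"{escaped}"'


def serialize_turtle(graph: Graph) -> str:
    """Serialize deterministically: prefixes, then subjects/predicates sorted."""
    lines = [f"@prefix {p}: <{ns}> ." for p, ns in sorted(graph.namespaces.items())]
    by_subject: dict[str, dict[str, list[str]]] = {}
    for s, p, o in graph.triples():
        stext = _term_text(s, graph.namespaces)
        ptext = _term_text(p, graph.namespaces)
        by_subject.setdefault(stext, {}).setdefault(ptext, []).append(
            _term_text(o, graph.namespaces)
        )
    for stext in sorted(by_subject):
        lines.append("")
        preds = by_subject[stext]
        # 'a' (rdf:type) first, the rest alphabetical
        keys = sorted(preds, key=lambda k: (k != "a", k))
        body = [f"    {ptext} {', '.join(sorted(preds[ptext]))}" for ptext in keys]
        lines.append(stext + " " + (" ;\n".join(body)).lstrip() + " .")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# BGP query engine
# ---------------------------------------------------------------------------

_FILTER_RE = re.compile(
    r'^FILTER\s*\(\s*LCASE\s*\(\s*STR\s*\(\s*\?(\w+)\s*\)\s*\)\s*=\s*"((?:[^"\\]|\\.)*)"\s*\)$',
    re.I,
)


@dataclass(frozen=True)
class Query:
    select: tuple[str, ...]  # empty tuple means SELECT *
    patterns: tuple[tuple[object, object, object], ...]
    filters: tuple[tuple[str, str], ...]  # (variable, normalized value)


def normalize_name(name: str) -> str:
    """Whitespace-normalize and casefold a drug/endpoint/event name."""
    return " ".join(name.split()).casefold()


def escape_string(value: str) -> str:
    """Escape a value for substitution inside a double-quoted query string."""
    return value.replace("\\", "\\\\").replace('"', '\\"')


def parse_query(text: str) -> Query:
    """Parse a query template: PREFIX lines, SELECT, a `{ }` block of triple
    patterns, and LCASE equality FILTERs."""
    prefixes: dict[str, str] = {}
    select: list[str] = []
    patterns: list[tuple[object, object, object]] = []
    filters: list[tuple[str, str]] = []
    in_where = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        upper = line.upper()
        if upper.startswith("PREFIX"):
            m = re.match(r"PREFIX\s+(\w*):\s*<([^>]*)>", line, re.I)
            if not m:
                raise TurtleParseError("malformed PREFIX line", lineno)
            prefixes[m.group(1)] = m.group(2)
        elif upper.startswith("SELECT"):
            select = re.findall(r"\?(\w+)", line)
        elif upper.startswith("WHERE") or line == "{":
            in_where = True
        elif line == "}":
            in_where = False
        elif upper.startswith("FILTER"):
            m = _FILTER_RE.match(line)
            if not m:
                raise TurtleParseError("unsupported FILTER expression", lineno)
            filters.append((m.group(1), normalize_name(m.group(2).replace('\\"', '"'))))
        elif in_where:
            stmt = line.rstrip(".").strip()
            parts = stmt.split(None, 2)
            if len(parts) != 3:
                raise TurtleParseError(f"malformed triple pattern {line!r}", lineno)
            patterns.append(tuple(_query_term(p, prefixes, lineno) for p in parts))
        else:
            raise TurtleParseError(f"unexpected line {line!r}", lineno)
    return Query(tuple(select), tuple(patterns), tuple(filters))


def _query_term(text: str, prefixes: dict[str, str], lineno: int):
    if text.startswith("?"):
        return Var(text[1:])
    if text == "a":
        return IRI(RDF_TYPE)
    if text.startswith("<") and text.endswith(">"):
        return IRI(text[1:-1])
    if text.startswith('"') and text.endswith('"'):
        return Literal(_unescape(text[1:-1], lineno))
    if ":" in text:
        prefix, _, local = text.partition(":")
        if prefix not in prefixes:
            raise TurtleParseError(f"undeclared prefix '{prefix}:'", lineno)
        return IRI(prefixes[prefix] + local)
    raise TurtleParseError(f"unsupported query term {text!r}", lineno)


def _term_string(term: Term) -> str:
    if isinstance(term, IRI):
        return term.value
    return str(term.value)


def _solve(
    patterns: tuple, graph: Graph, binding: dict[str, Term]
) -> Iterator[dict[str, Term]]:
    if not patterns:
        yield binding
        return
    spec = [binding.get(t.name) if isinstance(t, Var) else t for t in patterns[0]]
    for triple in graph.triples(
        spec[0] if isinstance(spec[0], IRI) else None,
        spec[1] if isinstance(spec[1], IRI) else None,
        spec[2] if spec[2] is not None else None,
    ):
        new = dict(binding)
        ok = True
        for term, actual in zip(patterns[0], triple):
            if isinstance(term, Var):
                if term.name in new and new[term.name] != actual:
                    ok = False
                    break
                new[term.name] = actual
        if ok:
            yield from _solve(patterns[1:], graph, new)


def run_query(
    graph: Graph, query_text: str, params: dict[str, str] | None = None
) -> list[dict[str, Term]]:
    """Evaluate a query template against a graph.

    ``params`` are substituted into ``{placeholder}`` slots of the template
    (values are escaped and normalized, since placeholders sit inside
    LCASE-comparison FILTER strings). Returns one dict per solution, projected
    onto the SELECT variables, deduplicated, in a deterministic order.
    """
    if params:
        try:
            query_text = query_text.format(
                **{k: escape_string(normalize_name(v)) for k, v in params.items()}
            )
        except (KeyError, IndexError) as exc:
            raise UsageError(f"unresolved query placeholder: {exc}") from exc
    query = parse_query(query_text)
    results: list[dict[str, Term]] = []
    seen: set[tuple] = set()
    for solution in _solve(query.patterns, graph, {}):
        if any(
            var not in solution or normalize_name(_term_string(solution[var])) != want
            for var, want in query.filters
        ):
            continue
        projected = (
            {v: solution[v] for v in query.select if v in solution}
            if query.select
            else solution
        )
        key = tuple(sorted((k, repr(v)) for k, v in projected.items()))
        if key not in seen:
            seen.add(key)
            results.append(projected)
    results.sort(key=lambda b: tuple(sorted((k, repr(v)) for k, v in b.items())))
    return results
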