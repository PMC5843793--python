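"""RDF triple emission and re-absorption for instantiated TEO graphs.

Instantiated patterns are published as RDF: one ``rdf:type`` triple per
node, ``rdfs:label`` triples for labels, and one triple per populated
property, with node ids following the event1/tInstant1/durat1
conventions.  Temporal relations between events serialize as direct
predicates (``event1 teo:before event2``); a relation qualified by
``hasApproximation`` or ``hasTemporalOffset`` uses standard RDF
reification so the qualifiers have a subject to hang on.

The per-instance variable placeholder (``*``) serializes as a typed
literal with the reserved datatype ``teo:Variable`` so it survives a
round trip; symbolic references such as ``date_of_CDE`` serialize as
reserved IRIs in the TEO namespace, not literals.

Output is deterministic: identical instances produce byte-identical
Turtle.  ``rdflib`` is used in the test suite as the independent parse
and isomorphism oracle for the emitted documents.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from typing import Iterable, NamedTuple, Sequence, Union

from .errors import GraphIntegrityError, TeoCdeError, VocabularyError
from .teo import (
    Duration,
    Granularity,
    Symbolic,
    TEMPORAL_RELATIONS,
    TEOEvent,
    TEOGraph,
    TemporalRelationStatement,
    TimeInstant,
    TimeInterval,
    TimePhase,
    Variable,
    VARIABLE,
)

__all__ = [
    "Ref",
    "Triple",
    "NamespaceConfig",
    "to_triples",
    "serialize",
    "from_triples",
    "to_rdflib",
    "isomorphic",
]


@dataclass(frozen=True)
class Ref:
    """A reference to another node in the same graph (vs a literal)."""

    node_id: str


#: Triple objects: node reference, class name (for rdf:type), literal,
#: variable placeholder, or symbolic IRI.
Object = Union[Ref, str, int, datetime, Variable, Symbolic, Granularity]


class Triple(NamedTuple):
    subject: str
    predicate: str
    object: Object


@dataclass(frozen=True)
class NamespaceConfig:
    """Namespace IRIs: TEO terms live under one configurable base (the
    placeholder default stands in for an official IRI, which the pattern
    tables never print); instance nodes under their own base."""

    teo: str = "http://example.org/teo#"
    instance: str = "http://example.org/cde-instance#"


DEFAULT_NAMESPACES = NamespaceConfig()

_CLASS_NAMES = {
    TEOEvent: "Event",
    TimeInstant: "TimeInstant",
    TimeInterval: "TimeInterval",
    TimePhase: "TimePhase",
    Duration: "Duration",
}

_KNOWN_CLASSES = {
    "Event",
    "TimeInstant",
    "TimeInterval",
    "TimePhase",
    "Duration",
    "TemporalRelationStatement",
}


def _node_property_triples(node, resolve) -> list[tuple[str, Object]]:
    """(predicate, object) pairs for a node's populated properties, in
    the canonical field order of the pattern tables."""
    out: list[tuple[str, Object]] = []

    def put(pred: str, value) -> None:
        if value is None:
            return
        out.append((pred, value))

    if isinstance(node, TEOEvent):
        put("hasModality", node.modality)
        if node.valid_time is not None:
            out.append(("hasValidTime", resolve(node.valid_time)))
    elif isinstance(node, TimeInstant):
        put("hasGranularity", node.granularity)
        put("hasOrigTime", node.orig_time)
        put("hasNormalizedTime", node.normalized_time)
    elif isinstance(node, TimeInterval):  # covers TimePhase too
        if node.start is not None:
            out.append(("hasStartTime", resolve(node.start)))
        if node.end is not None:
            out.append(("hasEndTime", resolve(node.end)))
        if node.duration is not None:
            out.append(("hasDuration", resolve(node.duration)))
        if isinstance(node, TimePhase):
            put("hasRepeatTime", node.repeat_time)
            if node.repeat_unit is not None:
                out.append(("hasRepeatUnit", resolve(node.repeat_unit)))
            if node.repeat_unit_interval is not None:
                out.append(("hasRepeatUnitInterval", resolve(node.repeat_unit_interval)))
            if node.period is not None:
                out.append(("hasPeriod", resolve(node.period)))
    elif isinstance(node, Duration):
        put("hasDurationPattern", node.duration_pattern)
        put("hasValue", node.value)
        put("hasUnit", node.unit)
    return out


def to_triples(graph_or_instance) -> list[Triple]:
    """Flatten a TEO node graph (or a pattern instance) to ordered
    triples.

    Raises :class:`GraphIntegrityError` on an empty graph or when a node
    property references a node that was never added to the graph.
    """
    graph: TEOGraph = getattr(graph_or_instance, "graph", graph_or_instance)
    if len(graph) == 0:
        raise GraphIntegrityError("cannot serialize an empty node graph")
    ids = {id(n): n.node_id for n in graph.nodes}

    def resolve(node) -> Ref:
        node_id = ids.get(id(node))
        if node_id is None:
            raise GraphIntegrityError(
                f"dangling reference to a node outside the graph: {node!r}"
            )
        return Ref(node_id)

    triples: list[Triple] = []
    for node in graph.nodes:
        triples.append(Triple(node.node_id, "rdf:type", _CLASS_NAMES[type(node)]))
        if isinstance(node, TEOEvent) and node.event_type:
            triples.append(Triple(node.node_id, "rdf:type", str(node.event_type)))
        if node.label is not None:
            triples.append(Triple(node.node_id, "rdfs:label", node.label))
        for pred, obj in _node_property_triples(node, resolve):
            triples.append(Triple(node.node_id, pred, obj))
    n_reified = 0
    for stmt in graph.relations:
        subj, obj = resolve(stmt.subject), resolve(stmt.object)
        if not stmt.has_approximation and stmt.temporal_offset is None:
            triples.append(Triple(subj.node_id, stmt.relation, obj))
        else:
            n_reified += 1
            sid = f"trs{n_reified}"
            triples.append(Triple(sid, "rdf:type", "TemporalRelationStatement"))
            triples.append(Triple(sid, "rdf:subject", subj))
            triples.append(Triple(sid, "rdf:predicate", stmt.relation))
            triples.append(Triple(sid, "rdf:object", obj))
            if stmt.has_approximation:
                triples.append(Triple(sid, "hasApproximation", "true"))
            if stmt.temporal_offset is not None:
                triples.append(
                    Triple(sid, "hasTemporalOffset", resolve(stmt.temporal_offset))
                )
    return triples


# --------------------------------------------------------------------------
# Text serialization
# --------------------------------------------------------------------------

_RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
_RDFS_NS = "http://www.w3.org/2000/01/rdf-schema#"
_XSD_NS = "http://www.w3.org/2001/XMLSchema#"


def _escape(text: str) -> str:
    return (
        text.replace("\\", "\\\\")
        .replace('"', '\\"')
        .replace("\n", "\\n")
        .replace("\r", "\\r")
    )


def _term(value: Object, ns: NamespaceConfig, compact: bool):
    """Render one RDF term; ``compact`` chooses prefixed names (Turtle)
    over full IRIs (N-Triples)."""

    def iri(base_prefix: str, base_iri: str, local: str) -> str:
        return f"{base_prefix}:{local}" if compact else f"<{base_iri}{local}>"

    if isinstance(value, Ref):
        return iri("inst", ns.instance, value.node_id)
    if isinstance(value, Variable):
        dt = iri("teo", ns.teo, "Variable")
        return f'"*"^^{dt}'
    if isinstance(value, Symbolic):
        return iri("teo", ns.teo, value.name)
    if isinstance(value, Granularity):
        return f'"{value.value}"'
    if isinstance(value, datetime):
        dt = iri("xsd", _XSD_NS, "dateTime")
        return f'"{value.isoformat()}"^^{dt}'
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, int):
        return str(value)
    return f'"{_escape(str(value))}"'


def _predicate(pred: str, ns: NamespaceConfig, compact: bool) -> str:
    if pred.startswith("rdf:"):
        return pred if compact else f"<{_RDF_NS}{pred[4:]}>"
    if pred.startswith("rdfs:"):
        return pred if compact else f"<{_RDFS_NS}{pred[5:]}>"
    return f"teo:{pred}" if compact else f"<{ns.teo}{pred}>"


def _type_object(obj: Object, ns: NamespaceConfig, compact: bool) -> str:
    # rdf:type objects are class IRIs, not literals
    if isinstance(obj, str):
        return f"teo:{obj}" if compact else f"<{ns.teo}{obj}>"
    return _term(obj, ns, compact)


def serialize(
    triples: Sequence[Triple],
    format: str = "turtle",
    namespaces: NamespaceConfig = DEFAULT_NAMESPACES,
) -> str:
    """Serialize triples as Turtle or N-Triples text.

    Ordering is stable — subjects in first-appearance order, ``rdf:type``
    and ``rdfs:label`` first within a subject, remaining predicates in
    triple order — so identical instances give byte-identical output.
    """
    if format not in ("turtle", "ntriples"):
        raise TeoCdeError(f"unknown serialization format {format!r}")
    subject_order: list[str] = []
    grouped: dict[str, list[Triple]] = {}
    for t in triples:
        if t.subject not in grouped:
            grouped[t.subject] = []
            subject_order.append(t.subject)
        grouped[t.subject].append(t)

    def pred_rank(t: Triple) -> int:
        return {"rdf:type": 0, "rdfs:label": 1}.get(t.predicate, 2)

    ns = namespaces
    if format == "ntriples":
        lines = []
        for subject in subject_order:
            for t in sorted(grouped[subject], key=pred_rank):
                obj = (
                    _type_object(t.object, ns, False)
                    if t.predicate == "rdf:type"
                    else _term(t.object, ns, False)
                )
                lines.append(
                    f"<{ns.instance}{subject}> "
                    f"{_predicate(t.predicate, ns, False)} {obj} ."
                )
        return "\n".join(lines) + ("\n" if lines else "")

    lines = [
        f"@prefix rdf: <{_RDF_NS}> .",
        f"@prefix rdfs: <{_RDFS_NS}> .",
        f"@prefix xsd: <{_XSD_NS}> .",
        f"@prefix teo: <{ns.teo}> .",
        f"@prefix inst: <{ns.instance}> .",
        "",
    ]
    for subject in subject_order:
        parts = []
        for t in sorted(grouped[subject], key=pred_rank):
            obj = (
                _type_object(t.object, ns, True)
                if t.predicate == "rdf:type"
                else _term(t.object, ns, True)
            )
            parts.append(f"{_predicate(t.predicate, ns, True)} {obj}")
        body = " ;\n    ".join(parts)
        lines.append(f"inst:{subject} {body} .")
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# Re-absorption and isomorphism
# --------------------------------------------------------------------------

_VALUE_SETTERS = {
    "hasOrigTime": "orig_time",
    "hasNormalizedTime": "normalized_time",
    "hasModality": "modality",
    "hasDurationPattern": "duration_pattern",
}

_REF_SETTERS = {
    "hasValidTime": "valid_time",
    "hasStartTime": "start",
    "hasEndTime": "end",
    "hasDuration": "duration",
    "hasRepeatUnit": "repeat_unit",
    "hasRepeatUnitInterval": "repeat_unit_interval",
    "hasPeriod": "period",
}

_NODE_FACTORY = {
    "Event": TEOEvent,
    "TimeInstant": TimeInstant,
    "TimeInterval": TimeInterval,
    "TimePhase": TimePhase,
    "Duration": Duration,
}


def from_triples(triples: Iterable[Triple]) -> TEOGraph:
    """Rebuild a TEO node graph from triples produced under the
    :func:`to_triples` conventions (triple order is immaterial).

    A subject with no ``rdf:type`` raises :class:`GraphIntegrityError`.
    """
    triples = list(triples)
    subjects: list[str] = []
    by_subject: dict[str, list[Triple]] = {}
    referenced: set[str] = set()
    for t in triples:
        if t.subject not in by_subject:
            by_subject[t.subject] = []
            subjects.append(t.subject)
        by_subject[t.subject].append(t)
        if isinstance(t.object, Ref):
            referenced.add(t.object.node_id)

    # first pass: create typed nodes
    nodes: dict[str, object] = {}
    reified: list[str] = []
    for subject in subjects:
        types = [t.object for t in by_subject[subject] if t.predicate == "rdf:type"]
        if not types:
            raise GraphIntegrityError(f"node {subject!r} has no rdf:type")
        main = [str(x) for x in types if str(x) in _KNOWN_CLASSES]
        extra = [str(x) for x in types if str(x) not in _KNOWN_CLASSES]
        if not main:
            raise VocabularyError(f"node {subject!r} has no known TEO class")
        cls = main[0]
        if cls == "TemporalRelationStatement":
            reified.append(subject)
            continue
        node = _NODE_FACTORY[cls]()
        node.node_id = subject
        if extra and isinstance(node, TEOEvent):
            node.event_type = extra[0]
        nodes[subject] = node
    dangling = referenced - set(by_subject)
    if dangling:
        raise GraphIntegrityError(f"references to untyped nodes: {sorted(dangling)}")

    graph = TEOGraph()
    for subject in subjects:
        if subject in nodes:
            graph.add(nodes[subject])

    # second pass: fill properties and relations
    for subject in subjects:
        if subject in reified:
            continue
        node = nodes[subject]
        for t in by_subject[subject]:
            pred, obj = t.predicate, t.object
            if pred == "rdf:type":
                continue
            if pred == "rdfs:label":
                node.label = obj
            elif pred in _REF_SETTERS:
                setattr(node, _REF_SETTERS[pred], nodes[obj.node_id])
            elif pred in _VALUE_SETTERS:
                setattr(node, _VALUE_SETTERS[pred], obj)
            elif pred == "hasGranularity":
                node.granularity = Granularity(obj) if isinstance(obj, str) else obj
            elif pred == "hasValue":
                node.value = int(obj) if isinstance(obj, str) and obj.isdigit() else obj
            elif pred == "hasUnit":
                node.unit = Granularity(obj) if isinstance(obj, str) else obj
            elif pred == "hasRepeatTime":
                node.repeat_time = int(obj) if isinstance(obj, (int, str)) else obj
            elif pred in TEMPORAL_RELATIONS:
                graph.add_relation(
                    TemporalRelationStatement(node, pred, nodes[obj.node_id])
                )
            else:
                raise VocabularyError(f"unknown predicate {pred!r}")

    for subject in reified:
        fields = {t.predicate: t.object for t in by_subject[subject]}
        graph.add_relation(
            TemporalRelationStatement(
                subject=nodes[fields["rdf:subject"].node_id],
                relation=str(fields["rdf:predicate"]),
                object=nodes[fields["rdf:object"].node_id],
                has_approximation=str(fields.get("hasApproximation", "")) == "true",
                temporal_offset=(
                    nodes[fields["hasTemporalOffset"].node_id]
                    if "hasTemporalOffset" in fields
                    else None
                ),
            )
        )
    return graph


def to_rdflib(
    source, namespaces: NamespaceConfig = DEFAULT_NAMESPACES, blank_nodes: bool = True
):
    """Convert triples (or a graph/instance) to an ``rdflib.Graph``.

    With ``blank_nodes=True`` instance nodes become blank nodes, so two
    graphs differing only in node ids compare isomorphic under
    ``rdflib.compare``.
    """
    import rdflib
    from rdflib import BNode, Literal, URIRef

    triples = source if isinstance(source, list) else to_triples(source)
    g = rdflib.Graph()
    bnodes: dict[str, "BNode"] = {}

    def node_term(node_id: str):
        if blank_nodes:
            return bnodes.setdefault(node_id, BNode())
        return URIRef(namespaces.instance + node_id)

    def obj_term(t: Triple):
        obj = t.object
        if t.predicate == "rdf:type" and isinstance(obj, str):
            return URIRef(namespaces.teo + obj)
        if isinstance(obj, Ref):
            return node_term(obj.node_id)
        if isinstance(obj, Variable):
            return Literal("*", datatype=URIRef(namespaces.teo + "Variable"))
        if isinstance(obj, Symbolic):
            return URIRef(namespaces.teo + obj.name)
        if isinstance(obj, Granularity):
            return Literal(obj.value)
        return Literal(obj)

    def pred_term(pred: str):
        if pred.startswith("rdf:"):
            return URIRef(_RDF_NS + pred[4:])
        if pred.startswith("rdfs:"):
            return URIRef(_RDFS_NS + pred[5:])
        return URIRef(namespaces.teo + pred)

    for t in triples:
        g.add((node_term(t.subject), pred_term(t.predicate), obj_term(t)))
    return g


def isomorphic(a, b, namespaces: NamespaceConfig = DEFAULT_NAMESPACES) -> bool:
    """True when two graphs/instances/triple lists are isomorphic up to
    node renaming (checked with ``rdflib.compare``)."""
    from rdflib.compare import isomorphic as rdflib_isomorphic

    return rdflib_isomorphic(
        to_rdflib(a, namespaces), to_rdflib(b, namespaces)
    )
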