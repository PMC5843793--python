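"""TEO pattern templates: grammar, registry, and instantiation.

A pattern string describes how a CDE's temporal content maps onto a TEO
node graph.  Bracketed class nodes carry parenthesized property lists,
recursively::

    [Event (hasValidTime=[TimeInstant (hasGranularity, hasOrigTime*)])]

A trailing ``*`` marks a slot (or a node's label) as *variable* — filled
per data instance — while unasterisked slots are static information
fixed by the CDE definition itself.  Whitespace-separated top-level
bracket groups form an ordered node sequence; a ``[TemporalRelation]``
node between two events relates them (``[Event*] [TemporalRelation]
[Event]``).

Instantiation binds slots by dotted paths over template node order
(``node1.hasValidTime.hasOrigTime``), producing a :class:`~teocde.teo.TEOGraph`
whose node ids follow the event1/tInstant1/durat1 conventions.
"""

from __future__ import annotations

import re
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .cadsr import CDERecord, PATTERN_CATEGORIES
from .errors import (
    BindingError,
    IncompleteBindingError,
    PatternSyntaxError,
    VocabularyError,
)
from .stats import round_half_up
from .teo import (
    DATE_OF_CDE,
    VARIABLE,
    Duration,
    Granularity,
    Symbolic,
    TEOEvent,
    TEOGraph,
    TemporalRelationStatement,
    TimeInstant,
    TimeInterval,
    TimePhase,
    Variable,
    check_relation,
)

__all__ = [
    "PatternTemplate",
    "PatternInstance",
    "TemplateNode",
    "TemplateSlot",
    "parse_pattern_string",
    "render_pattern",
    "builtin_templates",
    "BUILTIN_PATTERNS",
    "load_templates",
    "instantiate",
    "pattern_frequency",
    "candidate_templates",
    "slot_paths",
    "required_slots",
]

CLASS_VOCAB = frozenset(
    {"Event", "TimeInstant", "TimeInterval", "TimePhase", "Duration", "TemporalRelation"}
)

#: Properties whose slot value is a nested node.
NODE_PROPERTIES = frozenset(
    {
        "hasValidTime",
        "hasStartTime",
        "hasEndTime",
        "hasDuration",
        "hasPeriod",
        "hasRepeatUnit",
        "hasRepeatUnitInterval",
        "hasTemporalOffset",
    }
)

#: Properties whose slot value is a literal (or variable/symbolic).
VALUE_PROPERTIES = frozenset(
    {
        "hasDurationPattern",
        "hasValue",
        "hasUnit",
        "hasGranularity",
        "hasOrigTime",
        "hasNormalizedTime",
        "hasModality",
        "hasRepeatTime",
    }
)

PROPERTY_VOCAB = NODE_PROPERTIES | VALUE_PROPERTIES

#: Which properties each class accepts.
_CLASS_PROPERTIES = {
    "Event": {"hasValidTime", "hasModality"},
    "TimeInstant": {"hasOrigTime", "hasNormalizedTime", "hasGranularity"},
    "TimeInterval": {"hasStartTime", "hasEndTime", "hasDuration"},
    "TimePhase": {
        "hasStartTime",
        "hasEndTime",
        "hasDuration",
        "hasPeriod",
        "hasRepeatUnit",
        "hasRepeatUnitInterval",
        "hasRepeatTime",
    },
    "Duration": {"hasDurationPattern", "hasValue", "hasUnit"},
    "TemporalRelation": set(),
}


@dataclass(frozen=True)
class TemplateSlot:
    """One property slot: a value slot (child is None) or a nested node."""

    name: str
    variable: bool = False
    child: Optional["TemplateNode"] = None


@dataclass(frozen=True)
class TemplateNode:
    """One bracketed class node with its ordered slots."""

    cls: str
    variable: bool = False
    slots: tuple[TemplateSlot, ...] = ()


@dataclass(frozen=True)
class PatternTemplate:
    """A parsed pattern: id, original source string, canonical tree."""

    template_id: str
    source: str
    nodes: tuple[TemplateNode, ...]

    def render(self) -> str:
        return render_pattern(self.nodes)


# --------------------------------------------------------------------------
# Parsing and rendering
# --------------------------------------------------------------------------

_NAME = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def error(self, msg: str) -> PatternSyntaxError:
        return PatternSyntaxError(msg, self.pos)

    def skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def expect(self, ch: str) -> None:
        if self.pos >= len(self.text) or self.text[self.pos] != ch:
            found = self.text[self.pos] if self.pos < len(self.text) else "end of input"
            raise self.error(f"expected {ch!r}, found {found!r}")
        self.pos += 1

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def name(self) -> str:
        m = _NAME.match(self.text, self.pos)
        if not m:
            raise self.error("expected a name")
        self.pos = m.end()
        return m.group(0)

    def star(self) -> bool:
        if self.peek() == "*":
            self.pos += 1
            return True
        return False

    def node(self) -> TemplateNode:
        self.expect("[")
        self.skip_ws()
        cls = self.name()
        if cls not in CLASS_VOCAB:
            raise self.error(f"unknown TEO class {cls!r}")
        variable = self.star()
        self.skip_ws()
        slots: tuple[TemplateSlot, ...] = ()
        if self.peek() == "(":
            slots = self.slot_list(cls)
        self.skip_ws()
        self.expect("]")
        return TemplateNode(cls=cls, variable=variable, slots=slots)

    def slot_list(self, cls: str) -> tuple[TemplateSlot, ...]:
        self.expect("(")
        slots = []
        while True:
            self.skip_ws()
            prop = self.name()
            if prop not in PROPERTY_VOCAB:
                raise self.error(f"unknown TEO property {prop!r}")
            if prop not in _CLASS_PROPERTIES[cls]:
                raise self.error(f"property {prop!r} not valid on class {cls!r}")
            variable = self.star()
            child = None
            self.skip_ws()
            if self.peek() == "=":
                self.pos += 1
                self.skip_ws()
                child = self.node()
            if child is not None and prop not in NODE_PROPERTIES:
                raise self.error(f"value property {prop!r} cannot take a nested node")
            if child is None and prop in NODE_PROPERTIES:
                raise self.error(f"object property {prop!r} requires a nested node")
            slots.append(TemplateSlot(name=prop, variable=variable, child=child))
            self.skip_ws()
            if self.peek() == ",":
                self.pos += 1
                continue
            break
        self.expect(")")
        return tuple(slots)


def parse_pattern_string(s: str, template_id: str = "") -> PatternTemplate:
    """Parse a pattern string into its canonical template tree.

    Errors carry the character offset; unknown class/property names raise
    with the offending token.
    """
    if not s or not s.strip():
        raise PatternSyntaxError("empty pattern string")
    p = _Parser(s)
    nodes = []
    while True:
        p.skip_ws()
        if p.pos >= len(s):
            break
        nodes.append(p.node())
    if not nodes:
        raise PatternSyntaxError("pattern contains no nodes")
    _check_sequence(nodes)
    return PatternTemplate(template_id=template_id, source=s, nodes=tuple(nodes))


def _check_sequence(nodes: Sequence[TemplateNode]) -> None:
    # relation nodes must sit between two non-relation nodes
    for i, node in enumerate(nodes):
        if node.cls == "TemporalRelation":
            if i == 0 or i == len(nodes) - 1:
                raise PatternSyntaxError(
                    "a TemporalRelation node needs a node on each side"
                )
            if nodes[i - 1].cls == "TemporalRelation" or nodes[i + 1].cls == "TemporalRelation":
                raise PatternSyntaxError("adjacent TemporalRelation nodes")


def render_pattern(nodes: Sequence[TemplateNode]) -> str:
    """Canonical rendering: space after the class name before ``(``,
    ``", "`` between slots, no spaces around ``=``."""

    def render_node(n: TemplateNode) -> str:
        head = n.cls + ("*" if n.variable else "")
        if not n.slots:
            return f"[{head}]"
        slots = ", ".join(render_slot(s) for s in n.slots)
        return f"[{head} ({slots})]"

    def render_slot(s: TemplateSlot) -> str:
        out = s.name + ("*" if s.variable else "")
        if s.child is not None:
            out += "=" + render_node(s.child)
        return out

    return " ".join(render_node(n) for n in nodes)


# --------------------------------------------------------------------------
# Built-in registry: the ten most frequently used patterns
# --------------------------------------------------------------------------

#: The ten most frequently used pattern strings, ids in rank order.
BUILTIN_PATTERNS: tuple[str, ...] = (
    "[Event (hasValidTime=[TimeInstant (hasGranularity, hasOrigTime*)])]",
    "[Event* (hasValidTime=[TimeInterval (hasEndTime=[TimeInstant (hasOrigTime)],"
    " hasDuration=[Duration (hasDurationPattern)])])]",
    "[Event (hasValidTime=[TimeInstant (hasNormalizedTime*)])]",
    "[Event*] [TemporalRelation] [Event]",
    "[Event (hasModality*)] [TemporalRelation] [Event]",
    "[Event (hasValidTime=[TimeInterval (hasEndTime=[TimeInstant"
    " (hasGranularity,hasOrigTime*)])])]",
    "[Event (hasValidTime=[TimeInterval (hasStartTime=[TimeInstant"
    " (hasGranularity,hasOrigTime*)])])]",
    "[Event* (hasModality*,hasValidTime=[TimeInterval(hasEndTime=[TimeInstant"
    "(hasOrigTime)],hasDuration=[Duration(hasValue,hasUnit)])])]",
    "[Event (hasValidTime=[TimeInterval(hasDuration=[Duration(hasDurationPattern*)])])]",
    "[Event(hasValidTime=[TimeInterval(hasStartTime=[TimeInstant(hasOrigTime*)],"
    "hasEndTime=[TimeInstant(hasOrigTime*)])])]",
)


def builtin_templates() -> dict[str, PatternTemplate]:
    """The built-in registry: P1..P10 in rank order."""
    return {
        f"P{i}": parse_pattern_string(src, template_id=f"P{i}")
        for i, src in enumerate(BUILTIN_PATTERNS, start=1)
    }


def load_templates(source) -> dict[str, PatternTemplate]:
    """Load a template registry file: ``template_id<TAB>pattern string``
    per line.  New annotator-defined templates use the same grammar."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    registry = {}
    for line in text.splitlines():
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        template_id, _, pattern = line.partition("\t")
        template_id = template_id.strip()
        if not pattern.strip():
            raise PatternSyntaxError(f"template {template_id!r}: missing pattern")
        registry[template_id] = parse_pattern_string(pattern.strip(), template_id)
    return registry


# --------------------------------------------------------------------------
# Instantiation
# --------------------------------------------------------------------------


def _coerce(value):
    """Map the textual placeholder conventions onto sentinel objects."""
    if isinstance(value, str):
        if value == "*":
            return VARIABLE
        if value == "date_of_CDE":
            return DATE_OF_CDE
    return value


@dataclass
class PatternInstance:
    """A template applied to one CDE: resolved bindings plus the
    instantiated TEO node graph."""

    template_id: str
    cde_public_id: str
    bindings: dict[str, object]
    graph: TEOGraph
    roots: list = field(default_factory=list)


def instantiate(
    template: PatternTemplate,
    cde: CDERecord | None,
    bindings: Mapping[str, object] | None = None,
) -> PatternInstance:
    """Instantiate a template against a CDE with slot bindings.

    Binding keys are dotted slot paths rooted at ``node1``..``nodeN``
    (template node order) descending by property name, e.g.
    ``node1.hasValidTime.hasOrigTime``; ``.label`` and ``.event_type``
    address a node's label and event subclass, and ``relation`` (or
    ``nodeI.relation``) names the concrete temporal relation of a
    ``[TemporalRelation]`` node.  Unasterisked (static) slots must be
    bound — explicitly to ``"*"`` if genuinely unfilled — while
    asterisked slots default to the variable placeholder.  Unknown keys
    raise :class:`BindingError`; unbound static slots raise
    :class:`IncompleteBindingError`.
    """
    bindings = {k: _coerce(v) for k, v in (bindings or {}).items()}
    valid_paths: set[str] = set()
    required: dict[str, str] = {}  # path -> description
    graph = TEOGraph()
    relation_paths = [
        f"node{i + 1}.relation"
        for i, n in enumerate(template.nodes)
        if n.cls == "TemporalRelation"
    ]
    single_relation = len(relation_paths) == 1

    def lookup(path: str):
        if path in bindings:
            return bindings[path]
        if single_relation and path == relation_paths[0] and "relation" in bindings:
            return bindings["relation"]
        return None

    def build(node: TemplateNode, path: str):
        obj = _make_node(node)
        graph.add(obj)
        # label handling: Event labels are part of the pattern contract
        valid_paths.add(f"{path}.label")
        label = lookup(f"{path}.label")
        if node.cls == "Event":
            valid_paths.add(f"{path}.event_type")
            obj.event_type = lookup(f"{path}.event_type")
            if node.variable:
                obj.label = label if label is not None else VARIABLE
            else:
                required[f"{path}.label"] = "static Event label"
                obj.label = label
        elif label is not None:
            obj.label = label
        for slot in node.slots:
            spath = f"{path}.{slot.name}"
            if slot.child is not None:
                child_obj = build(slot.child, spath)
                _attach(obj, slot.name, child_obj)
            else:
                valid_paths.add(spath)
                value = lookup(spath)
                if not slot.variable and value is None:
                    required[spath] = f"static slot {slot.name}"
                if value is None and slot.variable:
                    value = VARIABLE
                _set_value(obj, slot.name, value)
        return obj

    instances = []
    for i, node in enumerate(template.nodes):
        path = f"node{i + 1}"
        if node.cls == "TemporalRelation":
            valid_paths.add(f"{path}.relation")
            required[f"{path}.relation"] = "temporal relation name"
            instances.append(("relation", path, node))
        else:
            instances.append(("node", path, build(node, path)))

    # wire relation statements between the flanking nodes
    relations = []
    for i, (kind, path, payload) in enumerate(instances):
        if kind != "relation":
            continue
        rel_name = lookup(f"{path}.relation")
        if rel_name is not None:
            check_relation(str(rel_name))
            subject = instances[i - 1][2]
            obj = instances[i + 1][2]
            relations.append(TemporalRelationStatement(subject, str(rel_name), obj))

    missing = [p for p in required if lookup(p) is None]
    if missing:
        raise IncompleteBindingError(
            f"unbound static slots: {', '.join(sorted(missing))}"
        )
    unknown = set(bindings) - valid_paths
    if single_relation:
        unknown -= {"relation"}
    if unknown:
        raise BindingError(f"unknown binding paths: {', '.join(sorted(unknown))}")

    for stmt in relations:
        graph.add_relation(stmt)
    return PatternInstance(
        template_id=template.template_id,
        cde_public_id=cde.public_id if cde is not None else "",
        bindings=dict(bindings),
        graph=graph,
        roots=[p for k, _, p in instances if k == "node"],
    )


def _make_node(node: TemplateNode):
    cls = {
        "Event": TEOEvent,
        "TimeInstant": TimeInstant,
        "TimeInterval": TimeInterval,
        "TimePhase": TimePhase,
        "Duration": Duration,
    }[node.cls]
    return cls()


_ATTACH_FIELD = {
    "hasValidTime": "valid_time",
    "hasStartTime": "start",
    "hasEndTime": "end",
    "hasDuration": "duration",
    "hasPeriod": "period",
    "hasRepeatUnit": "repeat_unit",
    "hasRepeatUnitInterval": "repeat_unit_interval",
}

_VALUE_FIELD = {
    "hasOrigTime": "orig_time",
    "hasNormalizedTime": "normalized_time",
    "hasGranularity": "granularity",
    "hasModality": "modality",
    "hasDurationPattern": "duration_pattern",
    "hasRepeatTime": "repeat_time",
}


def _attach(obj, prop: str, child) -> None:
    setattr(obj, _ATTACH_FIELD[prop], child)


def _set_value(obj, prop: str, value) -> None:
    if prop == "hasGranularity" and isinstance(value, str):
        value = Granularity(value.lower())
    if prop == "hasValue":
        if isinstance(value, str) and value.isdigit():
            value = int(value)
        obj.value = value
        return
    if prop == "hasUnit":
        obj.unit = Granularity(value.lower()) if isinstance(value, str) else value
        return
    setattr(obj, _VALUE_FIELD[prop], value)


def slot_paths(template: PatternTemplate) -> dict[str, bool]:
    """All bindable slot paths of a template, mapped to whether the slot
    is static (True = a binding is required; False = variable/optional).

    Paths follow the instantiation addressing: ``node1.hasValidTime.
    hasOrigTime``, ``node1.label``, ``node2.relation``, ...
    """
    out: dict[str, bool] = {}

    def walk(node: TemplateNode, path: str) -> None:
        out[f"{path}.label"] = node.cls == "Event" and not node.variable
        if node.cls == "Event":
            out[f"{path}.event_type"] = False
        for slot in node.slots:
            spath = f"{path}.{slot.name}"
            if slot.child is not None:
                walk(slot.child, spath)
            else:
                out[spath] = not slot.variable

    for i, node in enumerate(template.nodes):
        path = f"node{i + 1}"
        if node.cls == "TemporalRelation":
            out[f"{path}.relation"] = True
        else:
            walk(node, path)
    return out


def required_slots(template: PatternTemplate) -> list[str]:
    """The static slot paths a binding set must cover."""
    return [p for p, req in slot_paths(template).items() if req]


# --------------------------------------------------------------------------
# Frequency and candidate filtering
# --------------------------------------------------------------------------


def pattern_frequency(annotations: Iterable) -> list[tuple[str, float, float]]:
    """Rank patterns by how often annotators assigned them.

    Only pattern-bearing categories count.  With several annotators,
    counts are the arithmetic mean of the per-annotator counts; the
    percentage is count / total annotated, reported at one decimal.
    Returns (pattern_id, count, percentage) sorted by descending count.
    """
    per_annotator: dict[str, dict[str, int]] = {}
    for rec in annotations:
        if rec.category not in PATTERN_CATEGORIES:
            continue
        per_annotator.setdefault(rec.annotator_id, {})
        per_annotator[rec.annotator_id][rec.pattern_id] = (
            per_annotator[rec.annotator_id].get(rec.pattern_id, 0) + 1
        )
    if not per_annotator:
        return []
    pattern_ids = sorted({p for counts in per_annotator.values() for p in counts})
    averaged = {
        p: statistics.mean(counts.get(p, 0) for counts in per_annotator.values())
        for p in pattern_ids
    }
    total = sum(averaged.values())
    table = [
        (p, c, round_half_up(100.0 * c / total))
        for p, c in sorted(averaged.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return table


_BLOCK_CLASSES = {
    "TimeInstant": {"TimeInstant"},
    "TimeInterval": {"TimeInterval", "TimePhase"},
    "Date": {"TimeInstant"},
    "Granularity": {"TimeInstant", "Duration"},
    "Duration": {"Duration"},
    "TemporalRelation": {"TemporalRelation"},
    "TimeOffset": {"TemporalRelation"},
    "TimePhase": {"TimePhase"},
}


def _template_classes(template: PatternTemplate) -> set[str]:
    out: set[str] = set()

    def walk(node: TemplateNode) -> None:
        out.add(node.cls)
        for slot in node.slots:
            if slot.child is not None:
                walk(slot.child)

    for node in template.nodes:
        walk(node)
    return out


def candidate_templates(
    annotated_cde, registry: Mapping[str, PatternTemplate]
) -> list[str]:
    """Candidate filter for annotators: templates whose classes can host
    every building-block group of the CDE (each ambiguous group needs at
    least one alternative present).  This is a filter only — final
    pattern assignment stays manual."""
    candidates = []
    for template_id, template in registry.items():
        classes = _template_classes(template)
        ok = True
        for group in annotated_cde.building_blocks:
            alternatives = set()
            for block in group:
                alternatives |= _BLOCK_CLASSES[block.value]
            if not alternatives & classes:
                ok = False
                break
        if ok:
            candidates.append(template_id)
    return candidates
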