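"""Time Event Ontology (TEO) temporal data model.

TEO models time in clinical data with a small set of classes — ``Event``,
``TimeInstant``, ``TimeInterval``, ``TimePhase``, ``Duration``,
``Granularity`` and ``TemporalRelationStatement`` — connected by object
properties such as ``hasValidTime``, ``hasStartTime``/``hasEndTime``,
``hasDuration`` and the Allen-style temporal relations.  This module holds
those node types, the compact/verbose duration-pattern grammar
(``"5D10H"`` = five days and ten hours), time-literal normalization, and
the two inference contracts the ontology states:

* a time interval is inference-complete when two of {start, end, duration}
  are known, and the third follows by calendar arithmetic;
* a recurring time phase satisfies ``period = repeat_unit +
  repeat_unit_interval`` (the period is the duration of one recurrence
  plus the gap to the next), so any one of the three follows from the
  other two.

Months and years are calendar units with no fixed length; exact
arithmetic deliberately rejects them rather than approximating.
"""

from __future__ import annotations

import enum
import itertools
import re
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Optional, Sequence, Union

from .errors import (
    CommensurabilityError,
    DurationParseError,
    IncompleteIntervalError,
    InconsistentPhaseError,
    NormalizationError,
    OrderingError,
    VocabularyError,
)

__all__ = [
    "VARIABLE",
    "Variable",
    "Symbolic",
    "DATE_OF_CDE",
    "Granularity",
    "TEOEvent",
    "TimeInstant",
    "TimeInterval",
    "TimePhase",
    "Duration",
    "TemporalRelationStatement",
    "TEOGraph",
    "TEMPORAL_RELATIONS",
    "parse_duration_pattern",
    "format_duration",
    "complete_interval",
    "complete_timephase",
    "normalize_instant",
    "DEFAULT_DATE_FORMATS",
]


class Variable:
    """The per-instance placeholder (printed as ``*`` in pattern tables).

    A slot bound to :data:`VARIABLE` is present but takes its value per
    data instance, unlike an absent slot.  A single module-level instance
    is used; compare with ``is VARIABLE``.
    """

    _instance: "Variable | None" = None

    def __new__(cls) -> "Variable":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "*"


VARIABLE = Variable()


@dataclass(frozen=True)
class Symbolic:
    """A deferred symbolic reference, e.g. ``date_of_CDE`` (the date the
    data instance itself is recorded), distinct from both a literal value
    and the variable placeholder."""

    name: str

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<{self.name}>"


DATE_OF_CDE = Symbolic("date_of_CDE")

#: Slot values: a concrete literal, the variable placeholder, or a symbol.
SlotValue = Union[str, int, datetime, Variable, Symbolic]


class Granularity(enum.Enum):
    """Temporal unit resolution, second through year.

    second < minute < hour < day < week is a total order of fixed-length
    units; month and year are calendar units excluded from fixed-length
    conversion.
    """

    SECOND = "second"
    MINUTE = "minute"
    HOUR = "hour"
    DAY = "day"
    WEEK = "week"
    MONTH = "month"
    YEAR = "year"

    def __lt__(self, other: "Granularity") -> bool:
        return _GRAN_ORDER[self] < _GRAN_ORDER[other]

    def __le__(self, other: "Granularity") -> bool:
        return _GRAN_ORDER[self] <= _GRAN_ORDER[other]

    @property
    def seconds(self) -> int:
        """Length in seconds; raises for calendar units (month, year)."""
        try:
            return _FIXED_SECONDS[self]
        except KeyError:
            raise CommensurabilityError(
                f"{self.value} is a calendar unit with no fixed length"
            ) from None


_GRAN_ORDER = {g: i for i, g in enumerate(Granularity)}

_FIXED_SECONDS = {
    Granularity.SECOND: 1,
    Granularity.MINUTE: 60,
    Granularity.HOUR: 3600,
    Granularity.DAY: 86400,
    Granularity.WEEK: 604800,
}

#: Temporal relation vocabulary: the keyword-derived relations plus the
#: Allen interval-algebra extensions (inverses).  Unknown names are
#: rejected rather than passed through.
TEMPORAL_RELATIONS = frozenset(
    {
        "before",
        "after",
        "meets",
        "met_by",
        "overlaps",
        "overlapped_by",
        "starts",
        "started_by",
        "finishes",
        "finished_by",
        "during",
        "contains",
        "equals",
        "concurrent",
        "while",
        "within",
        "until",
        "when",
    }
)


def check_relation(name: str) -> str:
    if name not in TEMPORAL_RELATIONS:
        raise VocabularyError(f"unknown temporal relation {name!r}")
    return name


# --------------------------------------------------------------------------
# Node types
# --------------------------------------------------------------------------

_node_counter = itertools.count(1)


@dataclass
class _Node:
    node_id: Optional[str] = field(default=None, kw_only=True)
    label: Optional[SlotValue] = field(default=None, kw_only=True)


@dataclass
class TEOEvent(_Node):
    """Any occurrence.  ``event_type`` names an application-level subclass
    (e.g. Treatment); ``valid_time`` points at a Time node."""

    event_type: Optional[str] = None
    modality: Optional[SlotValue] = None
    valid_time: Optional["_Node"] = None


@dataclass
class TimeInstant(_Node):
    """A discrete time point, e.g. "28 APR 2017".

    ``orig_time`` keeps the surface form; ``normalized_time`` the parsed
    calendar timestamp; ``granularity`` its resolution.
    """

    orig_time: Optional[SlotValue] = None
    normalized_time: Optional[SlotValue] = None
    granularity: Optional[Union[Granularity, Variable]] = None


@dataclass
class Duration(_Node):
    """A span of time, written compactly ("5D10H"), as ordered
    (value, unit) component pairs, or as a single hasValue/hasUnit pair
    (either of which may still be a variable placeholder)."""

    duration_pattern: Optional[SlotValue] = None
    components: Optional[tuple[tuple[int, Granularity], ...]] = None
    value: Optional[SlotValue] = None
    unit: Optional[Union[Granularity, Variable]] = None

    def resolved_components(self) -> Optional[tuple[tuple[int, Granularity], ...]]:
        """Components, parsing ``duration_pattern`` or pairing
        value/unit when needed; None if only variable/symbolic
        placeholders are held."""
        if self.components is not None:
            return self.components
        if isinstance(self.duration_pattern, str):
            return tuple(parse_duration_pattern(self.duration_pattern))
        if isinstance(self.value, int) and isinstance(self.unit, Granularity):
            return ((self.value, self.unit),)
        return None


@dataclass
class TimeInterval(_Node):
    """A span anchored by start/end instants and/or a duration.

    Any subset of the three components may be stated; two concrete
    components make the interval inference-complete (see
    :func:`complete_interval`).
    """

    start: Optional[TimeInstant] = None
    end: Optional[TimeInstant] = None
    duration: Optional[Duration] = None


@dataclass
class TimePhase(TimeInterval):
    """A periodically recurring interval ("2 hours a day for 6 months").

    ``repeat_unit`` is the duration of one recurrence (or a nested
    phase), ``repeat_unit_interval`` the gap between recurrences, and
    ``period`` their sum; ``repeat_time`` counts recurrences.
    """

    repeat_time: Optional[int] = None
    repeat_unit: Optional[Union[Duration, "TimePhase"]] = None
    repeat_unit_interval: Optional[Duration] = None
    period: Optional[Duration] = None


@dataclass
class TemporalRelationStatement:
    """A qualified temporal relation between two nodes.

    ``has_approximation`` flags uncertainty ("may have started before");
    ``temporal_offset`` holds a Duration displacing the relation.
    """

    subject: _Node
    relation: str
    object: _Node
    has_approximation: bool = False
    temporal_offset: Optional[Duration] = None

    def __post_init__(self) -> None:
        check_relation(self.relation)
        if self.subject is self.object:
            raise VocabularyError("a temporal relation needs two distinct nodes")


class TEOGraph:
    """An ordered collection of TEO nodes plus relation statements.

    Node ids are assigned on insertion using per-class counters matching
    the conventions of the pattern tables (event1, tInstant1, tInterval1,
    tPhase1, durat1, ...).
    """

    _PREFIX = {
        TEOEvent: "event",
        TimeInstant: "tInstant",
        TimeInterval: "tInterval",
        TimePhase: "tPhase",
        Duration: "durat",
    }

    def __init__(self) -> None:
        self.nodes: list[_Node] = []
        self.relations: list[TemporalRelationStatement] = []
        self._counters: dict[str, int] = {}

    def add(self, node: _Node) -> _Node:
        if not any(n is node for n in self.nodes):
            if node.node_id is None:
                prefix = self._PREFIX[type(node)]
                self._counters[prefix] = self._counters.get(prefix, 0) + 1
                node.node_id = f"{prefix}{self._counters[prefix]}"
            self.nodes.append(node)
        return node

    def add_relation(self, stmt: TemporalRelationStatement) -> TemporalRelationStatement:
        self.relations.append(stmt)
        return stmt

    def __iter__(self):
        return iter(self.nodes)

    def __len__(self) -> int:
        return len(self.nodes)

    def node_by_id(self, node_id: str) -> _Node:
        for n in self.nodes:
            if n.node_id == node_id:
                return n
        raise KeyError(node_id)


# --------------------------------------------------------------------------
# Duration grammar
# --------------------------------------------------------------------------

# Compact grammar: (integer + unit letter)+ with Y, M (month!), W, D, H,
# Min, S.  "Min" must be tried before "M".
_COMPACT_TOKEN = re.compile(r"(\d+)\s*(Min|[YMWDHS])", re.IGNORECASE)
_COMPACT_UNIT = {
    "Y": Granularity.YEAR,
    "M": Granularity.MONTH,
    "W": Granularity.WEEK,
    "D": Granularity.DAY,
    "H": Granularity.HOUR,
    "MIN": Granularity.MINUTE,
    "S": Granularity.SECOND,
}
_COMPACT_LETTER = {
    Granularity.YEAR: "Y",
    Granularity.MONTH: "M",
    Granularity.WEEK: "W",
    Granularity.DAY: "D",
    Granularity.HOUR: "H",
    Granularity.MINUTE: "Min",
    Granularity.SECOND: "S",
}

_VERBOSE_TOKEN = re.compile(
    r"(\d+)\s+(second|minute|hour|day|week|month|year)s?", re.IGNORECASE
)
_VERBOSE_SEP = re.compile(r"^(?:\s|,|and\b)*", re.IGNORECASE)


def parse_duration_pattern(s: str) -> list[tuple[int, Granularity]]:
    """Parse a duration pattern into ordered (value, unit) pairs.

    Two dialects are accepted: the compact form ``"5D10H"`` (unit letters
    Y, M = month, W, D, H, Min = minute, S) and the verbose form
    ``"7 days"`` / ``"5 days 10 hours"`` with optional plural ``s``.

    >>> parse_duration_pattern("5D10H")
    [(5, <Granularity.DAY: 'day'>), (10, <Granularity.HOUR: 'hour'>)]
    """
    if not s or not s.strip():
        raise DurationParseError("empty duration pattern")
    text = s.strip()
    # verbose form requires whitespace between number and unit word
    token = _VERBOSE_TOKEN if re.match(r"\d+\s+[A-Za-z]", text) else _COMPACT_TOKEN
    unit_map = (
        {g.value.upper(): g for g in Granularity}
        if token is _VERBOSE_TOKEN
        else _COMPACT_UNIT
    )
    components: list[tuple[int, Granularity]] = []
    pos = 0
    while pos < len(text):
        pos += _VERBOSE_SEP.match(text[pos:]).end()
        if pos >= len(text):
            break
        m = token.match(text, pos)
        if m is None:
            raise DurationParseError(
                f"unknown unit token at {text[pos:]!r} in duration {s!r}"
            )
        value, unit = int(m.group(1)), unit_map[m.group(2).upper()]
        components.append((value, unit))
        pos = m.end()
    if not components:
        raise DurationParseError(f"no components in duration {s!r}")
    return components


def format_duration(components: Sequence[tuple[int, Granularity]]) -> str:
    """Render components in the canonical compact form (``[(1, DAY)]`` ->
    ``"1D"``); inverse of :func:`parse_duration_pattern` on compact
    strings."""
    if not components:
        raise DurationParseError("cannot format an empty component list")
    parts = []
    for value, unit in components:
        if value < 0:
            raise DurationParseError("duration values must be non-negative")
        parts.append(f"{value}{_COMPACT_LETTER[unit]}")
    return "".join(parts)


def _components_seconds(components: Sequence[tuple[int, Granularity]]) -> int:
    """Total seconds of exact-unit components; calendar units raise."""
    total = 0
    for value, unit in components:
        total += value * unit.seconds
    return total


def _decompose_seconds(
    seconds: int, finest: Granularity = Granularity.SECOND
) -> tuple[tuple[int, Granularity], ...]:
    """Greedy largest-unit-first decomposition of a second count into
    exact units no finer than ``finest``."""
    if seconds == 0:
        return ((0, finest if finest <= Granularity.DAY else Granularity.DAY),)
    out = []
    units = [g for g in (Granularity.WEEK, Granularity.DAY, Granularity.HOUR,
                         Granularity.MINUTE, Granularity.SECOND) if finest <= g]
    # do not promote whole days to weeks: day totals read more naturally
    # ("22 days", not "3W1D") and match how intervals are reported
    if seconds % 86400 == 0 and Granularity.DAY in units:
        return ((seconds // 86400, Granularity.DAY),)
    for unit in units:
        value, seconds = divmod(seconds, unit.seconds)
        if value:
            out.append((value, unit))
    if seconds:
        raise CommensurabilityError(
            "remainder finer than the requested finest granularity"
        )
    return tuple(out)


def _concrete_duration(d: Optional[Duration]) -> Optional[int]:
    """Seconds of a Duration node if concrete and exact-unit, else None.
    Calendar units raise CommensurabilityError."""
    if d is None or isinstance(d, TimePhase):
        return None
    comps = d.resolved_components()
    if comps is None:
        return None
    return _components_seconds(comps)


# --------------------------------------------------------------------------
# Interval and phase inference
# --------------------------------------------------------------------------


def _concrete_instant(i: Optional[TimeInstant]) -> Optional[datetime]:
    if i is None:
        return None
    if isinstance(i.normalized_time, datetime):
        return i.normalized_time
    return None


def complete_interval(interval: TimeInterval) -> TimeInterval:
    """Fill in the third of {start, end, duration} by calendar arithmetic.

    Requires exactly two concrete components: start/end with normalized
    calendar timestamps, duration in exact units (week and finer).  A
    fully specified interval is checked for consistency and returned
    unchanged.  Existing components are never modified.
    """
    start_dt = _concrete_instant(interval.start)
    end_dt = _concrete_instant(interval.end)
    dur_s = _concrete_duration(interval.duration)
    n_concrete = sum(x is not None for x in (start_dt, end_dt, dur_s))
    if start_dt is not None and end_dt is not None and start_dt > end_dt:
        raise OrderingError(f"start {start_dt} after end {end_dt}")
    if n_concrete < 2:
        raise IncompleteIntervalError(
            "interval inference needs two concrete components of "
            "{start, end, duration}"
        )
    if n_concrete == 3:
        if end_dt - start_dt != timedelta(seconds=dur_s):
            raise InconsistentPhaseError(
                "start, end and duration are mutually inconsistent"
            )
        return interval

    finest = _finest_granularity(interval)
    if dur_s is None:
        delta = end_dt - start_dt
        comps = _decompose_seconds(int(delta.total_seconds()), finest)
        return replace(interval, duration=Duration(
            duration_pattern=format_duration(comps), components=comps))
    if end_dt is None:
        new_end = start_dt + timedelta(seconds=dur_s)
        return replace(interval, end=TimeInstant(
            normalized_time=new_end, granularity=finest))
    new_start = end_dt - timedelta(seconds=dur_s)
    return replace(interval, start=TimeInstant(
        normalized_time=new_start, granularity=finest))


def _finest_granularity(interval: TimeInterval) -> Granularity:
    """Finest exact granularity among the interval's stated components,
    defaulting to day."""
    grans = []
    for inst in (interval.start, interval.end):
        if inst is not None and isinstance(inst.granularity, Granularity):
            grans.append(inst.granularity)
    if interval.duration is not None:
        comps = interval.duration.resolved_components()
        if comps:
            grans.extend(unit for _, unit in comps)
    exact = [g for g in grans if g <= Granularity.WEEK]
    return min(exact, key=lambda g: _GRAN_ORDER[g]) if exact else Granularity.DAY


def complete_timephase(phase: TimePhase) -> TimePhase:
    """Enforce ``period = repeat_unit + repeat_unit_interval`` on a
    recurring phase, inferring whichever of the three is missing.

    All three durations must be commensurable (exact units); with all
    three present the equation is verified and the phase returned
    unchanged.
    """
    unit_s = _concrete_duration(
        phase.repeat_unit if isinstance(phase.repeat_unit, Duration) else None
    )
    gap_s = _concrete_duration(phase.repeat_unit_interval)
    period_s = _concrete_duration(phase.period)
    n = sum(x is not None for x in (unit_s, gap_s, period_s))
    if n < 2:
        raise IncompleteIntervalError(
            "phase inference needs two concrete durations of "
            "{repeat_unit, repeat_unit_interval, period}"
        )
    if n == 3:
        if period_s != unit_s + gap_s:
            raise InconsistentPhaseError(
                f"period {period_s}s != repeat unit {unit_s}s + "
                f"gap {gap_s}s"
            )
        return phase

    def mk(seconds: int) -> Duration:
        if seconds < 0:
            raise InconsistentPhaseError("inferred a negative duration")
        comps = _decompose_seconds(seconds, Granularity.SECOND)
        return Duration(duration_pattern=format_duration(comps), components=comps)

    if period_s is None:
        return replace(phase, period=mk(unit_s + gap_s))
    if gap_s is None:
        return replace(phase, repeat_unit_interval=mk(period_s - unit_s))
    return replace(phase, repeat_unit=mk(period_s - gap_s))


# --------------------------------------------------------------------------
# Time-literal normalization
# --------------------------------------------------------------------------

#: Default formats tried in order: "28 APR 2017", "APR 28, 2017",
#: ISO 8601 date-time and date, then coarser ISO prefixes.
DEFAULT_DATE_FORMATS: tuple[str, ...] = (
    "%d %b %Y",
    "%d %B %Y",
    "%b %d, %Y",
    "%B %d, %Y",
    "%Y-%m-%dT%H:%M:%S",
    "%Y-%m-%d %H:%M:%S",
    "%Y-%m-%d",
    "%Y-%m",
    "%Y",
)

_DIRECTIVE_GRANULARITY = (
    ("%S", Granularity.SECOND),
    ("%M", Granularity.MINUTE),
    ("%H", Granularity.HOUR),
    ("%d", Granularity.DAY),
    ("%m", Granularity.MONTH),
    ("%b", Granularity.MONTH),
    ("%B", Granularity.MONTH),
    ("%Y", Granularity.YEAR),
)


def _format_granularity(fmt: str) -> Granularity:
    for directive, gran in _DIRECTIVE_GRANULARITY:
        if directive in fmt:
            return gran
    raise NormalizationError(f"format {fmt!r} has no date/time directive")


def normalize_instant(
    orig_time: str, formats: Sequence[str] = DEFAULT_DATE_FORMATS
) -> tuple[datetime, Granularity]:
    """Normalize a surface time literal against an ordered format list.

    The first matching format wins; the granularity is the finest field
    the matched format carries ("28 APR 2017" -> day, "2017" -> year).
    Raises :class:`NormalizationError` when nothing matches, in which
    case callers keep the instant with its original text only.
    """
    if not orig_time or not orig_time.strip():
        raise NormalizationError("empty time literal")
    text = orig_time.strip()
    for fmt in formats:
        try:
            dt = datetime.strptime(text, fmt)
        except ValueError:
            continue
        return dt, _format_granularity(fmt)
    raise NormalizationError(f"no configured format matches {orig_time!r}")
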