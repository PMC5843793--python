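"""Temporal keyword lexicon and time-relevant CDE extraction.

The CDE parser decides whether a common data element is time-relevant by
scanning its LongName and PreferredDefinition fields for temporal
keywords.  Each keyword is a small regular expression assigned to one or
more TEO classes ("building blocks"): month names and *date* point at
TimeInstant/TimeInterval/Date, unit words at Granularity/Duration,
relational words (*before*, *prior to*, *after*, ...) at
TemporalRelation/TimeOffset, recurrence words at TimePhase, and
*interval* at TimeInterval.  Building blocks are deliberately ambiguous
tag groups — they guide the human annotator rather than fix a class.

Matching is case-insensitive and anchored at word boundaries by default,
so "date" does not fire inside "candidate" or "validated"; pass
``word_boundary=False`` to reproduce a looser matcher.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from .cadsr import CDERecord
from .errors import TeoCdeError
from .stats import ConfusionCounts

__all__ = [
    "BuildingBlock",
    "LexiconEntry",
    "Lexicon",
    "KeywordMatch",
    "TimeAnnotatedCDE",
    "default_lexicon",
    "scan_text",
    "extract_time_relevant",
    "classify_against_gold",
]


class BuildingBlock(str, enum.Enum):
    """TEO class tag attached to a matched keyword."""

    TIME_INSTANT = "TimeInstant"
    TIME_INTERVAL = "TimeInterval"
    DATE = "Date"
    GRANULARITY = "Granularity"
    DURATION = "Duration"
    TEMPORAL_RELATION = "TemporalRelation"
    TIME_OFFSET = "TimeOffset"
    TIME_PHASE = "TimePhase"


# The five keyword groups: comma-delimited regex alternatives sharing a
# tag group.  Alternatives with embedded spaces ("prior to") are split on
# commas then trimmed.
_GROUPS: tuple[tuple[str, tuple[BuildingBlock, ...]], ...] = (
    (
        "Jan(uary)?,Feb(ruary)?,Mar(ch)?,Apr(il)?,May,June,July,Aug(ust)?,"
        "Sept(ember)?,Oct(ober)?,Nov(ember)?,Dec(ember)?,today,morning,night,date",
        (BuildingBlock.TIME_INSTANT, BuildingBlock.TIME_INTERVAL, BuildingBlock.DATE),
    ),
    (
        "seconds,minutes?,hours?,days?,weeks?,months?,years?",
        (BuildingBlock.GRANULARITY, BuildingBlock.DURATION),
    ),
    (
        "before,while,prior to, ago,previous(ly)?,post(-)?,subsequent,"
        "concurrent(ly)?,meets?,overlaps?,finish(es)?,starts?,during,after,"
        "within,until,when",
        (BuildingBlock.TEMPORAL_RELATION, BuildingBlock.TIME_OFFSET),
    ),
    (
        "recurrent,frequent,intermittent,periodic,repeat(ed)?",
        (BuildingBlock.TIME_PHASE,),
    ),
    (
        "Interval",
        (BuildingBlock.TIME_INTERVAL,),
    ),
)


@dataclass(frozen=True)
class LexiconEntry:
    """One keyword alternative: a regex source plus its tag group."""

    pattern: str
    building_blocks: tuple[BuildingBlock, ...]
    group_index: int = 0

    def __post_init__(self) -> None:
        re.compile(self.pattern)
        if not self.building_blocks:
            raise TeoCdeError(f"entry {self.pattern!r} has no building blocks")


class Lexicon:
    """A compiled, ordered keyword lexicon.

    ``word_boundary`` wraps each alternative in word-boundary lookarounds
    so keywords only fire as whole words ("post(-)?" still matches
    "post" and "post-" as a word prefix).
    """

    def __init__(self, entries: Sequence[LexiconEntry], word_boundary: bool = True):
        self.entries = list(entries)
        self.word_boundary = word_boundary
        self._compiled = [
            re.compile(
                rf"(?<!\w)(?:{e.pattern})(?!\w)" if word_boundary else e.pattern,
                re.IGNORECASE,
            )
            for e in self.entries
        ]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def default_lexicon(word_boundary: bool = True) -> Lexicon:
    """The built-in five-group keyword lexicon, one entry per
    comma-delimited alternative."""
    entries = []
    for gi, (alternatives, tags) in enumerate(_GROUPS):
        for alt in alternatives.split(","):
            alt = alt.strip()
            if alt:
                entries.append(LexiconEntry(alt, tags, gi))
    return Lexicon(entries, word_boundary=word_boundary)


def load_lexicon(source, word_boundary: bool = True) -> Lexicon:
    """Load a lexicon override from a tab-delimited file: one line per
    entry, columns ``pattern`` and comma-separated tag names."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    entries = []
    for gi, line in enumerate(ln for ln in text.splitlines() if ln.strip()):
        pattern, _, tags = line.partition("\t")
        entries.append(
            LexiconEntry(
                pattern.strip(),
                tuple(BuildingBlock(t.strip()) for t in tags.split(",") if t.strip()),
                gi,
            )
        )
    return Lexicon(entries, word_boundary=word_boundary)


@dataclass(frozen=True)
class KeywordMatch:
    """A keyword hit: surface text, half-open span, scanned field, tags."""

    keyword: str
    span: tuple[int, int]
    field: str  # "long_name" or "preferred_definition"
    building_blocks: tuple[BuildingBlock, ...]


@dataclass
class TimeAnnotatedCDE:
    """A time-relevant CDE: the record, its keyword matches, and the
    deduplicated building-block groups in first-occurrence order."""

    record: CDERecord
    matches: list[KeywordMatch]
    building_blocks: list[tuple[BuildingBlock, ...]]

    def __post_init__(self) -> None:
        if not self.matches:
            raise TeoCdeError("a time-annotated CDE must have at least one match")


def scan_text(text: str, lexicon: Lexicon, field: str = "long_name") -> list[KeywordMatch]:
    """Find all non-overlapping keyword matches in left-to-right order.

    At equal start offsets the longest match wins ("prior to" beats
    "prior"); remaining ties break by lexicon order.
    """
    if not text:
        return []
    candidates = []
    for order, (entry, rx) in enumerate(zip(lexicon.entries, lexicon._compiled)):
        for m in rx.finditer(text):
            if m.start() == m.end():
                continue
            candidates.append((m.start(), -(m.end() - m.start()), order, m.end(), entry, m.group(0)))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    out: list[KeywordMatch] = []
    last_end = -1
    for start, _neg_len, _order, end, entry, surface in candidates:
        if start < last_end:
            continue
        out.append(
            KeywordMatch(
                keyword=surface,
                span=(start, end),
                field=field,
                building_blocks=entry.building_blocks,
            )
        )
        last_end = end
    return out


def annotate_record(record: CDERecord, lexicon: Lexicon) -> TimeAnnotatedCDE | None:
    """Scan one CDE's LongName and PreferredDefinition; None if no hits."""
    matches = scan_text(record.long_name, lexicon, "long_name")
    matches += scan_text(record.preferred_definition, lexicon, "preferred_definition")
    if not matches:
        return None
    blocks: list[tuple[BuildingBlock, ...]] = []
    for m in matches:
        if m.building_blocks not in blocks:
            blocks.append(m.building_blocks)
    return TimeAnnotatedCDE(record=record, matches=matches, building_blocks=blocks)


def extract_time_relevant(
    records: Iterable[CDERecord], lexicon: Lexicon | None = None
) -> list[TimeAnnotatedCDE]:
    """Extract exactly those CDEs with at least one temporal keyword in
    LongName or PreferredDefinition."""
    lexicon = lexicon if lexicon is not None else default_lexicon()
    out = []
    for rec in records:
        annotated = annotate_record(rec, lexicon)
        if annotated is not None:
            out.append(annotated)
    return out


def classify_against_gold(
    predicted: Iterable[str], gold_positive: Iterable[str], universe: Iterable[str]
) -> ConfusionCounts:
    """Confusion counts of an extraction against gold labels.

    True positives are CDEs correctly identified as containing a
    temporal component; true negatives those correctly excluded.
    """
    predicted, gold_positive, universe = set(predicted), set(gold_positive), set(universe)
    if not predicted <= universe:
        raise TeoCdeError(
            f"predicted ids outside the universe: {sorted(predicted - universe)[:5]}"
        )
    if not gold_positive <= universe:
        raise TeoCdeError(
            f"gold ids outside the universe: {sorted(gold_positive - universe)[:5]}"
        )
    return ConfusionCounts(
        tp=len(predicted & gold_positive),
        fp=len(predicted - gold_positive),
        fn=len(gold_positive - predicted),
        tn=len(universe - (predicted | gold_positive)),
    )
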