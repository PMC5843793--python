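"""Reading and writing the caDSR common-data-element XML dialect.

A caDSR export is an XML document whose ``DataElement`` children each
carry a ``num`` attribute and the child elements ``PUBLICID``,
``LONGNAME``, ``PREFERREDNAME``, ``PREFERREDDEFINITION`` and
``DATAELEMENTCONCEPT/PreferredName``.  Element names are matched
case-sensitively in that upper-case dialect by default; a
``case_insensitive`` switch relaxes this for variant exports.

The module also defines the tab-delimited annotation-file format used to
record, per annotator and CDE, which TEO pattern (if any) represents its
temporal content.
"""

from __future__ import annotations

import enum
import io
import json
import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Union

from lxml import etree

from .errors import AnnotationError, CdeXmlError

__all__ = [
    "CDERecord",
    "AnnotationCategory",
    "AnnotationRecord",
    "read_cadsr_xml",
    "write_cadsr_xml",
    "read_annotations",
    "write_annotations",
]

_FIELDS = ("PUBLICID", "LONGNAME", "PREFERREDNAME", "PREFERREDDEFINITION")


@dataclass
class CDERecord:
    """One caDSR data element (ISO/IEC 11179 common data element)."""

    num: int | None
    public_id: str
    long_name: str
    preferred_name: str = ""
    preferred_definition: str = ""
    data_element_concept: str | None = None

    def __post_init__(self) -> None:
        if not self.public_id:
            raise CdeXmlError(f"DataElement num={self.num}: empty PUBLICID")
        if not self.long_name:
            raise CdeXmlError(f"DataElement num={self.num}: empty LONGNAME")


class AnnotationCategory(str, enum.Enum):
    """Outcome of annotating one CDE against the pattern registry."""

    EXISTING_PATTERN = "existing_pattern"
    NEW_PATTERN = "new_pattern"
    NOT_TIME_RELATED = "not_time_related"
    CANNOT_REPRESENT = "cannot_represent"


#: Categories that carry a pattern assignment.
PATTERN_CATEGORIES = frozenset(
    {AnnotationCategory.EXISTING_PATTERN, AnnotationCategory.NEW_PATTERN}
)


@dataclass
class AnnotationRecord:
    """One annotator's judgement on one CDE.

    ``pattern_id`` is required exactly when the category assigns a
    pattern (existing or new); ``bindings`` optionally maps template slot
    paths to concrete values.
    """

    public_id: str
    annotator_id: str
    category: AnnotationCategory
    pattern_id: str | None = None
    bindings: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.category = AnnotationCategory(self.category)
        has_pattern = self.pattern_id not in (None, "", "-")
        if self.category in PATTERN_CATEGORIES and not has_pattern:
            raise AnnotationError(
                f"{self.public_id}/{self.annotator_id}: category "
                f"{self.category.value} requires a pattern_id"
            )
        if self.category not in PATTERN_CATEGORIES and has_pattern:
            raise AnnotationError(
                f"{self.public_id}/{self.annotator_id}: category "
                f"{self.category.value} must not carry a pattern_id"
            )
        if self.pattern_id in ("", "-"):
            self.pattern_id = None


Source = Union[str, os.PathLike, bytes, IO]


def _to_tree(source: Source) -> etree._ElementTree:
    if isinstance(source, bytes):
        return etree.parse(io.BytesIO(source))
    return etree.parse(source)


def read_cadsr_xml(source: Source, case_insensitive: bool = False) -> list[CDERecord]:
    """Parse a caDSR XML export into :class:`CDERecord` objects.

    Document order is preserved; missing optional elements become empty
    strings.  Malformed XML raises ``lxml``'s syntax error (with line
    info); a ``DataElement`` lacking ``PUBLICID`` or ``LONGNAME`` raises
    :class:`CdeXmlError` naming its ``num`` attribute.
    """
    tree = _to_tree(source)

    def find_text(el: etree._Element, name: str) -> str:
        for child in el:
            tag = child.tag if isinstance(child.tag, str) else ""
            if tag == name or (case_insensitive and tag.lower() == name.lower()):
                return (child.text or "").strip()
        return ""

    def match(el: etree._Element) -> bool:
        tag = el.tag if isinstance(el.tag, str) else ""
        return tag == "DataElement" or (
            case_insensitive and tag.lower() == "dataelement"
        )

    records = []
    for el in tree.getroot().iter():
        if not match(el):
            continue
        num_attr = el.get("num")
        dec = ""
        for child in el:
            tag = child.tag if isinstance(child.tag, str) else ""
            if tag == "DATAELEMENTCONCEPT" or (
                case_insensitive and tag.lower() == "dataelementconcept"
            ):
                dec = find_text(child, "PreferredName")
        public_id = find_text(el, "PUBLICID")
        long_name = find_text(el, "LONGNAME")
        if not public_id or not long_name:
            missing = "PUBLICID" if not public_id else "LONGNAME"
            raise CdeXmlError(
                f"DataElement num={num_attr!r}: missing required {missing}"
            )
        records.append(
            CDERecord(
                num=int(num_attr) if num_attr is not None else None,
                public_id=public_id,
                long_name=long_name,
                preferred_name=find_text(el, "PREFERREDNAME"),
                preferred_definition=find_text(el, "PREFERREDDEFINITION"),
                data_element_concept=dec or None,
            )
        )
    return records


def write_cadsr_xml(records: Iterable[CDERecord]) -> bytes:
    """Serialize records to the caDSR XML dialect (UTF-8 bytes).

    The output round-trips through :func:`read_cadsr_xml` with
    field-level equality.  Duplicate ``public_id`` values raise
    :class:`CdeXmlError` naming the duplicate.
    """
    root = etree.Element("DataElementsList")
    seen: set[str] = set()
    for rec in records:
        if rec.public_id in seen:
            raise CdeXmlError(f"duplicate public_id {rec.public_id!r}")
        seen.add(rec.public_id)
        el = etree.SubElement(root, "DataElement")
        if rec.num is not None:
            el.set("num", str(rec.num))
        for name, value in (
            ("PUBLICID", rec.public_id),
            ("LONGNAME", rec.long_name),
            ("PREFERREDNAME", rec.preferred_name),
            ("PREFERREDDEFINITION", rec.preferred_definition),
        ):
            etree.SubElement(el, name).text = value
        if rec.data_element_concept:
            dec = etree.SubElement(el, "DATAELEMENTCONCEPT")
            etree.SubElement(dec, "PreferredName").text = rec.data_element_concept
    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


_ANNOT_HEADER = ["public_id", "annotator_id", "category", "pattern_id", "bindings"]


def read_annotations(source: Union[str, os.PathLike, IO]) -> list[AnnotationRecord]:
    """Read a tab-delimited annotation file (header row required).

    Columns: public_id, annotator_id, category, pattern_id, bindings.
    ``pattern_id`` and ``bindings`` use ``-`` for absent; bindings are
    JSON-encoded.  Unknown category tokens and schema violations raise
    :class:`AnnotationError`.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise AnnotationError("empty annotation file")
    header = lines[0].split("\t")
    if [h.strip() for h in header] != _ANNOT_HEADER:
        raise AnnotationError(
            f"bad header {header!r}; expected {_ANNOT_HEADER!r}"
        )
    records = []
    for lineno, line in enumerate(lines[1:], start=2):
        cols = line.split("\t")
        if len(cols) != len(_ANNOT_HEADER):
            raise AnnotationError(f"line {lineno}: expected 5 columns, got {len(cols)}")
        public_id, annotator_id, category, pattern_id, bindings = (
            c.strip() for c in cols
        )
        try:
            cat = AnnotationCategory(category)
        except ValueError:
            raise AnnotationError(
                f"line {lineno}: unknown category {category!r}"
            ) from None
        try:
            records.append(
                AnnotationRecord(
                    public_id=public_id,
                    annotator_id=annotator_id,
                    category=cat,
                    pattern_id=pattern_id if pattern_id != "-" else None,
                    bindings={} if bindings == "-" else json.loads(bindings),
                )
            )
        except AnnotationError as exc:
            raise AnnotationError(f"line {lineno}: {exc}") from None
    return records


def write_annotations(records: Iterable[AnnotationRecord]) -> str:
    """Render annotation records as the tab-delimited text format."""
    lines = ["\t".join(_ANNOT_HEADER)]
    for rec in records:
        lines.append(
            "\t".join(
                [
                    rec.public_id,
                    rec.annotator_id,
                    rec.category.value,
                    rec.pattern_id or "-",
                    json.dumps(rec.bindings, sort_keys=True) if rec.bindings else "-",
                ]
            )
        )
    return "\n".join(lines) + "\n"
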