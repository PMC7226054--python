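"""Annotated-document model and IOB span encoding.

A document is raw note text plus standoff PHI entities with 0-based,
half-open character offsets and one of the 23 i2b2 subcategories. Two
on-disk formats are supported: i2b2-2014-style standoff XML (a TEXT element
plus per-entity tags carrying start/end/TYPE) and a minimal JSON dialect
(``{"doc_id", "text", "entities": [{"start", "end", "category"}]}``) usable
where the XML schema is overkill.

Token-level taggers operate on IOB tag strings — ``O`` outside any entity,
``B(CAT)`` on the first token of an entity, ``I(CAT)`` on subsequent ones —
so this module also converts between character-offset entities and tag
sequences over a tokenization.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

from lxml import etree

from .tokenizer import TokenSequence

#: The 23 i2b2 PHI subcategories, grouped by HIPAA parent category.
HIPAA_MAP: dict[str, str] = {
    "DATE": "DATE",
    "DOCTOR": "NAME",
    "PATIENT": "NAME",
    "USERNAME": "NAME",
    "AGE": "AGE",
    "PHONE": "CONTACT",
    "FAX": "CONTACT",
    "EMAIL": "CONTACT",
    "URL": "CONTACT",
    "MEDICALRECORD": "ID",
    "IDNUM": "ID",
    "DEVICE": "ID",
    "BIOID": "ID",
    "HEALTHPLAN": "ID",
    "HOSPITAL": "LOCATION",
    "CITY": "LOCATION",
    "STATE": "LOCATION",
    "STREET": "LOCATION",
    "ZIP": "LOCATION",
    "ORGANIZATION": "LOCATION",
    "COUNTRY": "LOCATION",
    "LOCATION-OTHER": "LOCATION",
    "PROFESSION": "PROFESSION",
}

#: The closed 23-subcategory set used for annotation.
I2B2_CATEGORIES: tuple[str, ...] = tuple(HIPAA_MAP)

# The coarse HIPAA label NAME is additionally accepted on input (some
# worked examples and external annotations use it); it maps to itself.
HIPAA_MAP["NAME"] = "NAME"
CATEGORIES: frozenset[str] = frozenset(HIPAA_MAP)


class ValidationError(ValueError):
    """An annotated document violates the data-model invariants."""


class ParseError(ValueError):
    """A file could not be parsed in the requested format."""


@dataclass(frozen=True, order=True)
class PHIEntity:
    start: int
    end: int
    category: str
    text: str = field(default="", compare=False)

    def overlaps(self, other: "PHIEntity") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class AnnotatedDocument:
    doc_id: str
    text: str
    entities: list[PHIEntity] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entities = sorted(self.entities)
        self.validate()

    def validate(self) -> None:
        for ent in self.entities:
            if not (0 <= ent.start < ent.end <= len(self.text)):
                raise ValidationError(
                    f"{self.doc_id}: entity span [{ent.start}, {ent.end}) out of "
                    f"range for text of length {len(self.text)} "
                    f"(category {ent.category})"
                )
            if ent.category not in CATEGORIES:
                raise ValidationError(
                    f"{self.doc_id}: unknown PHI category {ent.category!r}"
                )
            if ent.text and ent.text != self.text[ent.start : ent.end]:
                raise ValidationError(
                    f"{self.doc_id}: entity text {ent.text!r} != document "
                    f"substring {self.text[ent.start:ent.end]!r}"
                )
        for a, b in zip(self.entities, self.entities[1:]):
            if a.overlaps(b):
                raise ValidationError(
                    f"{self.doc_id}: overlapping gold entities "
                    f"[{a.start},{a.end}) {a.category} and "
                    f"[{b.start},{b.end}) {b.category}"
                )
        # fill surface text where omitted
        self.entities = [
            ent if ent.text else replace(ent, text=self.text[ent.start : ent.end])
            for ent in self.entities
        ]


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------


def _read_json(path: str) -> AnnotatedDocument:
    try:
        with open(path, encoding="utf-8") as fh:
            obj = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON: {exc}") from exc
    try:
        entities = [
            PHIEntity(int(e["start"]), int(e["end"]), str(e["category"]))
            for e in obj.get("entities", [])
        ]
        doc_id = obj.get("doc_id") or os.path.splitext(os.path.basename(path))[0]
        text = obj["text"]
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"{path}: malformed document object: {exc}") from exc
    for ent in entities:
        if ent.end <= ent.start:
            raise ValidationError(
                f"{path}: inverted or empty span [{ent.start}, {ent.end}) "
                f"(category {ent.category})"
            )
    return AnnotatedDocument(doc_id, text, entities)


def _write_json(doc: AnnotatedDocument, path: str) -> None:
    obj = {
        "doc_id": doc.doc_id,
        "text": doc.text,
        "entities": [
            {
                "start": e.start,
                "end": e.end,
                "category": e.category,
                "text": e.text,
            }
            for e in doc.entities
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, ensure_ascii=False, indent=1)
        fh.write("\n")


def _read_xml(path: str) -> AnnotatedDocument:
    try:
        tree = etree.parse(path)
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"{path}: invalid XML: {exc}") from exc
    root = tree.getroot()
    text_el = root.find("TEXT")
    if text_el is None or text_el.text is None:
        raise ParseError(f"{path}: missing TEXT element")
    tags_el = root.find("TAGS")
    entities = []
    if tags_el is not None:
        for el in tags_el:
            try:
                start = int(el.get("start"))
                end = int(el.get("end"))
                category = el.get("TYPE")
            except (TypeError, ValueError) as exc:
                raise ParseError(
                    f"{path}: tag {el.tag} missing/invalid start/end/TYPE"
                ) from exc
            if category is None:
                raise ParseError(f"{path}: tag {el.tag} missing TYPE")
            if end <= start:
                raise ValidationError(
                    f"{path}: inverted or empty span [{start}, {end}) "
                    f"(category {category})"
                )
            entities.append(PHIEntity(start, end, category))
    doc_id = root.get("id") or os.path.splitext(os.path.basename(path))[0]
    return AnnotatedDocument(doc_id, text_el.text, entities)


def _write_xml(doc: AnnotatedDocument, path: str) -> None:
    root = etree.Element("deIdi2b2", id=doc.doc_id)
    text_el = etree.SubElement(root, "TEXT")
    text_el.text = etree.CDATA(doc.text)
    tags_el = etree.SubElement(root, "TAGS")
    for k, ent in enumerate(doc.entities):
        etree.SubElement(
            tags_el,
            HIPAA_MAP[ent.category],
            id=f"P{k}",
            start=str(ent.start),
            end=str(ent.end),
            text=ent.text,
            TYPE=ent.category,
        )
    etree.ElementTree(root).write(
        path, encoding="utf-8", xml_declaration=True, pretty_print=True
    )


_FORMATS = {
    "json": (_read_json, _write_json),
    "xml": (_read_xml, _write_xml),
}


def _resolve_format(path: str, format: str | None) -> str:
    if format is None:
        ext = os.path.splitext(path)[1].lstrip(".").lower()
        format = ext if ext in _FORMATS else "json"
    if format not in _FORMATS:
        raise ValueError(
            f"unknown format {format!r}; expected one of {sorted(_FORMATS)}"
        )
    return format


def read_annotated(path: str, format: str | None = None) -> AnnotatedDocument:
    """Read an annotated document (``json`` or ``xml``, inferred from suffix)."""
    return _FORMATS[_resolve_format(path, format)][0](str(path))


def write_annotated(
    doc: AnnotatedDocument, path: str, format: str | None = None
) -> None:
    """Write an annotated document; ``read_annotated`` round-trips it."""
    _FORMATS[_resolve_format(path, format)][1](doc, str(path))


# ---------------------------------------------------------------------------
# IOB tag sequences
# ---------------------------------------------------------------------------

TagSequence = list  # list[str]; one "O" / "B(CAT)" / "I(CAT)" tag per token


class AlignmentError(ValueError):
    """An entity boundary falls strictly inside a token."""


def tag_category(tag: str) -> str | None:
    """The category named by a B(...)/I(...) tag, or None for "O"."""
    if tag == "O":
        return None
    return tag[2:-1]


def make_tag(kind: str, category: str) -> str:
    return f"{kind}({category})"


def encode_iob(tokens: TokenSequence, entities: list[PHIEntity]) -> list[str]:
    """Encode character-offset entities as per-token IOB tags.

    Every entity boundary must coincide with a token boundary (tokenize
    first; see :func:`deidkit.tokenizer.phi_alignment_error_rate`).
    """
    tags = ["O"] * len(tokens)
    for ent in entities:
        first = True
        covered = False
        for i, tok in enumerate(tokens):
            if tok.start < ent.start < tok.end or tok.start < ent.end < tok.end:
                raise AlignmentError(
                    f"entity [{ent.start},{ent.end}) {ent.category} boundary "
                    f"falls inside token {tok.text!r} [{tok.start},{tok.end})"
                )
            if ent.start <= tok.start and tok.end <= ent.end:
                tags[i] = make_tag("B" if first else "I", ent.category)
                first = False
                covered = True
        if not covered:
            raise AlignmentError(
                f"entity [{ent.start},{ent.end}) {ent.category} covers no token"
            )
    return tags


def repair_tags(tags: list[str]) -> list[str]:
    """Normalize ill-formed IOB output from taggers.

    An I tag following O, the sequence start, or a different category is
    rewritten to B of its own category. Taggers (including the regex initial
    annotator, which emits Table-style bare I tags) may produce such
    sequences; downstream span logic assumes the repaired form.
    """
    out = []
    prev_cat = None
    for tag in tags:
        if tag.startswith("I("):
            cat = tag_category(tag)
            if prev_cat != cat:
                tag = make_tag("B", cat)
        prev_cat = tag_category(tag) if tag != "O" else None
        out.append(tag)
    return out


def decode_iob(
    tokens: TokenSequence, tags: list[str], text: str | None = None
) -> list[PHIEntity]:
    """Merge maximal B,I...I runs of one category into character-offset entities.

    Ill-formed sequences are repaired first (see :func:`repair_tags`), so this
    never raises on tagger output. Inverse of :func:`encode_iob` for aligned,
    non-overlapping entities. Pass the source ``text`` to fill each entity's
    surface string.
    """
    if len(tags) != len(tokens):
        raise ValueError(
            f"{len(tags)} tags for {len(tokens)} tokens"
        )
    tags = repair_tags(list(tags))
    entities: list[PHIEntity] = []
    run_start: int | None = None
    run_cat: str | None = None

    def close(last_idx: int) -> None:
        if run_start is not None:
            start, end = tokens[run_start].start, tokens[last_idx].end
            surface = text[start:end] if text is not None else ""
            entities.append(PHIEntity(start, end, run_cat, surface))

    for i, tag in enumerate(tags):
        if tag.startswith("B("):
            close(i - 1)
            run_start, run_cat = i, tag_category(tag)
        elif tag == "O":
            close(i - 1)
            run_start, run_cat = None, None
        # I(cat): repaired tags guarantee same category as the open run
    close(len(tags) - 1)
    return entities
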