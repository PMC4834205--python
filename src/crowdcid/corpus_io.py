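"""Read, write and validate the PubTator corpus dialect.

The corpus format carries one blank-line-separated block per document:

    <doc_id>|t|<title text>
    <doc_id>|a|<abstract text>
    <doc_id>\t<start>\t<end>\t<surface>\t<Chemical|Disease>\t<concept id>
    <doc_id>\tCID\t<chemical MeSH id>\t<disease MeSH id>

Annotation offsets are 0-based character offsets (end-exclusive) into the
concatenation ``title + separator + abstract``, where the separator is a
single space by default.  Concept IDs may be MeSH descriptor/supplementary
IDs (``D…``/``C…``, optionally prefixed ``MESH:`` which is stripped at
parse time), the sentinel ``-1`` for unmapped mentions, foreign-ontology
IDs (e.g. ``CHEBI:…``), or several IDs joined by ``|`` on one annotation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "Document",
    "ConceptAnnotation",
    "GoldRelation",
    "ParseError",
    "ValidationError",
    "normalize_concept_id",
    "is_mesh_id",
    "parse_pubtator",
    "write_pubtator",
]

_MESH_ID_RE = re.compile(r"^[CD]\d+$")

CHEMICAL = "chemical"
DISEASE = "disease"


class ParseError(ValueError):
    """A line of PubTator input could not be interpreted."""


class ValidationError(ValueError):
    """Parsed content violates a corpus invariant (spans, IDs, duplicates)."""


def normalize_concept_id(raw: str) -> str:
    """Strip a leading ``MESH:`` prefix; leave everything else verbatim."""
    raw = raw.strip()
    if raw.upper().startswith("MESH:"):
        return raw[5:]
    return raw


def is_mesh_id(concept_id: str) -> bool:
    """True for normalized MeSH descriptor/supplementary IDs (D…/C…)."""
    return bool(_MESH_ID_RE.match(concept_id))


@dataclass(frozen=True)
class Document:
    """A title+abstract document.

    ``combined_text`` joins title and abstract with a single separator
    character (a space by default); annotation offsets index it.
    """

    doc_id: str
    title: str
    abstract: str
    separator: str = " "

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValidationError("document ID must be non-empty")
        if len(self.separator) != 1:
            raise ValidationError("title/abstract separator must be a single character")

    @property
    def combined_text(self) -> str:
        return self.title + self.separator + self.abstract


@dataclass(frozen=True)
class ConceptAnnotation:
    """One concept mention: a character span plus one or more concept IDs."""

    doc_id: str
    start: int
    end: int
    surface: str
    concept_class: str  # "chemical" | "disease"
    concept_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.concept_class not in (CHEMICAL, DISEASE):
            raise ValidationError(
                f"unknown concept class {self.concept_class!r} in {self.doc_id}"
            )
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid span [{self.start},{self.end}) in {self.doc_id}"
            )
        if not self.concept_ids:
            raise ValidationError(f"annotation in {self.doc_id} has no concept IDs")

    @property
    def mesh_ids(self) -> tuple[str, ...]:
        """The MeSH components of the ID list (may be empty)."""
        return tuple(i for i in self.concept_ids if is_mesh_id(i))

    @property
    def is_unmapped(self) -> bool:
        """True when the mention carries only the ``-1`` sentinel."""
        return all(i == "-1" for i in self.concept_ids)

    def validate_against(self, document: Document) -> None:
        text = document.combined_text
        if self.end > len(text):
            raise ValidationError(
                f"annotation [{self.start},{self.end}) exceeds text length "
                f"{len(text)} in document {self.doc_id}"
            )
        actual = text[self.start : self.end]
        if actual != self.surface:
            raise ValidationError(
                f"annotation text mismatch in document {self.doc_id} at "
                f"[{self.start},{self.end}): expected {self.surface!r}, "
                f"text has {actual!r}"
            )


@dataclass(frozen=True, order=True)
class GoldRelation:
    """A gold CID assertion: (document, chemical MeSH ID, disease MeSH ID)."""

    doc_id: str
    chemical_id: str
    disease_id: str

    def __post_init__(self) -> None:
        for cid in (self.chemical_id, self.disease_id):
            if not is_mesh_id(cid):
                raise ValidationError(
                    f"relation in {self.doc_id} uses non-MeSH ID {cid!r}"
                )

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.doc_id, self.chemical_id, self.disease_id)


@dataclass
class Corpus:
    """A parsed corpus: documents plus annotations and gold relations."""

    documents: list[Document] = field(default_factory=list)
    annotations: list[ConceptAnnotation] = field(default_factory=list)
    relations: list[GoldRelation] = field(default_factory=list)

    def document(self, doc_id: str) -> Document:
        for doc in self.documents:
            if doc.doc_id == doc_id:
                return doc
        raise KeyError(doc_id)


_CLASS_ALIASES = {
    "chemical": CHEMICAL,
    "disease": DISEASE,
}


def _parse_class(raw: str, lineno: int) -> str:
    key = raw.strip().lower()
    if key not in _CLASS_ALIASES:
        raise ParseError(f"line {lineno}: unknown annotation type {raw!r}")
    return _CLASS_ALIASES[key]


def parse_pubtator(
    stream: str | Iterable[str], separator: str = " "
) -> tuple[list[Document], list[ConceptAnnotation], list[GoldRelation]]:
    """Parse PubTator text into documents, annotations and gold relations.

    Parameters
    ----------
    stream:
        Full text or an iterable of lines.
    separator:
        The character assumed to join title and abstract when validating
        annotation offsets (a single space in the CDR distribution).

    Raises
    ------
    ParseError
        On a malformed line (names the 1-based line number).
    ValidationError
        On span/text mismatch, duplicate document IDs, or a relation
        referencing the wrong document.
    """
    if isinstance(stream, str):
        lines = stream.split("\n")
    else:
        lines = [ln.rstrip("\n") for ln in stream]

    documents: list[Document] = []
    annotations: list[ConceptAnnotation] = []
    relations: list[GoldRelation] = []
    seen_ids: set[str] = set()

    cur_id: str | None = None
    cur_title: str | None = None
    cur_abstract: str | None = None
    cur_anns: list[ConceptAnnotation] = []
    cur_rels: list[GoldRelation] = []

    def flush(lineno: int) -> None:
        nonlocal cur_id, cur_title, cur_abstract, cur_anns, cur_rels
        if cur_id is None:
            return
        if cur_title is None or cur_abstract is None:
            raise ParseError(
                f"line {lineno}: document {cur_id} is missing its "
                f"{'title' if cur_title is None else 'abstract'} line"
            )
        if cur_id in seen_ids:
            raise ValidationError(f"duplicate document ID {cur_id}")
        seen_ids.add(cur_id)
        doc = Document(cur_id, cur_title, cur_abstract, separator=separator)
        for ann in cur_anns:
            ann.validate_against(doc)
        documents.append(doc)
        annotations.extend(cur_anns)
        relations.extend(cur_rels)
        cur_id, cur_title, cur_abstract = None, None, None
        cur_anns, cur_rels = [], []

    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            flush(lineno)
            continue
        if "\t" not in line and "|" in line:
            parts = line.split("|", 2)
            if len(parts) != 3 or parts[1] not in ("t", "a"):
                raise ParseError(f"line {lineno}: malformed title/abstract line")
            doc_id, kind, text = parts
            if cur_id is not None and doc_id != cur_id:
                flush(lineno)
            cur_id = doc_id
            if kind == "t":
                if cur_title is not None:
                    raise ParseError(f"line {lineno}: duplicate title for {doc_id}")
                cur_title = text
            else:
                if cur_abstract is not None:
                    raise ParseError(f"line {lineno}: duplicate abstract for {doc_id}")
                cur_abstract = text
            continue
        fields = line.split("\t")
        if len(fields) == 4 and fields[1] == "CID":
            doc_id, _, chem, dis = fields
            if doc_id != cur_id:
                raise ValidationError(
                    f"line {lineno}: relation references {doc_id}, "
                    f"expected {cur_id}"
                )
            cur_rels.append(
                GoldRelation(
                    doc_id,
                    normalize_concept_id(chem),
                    normalize_concept_id(dis),
                )
            )
        elif len(fields) == 6:
            doc_id, start_s, end_s, surface, type_s, id_field = fields
            if doc_id != cur_id:
                raise ValidationError(
                    f"line {lineno}: annotation references {doc_id}, "
                    f"expected {cur_id}"
                )
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer offsets") from exc
            ids = tuple(
                normalize_concept_id(part) for part in id_field.split("|") if part
            )
            cur_anns.append(
                ConceptAnnotation(
                    doc_id=doc_id,
                    start=start,
                    end=end,
                    surface=surface,
                    concept_class=_parse_class(type_s, lineno),
                    concept_ids=ids,
                )
            )
        else:
            raise ParseError(
                f"line {lineno}: expected annotation (6 fields) or CID "
                f"relation (4 fields), got {len(fields)} fields"
            )
    flush(len(lines) + 1)
    return documents, annotations, relations


def write_pubtator(
    documents: Sequence[Document],
    annotations: Sequence[ConceptAnnotation] = (),
    relations: Sequence[GoldRelation] = (),
) -> str:
    """Serialize a corpus back to PubTator text.

    ``parse_pubtator(write_pubtator(...))`` is the identity on valid
    corpora; annotation order within a document is preserved and
    composite ID lists are re-joined with ``|``.
    """
    ann_by_doc: dict[str, list[ConceptAnnotation]] = {}
    for ann in annotations:
        ann_by_doc.setdefault(ann.doc_id, []).append(ann)
    rel_by_doc: dict[str, list[GoldRelation]] = {}
    for rel in relations:
        rel_by_doc.setdefault(rel.doc_id, []).append(rel)

    blocks: list[str] = []
    for doc in documents:
        lines = [f"{doc.doc_id}|t|{doc.title}", f"{doc.doc_id}|a|{doc.abstract}"]
        for ann in ann_by_doc.get(doc.doc_id, []):
            type_label = "Chemical" if ann.concept_class == CHEMICAL else "Disease"
            lines.append(
                "\t".join(
                    (
                        doc.doc_id,
                        str(ann.start),
                        str(ann.end),
                        ann.surface,
                        type_label,
                        "|".join(ann.concept_ids),
                    )
                )
            )
        for rel in rel_by_doc.get(doc.doc_id, []):
            lines.append(
                "\t".join((doc.doc_id, "CID", rel.chemical_id, rel.disease_id))
            )
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + ("\n" if blocks else "")
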