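"""Candidate-pair generation, lexical auto-acceptance and task routing.

For every document, all unique chemical x disease MeSH ID pairs are
generated from the surviving annotations, then divided into three
mutually exclusive classes:

``pattern``
    The pair matches a lexical "chemical-induced disease" template: a
    chemical mention ends at most ``max_gap`` characters before a
    disease mention starts, and the intervening text contains the
    trigger ``induce``.  Such pairs are accepted automatically and
    never routed to the crowd.
``sentence``
    The two concepts co-occur within at least one sentence; the pair
    is judged once per co-occurring sentence.
``abstract``
    The concepts never share a sentence; the pair is judged once
    against the whole abstract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from crowdcid.corpus_io import CHEMICAL, DISEASE, ConceptAnnotation, Document

__all__ = [
    "PatternConfig",
    "SentenceSpan",
    "CandidateRelation",
    "generate_candidate_pairs",
    "match_cid_pattern",
    "split_sentences",
    "classify_scope",
    "sentence_index_of",
]

SCOPE_PATTERN = "pattern"
SCOPE_SENTENCE = "sentence"
SCOPE_ABSTRACT = "abstract"

#: Abbreviations that must not terminate a sentence.
DEFAULT_ABBREVIATIONS = (
    "e.g.",
    "i.e.",
    "vs.",
    "cf.",
    "etc.",
    "al.",
    "Dr.",
    "Fig.",
    "Figs.",
    "No.",
    "St.",
    "approx.",
)


@dataclass(frozen=True)
class PatternConfig:
    """Parameters of the lexical chemical-induced-disease pattern."""

    max_gap: int = 15
    trigger: str = "induce"
    case_insensitive: bool = True

    def __post_init__(self) -> None:
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if not self.trigger:
            raise ValueError("trigger must be non-empty")


@dataclass(frozen=True)
class SentenceSpan:
    """One sentence as a character span into ``combined_text``."""

    doc_id: str
    start: int
    end: int
    index: int


@dataclass(frozen=True)
class CandidateRelation:
    """A candidate (document, chemical, disease) triple with its routing scope."""

    doc_id: str
    chemical_id: str
    disease_id: str
    scope: str  # pattern | sentence | abstract
    sentence_indices: tuple[int, ...] = field(default_factory=tuple)

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.doc_id, self.chemical_id, self.disease_id)


def generate_candidate_pairs(
    document: Document, annotations: Sequence[ConceptAnnotation]
) -> set[tuple[str, str]]:
    """All unique chemical x disease MeSH ID pairs present in the document.

    Composite-ID annotations contribute each MeSH component.  The input
    should already be filtered by ``exclude_non_mesh``; non-MeSH IDs are
    ignored regardless.
    """
    chem_ids: set[str] = set()
    dis_ids: set[str] = set()
    for ann in annotations:
        if ann.doc_id != document.doc_id:
            continue
        target = chem_ids if ann.concept_class == CHEMICAL else dis_ids
        target.update(ann.mesh_ids)
    return {(c, d) for c in chem_ids for d in dis_ids}


def match_cid_pattern(
    document: Document,
    annotations: Sequence[ConceptAnnotation],
    pair: tuple[str, str],
    config: PatternConfig | None = None,
) -> bool:
    """True when some mention pair realizes the "<chem>-induced <disease>" template.

    A chemical mention must end no more than ``max_gap`` characters
    before a disease mention starts, with the trigger substring inside
    the gap text (inclusive of zero-length gaps only when the trigger is
    empty, which is disallowed — so in practice the gap must contain the
    trigger).
    """
    if config is None:
        config = PatternConfig()
    chem_id, dis_id = pair
    text = document.combined_text
    trigger = config.trigger.lower() if config.case_insensitive else config.trigger
    chems = [
        a
        for a in annotations
        if a.doc_id == document.doc_id
        and a.concept_class == CHEMICAL
        and chem_id in a.mesh_ids
    ]
    diseases = [
        a
        for a in annotations
        if a.doc_id == document.doc_id
        and a.concept_class == DISEASE
        and dis_id in a.mesh_ids
    ]
    for a in chems:
        for b in diseases:
            gap = b.start - a.end
            if 0 <= gap <= config.max_gap:
                between = text[a.end : b.start]
                if config.case_insensitive:
                    between = between.lower()
                if trigger in between:
                    return True
    return False


def _is_abbreviation(text: str, dot_pos: int, abbreviations: Sequence[str]) -> bool:
    for abbr in abbreviations:
        lo = dot_pos - len(abbr) + 1
        if lo >= 0 and text[lo : dot_pos + 1] == abbr:
            # preceding char must not extend the token (e.g. "tal." vs "al.")
            if lo == 0 or not text[lo - 1].isalpha():
                return True
    return False


def split_sentences(
    document: Document,
    abbreviations: Sequence[str] = DEFAULT_ABBREVIATIONS,
) -> list[SentenceSpan]:
    """Deterministic rule-based sentence segmentation.

    The title is always its own first sentence.  Inside the abstract, a
    sentence ends at ``.``, ``!`` or ``?`` followed by whitespace and an
    uppercase letter or digit, unless the terminator closes a known
    abbreviation.  Spans index ``combined_text`` and exclude the
    inter-sentence whitespace.
    """
    text = document.combined_text
    spans: list[SentenceSpan] = []
    title_end = len(document.title)
    if title_end > 0:
        spans.append(SentenceSpan(document.doc_id, 0, title_end, 0))

    abs_start = title_end + 1
    cursor = abs_start
    n = len(text)
    i = abs_start
    while i < n:
        ch = text[i]
        if ch in ".!?":
            j = i + 1
            # allow closing quotes/brackets after the terminator
            while j < n and text[j] in ")]'\"":
                j += 1
            if j < n and text[j].isspace():
                k = j
                while k < n and text[k].isspace():
                    k += 1
                next_ok = k < n and (text[k].isupper() or text[k].isdigit())
                if next_ok and not (
                    ch == "." and _is_abbreviation(text, i, abbreviations)
                ):
                    spans.append(
                        SentenceSpan(document.doc_id, cursor, j, len(spans))
                    )
                    cursor = k
                    i = k
                    continue
        i += 1
    if cursor < n:
        spans.append(SentenceSpan(document.doc_id, cursor, n, len(spans)))
    return spans


def sentence_index_of(
    sentences: Sequence[SentenceSpan], offset: int
) -> int | None:
    """Index of the sentence containing a character offset (by span start)."""
    result: int | None = None
    for s in sentences:
        if s.start <= offset < s.end:
            return s.index
        if s.start <= offset:
            result = s.index  # offset falls in inter-span whitespace
    return result


def classify_scope(
    document: Document,
    annotations: Sequence[ConceptAnnotation],
    pairs: Iterable[tuple[str, str]],
    sentences: Sequence[SentenceSpan] | None = None,
    config: PatternConfig | None = None,
) -> list[CandidateRelation]:
    """Assign each candidate pair its routing scope.

    Pattern matches take precedence; remaining pairs are sentence-scoped
    when both concepts have a mention inside at least one common
    sentence (a mention belongs to the sentence containing its start
    offset), else abstract-scoped.  The three classes partition the
    candidates.
    """
    if sentences is None:
        sentences = split_sentences(document)
    if config is None:
        config = PatternConfig()
    doc_anns = [a for a in annotations if a.doc_id == document.doc_id]

    # sentence index -> (chem ids, disease ids) present in the sentence
    per_sentence: dict[int, tuple[set[str], set[str]]] = {}
    for ann in doc_anns:
        idx = sentence_index_of(sentences, ann.start)
        if idx is None:
            continue
        chems, diss = per_sentence.setdefault(idx, (set(), set()))
        (chems if ann.concept_class == CHEMICAL else diss).update(ann.mesh_ids)

    out: list[CandidateRelation] = []
    for chem_id, dis_id in sorted(pairs):
        if match_cid_pattern(document, doc_anns, (chem_id, dis_id), config):
            out.append(
                CandidateRelation(document.doc_id, chem_id, dis_id, SCOPE_PATTERN)
            )
            continue
        cooccur = tuple(
            idx
            for idx in sorted(per_sentence)
            if chem_id in per_sentence[idx][0] and dis_id in per_sentence[idx][1]
        )
        if cooccur:
            out.append(
                CandidateRelation(
                    document.doc_id, chem_id, dis_id, SCOPE_SENTENCE, cooccur
                )
            )
        else:
            out.append(
                CandidateRelation(document.doc_id, chem_id, dis_id, SCOPE_ABSTRACT)
            )
    return out
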