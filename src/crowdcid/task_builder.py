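"""Materialize routed candidate pairs as crowd judgment tasks.

Sentence-scoped pairs yield one task per co-occurring sentence;
abstract-scoped pairs yield a single task over the full title+abstract.
Every mention of the pair inside the judged text unit is highlighted.
Sentence tasks offer three choices — the extra ``chained_induction``
choice captures "chemical-induced X causes Y" chains, which count as
negative during evaluation — while abstract tasks are binary.

The module also carries the task-economics model: maximum theoretical
hourly pay given per-judgment pay and the platform's minimum seconds
per judgment.
"""

from __future__ import annotations

import csv
import hashlib
import io
from dataclasses import dataclass
from typing import Sequence

from crowdcid.candidate_routing import (
    SCOPE_ABSTRACT,
    SCOPE_SENTENCE,
    CandidateRelation,
    SentenceSpan,
    sentence_index_of,
    split_sentences,
)
from crowdcid.corpus_io import CHEMICAL, ConceptAnnotation, Document

__all__ = [
    "CrowdTask",
    "TaskPricing",
    "TaskBuildError",
    "SENTENCE_CHOICES",
    "ABSTRACT_CHOICES",
    "YES_CID",
    "NO_RELATION",
    "CHAINED_INDUCTION",
    "build_tasks",
    "render_highlight",
    "strip_highlight",
    "export_tasks",
    "import_tasks",
    "max_hourly_pay",
]

YES_CID = "yes_cid"
NO_RELATION = "no_relation"
CHAINED_INDUCTION = "chained_induction"

SENTENCE_CHOICES = (YES_CID, NO_RELATION, CHAINED_INDUCTION)
ABSTRACT_CHOICES = (YES_CID, NO_RELATION)


class TaskBuildError(ValueError):
    """A candidate could not be materialized as a task."""


@dataclass(frozen=True)
class CrowdTask:
    """One judgment unit shown to workers."""

    task_id: str
    doc_id: str
    chemical_id: str
    disease_id: str
    scope: str  # sentence | abstract
    unit_span: tuple[int, int]
    highlight_spans: tuple[tuple[int, int, str], ...]  # absolute offsets
    choices: tuple[str, ...]
    sentence_index: int | None = None
    is_test_question: bool = False
    expected_choice: str | None = None

    def __post_init__(self) -> None:
        expected = SENTENCE_CHOICES if self.scope == SCOPE_SENTENCE else ABSTRACT_CHOICES
        if self.choices != expected:
            raise TaskBuildError(
                f"{self.scope} task must offer choices {expected}, got {self.choices}"
            )
        lo, hi = self.unit_span
        for s, e, _ in self.highlight_spans:
            if not (lo <= s < e <= hi):
                raise TaskBuildError(
                    f"highlight [{s},{e}) outside unit [{lo},{hi}) "
                    f"in task {self.task_id}"
                )
        if self.is_test_question and self.expected_choice is None:
            raise TaskBuildError("test question requires an expected choice")

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.doc_id, self.chemical_id, self.disease_id)


@dataclass(frozen=True)
class TaskPricing:
    """Pay and timing parameters for one task type."""

    pay_per_judgment: float  # USD
    min_seconds_per_judgment: float
    judgments_per_task: int = 5

    def __post_init__(self) -> None:
        if (
            self.pay_per_judgment <= 0
            or self.min_seconds_per_judgment <= 0
            or self.judgments_per_task <= 0
        ):
            raise ValueError("pricing parameters must be strictly positive")


def max_hourly_pay(pricing: TaskPricing) -> float:
    """Maximum theoretical pay in USD/hour for a worker at the minimum pace."""
    return 3600.0 * pricing.pay_per_judgment / pricing.min_seconds_per_judgment


def _task_id(
    doc_id: str, chem: str, dis: str, scope: str, sent_idx: int | None
) -> str:
    key = f"{doc_id}|{chem}|{dis}|{scope}|{'' if sent_idx is None else sent_idx}"
    return hashlib.sha1(key.encode("utf-8")).hexdigest()[:12]


def build_tasks(
    routed_candidates: Sequence[CandidateRelation],
    documents: Sequence[Document],
    annotations: Sequence[ConceptAnnotation],
) -> list[CrowdTask]:
    """Build the crowd task list for sentence- and abstract-scoped candidates.

    Pattern-scoped candidates are auto-accepted upstream and are skipped
    here.  Raises :class:`TaskBuildError` when a candidate's pair has no
    mention of either concept inside its unit, which indicates a routing
    invariant was broken upstream.
    """
    docs = {d.doc_id: d for d in documents}
    sentences: dict[str, list[SentenceSpan]] = {}
    tasks: list[CrowdTask] = []

    ordered = sorted(
        routed_candidates,
        key=lambda c: (c.doc_id, c.chemical_id, c.disease_id),
    )
    for cand in ordered:
        if cand.scope not in (SCOPE_SENTENCE, SCOPE_ABSTRACT):
            continue
        doc = docs[cand.doc_id]
        doc_anns = [a for a in annotations if a.doc_id == cand.doc_id]
        pair_anns = [
            a
            for a in doc_anns
            if (cand.chemical_id in a.mesh_ids and a.concept_class == CHEMICAL)
            or (cand.disease_id in a.mesh_ids and a.concept_class != CHEMICAL)
        ]
        if cand.scope == SCOPE_ABSTRACT:
            unit = (0, len(doc.combined_text))
            spans = tuple(
                (a.start, a.end, a.concept_class)
                for a in sorted(pair_anns, key=lambda a: a.start)
            )
            classes = {c for _, _, c in spans}
            if len(classes) < 2:
                raise TaskBuildError(
                    f"pair ({cand.chemical_id},{cand.disease_id}) has no "
                    f"mention of both concepts in document {cand.doc_id}"
                )
            tasks.append(
                CrowdTask(
                    task_id=_task_id(*cand.triple, SCOPE_ABSTRACT, None),
                    doc_id=cand.doc_id,
                    chemical_id=cand.chemical_id,
                    disease_id=cand.disease_id,
                    scope=SCOPE_ABSTRACT,
                    unit_span=unit,
                    highlight_spans=spans,
                    choices=ABSTRACT_CHOICES,
                )
            )
            continue
        sents = sentences.setdefault(cand.doc_id, split_sentences(doc))
        for idx in cand.sentence_indices:
            span = next(s for s in sents if s.index == idx)
            in_unit = [
                a
                for a in pair_anns
                if sentence_index_of(sents, a.start) == idx
            ]
            spans = tuple(
                (a.start, a.end, a.concept_class)
                for a in sorted(in_unit, key=lambda a: a.start)
            )
            classes = {c for _, _, c in spans}
            if len(classes) < 2:
                raise TaskBuildError(
                    f"pair ({cand.chemical_id},{cand.disease_id}) does not "
                    f"co-occur in sentence {idx} of document {cand.doc_id}"
                )
            tasks.append(
                CrowdTask(
                    task_id=_task_id(*cand.triple, SCOPE_SENTENCE, idx),
                    doc_id=cand.doc_id,
                    chemical_id=cand.chemical_id,
                    disease_id=cand.disease_id,
                    scope=SCOPE_SENTENCE,
                    unit_span=(span.start, span.end),
                    highlight_spans=spans,
                    sentence_index=idx,
                    choices=SENTENCE_CHOICES,
                )
            )
    return tasks


def render_highlight(
    unit_text: str, local_spans: Sequence[tuple[int, int, str]]
) -> str:
    """Wrap each span in a class-labeled tag, e.g. ``[[chemical:aspirin]]``.

    Spans are local to ``unit_text``, must not overlap, and stripping
    the tags recovers the input exactly (see :func:`strip_highlight`).
    """
    ordered = sorted(local_spans, key=lambda s: s[0])
    prev_end = 0
    parts: list[str] = []
    for start, end, cls in ordered:
        if start < prev_end:
            raise ValueError(f"overlapping highlight spans at {start}")
        if not (0 <= start < end <= len(unit_text)):
            raise ValueError(f"span [{start},{end}) outside unit text")
        parts.append(unit_text[prev_end:start])
        parts.append(f"[[{cls}:{unit_text[start:end]}]]")
        prev_end = end
    parts.append(unit_text[prev_end:])
    return "".join(parts)


def strip_highlight(markup: str) -> str:
    """Inverse of :func:`render_highlight`."""
    import re

    return re.sub(r"\[\[(?:chemical|disease):(.*?)\]\]", r"\1", markup, flags=re.S)


_EXPORT_COLUMNS = (
    "task_id",
    "doc_id",
    "chemical_id",
    "disease_id",
    "scope",
    "sentence_index",
    "unit_start",
    "unit_end",
    "unit_markup",
    "choices",
    "is_test_question",
    "expected_choice",
)


def export_tasks(
    tasks: Sequence[CrowdTask], documents: Sequence[Document]
) -> str:
    """Serialize tasks as CSV (UTF-8, quoted), one row per task.

    Rows are ordered by (doc_id, chemical_id, disease_id, sentence
    index); the judged unit is exported with highlight markup applied.
    """
    docs = {d.doc_id: d for d in documents}
    buf = io.StringIO()
    writer = csv.writer(buf, quoting=csv.QUOTE_MINIMAL, lineterminator="\n")
    writer.writerow(_EXPORT_COLUMNS)
    ordered = sorted(
        tasks,
        key=lambda t: (
            t.doc_id,
            t.chemical_id,
            t.disease_id,
            -1 if t.sentence_index is None else t.sentence_index,
        ),
    )
    for t in ordered:
        lo, hi = t.unit_span
        unit_text = docs[t.doc_id].combined_text[lo:hi]
        local = [(s - lo, e - lo, c) for s, e, c in t.highlight_spans]
        writer.writerow(
            (
                t.task_id,
                t.doc_id,
                t.chemical_id,
                t.disease_id,
                t.scope,
                "" if t.sentence_index is None else t.sentence_index,
                lo,
                hi,
                render_highlight(unit_text, local),
                "|".join(t.choices),
                int(t.is_test_question),
                t.expected_choice or "",
            )
        )
    return buf.getvalue()


def import_tasks(csv_text: str) -> list[dict]:
    """Read an exported task table back into row dictionaries.

    Numeric fields are restored; the markup column is left as written so
    the caller can verify the strip-inverse property.
    """
    reader = csv.DictReader(io.StringIO(csv_text))
    rows = []
    for row in reader:
        row["unit_start"] = int(row["unit_start"])
        row["unit_end"] = int(row["unit_end"])
        row["sentence_index"] = (
            None if row["sentence_index"] == "" else int(row["sentence_index"])
        )
        row["choices"] = tuple(row["choices"].split("|"))
        row["is_test_question"] = bool(int(row["is_test_question"]))
        rows.append(row)
    return rows
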