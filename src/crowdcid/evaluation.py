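"""Evaluation protocol for CID relation extraction.

Predictions and gold annotations are pooled over all documents into
single sets before counting (micro-averaging).  A relation is the
3-tuple (document ID, chemical MeSH ID, disease MeSH ID); two relations
match only when all three components are exactly equal.  Concept
recognition is scored the same way at two levels: exact mention match
(document, span, ID set) or the (document, concept ID) 2-tuple.

The NER-error filter isolates judgment quality from recognition errors
by restricting both predictions and gold to relations whose chemical
and disease IDs are each carried by at least one predicted annotation
exactly matching a gold annotation (same position and IDs).

The ROC sweep scores every judged candidate by its positive-vote count;
gold relations that were never generated as candidates ("unindexable"
due to NER loss) are injected with zero votes, as if unanimously voted
false.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from crowdcid.aggregation import VoteTally
from crowdcid.corpus_io import ConceptAnnotation, GoldRelation

__all__ = [
    "PRFResult",
    "RocPoint",
    "relation_prf",
    "prf_from_counts",
    "f_measure",
    "annotation_match",
    "ner_prf",
    "ner_error_filter",
    "max_recall",
    "roc_points",
    "roc_auc",
    "overlap_partition",
    "share_of_total",
]

logger = logging.getLogger(__name__)

Triple = tuple[str, str, str]


@dataclass(frozen=True)
class PRFResult:
    """Micro-averaged true/false positive/negative counts with P, R and F."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float


def f_measure(precision: float, recall: float) -> float:
    """Balanced harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def prf_from_counts(tp: int, fp: int, fn: int) -> PRFResult:
    """Build a :class:`PRFResult` from raw counts.

    Empty denominators yield 0.0 (with a warning for precision), so
    degenerate sweeps stay well defined.
    """
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        if tp + fn > 0:
            logger.warning("no predictions; precision defined as 0")
        precision = 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    return PRFResult(tp, fp, fn, precision, recall, f_measure(precision, recall))


def _as_triples(relations: Iterable) -> set[Triple]:
    out: set[Triple] = set()
    for r in relations:
        if isinstance(r, GoldRelation):
            out.add(r.triple)
        elif hasattr(r, "triple"):
            out.add(r.triple)
        else:
            out.add(tuple(r))
    return out


def relation_prf(predicted: Iterable, gold: Iterable) -> PRFResult:
    """Micro P/R/F over relation triples (duplicates collapse to sets)."""
    pred = _as_triples(predicted)
    gold_set = _as_triples(gold)
    tp = len(pred & gold_set)
    return prf_from_counts(tp, len(pred - gold_set), len(gold_set - pred))


def annotation_match(a: ConceptAnnotation, b: ConceptAnnotation) -> bool:
    """Exact annotation equivalence: same document, positions and ID set."""
    return (
        a.doc_id == b.doc_id
        and a.start == b.start
        and a.end == b.end
        and set(a.concept_ids) == set(b.concept_ids)
    )


def _mention_key(a: ConceptAnnotation) -> tuple:
    return (a.doc_id, a.start, a.end, frozenset(a.concept_ids))


def ner_prf(
    predicted_annotations: Sequence[ConceptAnnotation],
    gold_annotations: Sequence[ConceptAnnotation],
    level: str = "mention",
) -> PRFResult:
    """Concept-recognition P/R/F at mention or document-concept level.

    ``mention`` compares exact (document, span, ID set) matches;
    ``concept_doc`` compares unique (document, concept ID) 2-tuples,
    with composite ID lists contributing each ID.
    """
    if level == "mention":
        pred = {_mention_key(a) for a in predicted_annotations}
        gold = {_mention_key(a) for a in gold_annotations}
    elif level == "concept_doc":
        pred = {
            (a.doc_id, cid) for a in predicted_annotations for cid in a.concept_ids
        }
        gold = {
            (a.doc_id, cid) for a in gold_annotations for cid in a.concept_ids
        }
    else:
        raise ValueError("level must be 'mention' or 'concept_doc'")
    tp = len(pred & gold)
    return prf_from_counts(tp, len(pred - gold), len(gold - pred))


def ner_error_filter(
    pred_relations: Iterable,
    gold_relations: Iterable,
    pred_annotations: Sequence[ConceptAnnotation],
    gold_annotations: Sequence[ConceptAnnotation],
) -> tuple[set[Triple], set[Triple]]:
    """Restrict both relation sets to perfectly recognized concepts.

    A relation survives only when, within its document, both its
    chemical and its disease ID are carried by at least one predicted
    annotation that exactly matches a gold annotation.  The operation
    is idempotent and returns subsets of its inputs.
    """
    gold_keys = {_mention_key(a) for a in gold_annotations}
    matched_ids: dict[str, set[str]] = {}
    for a in pred_annotations:
        if _mention_key(a) in gold_keys:
            matched_ids.setdefault(a.doc_id, set()).update(a.concept_ids)

    def keep(triple: Triple) -> bool:
        doc, chem, dis = triple
        ids = matched_ids.get(doc, set())
        return chem in ids and dis in ids

    pred = {t for t in _as_triples(pred_relations) if keep(t)}
    gold = {t for t in _as_triples(gold_relations) if keep(t)}
    return pred, gold


def max_recall(
    candidate_pairs_by_doc: Mapping[str, Iterable[tuple[str, str]]],
    gold_relations: Iterable,
) -> float:
    """Theoretical recall ceiling of the workflow.

    The fraction of gold triples whose (chemical, disease) pair was
    generated as a candidate in its document — i.e. the recall obtained
    if every judged candidate were accepted.  Gold relations whose IDs
    were never produced by recognition are unindexable and bound recall
    from above.
    """
    gold = _as_triples(gold_relations)
    if not gold:
        return 0.0
    by_doc = {doc: set(map(tuple, pairs)) for doc, pairs in candidate_pairs_by_doc.items()}
    hit = sum(
        1 for doc, chem, dis in gold if (chem, dis) in by_doc.get(doc, set())
    )
    return hit / len(gold)


@dataclass(frozen=True)
class RocPoint:
    threshold: int
    tpr: float
    fpr: float


def roc_points(
    tallies: Sequence[VoteTally] | Mapping[Triple, int],
    candidates: Iterable,
    gold: Iterable,
    thresholds: Sequence[int] = (6, 5, 4, 3, 2, 1, 0),
    pattern_relations: Iterable = (),
    pattern_votes: int = 5,
) -> list[RocPoint]:
    """ROC sweep over vote thresholds.

    The instance universe is the judged candidates plus unindexable
    gold relations (injected with zero votes); positives are the gold
    triples.  Pattern-accepted relations carry ``pattern_votes``
    positive votes by default, reflecting their unconditional
    acceptance.  At threshold *t* an instance is predicted positive
    when its votes are at least *t*.
    """
    if isinstance(tallies, Mapping):
        votes: dict[Triple, int] = {tuple(k): v for k, v in tallies.items()}
    else:
        votes = {t.triple: t.positive_votes for t in tallies}
    for rel in _as_triples(pattern_relations):
        votes[rel] = max(votes.get(rel, 0), pattern_votes)

    cand_set = _as_triples(candidates) | set(votes)
    missing = {c for c in cand_set if c not in votes}
    if missing:
        raise ValueError(f"{len(missing)} candidate(s) lack a vote tally")
    gold_set = _as_triples(gold)
    universe = cand_set | gold_set  # unindexable gold enters with 0 votes
    for t in gold_set - cand_set:
        votes[t] = 0

    n_pos = len(gold_set & universe)
    n_neg = len(universe - gold_set)
    points: list[RocPoint] = []
    for thr in thresholds:
        predicted = {t for t in universe if votes[t] >= thr}
        tp = len(predicted & gold_set)
        fp = len(predicted - gold_set)
        tpr = tp / n_pos if n_pos else 0.0
        fpr = fp / n_neg if n_neg else 0.0
        points.append(RocPoint(thr, tpr, fpr))
    return points


def roc_auc(points: Sequence[RocPoint]) -> float:
    """Trapezoidal area under the ROC curve, anchored at (0,0) and (1,1)."""
    xs = [p.fpr for p in points] + [0.0, 1.0]
    ys = [p.tpr for p in points] + [0.0, 1.0]
    order = np.lexsort((ys, xs))
    x = np.asarray(xs)[order]
    y = np.asarray(ys)[order]
    return float(np.trapezoid(y, x))


def overlap_partition(
    systems: Mapping[str, Iterable], gold: Iterable
) -> dict[tuple[str, ...], int]:
    """Venn partition of the gold standard across prediction systems.

    Returns counts of gold triples for every region of the systems'
    Venn diagram, keyed by the sorted tuple of system names predicting
    the triple; the empty tuple counts gold triples predicted by none.
    """
    if not systems:
        raise ValueError("at least one system is required")
    sets = {name: _as_triples(preds) for name, preds in systems.items()}
    names = sorted(sets)
    counts: dict[tuple[str, ...], int] = {}
    for triple in _as_triples(gold):
        region = tuple(n for n in names if triple in sets[n])
        counts[region] = counts.get(region, 0) + 1
    return counts


def share_of_total(count: int, total: int) -> float:
    """Percentage ``100*count/total`` reported to two decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError("count must lie in [0, total]")
    return round(100.0 * count / total, 2)
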