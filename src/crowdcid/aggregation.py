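"""Threshold-vote aggregation of trusted crowd judgments.

Per task, positive votes are the trusted ``yes_cid`` answers (the
chained-induction choice counts as negative, like ``no_relation``).
For sentence-scoped relations judged in several sentences, the
sentence with the most positive votes represents the relation: the
relation is assumed true for the abstract if at least one sentence
supports it.  A relation is predicted when its positive votes reach
the vote threshold; pattern-accepted relations are unioned in
unconditionally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from crowdcid.candidate_routing import SCOPE_SENTENCE, CandidateRelation
from crowdcid.crowd_sim import Judgment
from crowdcid.task_builder import YES_CID, CrowdTask

__all__ = ["VoteTally", "AggregationConfig", "TallyError", "tally", "decide"]


class TallyError(ValueError):
    """A task's trusted-judgment count is inconsistent with the config."""


@dataclass(frozen=True)
class AggregationConfig:
    vote_threshold: int = 4
    judgments_per_task: int = 5

    def __post_init__(self) -> None:
        # a threshold above judgments_per_task is allowed: it turns off
        # crowd predictions, leaving only pattern-accepted relations
        if self.vote_threshold < 0 or self.judgments_per_task < 1:
            raise ValueError("vote_threshold must be >= 0 and judgments_per_task >= 1")


@dataclass(frozen=True)
class VoteTally:
    """Positive-vote count for one candidate relation."""

    doc_id: str
    chemical_id: str
    disease_id: str
    scope: str
    positive_votes: int
    per_sentence_votes: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.doc_id, self.chemical_id, self.disease_id)


def tally(
    judgments: Sequence[Judgment],
    tasks: Sequence[CrowdTask],
    config: AggregationConfig | None = None,
) -> list[VoteTally]:
    """Count positive votes per task, then reduce to one tally per relation.

    Every task must hold exactly ``judgments_per_task`` trusted
    judgments; otherwise a :class:`TallyError` names the offending task.
    """
    if config is None:
        config = AggregationConfig()
    by_task: dict[str, list[Judgment]] = {}
    for j in judgments:
        if j.trusted:
            by_task.setdefault(j.task_id, []).append(j)

    positives: dict[str, int] = {}
    for task in tasks:
        got = by_task.get(task.task_id, [])
        if len(got) != config.judgments_per_task:
            raise TallyError(
                f"task {task.task_id} has {len(got)} trusted judgments, "
                f"expected {config.judgments_per_task}"
            )
        positives[task.task_id] = sum(1 for j in got if j.choice == YES_CID)

    grouped: dict[tuple[str, str, str, str], list[CrowdTask]] = {}
    for task in tasks:
        grouped.setdefault((*task.triple, task.scope), []).append(task)

    tallies: list[VoteTally] = []
    for (doc_id, chem, dis, scope), ts in sorted(grouped.items()):
        if scope == SCOPE_SENTENCE:
            per_sentence = tuple(
                sorted(
                    (t.sentence_index, positives[t.task_id])
                    for t in ts
                    if t.sentence_index is not None
                )
            )
            votes = max(v for _, v in per_sentence)
            tallies.append(
                VoteTally(doc_id, chem, dis, scope, votes, per_sentence)
            )
        else:
            votes = max(positives[t.task_id] for t in ts)
            tallies.append(VoteTally(doc_id, chem, dis, scope, votes))
    return tallies


def decide(
    tallies: Sequence[VoteTally],
    pattern_relations: Iterable[CandidateRelation | tuple[str, str, str]],
    config: AggregationConfig | None = None,
) -> set[tuple[str, str, str]]:
    """Final predicted CID triples: thresholded tallies ∪ pattern relations."""
    if config is None:
        config = AggregationConfig()
    predicted = {
        t.triple for t in tallies if t.positive_votes >= config.vote_threshold
    }
    for rel in pattern_relations:
        predicted.add(
            rel.triple if isinstance(rel, CandidateRelation) else tuple(rel)
        )
    return predicted
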