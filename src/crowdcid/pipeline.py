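"""End-to-end orchestration of the relation-extraction workflow.

``run_pipeline`` chains the stages: concept post-processing →
candidate generation and routing → task building → (simulated) crowd
judgment → vote aggregation → evaluation.  Every stage is a pure
function of its inputs, the configuration and the seed, so reruns are
byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from crowdcid.aggregation import AggregationConfig, VoteTally, decide, tally
from crowdcid.candidate_routing import (
    SCOPE_ABSTRACT,
    SCOPE_PATTERN,
    SCOPE_SENTENCE,
    CandidateRelation,
    PatternConfig,
    classify_scope,
    generate_candidate_pairs,
    split_sentences,
)
from crowdcid.concept_postprocess import (
    AcronymRuleConfig,
    exclude_non_mesh,
    resolve_acronyms,
)
from crowdcid.corpus_io import ConceptAnnotation, Document, GoldRelation
from crowdcid.crowd_sim import (
    Judgment,
    SimConfig,
    WorkerProfile,
    oracle_from_gold,
    simulate_judgments,
)
from crowdcid.evaluation import (
    PRFResult,
    RocPoint,
    max_recall,
    ner_error_filter,
    relation_prf,
    roc_auc,
    roc_points,
)
from crowdcid.task_builder import CrowdTask, build_tasks

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "make_workers"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All stage configurations plus the simulated worker pool."""

    acronym: AcronymRuleConfig = field(default_factory=AcronymRuleConfig)
    pattern: PatternConfig = field(default_factory=PatternConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    aggregation: AggregationConfig = field(default_factory=AggregationConfig)
    n_workers: int = 40
    worker_accuracy: float = 0.85

    def __post_init__(self) -> None:
        if self.n_workers < self.sim.judgments_per_task:
            raise ValueError(
                "worker pool smaller than the judgments required per task"
            )


@dataclass
class PipelineResult:
    """Artifacts and metrics of one workflow run."""

    candidates: list[CandidateRelation]
    pattern_relations: list[CandidateRelation]
    tasks: list[CrowdTask]
    judgments: list[Judgment]
    worker_ledger: object
    tallies: list[VoteTally]
    predicted: set[tuple[str, str, str]]
    prf: PRFResult
    max_recall: float
    roc: list[RocPoint]
    auc: float
    prf_filtered: PRFResult | None = None
    roc_filtered: list[RocPoint] | None = None
    auc_filtered: float | None = None

    @property
    def scope_counts(self) -> dict[str, int]:
        counts = {SCOPE_PATTERN: 0, SCOPE_SENTENCE: 0, SCOPE_ABSTRACT: 0}
        for c in self.candidates:
            counts[c.scope] += 1
        return counts


def make_workers(n: int, accuracy: float | Sequence[float]) -> list[WorkerProfile]:
    """A worker pool with uniform or per-worker accuracies."""
    if isinstance(accuracy, (int, float)):
        accs = [float(accuracy)] * n
    else:
        accs = [float(a) for a in accuracy]
        if len(accs) != n:
            raise ValueError("accuracy sequence length must equal n")
    return [WorkerProfile(f"w{i:04d}", a) for i, a in enumerate(accs)]


def run_pipeline(
    documents: Sequence[Document],
    annotations: Sequence[ConceptAnnotation],
    gold_relations: Sequence[GoldRelation],
    config: PipelineConfig | None = None,
    gold_annotations: Sequence[ConceptAnnotation] | None = None,
    judgments: Sequence[Judgment] | None = None,
) -> PipelineResult:
    """Run the full workflow on a parsed corpus.

    When ``judgments`` is not supplied, a simulated gated crowd answers
    the tasks, informed by the gold standard through the truth oracle.
    ``gold_annotations`` (perfectly mapped mentions) enable the
    NER-error-filtered evaluation alongside the full one.
    """
    if config is None:
        config = PipelineConfig()

    candidates: list[CandidateRelation] = []
    pairs_by_doc: dict[str, set[tuple[str, str]]] = {}
    processed_anns: list[ConceptAnnotation] = []
    for doc in documents:
        doc_anns = [a for a in annotations if a.doc_id == doc.doc_id]
        doc_anns = resolve_acronyms(doc, doc_anns, config.acronym)
        doc_anns = exclude_non_mesh(doc_anns)
        processed_anns.extend(doc_anns)
        pairs = generate_candidate_pairs(doc, doc_anns)
        pairs_by_doc[doc.doc_id] = pairs
        sentences = split_sentences(doc)
        candidates.extend(
            classify_scope(doc, doc_anns, pairs, sentences, config.pattern)
        )
    pattern_relations = [c for c in candidates if c.scope == SCOPE_PATTERN]
    logger.info(
        "documents=%d candidates=%d (pattern=%d sentence=%d abstract=%d)",
        len(documents),
        len(candidates),
        len(pattern_relations),
        sum(c.scope == SCOPE_SENTENCE for c in candidates),
        sum(c.scope == SCOPE_ABSTRACT for c in candidates),
    )

    tasks = build_tasks(candidates, documents, processed_anns)
    logger.info("tasks=%d", len(tasks))

    ledger = None
    if judgments is None:
        workers = make_workers(config.n_workers, config.worker_accuracy)
        oracle = oracle_from_gold(tasks, gold_relations)
        judgments, ledger = simulate_judgments(tasks, oracle, workers, config.sim)
        logger.info(
            "judgments=%d removals=%d",
            len(judgments),
            int(ledger["removed"].sum()),
        )
    judgments = list(judgments)

    tallies = tally(judgments, tasks, config.aggregation)
    predicted = decide(tallies, pattern_relations, config.aggregation)

    prf = relation_prf(predicted, gold_relations)
    mr = max_recall(pairs_by_doc, gold_relations)
    thresholds = tuple(range(config.sim.judgments_per_task + 1, -1, -1))
    roc = roc_points(
        tallies,
        candidates,
        gold_relations,
        thresholds,
        pattern_relations=pattern_relations,
        pattern_votes=config.sim.judgments_per_task,
    )
    auc = roc_auc(roc)

    result = PipelineResult(
        candidates=candidates,
        pattern_relations=pattern_relations,
        tasks=tasks,
        judgments=judgments,
        worker_ledger=ledger,
        tallies=tallies,
        predicted=predicted,
        prf=prf,
        max_recall=mr,
        roc=roc,
        auc=auc,
    )

    if gold_annotations is not None:
        pred_f, gold_f = ner_error_filter(
            predicted, gold_relations, processed_anns, gold_annotations
        )
        result.prf_filtered = relation_prf(pred_f, gold_f)
        cand_f, _ = ner_error_filter(
            [c.triple for c in candidates],
            gold_relations,
            processed_anns,
            gold_annotations,
        )
        tallies_f = [t for t in tallies if t.triple in cand_f]
        pattern_f = [p for p in pattern_relations if p.triple in cand_f]
        result.roc_filtered = roc_points(
            tallies_f,
            cand_f,
            gold_f,
            thresholds,
            pattern_relations=pattern_f,
            pattern_votes=config.sim.judgments_per_task,
        )
        result.auc_filtered = roc_auc(result.roc_filtered)
    return result
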