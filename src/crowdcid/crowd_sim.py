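"""Simulate a quality-gated crowd answering judgment tasks.

The simulator stands in for a live microtask platform: each worker must
first pass a short admission quiz; admitted workers answer streamed
tasks with hidden test questions interleaved, and anyone whose running
test-question accuracy falls below the acceptance floor is removed, all
of their judgments becoming untrusted (removed workers keep their pay;
their work is simply discarded).  Removed workers' slots are refilled
until every real task holds exactly ``judgments_per_task`` trusted
judgments from distinct workers.

Worker behaviour is a single per-worker accuracy: with that probability
the worker gives the task's true choice, otherwise an error drawn
uniformly from the remaining choices.  Everything is driven by one
seeded generator, so identical seeds and inputs give identical judgment
tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from crowdcid.corpus_io import GoldRelation
from crowdcid.task_builder import NO_RELATION, YES_CID, CrowdTask

__all__ = [
    "WorkerProfile",
    "SimConfig",
    "Judgment",
    "WorkerPoolExhaustedError",
    "simulate_judgments",
    "oracle_from_gold",
    "judgments_frame",
]


class WorkerPoolExhaustedError(RuntimeError):
    """Not enough trusted workers remained to fill every task."""


@dataclass(frozen=True)
class WorkerProfile:
    """A simulated worker with a flat probability of answering correctly."""

    worker_id: str
    accuracy: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy must lie in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Quality-gate and stream parameters of the simulated platform."""

    judgments_per_task: int = 5
    quiz_size: int = 6
    quiz_pass_min_correct: int = 5
    accuracy_floor: float = 0.70
    test_question_rate: float = 0.10
    min_test_answers: int = 4  # removal cannot trigger before this many
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.quiz_pass_min_correct > self.quiz_size:
            raise ValueError("quiz_pass_min_correct cannot exceed quiz_size")
        if not 0.0 < self.accuracy_floor <= 1.0:
            raise ValueError("accuracy_floor must lie in (0, 1]")
        if not 0.0 <= self.test_question_rate < 1.0:
            raise ValueError("test_question_rate must lie in [0, 1)")
        if self.judgments_per_task < 1:
            raise ValueError("judgments_per_task must be >= 1")


@dataclass
class Judgment:
    """One worker's answer to one task."""

    task_id: str
    worker_id: str
    choice: str
    trusted: bool = True


class _WorkerState:
    __slots__ = (
        "profile",
        "quiz_passed",
        "removed",
        "test_correct",
        "test_total",
        "answered",
        "judgments",
    )

    def __init__(self, profile: WorkerProfile):
        self.profile = profile
        self.quiz_passed = False
        self.removed = False
        self.test_correct = 0
        self.test_total = 0
        self.answered: set[str] = set()
        self.judgments: list[Judgment] = []


def oracle_from_gold(
    tasks: Sequence[CrowdTask],
    gold_relations: Sequence[GoldRelation] | set[tuple[str, str, str]],
) -> Callable[[CrowdTask], str]:
    """Truth oracle for a perfectly informed crowd.

    A task's correct choice is ``yes_cid`` exactly when its
    (document, chemical, disease) triple is in the gold standard.
    """
    gold_triples = {
        r.triple if isinstance(r, GoldRelation) else tuple(r)
        for r in gold_relations
    }

    def oracle(task: CrowdTask) -> str:
        return YES_CID if task.triple in gold_triples else NO_RELATION

    return oracle


def _answer(
    rng: np.random.Generator,
    accuracy: float,
    truth: str,
    choices: Sequence[str],
) -> str:
    if rng.random() < accuracy:
        return truth
    wrong = [c for c in choices if c != truth]
    if not wrong:
        return truth
    return wrong[int(rng.integers(len(wrong)))]


def simulate_judgments(
    tasks: Sequence[CrowdTask],
    truth_oracle: Callable[[CrowdTask], str],
    workers: Sequence[WorkerProfile],
    config: SimConfig | None = None,
) -> tuple[list[Judgment], pd.DataFrame]:
    """Run the gated crowd over a task list.

    Returns the full judgment list (including untrusted judgments from
    removed workers) and a per-worker ledger.  Raises
    :class:`WorkerPoolExhaustedError` when the pool cannot supply
    ``judgments_per_task`` trusted judgments for every task.
    """
    if config is None:
        config = SimConfig()
    rng = np.random.default_rng(config.rng_seed)
    k = config.judgments_per_task

    states = [_WorkerState(p) for p in workers]
    # Admission quiz: answered correctly with probability = accuracy.
    for st in states:
        correct = int(
            (rng.random(config.quiz_size) < st.profile.accuracy).sum()
        )
        st.quiz_passed = correct >= config.quiz_pass_min_correct

    active = [st for st in states if st.quiz_passed]
    trusted_by_task: dict[str, int] = {t.task_id: 0 for t in tasks}

    def remove_worker(st: _WorkerState) -> None:
        st.removed = True
        for j in st.judgments:
            if j.trusted:
                j.trusted = False
                trusted_by_task[j.task_id] -= 1

    # Fill tasks; a removal untrusts earlier work, so iterate to a fixed point.
    pending = list(tasks)
    cursor = 0
    while pending:
        for task in pending:
            while trusted_by_task[task.task_id] < k:
                candidates = [
                    st
                    for st in active
                    if not st.removed and task.task_id not in st.answered
                ]
                if not candidates:
                    break
                st = candidates[cursor % len(candidates)]
                cursor += 1
                # Hidden test question interleaved in the stream.
                if rng.random() < config.test_question_rate:
                    st.test_total += 1
                    if rng.random() < st.profile.accuracy:
                        st.test_correct += 1
                    if (
                        st.test_total >= config.min_test_answers
                        and st.test_correct / st.test_total
                        < config.accuracy_floor
                    ):
                        remove_worker(st)
                        continue
                choice = _answer(
                    rng, st.profile.accuracy, truth_oracle(task), task.choices
                )
                st.answered.add(task.task_id)
                st.judgments.append(
                    Judgment(task.task_id, st.profile.worker_id, choice)
                )
                trusted_by_task[task.task_id] += 1
        # a removal while filling a later task can damage an earlier one,
        # so recompute the deficit over the whole task list each pass
        still_pending = [t for t in tasks if trusted_by_task[t.task_id] < k]
        # Progress check: if no remaining task can still be filled, fail.
        if still_pending:
            fillable = any(
                any(
                    not st.removed and t.task_id not in st.answered
                    for st in active
                )
                for t in still_pending
            )
            if not fillable:
                raise WorkerPoolExhaustedError(
                    f"worker pool exhausted with {len(still_pending)} "
                    f"task(s) lacking {k} trusted judgments"
                )
        pending = still_pending

    judgments = [j for st in states for j in st.judgments]
    ledger = pd.DataFrame(
        {
            "worker_id": [st.profile.worker_id for st in states],
            "quiz_passed": [st.quiz_passed for st in states],
            "removed": [st.removed for st in states],
            "n_judgments": [len(st.judgments) for st in states],
            "test_accuracy": [
                st.test_correct / st.test_total if st.test_total else np.nan
                for st in states
            ],
        }
    )
    return judgments, ledger


def judgments_frame(judgments: Sequence[Judgment]) -> pd.DataFrame:
    """Judgment table as a DataFrame (task_id, worker_id, choice, trusted)."""
    return pd.DataFrame(
        {
            "task_id": [j.task_id for j in judgments],
            "worker_id": [j.worker_id for j in judgments],
            "choice": [j.choice for j in judgments],
            "trusted": [j.trusted for j in judgments],
        }
    )
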