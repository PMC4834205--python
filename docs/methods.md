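# Methods

`crowdcid` implements a crowdsourced workflow for extracting
chemical-induced disease (CID) relations from concept-annotated
biomedical abstracts, together with everything needed to study that
workflow at desk scale: a synthetic corpus generator with planted
ground truth and a simulator for a quality-gated worker pool.

## The workflow

Input is a PubTator-format corpus: title+abstract documents whose
chemical and disease mentions carry character spans and MeSH concept
IDs, as produced by upstream named-entity recognition (NER) and
normalization tools. The pipeline then proceeds document by document:

1. **Concept post-processing.** Unmapped acronym mentions (concept ID
   `-1`) inherit IDs from mapped mentions in the same document by a
   two-clause rule: exact same-surface propagation, or a parenthetical
   definition — an acronym wrapped in parentheses within 2 characters
   after a mapped same-class mention resolves every same-surface
   unmapped mention in the document. A surface qualifies as an acronym
   when it is at most `max_acronym_length` (default 10) characters,
   contains an uppercase letter and no whitespace; resolution is
   same-class only and, under competition, the nearest preceding
   resolver wins. Mentions left without any MeSH ID (the `-1`
   sentinel, foreign ontologies such as CHEBI) are then discarded.
2. **Candidate generation.** All unique chemical x disease MeSH ID
   pairs present in a document are candidates; composite ID fields
   (`D1|D2`) contribute each component. The unit of analysis
   throughout is the triple (document, chemical ID, disease ID).
3. **Routing.** Candidates split into three mutually exclusive
   classes. Pairs matching the lexical template — a chemical mention
   ending at most 15 characters before a disease mention with the
   substring `induce` (case-insensitive) in the gap — are accepted
   automatically and never judged. Of the rest, pairs whose concepts
   co-occur in at least one sentence are judged once per co-occurring
   sentence; pairs that never share a sentence are judged once against
   the whole abstract.
4. **Task building.** Every mention of the pair inside the judged unit
   is highlighted. Sentence tasks offer three choices (`yes_cid`,
   `no_relation`, `chained_induction`); the third captures
   "chemical-induced X causes Y" chains and counts as negative.
   Abstract tasks are binary.
5. **Aggregation.** Per task, positive votes are the trusted `yes_cid`
   answers out of 5. A sentence-scoped relation takes the maximum over
   its sentence tasks (true for the abstract if true in any sentence).
   Relations with at least `vote_threshold` (default 4) positive votes,
   unioned with the pattern-accepted relations, form the prediction.
6. **Evaluation.** Micro-averaged precision, recall and F over pooled
   relation triples. Concept recognition is scored at exact-mention
   level (document, span, ID set) or (document, ID) level. The
   NER-error filter keeps only relations whose chemical and disease IDs
   are both carried by a predicted annotation exactly matching a gold
   annotation, isolating judgment quality from recognition errors.
   `max_recall` reports the recall ceiling — the fraction of gold
   triples that were generated as candidates at all; the remainder are
   *unindexable* (an ID never recognized in that document). The ROC
   sweep scores each candidate by its vote count over thresholds
   6..0, injects unindexable gold at zero votes (as if unanimously
   voted false), gives pattern-accepted relations the full 5 votes
   (they are accepted unconditionally; exposed as `pattern_votes`),
   and integrates by the trapezoidal rule anchored at (0,0) and (1,1).

## The crowd simulator

Real platforms gate workers by an admission quiz and hidden test
questions; the simulator reproduces that structure so aggregation and
evaluation can be exercised without live workers. Each simulated
worker has a single accuracy `a`: any question is answered correctly
with probability `a`, and errors are uniform over the remaining
choices (the simplest symmetric model; no choice-specific bias is
modeled). A worker must pass a 6-question quiz at 5/6 or better
(70% of six, rounded up), then answers streamed tasks with hidden test
questions interleaved at rate 0.10; once at least 4 test questions
have been answered, a running test accuracy below the 0.70 floor
removes the worker and discards (untrusts) all of their judgments.
Removed workers' slots are refilled until every task holds exactly 5
trusted judgments from distinct workers; if the pool cannot supply
them, the simulation fails loudly rather than degrade. Because
removal depends only on test questions, trusted judgments remain
Bernoulli(`a`) — a property the tests check against the binomial
closed form.

The truth oracle for simulated workers answers `yes_cid` exactly when
the task's triple is in the gold standard. With accuracy 1.0 the
workflow therefore recovers exactly (candidates ∩ gold) ∪
pattern-accepted relations — the recovery property used as an
end-to-end test.

The task-economics model is the closed form
`3600 × pay_per_judgment / min_seconds_per_judgment` (USD/hour): 2
cents at 3 s minimum gives $24/h, 4 cents at 10 s gives $14.40/h.
Platform fees and test-question economics are deliberately not
modeled.

## The synthetic corpus generator

`generate_corpus` emulates the structural features of NER-annotated
abstracts that drive the workflow's behavior, not their linguistic
surface. Each document carries 2 planted gold relations (the original
corpus averages ~2.1 per abstract) plus 2 co-occurring distractor
pairs, drawn from reserved `D91…`/`D92…` vocabularies that cannot
collide with real MeSH. Per relation, a branch is drawn —
pattern 0.15, sentence co-occurrence 0.55, abstract-only 0.30 (chosen
once so sentence- and abstract-task counts are of the same order, as
in the original task tables) — and realized through fixed sentence
templates. Independently, each concept is emitted plain, as an
acronym (long form with parenthetical definition, then bare unmapped
acronym; p = 0.15), or entirely unmapped with no resolvable
definition (p = 0.13, so the expected indexable fraction
(1 − 0.13)² ≈ 0.757 mirrors the ~0.75 recall ceiling reported for
real NER output). Distractor templates include an objective-style
"aim of this study" sentence naming both concepts without asserting
causation — structurally reproducing the out-of-context trap that
sentence-scoped judgments face. A fifth of documents add a
foreign-ontology (CHEBI) mention that must be filtered out.

What the generator does **not** emulate: real lexical variety,
anaphora, MeSH hierarchy effects, annotator disagreement about
span boundaries, or correlated worker errors. Passing tests
therefore demonstrate the correctness of the workflow's mechanics —
routing, gating, aggregation, scoring — not the linguistic difficulty
of real abstracts.

## Numerical and design choices

* Offsets are 0-based, end-exclusive character (not byte) offsets into
  `title + " " + abstract`; the separator is configurable at parse
  time.
* The sentence splitter is deterministic and rule-based (terminator
  `.!?` followed by whitespace and an uppercase letter or digit, with
  a fixed abbreviation list: e.g., i.e., vs., Fig., …). It replaces a
  statistical segmenter by design — no model dependency, injectable if
  a different splitter is wanted. A mention belongs to the sentence
  containing its start offset.
* Pattern gap is measured from chemical end to disease start
  (disease must follow the chemical); trigger matching is a
  case-insensitive substring, so `induce` also hits `induced`,
  `induces`, `Induced`.
* Votes are raw integer counts; no worker-trust weighting and no
  Bayesian/EM aggregation.
* Precision with an empty prediction set is defined as 0 (with a
  warning) so threshold sweeps stay total; F is 0 when P + R = 0.
* `vote_threshold` may exceed `judgments_per_task`: that switches the
  crowd channel off entirely and leaves only pattern-accepted
  relations, the degenerate top end of the threshold sweep.
* Percentages are reported to two decimals via `share_of_total`.
* Task IDs are SHA-1 hashes of (document, pair, scope, sentence
  index), so task tables join stably across runs.

## Problem sizes

The bundled tests and the acceptance script run the simulator on
corpora of 8–30 documents (roughly 100–450 candidates, 500–2000
judgments) with worker pools of 40–300 — sizes at which every
stochastic check (binomial calibration at 10,000 judgments, F-score
monotonicity over 10 seeds × 3 accuracy levels) is stable while the
whole suite completes in seconds.

## Known limitations

* The acronym rule is a deliberately simple stand-in exposed through
  `AcronymRuleConfig`; it reproduces the parenthetical-definition
  behavior but not every convention real abstracts use (inflected
  long forms, cross-class abbreviations, nested parentheses).
* The simulator's flat per-worker accuracy ignores task difficulty
  and worker-task interaction; real crowds are harder on
  abstract-scoped tasks.
* `judgments_per_task` trusted judgments are guaranteed per task, but
  the per-worker stream order is a simple rotation, not a model of
  platform scheduling.
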