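# crowdcid

Crowdsourced extraction of chemical-induced disease (CID) relations
from biomedical abstracts — the complete workflow from
concept-annotated text to evaluated predictions, with a simulated
crowd and a synthetic corpus generator so the whole system runs and is
testable on a desk.

## The problem

Curated chemical–disease relations (which drug causes which adverse
effect) are among the most queried biomedical facts, but expert manual
curation does not scale to the literature. One alternative routes the
problem to non-expert crowd workers: given an abstract whose chemical
and disease mentions have been recognized and normalized to MeSH
concept IDs by upstream NER tools, show workers each candidate pair in
context and aggregate their judgments by voting.

`crowdcid` is for researchers studying that workflow: it implements
candidate generation and routing, crowd task construction, vote
aggregation and the full evaluation protocol, and replaces the live
worker platform with a quality-gated simulator.

## The method

A relation is a triple *(document, chemical MeSH ID, disease MeSH
ID)*. Per document, all unique chemical x disease ID pairs are
candidates, split into three mutually exclusive classes:

* **pattern** — a chemical mention ends ≤ 15 characters before a
  disease mention and the gap contains `induce`
  ("cisplatin-induced nephrotoxicity"): accepted automatically,
  never judged;
* **sentence** — the concepts co-occur in ≥ 1 sentence: judged once
  per co-occurring sentence, with a third choice for
  "chemical-induced X causes Y" chains (counted negative);
* **abstract** — the concepts never share a sentence: one binary
  judgment against the whole abstract.

Five trusted workers judge each task. With per-task positive votes
*v* (sentence-scoped relations take max *v* over their sentences),
the prediction at threshold *t* is

    predicted = { relations with v ≥ t }  ∪  pattern relations,   t = 4 by default.

Scoring is micro-averaged over pooled triples: precision
tp/(tp+fp), recall tp/(tp+fn), F = 2PR/(P+R). An NER-error filter
restricts both sides to relations whose concepts are carried by
predicted annotations exactly matching gold (span and ID), separating
judgment errors from recognition errors; an ROC sweep over vote
thresholds treats gold relations that were never candidates
("unindexable": the recall ceiling) as unanimously voted false.

Simulated workers answer correctly with probability equal to their
accuracy, must pass a 6-question quiz at 5/6, and are removed — their
judgments discarded — when their accuracy on hidden test questions
falls below 70%. See `docs/methods.md` for the full model and its
assumptions.

## Worked example

Generate a 20-document synthetic corpus with planted ground truth and
run the whole workflow with a simulated crowd at 85% worker accuracy:

```sh
$ crowdcid fixtures --n-documents 20 --seed 7 --out-dir corpus
wrote 20 documents, 241 annotations, 40 gold relations to corpus

$ crowdcid run-all corpus/corpus.pubtator \
    --gold-annotations corpus/gold_annotations.pubtator \
    --seed 11 --accuracy 0.85 --out-dir results
documents=20 candidates=240 (pattern=3 sentence=41 abstract=196) tasks=237
precision=1.000 recall=0.700 f=0.824 max_recall=0.750 auc=0.8082
[NER-filtered] precision=1.000 recall=0.933 f=0.966 auc=0.9990
```

Reading the numbers: of 240 candidate pairs, 3 matched the lexical
pattern and were auto-accepted; the rest became 237 crowd tasks. The
crowd's recall is capped at `max_recall=0.750` because a quarter of
the planted gold relations involve a concept the (simulated) NER left
unmapped — those relations are never generated as candidates. Once
the NER-error filter removes relations built on imperfect annotations,
F rises from 0.824 to 0.966 and the ROC area from 0.81 to 1.00,
showing that most residual error was recognition, not judgment —
the same decomposition the evaluation protocol is designed to expose
on real corpora.

Every stage is also a subcommand (`candidates`, `tasks`, `simulate`,
`aggregate`, `evaluate`, `roc`, `overlap`) reading and writing plain
TSV/CSV/PubTator files, and a library call (`crowdcid.run_pipeline`
and the per-module functions).

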