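"""Synthetic PubTator corpora with planted ground truth.

The generator emits title+abstract documents whose chemical and disease
mentions, concept IDs and gold CID relations are all known, so every
pipeline branch can be exercised and verified without the original
challenge corpus:

* gold relations expressed through a lexical "<chemical>-induced
  <disease>" surface pattern, through same-sentence co-occurrence, or
  only at abstract level (mentions never sharing a sentence);
* concepts introduced long-form with a parenthetical acronym and then
  mentioned by the bare (unmapped) acronym, exercising acronym
  resolution;
* concepts emitted entirely unmapped (ID ``-1``) with no resolvable
  definition, making their gold relations unindexable and bounding
  attainable recall, as NER losses do on real corpora;
* co-occurring distractor pairs that are not relations, including an
  objective-style "aim of this study" sentence that names both concepts
  without asserting causation — the classic out-of-context trap for
  sentence-scoped judgments;
* occasional foreign-ontology mentions (CHEBI IDs) that must be
  filtered out before candidate generation.

Synthetic concept IDs live in a reserved ``D9…`` namespace so they can
never collide with real MeSH descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from crowdcid.corpus_io import (
    CHEMICAL,
    DISEASE,
    ConceptAnnotation,
    Document,
    GoldRelation,
)

__all__ = ["FixtureConfig", "FixtureTruth", "generate_corpus"]

BRANCH_PATTERN = "pattern"
BRANCH_SENTENCE = "sentence"
BRANCH_ABSTRACT = "abstract"

FORM_PLAIN = "plain"
FORM_ACRONYM = "acronym"
FORM_UNMAPPED = "unmapped"


@dataclass(frozen=True)
class FixtureConfig:
    """Shape of the generated corpus.

    The branch fractions must sum to 1.  ``p_unmapped`` is applied per
    concept slot in a relation; with two concepts per relation the
    expected indexable fraction is ``(1 - p_unmapped)**2``.
    """

    n_documents: int = 50
    n_chemical_ids: int = 40
    n_disease_ids: int = 40
    n_relations_per_doc: int = 2
    p_pattern: float = 0.15
    p_sentence_cooccur: float = 0.55
    p_abstract_only: float = 0.30
    p_unmapped: float = 0.13
    p_acronym: float = 0.15
    p_foreign: float = 0.20
    n_distractor_pairs: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        fracs = (
            self.p_pattern,
            self.p_sentence_cooccur,
            self.p_abstract_only,
            self.p_unmapped,
            self.p_acronym,
            self.p_foreign,
        )
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(self.p_pattern + self.p_sentence_cooccur + self.p_abstract_only - 1.0) > 1e-9:
            raise ValueError("branch fractions must sum to 1")
        if self.n_documents < 1 or self.n_relations_per_doc < 1:
            raise ValueError("document and relation counts must be positive")
        per_doc = self.n_relations_per_doc + self.n_distractor_pairs
        if self.n_chemical_ids < per_doc or self.n_disease_ids < per_doc:
            raise ValueError(
                "vocabulary too small: need at least "
                f"{per_doc} chemical and disease IDs per document"
            )


@dataclass
class FixtureTruth:
    """Planted ground truth accompanying a generated corpus.

    ``relations`` has one row per gold relation with its expressing
    branch, the surface form of each concept (plain / acronym /
    unmapped) and whether the relation is indexable (no concept emitted
    unmapped-unresolvable).  ``distractors`` lists co-occurring
    non-relation pairs.  ``gold_annotations`` carry the true concept
    IDs on every mention, emulating perfect recognition.
    """

    relations: pd.DataFrame
    distractors: pd.DataFrame
    gold_annotations: list[ConceptAnnotation] = field(default_factory=list)


@dataclass(frozen=True)
class _Concept:
    name: str
    acronym: str
    concept_id: str
    concept_class: str


def _chemical(i: int) -> _Concept:
    return _Concept(f"chemorin{i}", f"CHR{i}", f"D91{i:05d}", CHEMICAL)


def _disease(i: int) -> _Concept:
    return _Concept(f"maladrosis{i}", f"MLD{i}", f"D92{i:05d}", DISEASE)


class _DocBuilder:
    """Accumulates sentences and mention annotations with running offsets."""

    def __init__(self, doc_id: str, title_parts: list) -> None:
        self.doc_id = doc_id
        self.sentences: list[list] = []
        self.title_parts = title_parts

    def add_sentence(self, parts: list) -> None:
        self.sentences.append(parts)

    def realize(self) -> tuple[Document, list[ConceptAnnotation], list[ConceptAnnotation]]:
        def render(parts: list, offset: int) -> tuple[str, list, list]:
            text = ""
            observed: list[ConceptAnnotation] = []
            perfect: list[ConceptAnnotation] = []
            for part in parts:
                if isinstance(part, str):
                    text += part
                    continue
                surface, concept, observed_ids = part
                start = offset + len(text)
                end = start + len(surface)
                common = dict(
                    doc_id=self.doc_id,
                    start=start,
                    end=end,
                    surface=surface,
                    concept_class=concept.concept_class,
                )
                observed.append(
                    ConceptAnnotation(concept_ids=tuple(observed_ids), **common)
                )
                perfect.append(
                    ConceptAnnotation(concept_ids=(concept.concept_id,), **common)
                )
                text += surface
            return text, observed, perfect

        title, t_obs, t_perf = render(self.title_parts, 0)
        observed = list(t_obs)
        perfect = list(t_perf)
        abstract = ""
        offset = len(title) + 1
        for i, parts in enumerate(self.sentences):
            if i > 0:
                abstract += " "
                offset += 1
            text, obs, perf = render(parts, offset)
            abstract += text
            offset += len(text)
            observed.extend(obs)
            perfect.extend(perf)
        doc = Document(self.doc_id, title, abstract)
        for ann in observed + perfect:
            ann.validate_against(doc)
        return doc, observed, perfect


def _mention(concept: _Concept, form: str, as_acronym: bool = False) -> tuple:
    """A mention part: (surface, concept, observed ID list)."""
    if form == FORM_UNMAPPED:
        return (concept.name, concept, ("-1",))
    if form == FORM_ACRONYM and as_acronym:
        return (concept.acronym, concept, ("-1",))
    return (concept.name, concept, (concept.concept_id,))


def _intro_sentence(concept: _Concept, form: str) -> list | None:
    """Long-form definition sentence for acronym concepts."""
    if form != FORM_ACRONYM:
        return None
    if concept.concept_class == CHEMICAL:
        lead, verb = "The compound ", "was administered to all subjects"
    else:
        lead, verb = "The condition ", "was assessed at baseline"
    return [
        lead,
        _mention(concept, FORM_PLAIN),
        " (",
        (concept.acronym, concept, ("-1",)),
        f") {verb}.",
    ]


def generate_corpus(
    config: FixtureConfig | None = None,
) -> tuple[list[Document], list[ConceptAnnotation], list[GoldRelation], FixtureTruth]:
    """Generate a corpus with planted relations; deterministic given the seed.

    Returns observed documents/annotations (what imperfect recognition
    would deliver), the gold relation list, and the truth metadata
    (including perfectly mapped annotations).
    """
    if config is None:
        config = FixtureConfig()
    rng = np.random.default_rng(config.rng_seed)

    documents: list[Document] = []
    annotations: list[ConceptAnnotation] = []
    gold: list[GoldRelation] = []
    gold_annotations: list[ConceptAnnotation] = []
    rel_rows: list[dict] = []
    distractor_rows: list[dict] = []

    n_concepts = config.n_relations_per_doc + config.n_distractor_pairs
    branches = (BRANCH_PATTERN, BRANCH_SENTENCE, BRANCH_ABSTRACT)
    branch_p = (config.p_pattern, config.p_sentence_cooccur, config.p_abstract_only)

    for d in range(config.n_documents):
        doc_id = f"9{d:07d}"
        chem_idx = rng.choice(config.n_chemical_ids, size=n_concepts, replace=False)
        dis_idx = rng.choice(config.n_disease_ids, size=n_concepts, replace=False)
        chems = [_chemical(int(i)) for i in chem_idx]
        diseases = [_disease(int(i)) for i in dis_idx]

        def concept_form() -> str:
            u = rng.random()
            if u < config.p_unmapped:
                return FORM_UNMAPPED
            if u < config.p_unmapped + config.p_acronym:
                return FORM_ACRONYM
            return FORM_PLAIN

        title_chem = chems[0]
        title_chem_form = concept_form()
        builder = _DocBuilder(
            doc_id,
            [
                "Observations on ",
                _mention(title_chem, title_chem_form),
                f" exposure in synthetic cohort {d}.",
            ],
        )

        forms: dict[str, str] = {title_chem.concept_id: title_chem_form}
        introduced: set[str] = set()

        def ensure_intro(concept: _Concept) -> str:
            form = forms.setdefault(concept.concept_id, concept_form())
            if form == FORM_ACRONYM and concept.concept_id not in introduced:
                intro = _intro_sentence(concept, form)
                assert intro is not None
                builder.add_sentence(intro)
                introduced.add(concept.concept_id)
            return form

        for r in range(config.n_relations_per_doc):
            chem, dis = chems[r], diseases[r]
            branch = branches[int(rng.choice(3, p=branch_p))]
            chem_form = ensure_intro(chem)
            dis_form = ensure_intro(dis)
            c_m = _mention(chem, chem_form, as_acronym=True)
            d_m = _mention(dis, dis_form, as_acronym=True)
            if branch == BRANCH_PATTERN:
                builder.add_sentence(
                    [
                        "Notably, ",
                        c_m,
                        "-induced ",
                        d_m,
                        " was observed in treated animals.",
                    ]
                )
            elif branch == BRANCH_SENTENCE:
                builder.add_sentence(
                    [
                        "Treatment with ",
                        c_m,
                        " was associated with severe ",
                        d_m,
                        " in most patients.",
                    ]
                )
            else:
                builder.add_sentence(
                    ["We administered ", c_m, " to the exposed group."]
                )
                builder.add_sentence(
                    ["Many subjects later developed ", d_m, " during follow-up."]
                )
            gold.append(GoldRelation(doc_id, chem.concept_id, dis.concept_id))
            rel_rows.append(
                {
                    "doc_id": doc_id,
                    "chemical_id": chem.concept_id,
                    "disease_id": dis.concept_id,
                    "branch": branch,
                    "chem_form": chem_form,
                    "dis_form": dis_form,
                    "indexable": chem_form != FORM_UNMAPPED
                    and dis_form != FORM_UNMAPPED,
                }
            )

        for k in range(config.n_distractor_pairs):
            chem = chems[config.n_relations_per_doc + k]
            dis = diseases[config.n_relations_per_doc + k]
            chem_form = ensure_intro(chem)
            dis_form = ensure_intro(dis)
            c_m = _mention(chem, chem_form, as_acronym=True)
            d_m = _mention(dis, dis_form, as_acronym=True)
            if k % 2 == 0:
                builder.add_sentence(
                    ["Both ", c_m, " levels and ", d_m, " status were monitored."]
                )
                template = "monitored"
            else:
                builder.add_sentence(
                    [
                        "The aim of this study was to evaluate ",
                        c_m,
                        " exposure and ",
                        d_m,
                        " incidence.",
                    ]
                )
                template = "objective"
            distractor_rows.append(
                {
                    "doc_id": doc_id,
                    "chemical_id": chem.concept_id,
                    "disease_id": dis.concept_id,
                    "template": template,
                }
            )

        if rng.random() < config.p_foreign:
            vehicle = _Concept("sodium chloride", "NACL", "CHEBI:26710", CHEMICAL)
            builder.add_sentence(
                [
                    "A ",
                    ("sodium chloride", vehicle, ("CHEBI:26710",)),
                    " solution served as vehicle control.",
                ]
            )

        doc, observed, perfect = builder.realize()
        documents.append(doc)
        annotations.extend(observed)
        gold_annotations.extend(
            a for a in perfect if not a.concept_ids[0].startswith("CHEBI")
        )

    truth = FixtureTruth(
        relations=pd.DataFrame(rel_rows),
        distractors=pd.DataFrame(distractor_rows),
        gold_annotations=gold_annotations,
    )
    return documents, annotations, gold, truth
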