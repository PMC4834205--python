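"""Candidate pairs, the lexical CID pattern, sentence splitting and routing."""

import itertools

from crowdcid import (
    ConceptAnnotation,
    Document,
    PatternConfig,
    classify_scope,
    exclude_non_mesh,
    generate_candidate_pairs,
    match_cid_pattern,
    resolve_acronyms,
    split_sentences,
)
from crowdcid.candidate_routing import sentence_index_of


def _doc_with(text_pairs, doc_id="1", title="Title line."):
    """Build a document from (surface, class, id) mentions placed in order."""
    abstract = ""
    mentions = []
    for part in text_pairs:
        if isinstance(part, str):
            abstract += part
        else:
            surface, cls, cid = part
            start = len(title) + 1 + len(abstract)
            mentions.append((start, start + len(surface), surface, cls, cid))
            abstract += surface
    doc = Document(doc_id, title, abstract)
    anns = [
        ConceptAnnotation(doc_id, s, e, surf, cls, (cid,))
        for s, e, surf, cls, cid in mentions
    ]
    return doc, anns


class TestGeneratePairs:
    def test_cartesian_product_of_distinct_ids(self):
        doc, anns = _doc_with(
            [
                ("alphaline", "chemical", "D1000001"), " and ",
                ("betaline", "chemical", "D1000002"), " with ",
                ("gammosis", "disease", "D2000001"), ".",
            ]
        )
        assert generate_candidate_pairs(doc, anns) == {
            ("D1000001", "D2000001"),
            ("D1000002", "D2000001"),
        }

    def test_no_chemicals_gives_empty_set(self):
        doc, anns = _doc_with(
            [("gammosis", "disease", "D2000001"), " and ",
             ("deltosis", "disease", "D2000002"), "."]
        )
        assert generate_candidate_pairs(doc, anns) == set()

    def test_duplicate_mentions_dedup_to_unique_pairs(self):
        # 3 chemical IDs x 4 disease IDs, every mention duplicated
        parts = []
        for i in range(3):
            parts += [(f"chem{i}", "chemical", f"D10000{i}"), " "] * 2
        for j in range(4):
            parts += [(f"dis{j}", "disease", f"D20000{j}"), " "] * 2
        doc, anns = _doc_with(parts)
        pairs = generate_candidate_pairs(doc, anns)
        # brute force over all mention pairs, then dedup
        expected = {
            (a.concept_ids[0], b.concept_ids[0])
            for a, b in itertools.product(anns, anns)
            if a.concept_class == "chemical" and b.concept_class == "disease"
        }
        assert pairs == expected
        assert len(pairs) == 12


class TestCidPattern:
    def test_induced_within_gap_matches(self):
        doc, anns = _doc_with(
            [("cisplatin", "chemical", "D1"), "-induced ",
             ("nephrotoxicity", "disease", "D2"), " was seen."]
        )
        assert match_cid_pattern(doc, anns, ("D1", "D2"))

    def test_gap_boundary_15_vs_16(self):
        gap15 = "--induced-pad--"  # 15 chars containing "induce"
        assert len(gap15) == 15
        doc, anns = _doc_with(
            [("cisplatin", "chemical", "D1"), gap15,
             ("nephrotoxicity", "disease", "D2"), "."]
        )
        assert match_cid_pattern(doc, anns, ("D1", "D2"))
        gap16 = "--induced-pad---"
        assert len(gap16) == 16
        doc, anns = _doc_with(
            [("cisplatin", "chemical", "D1"), gap16,
             ("nephrotoxicity", "disease", "D2"), "."]
        )
        assert not match_cid_pattern(doc, anns, ("D1", "D2"))

    def test_trigger_absent_no_match(self):
        doc, anns = _doc_with(
            [("cisplatin", "chemical", "D1"), " causes ",
             ("nephrotoxicity", "disease", "D2"), "."]
        )
        assert not match_cid_pattern(doc, anns, ("D1", "D2"))

    def test_disease_before_chemical_no_match(self):
        doc, anns = _doc_with(
            [("nephrotoxicity", "disease", "D2"), "-inducing ",
             ("cisplatin", "chemical", "D1"), "."]
        )
        assert not match_cid_pattern(doc, anns, ("D1", "D2"))

    def test_case_insensitive_trigger(self):
        doc, anns = _doc_with(
            [("cisplatin", "chemical", "D1"), "-Induced ",
             ("nephrotoxicity", "disease", "D2"), "."]
        )
        assert match_cid_pattern(doc, anns, ("D1", "D2"))
        assert not match_cid_pattern(
            doc, anns, ("D1", "D2"), PatternConfig(case_insensitive=False)
        )


class TestSplitSentences:
    def test_two_sentences_plus_title(self):
        doc = Document("1", "Title line.", "First point. Second point.")
        spans = split_sentences(doc)
        texts = [doc.combined_text[s.start : s.end] for s in spans]
        assert texts == ["Title line.", "First point.", "Second point."]
        assert [s.index for s in spans] == [0, 1, 2]

    def test_abbreviation_not_split(self):
        doc = Document("1", "T.", "We saw e.g. Something odd. Then more.")
        spans = split_sentences(doc)
        texts = [doc.combined_text[s.start : s.end] for s in spans]
        assert texts == ["T.", "We saw e.g. Something odd.", "Then more."]

    def test_single_unterminated_sentence(self):
        doc = Document("1", "T.", "no terminator at all")
        spans = split_sentences(doc)
        assert len(spans) == 2  # title + the whole abstract
        assert spans[1].end == len(doc.combined_text)

    def test_spans_ordered_and_nonoverlapping(self, small_corpus):
        docs, _, _, _ = small_corpus
        for doc in docs:
            spans = split_sentences(doc)
            for a, b in zip(spans, spans[1:]):
                assert a.end <= b.start
                # only whitespace between spans
                assert doc.combined_text[a.end : b.start].strip() == ""
            assert spans[0].start == 0
            assert spans[-1].end == len(doc.combined_text)


def _brute_force_scope(doc, anns, pairs, config=None):
    """Exhaustive mention-pair x sentence scan, independent of classify_scope."""
    config = config or PatternConfig()
    sentences = split_sentences(doc)
    text = doc.combined_text
    out = {}
    for chem_id, dis_id in pairs:
        chems = [a for a in anns if a.concept_class == "chemical" and chem_id in a.mesh_ids]
        diss = [a for a in anns if a.concept_class == "disease" and dis_id in a.mesh_ids]
        pattern = any(
            0 <= b.start - a.end <= config.max_gap
            and config.trigger in text[a.end : b.start].lower()
            for a in chems
            for b in diss
        )
        if pattern:
            out[(chem_id, dis_id)] = ("pattern", ())
            continue
        idxs = sorted(
            {
                s.index
                for s in sentences
                for a in chems
                for b in diss
                if sentence_index_of(sentences, a.start) == s.index
                and sentence_index_of(sentences, b.start) == s.index
            }
        )
        out[(chem_id, dis_id)] = (
            ("sentence", tuple(idxs)) if idxs else ("abstract", ())
        )
    return out


class TestClassifyScope:
    def test_pair_cooccurring_in_multiple_sentences(self):
        doc, anns = _doc_with(
            [
                ("alphaline", "chemical", "D1"), " with ",
                ("gammosis", "disease", "D2"), " seen. Unrelated filler here. Dosed ",
                ("alphaline", "chemical", "D1"), " again near ",
                ("gammosis", "disease", "D2"), " later.",
            ]
        )
        (cand,) = classify_scope(doc, anns, {("D1", "D2")})
        assert cand.scope == "sentence"
        assert cand.sentence_indices == (1, 3)

    def test_never_cooccurring_pair_is_abstract(self):
        doc, anns = _doc_with(
            [("alphaline", "chemical", "D1"), " was given. Patients got ",
             ("gammosis", "disease", "D2"), " later."]
        )
        (cand,) = classify_scope(doc, anns, {("D1", "D2")})
        assert cand.scope == "abstract"

    def test_pattern_wins_over_sentence_cooccurrence(self):
        doc, anns = _doc_with(
            [("alphaline", "chemical", "D1"), "-induced ",
             ("gammosis", "disease", "D2"), " was seen."]
        )
        (cand,) = classify_scope(doc, anns, {("D1", "D2")})
        assert cand.scope == "pattern"

    def test_scope_partition_is_exhaustive_and_exclusive(self, small_corpus):
        docs, anns, _, _ = small_corpus
        for doc in docs:
            doc_anns = exclude_non_mesh(
                resolve_acronyms(doc, [a for a in anns if a.doc_id == doc.doc_id])
            )
            pairs = generate_candidate_pairs(doc, doc_anns)
            cands = classify_scope(doc, doc_anns, pairs)
            assert len(cands) == len(pairs)
            assert {(c.chemical_id, c.disease_id) for c in cands} == pairs

    def test_agrees_with_brute_force_on_synthetic_corpus(self, small_corpus):
        docs, anns, _, _ = small_corpus
        for doc in docs:
            doc_anns = exclude_non_mesh(
                resolve_acronyms(doc, [a for a in anns if a.doc_id == doc.doc_id])
            )
            pairs = generate_candidate_pairs(doc, doc_anns)
            expected = _brute_force_scope(doc, doc_anns, pairs)
            for cand in classify_scope(doc, doc_anns, pairs):
                scope, idxs = expected[(cand.chemical_id, cand.disease_id)]
                assert cand.scope == scope
                assert cand.sentence_indices == idxs
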