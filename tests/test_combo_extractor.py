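import random

import pytest

from _oracles import windowed_cooccurrence_oracle
from crossmine import synthetic_corpus as sc
from crossmine.combo_extractor import (
    build_context,
    explode_pairs,
    extract_all,
    extract_combinations,
    find_matches,
    load_combination_rules,
)
from crossmine.drug_ner import DrugMention, harvest_lexicon_mentions
from crossmine.text_prep import tokenize_doc

RULES = load_combination_rules()

FIG_STYLE_TEXT = (
    "Xenograft experiments were performed in mice. The efficacy of ABT-737 "
    "in combination with paclitaxel was evaluated across several cohorts. "
    "Tumor volume decreased substantially."
)


def _mentions(text, lexicon, article_id="1"):
    return harvest_lexicon_mentions(text, lexicon, article_id)


def test_shipped_rule_set_has_27_rules():
    assert len(RULES) == 27
    assert {r.rule_id for r in RULES} == set(range(1, 28))


class TestFindMatches:
    def test_in_combination_with_is_rule_nine(self):
        doc = tokenize_doc("1", FIG_STYLE_TEXT)
        rule9 = [m for m in find_matches(doc, RULES) if m[0] == 9]
        assert len(rule9) == 1

    def test_no_cue_phrases_gives_empty_list(self):
        doc = tokenize_doc("1", "Plain report of monotherapy outcomes in dogs.")
        assert find_matches(doc, RULES) == []

    def test_cue_occurring_twice_matches_twice(self):
        text = ("Drug A combined with drug B was studied. Later drug C "
                "combined with drug D was studied.")
        doc = tokenize_doc("1", text)
        rule1 = [m for m in find_matches(doc, RULES) if m[0] == 1]
        assert len(rule1) == 2

    def test_ordering_by_position_then_rule(self):
        doc = tokenize_doc("1", FIG_STYLE_TEXT)
        matches = find_matches(doc, RULES)
        assert matches == sorted(matches, key=lambda m: (m[1][0], m[0]))


class TestBuildContext:
    DOC = tokenize_doc("1", " ".join(f"w{i}" for i in range(30)))

    def test_edge_truncation_left(self):
        tree = build_context(self.DOC, (2, 3), window=5)
        # control extends 2 tokens left (all that exist), nothing remains for left node
        assert len(tree.left_context) == 0
        assert self.DOC.tokens[0] in tree.control

    def test_mid_document_full_windows(self):
        tree = build_context(self.DOC, (15, 16), window=5)
        assert len(tree.control) == 11  # cue token + 5 either side
        assert len(tree.left_context) == 5
        assert len(tree.right_context) == 5

    def test_match_on_final_token_empty_right(self):
        tree = build_context(self.DOC, (29, 30), window=5)
        assert tree.right_context == []

    def test_cue_only_control_mode(self):
        tree = build_context(self.DOC, (15, 16), window=5, extend_control=False)
        assert len(tree.control) == 1
        assert len(tree.left_context) == 5

    def test_match_outside_document_rejected(self):
        with pytest.raises(ValueError):
            build_context(self.DOC, (29, 40), window=5)


class TestExtractCombinations:
    LEXICON = ["ABT-737", "paclitaxel", "imatinib"]

    def _tree_and_mentions(self, text):
        doc = tokenize_doc("1", text)
        match = [m for m in find_matches(doc, RULES) if m[0] == 9][0]
        return doc, build_context(doc, match[1]), _mentions(text, self.LEXICON)

    def test_fig_style_pair_extracted(self):
        doc, tree, mentions = self._tree_and_mentions(FIG_STYLE_TEXT)
        records = extract_combinations(tree, mentions, "1", 9, doc.text)
        assert len(records) == 1
        assert records[0].drugs == frozenset({"ABT-737", "paclitaxel"})

    def test_single_drug_gives_no_record(self):
        text = ("The efficacy of ABT-737 in combination with radiation was "
                "evaluated across several treatment cohorts.")
        doc, tree, mentions = self._tree_and_mentions(text)
        assert extract_combinations(tree, mentions, "1", 9, doc.text) == []

    def test_same_drug_twice_fails_distinctness(self):
        text = ("Use of paclitaxel in combination with PACLITAXEL rechallenge "
                "was evaluated across several cohorts.")
        doc, tree, mentions = self._tree_and_mentions(text)
        assert extract_combinations(tree, mentions, "1", 9, doc.text) == []


class TestExtractAll:
    def test_fig_style_corpus_yields_one_record(self):
        from crossmine.corpus_io import Article, Corpus

        corpus = Corpus([Article("7", "Combination report.", FIG_STYLE_TEXT)])
        mentions = {"7": _mentions(FIG_STYLE_TEXT, ["ABT-737", "paclitaxel"], "7")}
        records = extract_all(corpus, RULES, mentions)
        assert len(records) == 1
        assert records[0].drugs == frozenset({"ABT-737", "paclitaxel"})

    def test_two_rules_same_drug_set_deduplicated_to_lowest_rule(self):
        from crossmine.corpus_io import Article, Corpus

        # rule 1 ("combined with") and rule 9 ("in combination with") both
        # find the same pair; the surviving record carries the lower rule id
        text = ("ABT-737 combined with paclitaxel was studied. Again ABT-737 "
                "in combination with paclitaxel was studied.")
        corpus = Corpus([Article("1", "T.", text)])
        mentions = {"1": _mentions(text, ["ABT-737", "paclitaxel"])}
        records = extract_all(corpus, RULES, mentions)
        assert len(records) == 1
        assert records[0].rule_id == 1

    def test_rule_order_shuffle_invariance(self, small_synth):
        corpus, truth, lexicon, _ = small_synth
        mentions = {
            a.article_id: _mentions(a.text, list(lexicon.name), a.article_id)
            for a in corpus
        }
        base = extract_all(corpus, RULES, mentions)
        shuffled = list(RULES)
        random.Random(3).shuffle(shuffled)
        assert extract_all(corpus, shuffled, mentions) == base

    def test_window_monotonicity(self, small_synth):
        corpus, truth, lexicon, _ = small_synth
        mentions = {
            a.article_id: _mentions(a.text, list(lexicon.name), a.article_id)
            for a in corpus
        }
        # compared at pair level: a wider window may grow a record's drug
        # set (a pair becomes a triple) but never loses a pair
        previous = set()
        for window in (3, 5, 8):
            records = explode_pairs(extract_all(corpus, RULES, mentions, window=window))
            found = {(r.article_id, r.drugs) for r in records}
            assert previous <= found
            previous = found

    def test_matches_ground_truth_and_oracle(self, small_synth):
        corpus, truth, lexicon, _ = small_synth
        mentions = {
            a.article_id: _mentions(a.text, list(lexicon.name), a.article_id)
            for a in corpus
        }
        records = extract_all(corpus, RULES, mentions, window=5)
        found = {(r.article_id, r.drugs) for r in records}
        expected = {(aid, drugs) for aid, drugs, _ in truth.combinations}
        oracle = windowed_cooccurrence_oracle(corpus, mentions, RULES, window=5)
        assert found == expected == oracle

    def test_locality_every_drug_has_mention_inside_evidence(self, small_synth):
        corpus, truth, lexicon, _ = small_synth
        mentions = {
            a.article_id: _mentions(a.text, list(lexicon.name), a.article_id)
            for a in corpus
        }
        for rec in extract_all(corpus, RULES, mentions):
            lo, hi = rec.evidence_span
            for drug in rec.drugs:
                spans = [
                    (m.start, m.end)
                    for m in mentions[rec.article_id]
                    if m.surface == drug
                ]
                assert any(s < hi and e > lo for s, e in spans)
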