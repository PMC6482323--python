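import logging

import pytest

from crossmine import corpus_io
from crossmine.combo_extractor import CombinationRecord
from crossmine.corpus_io import Article, Corpus, SchemaError


class TestReadMedlineXml:
    def test_reads_all_records_with_matching_pmids(self, medline_path):
        corpus = corpus_io.read_medline_xml(medline_path)
        assert len(corpus) == 2
        assert corpus.ids() == ["11111", "22222"]
        assert corpus["11111"].title == "Paclitaxel activity in canine carcinoma."

    def test_labeled_abstract_sections_joined_by_single_spaces(self, medline_path):
        corpus = corpus_io.read_medline_xml(medline_path)
        assert corpus["11111"].abstract == (
            "Canine tumors resemble human disease. "
            "Dogs received weekly paclitaxel. "
            "Durable responses were recorded."
        )

    def test_missing_abstract_yields_empty_string(self, medline_path):
        corpus = corpus_io.read_medline_xml(medline_path)
        assert corpus["22222"].abstract == ""
        assert corpus["22222"].text == "A title without any abstract."

    def test_malformed_xml_error_names_byte_offset(self, tmp_path):
        p = tmp_path / "broken.xml"
        p.write_text("<PubmedArticleSet><PubmedArticle>", encoding="utf-8")
        with pytest.raises(ValueError, match="byte offset"):
            corpus_io.read_medline_xml(p)

    def test_record_without_pmid_skipped_with_warning(self, tmp_path, caplog):
        p = tmp_path / "nopmid.xml"
        p.write_text(
            "<PubmedArticleSet><PubmedArticle><MedlineCitation>"
            "<Article><ArticleTitle>T</ArticleTitle></Article>"
            "</MedlineCitation></PubmedArticle></PubmedArticleSet>",
            encoding="utf-8",
        )
        with caplog.at_level(logging.WARNING):
            corpus = corpus_io.read_medline_xml(p)
        assert len(corpus) == 0
        assert "missing PMID" in caplog.text

    def test_write_read_round_trip(self, tmp_path):
        corpus = Corpus(
            [
                Article("1", "First title.", "Some abstract.", "eng"),
                Article("2", "Second title."),
            ]
        )
        path = tmp_path / "out.xml"
        corpus_io.write_medline_xml(corpus, path)
        back = corpus_io.read_medline_xml(path)
        assert [(a.article_id, a.title, a.abstract) for a in back] == [
            (a.article_id, a.title, a.abstract) for a in corpus
        ]


def test_corpus_rejects_duplicate_ids():
    with pytest.raises(ValueError, match="duplicate"):
        Corpus([Article("1", "a"), Article("1", "b")])


class TestReadTable:
    SCHEMA = {
        "human_gene_id": "str",
        "dog_gene_id": "str",
        "similarity": "percent",
    }

    def test_typed_records(self, tmp_path):
        p = tmp_path / "orth.tsv"
        p.write_text(
            "human_gene_id\tdog_gene_id\tsimilarity\n"
            "ENSG1\tENSCAFG1\t80.5\nENSG2\tENSCAFG2\t75.0\nENSG3\tENSCAFG3\t10\n",
            encoding="utf-8",
        )
        df = corpus_io.read_table(p, self.SCHEMA)
        assert len(df) == 3
        assert df.similarity.tolist() == [80.5, 75.0, 10.0]

    def test_percent_out_of_range_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "human_gene_id\tdog_gene_id\tsimilarity\nENSG1\tENSCAFG1\t101.0\n",
            encoding="utf-8",
        )
        with pytest.raises(SchemaError, match="similarity"):
            corpus_io.read_table(p, self.SCHEMA)

    def test_header_only_file_gives_empty_table(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("human_gene_id\tdog_gene_id\tsimilarity\n", encoding="utf-8")
        assert len(corpus_io.read_table(p, self.SCHEMA)) == 0

    def test_missing_column_named_in_error(self, tmp_path):
        p = tmp_path / "short.tsv"
        p.write_text("human_gene_id\tdog_gene_id\nENSG1\tENSCAFG1\n", encoding="utf-8")
        with pytest.raises(SchemaError, match="similarity"):
            corpus_io.read_table(p, self.SCHEMA)


def _record(article_id, rule_id, drugs, phrase="x in combination with y"):
    return CombinationRecord(article_id, rule_id, frozenset(drugs), phrase, (0, 1))


class TestWriteResults:
    def test_drugs_sorted_and_pipe_joined(self, tmp_path):
        path = tmp_path / "r.tsv"
        corpus_io.write_results(
            [_record("9", 9, {"paclitaxel", "ABT-737"})], path
        )
        row = path.read_text(encoding="utf-8").splitlines()[1]
        assert row.split("\t")[:3] == ["9", "9", "ABT-737|paclitaxel"]

    def test_empty_collection_writes_header_only(self, tmp_path):
        path = tmp_path / "r.tsv"
        corpus_io.write_results([], path)
        assert path.read_text(encoding="utf-8") == (
            "article_id\trule_id\tdrugs\tcontrol_phrase\n"
        )

    def test_repeat_writes_byte_identical(self, tmp_path):
        records = [
            _record("2", 3, {"b", "a"}),
            _record("1", 9, {"c", "d"}),
            _record("1", 1, {"e", "f"}),
        ]
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        corpus_io.write_results(records, p1)
        corpus_io.write_results(list(reversed(records)), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_round_trip_recovers_triples(self, tmp_path):
        records = [
            _record("10", 9, {"ABT-737", "paclitaxel"}),
            _record("11", 2, {"imatinib", "gemcitabine"}),
        ]
        path = tmp_path / "r.tsv"
        corpus_io.write_results(records, path)
        triples = set(corpus_io.read_results(path))
        assert triples == {
            ("10", 9, frozenset({"ABT-737", "paclitaxel"})),
            ("11", 2, frozenset({"imatinib", "gemcitabine"})),
        }
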