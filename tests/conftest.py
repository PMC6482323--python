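import pytest

from crossmine import synthetic_corpus as sc

MEDLINE_FIXTURE = """<?xml version="1.0" encoding="UTF-8"?>
<PubmedArticleSet>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>11111</PMID>
      <Article>
        <ArticleTitle>Paclitaxel activity in canine carcinoma.</ArticleTitle>
        <Abstract>
          <AbstractText Label="BACKGROUND">Canine tumors resemble human disease.</AbstractText>
          <AbstractText Label="METHODS">Dogs received weekly paclitaxel.</AbstractText>
          <AbstractText Label="RESULTS">Durable responses were recorded.</AbstractText>
        </Abstract>
        <Language>eng</Language>
      </Article>
    </MedlineCitation>
  </PubmedArticle>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>22222</PMID>
      <Article>
        <ArticleTitle>A title without any abstract.</ArticleTitle>
      </Article>
    </MedlineCitation>
  </PubmedArticle>
</PubmedArticleSet>
"""


@pytest.fixture
def medline_path(tmp_path):
    p = tmp_path / "fixture.xml"
    p.write_text(MEDLINE_FIXTURE, encoding="utf-8")
    return p


@pytest.fixture(scope="session")
def small_synth():
    """A 60-article synthetic corpus with full ground truth and lexicon."""
    config = sc.GeneratorConfig(n_articles=60, seed=7)
    corpus, truth = sc.generate(config)
    lexicon = sc.generate_lexicon(config)
    return corpus, truth, lexicon, config
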