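import pytest

from genetrends import (
    AbstractRecord,
    Author,
    Corpus,
    CountryGazetteer,
    SyntheticSpec,
    build_lexicon,
)

MEDLINE_XML = """<?xml version="1.0" encoding="utf-8"?>
<PubmedArticleSet>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>1001</PMID>
      <Article>
        <Journal>
          <JournalIssue><PubDate><Year>2010</Year></PubDate></JournalIssue>
          <Title>Journal of Testing</Title>
        </Journal>
        <ArticleTitle>PTEN in breast  cancer</ArticleTitle>
        <Abstract><AbstractText>PTEN and MMAC1 regulate growth.</AbstractText></Abstract>
        <AuthorList>
          <Author>
            <LastName>Smith</LastName><ForeName>Ann</ForeName>
            <AffiliationInfo><Affiliation>Dept of CS, University of Calgary, Calgary, AB Canada</Affiliation></AffiliationInfo>
          </Author>
          <Author>
            <LastName>Kaya</LastName><ForeName>Ozan</ForeName>
            <AffiliationInfo><Affiliation>TOBB University, Ankara, Turkey</Affiliation></AffiliationInfo>
          </Author>
        </AuthorList>
      </Article>
    </MedlineCitation>
  </PubmedArticle>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>1002</PMID>
      <Article>
        <Journal>
          <JournalIssue><PubDate><MedlineDate>1998 Dec-1999 Jan</MedlineDate></PubDate></JournalIssue>
          <Title>Journal of Testing</Title>
        </Journal>
        <ArticleTitle>A paper without an abstract</ArticleTitle>
        <AuthorList>
          <Author><LastName>Lee</LastName><ForeName>Bo</ForeName></Author>
        </AuthorList>
      </Article>
    </MedlineCitation>
  </PubmedArticle>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>1003</PMID>
      <Article>
        <Journal>
          <JournalIssue><PubDate><Year>2012</Year></PubDate></JournalIssue>
          <Title>Another Journal</Title>
        </Journal>
        <ArticleTitle>ESR1 expression</ArticleTitle>
        <Abstract><AbstractText>ESR1 and ERBB2 were measured.</AbstractText></Abstract>
        <AuthorList>
          <Author>
            <LastName>Wang</LastName><ForeName>Li</ForeName>
            <AffiliationInfo><Affiliation>Jilin University, Changchun, China</Affiliation></AffiliationInfo>
          </Author>
        </AuthorList>
      </Article>
    </MedlineCitation>
  </PubmedArticle>
</PubmedArticleSet>
"""


@pytest.fixture
def medline_file(tmp_path):
    path = tmp_path / "citations.xml"
    path.write_text(MEDLINE_XML, encoding="utf-8")
    return path


@pytest.fixture
def small_lexicon():
    lex, report = build_lexicon(
        [
            ("PTEN", "PTEN"),
            ("PTEN", "MMAC1"),
            ("ESR1", "ESR1"),
            ("ERBB2", "ERBB2"),
            ("ERBB2", "HER2"),
            ("BRCA1", "BRCA1"),
        ]
    )
    assert not report
    return lex


@pytest.fixture
def toy_gazetteer():
    return CountryGazetteer(
        aliases={
            "Canada": "Canada",
            "AB Canada": "Canada",
            "Turkey": "Turkey",
            "China": "China",
            "USA": "United States",
            "United States": "United States",
        },
        hints={"Ankara": "Turkey", "Calgary": "Canada", "Changchun": "China"},
    )


def make_record(record_id="r1", title="t", abstract="a", year=2010,
                journal="J", authors=None, **kwargs):
    if authors is None:
        authors = [Author(given_name="A", family_name="B", affiliations=[])]
    return AbstractRecord(
        record_id=record_id, title=title, abstract_text=abstract, year=year,
        journal=journal, authors=authors, **kwargs,
    )


@pytest.fixture
def small_corpus():
    return Corpus(
        records=[
            make_record("r1", abstract="PTEN and MMAC1 regulate growth."),
            make_record("r2", abstract=""),
            make_record("r3", abstract="ESR1 was measured."),
        ]
    )


@pytest.fixture(scope="session")
def default_synthetic():
    """The standard 2,000-record planted corpus, generated once per session."""
    import genetrends as gt

    spec = SyntheticSpec()  # seed 42 defaults
    corpus, truth = gt.generate(spec)
    annotated = gt.filter_gene_bearing(
        gt.annotate_corpus(corpus, gt.default_lexicon(spec))
    )
    gt.resolve_corpus(annotated, gt.default_gazetteer(spec))
    return spec, corpus, truth, annotated
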