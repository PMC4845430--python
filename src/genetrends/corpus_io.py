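"""Reading, validating, filtering and persisting abstract corpora.

Two on-disk formats are supported: the MEDLINE/PubMed citation XML dialect
(as exported by the PubMed API or E-utilities) and a line-delimited JSON
corpus schema (one abstract record per line, ``"schema": 1``) that carries
the record through the rest of the pipeline, including gene and country
annotations once they have been attached.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field

from lxml import etree

SCHEMA_VERSION = 1

_YEAR_RE = re.compile(r"\b(1[89]\d{2}|20\d{2}|2100)\b")


class CorpusFormatError(ValueError):
    """Raised when an input file does not conform to the expected format."""


def _norm(text: str | None) -> str:
    """Whitespace-normalize a text field: collapse runs, trim."""
    if text is None:
        return ""
    return " ".join(text.split())


@dataclass
class Author:
    given_name: str = ""
    family_name: str = ""
    affiliations: list[str] = field(default_factory=list)


@dataclass
class AbstractRecord:
    """One publication: identifier, texts, year, journal and author list."""

    record_id: str
    title: str = ""
    abstract_text: str = ""
    year: int | None = None
    journal: str = ""
    authors: list[Author] = field(default_factory=list)
    keywords: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.year is not None and not (1800 <= self.year <= 2100):
            raise ValueError(
                f"record {self.record_id}: year {self.year} outside [1800, 2100]"
            )


@dataclass
class Corpus:
    records: list[AbstractRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.record_id in seen:
                raise ValueError(f"duplicate record_id {rec.record_id!r} in corpus")
            seen.add(rec.record_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


# ---------------------------------------------------------------------------
# MEDLINE XML
# ---------------------------------------------------------------------------

def _medline_year(citation: etree._Element) -> int | None:
    """Year of an article: the PubDate Year element, else the first 4-digit
    token of the MedlineDate string (e.g. "1998 Dec-1999 Jan" -> 1998)."""
    year_el = citation.find(".//Article/Journal/JournalIssue/PubDate/Year")
    if year_el is not None and year_el.text:
        try:
            return int(year_el.text.strip())
        except ValueError:
            pass
    md = citation.find(".//Article/Journal/JournalIssue/PubDate/MedlineDate")
    if md is not None and md.text:
        m = _YEAR_RE.search(md.text)
        if m:
            return int(m.group(0))
    return None


def _medline_authors(citation: etree._Element) -> list[Author]:
    authors = []
    for au in citation.findall(".//Article/AuthorList/Author"):
        affs = [aff.text or "" for aff in au.findall(".//Affiliation")]
        authors.append(
            Author(
                given_name=_norm(au.findtext("ForeName")),
                family_name=_norm(au.findtext("LastName")),
                # affiliation strings are preserved verbatim for the resolver
                affiliations=[a for a in affs if a.strip()],
            )
        )
    return authors


def read_medline_xml(path) -> Corpus:
    """Read a MEDLINE/PubMed citation XML file into a :class:`Corpus`.

    Missing elements yield empty fields; a citation without an AbstractText
    simply gets ``abstract_text == ""``.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise CorpusFormatError(f"unparseable MEDLINE XML in {path}: {exc}") from exc
    records = []
    for citation in tree.iter("MedlineCitation"):
        pmid = _norm(citation.findtext("PMID"))
        abstract_parts = [
            _norm(el.text)
            for el in citation.findall(".//Article/Abstract/AbstractText")
        ]
        keywords = [
            _norm(kw.text) for kw in citation.findall(".//KeywordList/Keyword")
        ]
        records.append(
            AbstractRecord(
                record_id=pmid,
                title=_norm(citation.findtext(".//Article/ArticleTitle")),
                abstract_text=" ".join(p for p in abstract_parts if p),
                year=_medline_year(citation),
                journal=_norm(citation.findtext(".//Article/Journal/Title")),
                authors=_medline_authors(citation),
                keywords=[k for k in keywords if k],
            )
        )
    if not records:
        warnings.warn(f"no MedlineCitation elements found in {path}", stacklevel=2)
    return Corpus(records=records, provenance=f"medline-xml:{path}")


# ---------------------------------------------------------------------------
# JSON-lines corpus schema
# ---------------------------------------------------------------------------

def _record_to_dict(rec: AbstractRecord) -> dict:
    return {
        "schema": SCHEMA_VERSION,
        "record_id": rec.record_id,
        "title": rec.title,
        "abstract": rec.abstract_text,
        "year": rec.year,
        "journal": rec.journal,
        "keywords": list(rec.keywords),
        "authors": [
            {
                "given": a.given_name,
                "family": a.family_name,
                "affiliations": list(a.affiliations),
            }
            for a in rec.authors
        ],
    }


def _record_from_dict(obj: dict, lineno: int) -> AbstractRecord:
    if "record_id" not in obj or obj["record_id"] in (None, ""):
        raise CorpusFormatError(f"line {lineno}: missing record_id")
    authors = [
        Author(
            given_name=a.get("given", ""),
            family_name=a.get("family", ""),
            affiliations=list(a.get("affiliations", [])),
        )
        for a in obj.get("authors", [])
    ]
    return AbstractRecord(
        record_id=str(obj["record_id"]),
        title=_norm(obj.get("title", "")),
        abstract_text=_norm(obj.get("abstract", "")),
        year=obj.get("year"),
        journal=_norm(obj.get("journal", "")),
        authors=authors,
        keywords=list(obj.get("keywords", [])),
    )


def read_jsonl(path) -> Corpus:
    """Read a JSON-lines corpus; malformed lines raise with their line number."""
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"line {lineno}: invalid JSON: {exc}") from exc
            records.append(_record_from_dict(obj, lineno))
    return Corpus(records=records, provenance=f"jsonl:{path}")


def write_jsonl(corpus: Corpus, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in corpus:
            fh.write(json.dumps(_record_to_dict(rec), sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Completeness filter
# ---------------------------------------------------------------------------

def filter_complete(corpus: Corpus) -> tuple[Corpus, dict[str, int]]:
    """Keep records that have an abstract, a title, >=1 author and a journal.

    Returns the filtered corpus and a removal report counting, per missing
    field, how many records lacked it (a record may be counted under several
    reasons). Records missing only their year are retained: year-dependent
    analyses drop them themselves, keeping the filters orthogonal.
    """
    kept = []
    report = {"no_abstract": 0, "no_title": 0, "no_authors": 0, "no_journal": 0}
    for rec in corpus:
        reasons = []
        if not rec.abstract_text:
            reasons.append("no_abstract")
        if not rec.title:
            reasons.append("no_title")
        if not rec.authors:
            reasons.append("no_authors")
        if not rec.journal:
            reasons.append("no_journal")
        if reasons:
            for r in reasons:
                report[r] += 1
        else:
            kept.append(rec)
    return Corpus(records=kept, provenance=corpus.provenance), report
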