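"""Dictionary-based gene mention recognition and synonym normalization.

Gene names in abstracts appear under many synonyms (PTEN and MMAC1 name the
same gene); a dictionary matcher with a curated synonym lexicon normalizes
every surface form to one canonical symbol. Matching is longest-leftmost,
non-overlapping and token-boundary aware. Short synonyms (<= 3 characters)
are matched case-sensitively to curb false hits from acronyms such as "BC"
(breast cancer vs. British Columbia); longer synonyms match
case-insensitively.

Protein names are handled by listing them as synonyms of their gene, so the
matcher stays single-pass.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

from .corpus_io import AbstractRecord, Corpus

#: synonyms at or below this length are matched case-sensitively
CASE_SENSITIVE_MAX_LEN = 3


def _match_key(synonym: str) -> str:
    """The string a synonym is matched under, per the case policy."""
    return synonym if len(synonym) <= CASE_SENSITIVE_MAX_LEN else synonym.lower()


@dataclass
class GeneLexicon:
    """Mapping canonical symbol -> synonyms, with unambiguous match keys.

    ``_key_to_symbol`` maps each match key (case-policy-folded synonym) to
    its single canonical symbol; ambiguous synonyms never enter it.
    """

    entries: dict[str, set[str]]
    _key_to_symbol: dict[str, str] = field(default_factory=dict, repr=False)

    @property
    def symbols(self) -> set[str]:
        return set(self.entries)


def build_lexicon(rows) -> tuple[GeneLexicon, dict[str, list[str]]]:
    """Build a lexicon from ``(canonical_symbol, synonym)`` pairs.

    Every canonical symbol is a synonym of itself. A synonym claimed by two
    or more distinct symbols (under the case policy) is ambiguous: it is
    dropped from the lexicon and listed in the returned ambiguity report
    (match key -> sorted claiming symbols).
    """
    rows = list(rows)
    if not rows:
        raise ValueError("lexicon input is empty")
    entries: dict[str, set[str]] = {}
    claims: dict[str, set[str]] = {}
    for symbol, synonym in rows:
        symbol = symbol.strip()
        synonym = synonym.strip()
        if not symbol or not synonym:
            continue
        entries.setdefault(symbol, set()).add(synonym)
        entries[symbol].add(symbol)
        claims.setdefault(_match_key(synonym), set()).add(symbol)
        claims.setdefault(_match_key(symbol), set()).add(symbol)
    if not entries:
        raise ValueError("lexicon input contains no usable symbol/synonym pairs")
    ambiguous = {k: sorted(v) for k, v in claims.items() if len(v) > 1}
    key_to_symbol = {
        k: next(iter(v)) for k, v in claims.items() if len(v) == 1
    }
    lex = GeneLexicon(entries=entries)
    lex._key_to_symbol = key_to_symbol
    return lex, ambiguous


def read_lexicon_tsv(path) -> tuple[GeneLexicon, dict[str, list[str]]]:
    """Read a 2-column tab-separated (canonical_symbol, synonym) file."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"lexicon line not 2-column TSV: {line!r}")
            rows.append((parts[0], parts[1]))
    return build_lexicon(rows)


@dataclass(frozen=True)
class GeneMention:
    """One matched gene name: character span into title+abstract text."""

    start: int
    end: int
    surface: str
    symbol: str
    field: str  # "title" | "abstract"


@dataclass
class AnnotatedAbstract:
    record: AbstractRecord
    mentions: list[GeneMention] = field(default_factory=list)
    genes: set[str] = field(default_factory=set)
    countries: set[str] = field(default_factory=set)


def full_text(record: AbstractRecord) -> str:
    """Title and abstract concatenated with a newline separator.

    The separator is a token boundary, so no synonym can match across the
    title/abstract join.
    """
    return record.title + "\n" + record.abstract_text


def _candidate_matches(text: str, lexicon: GeneLexicon):
    """All boundary-respecting occurrences of any lexicon synonym."""
    lowered = text.lower()
    out = []
    for key, symbol in lexicon._key_to_symbol.items():
        haystack = text if len(key) <= CASE_SENSITIVE_MAX_LEN else lowered
        # lookaround boundary assertions around the literal synonym
        pattern = re.compile(
            r"(?<![0-9A-Za-z])" + re.escape(key) + r"(?![0-9A-Za-z])"
        )
        for m in pattern.finditer(haystack):
            out.append((m.start(), m.end(), symbol))
    return out


def _select_longest_leftmost(candidates):
    """Greedy longest-leftmost non-overlapping selection.

    Candidates are (start, end, symbol); ties among equal-length overlapping
    matches go to the leftmost, then to the lexicographically smaller symbol
    (reachable only for distinct symbols at the same span, which the
    ambiguity filter already precludes).
    """
    chosen = []
    cursor = -1
    for start, end, symbol in sorted(
        candidates, key=lambda c: (c[0], -(c[1] - c[0]), c[2])
    ):
        if start > cursor:
            chosen.append((start, end, symbol))
            cursor = end - 1
    return chosen


def annotate(record: AbstractRecord, lexicon: GeneLexicon) -> AnnotatedAbstract:
    """Recognize gene mentions in a record's title and abstract.

    Pure function of the text and the lexicon: repeated runs and record
    order cannot change the result.
    """
    text = full_text(record)
    title_len = len(record.title)
    mentions = []
    for start, end, symbol in _select_longest_leftmost(
        _candidate_matches(text, lexicon)
    ):
        mentions.append(
            GeneMention(
                start=start,
                end=end,
                surface=text[start:end],
                symbol=symbol,
                field="title" if end <= title_len else "abstract",
            )
        )
    return AnnotatedAbstract(
        record=record,
        mentions=mentions,
        genes={m.symbol for m in mentions},
    )


def annotate_corpus(corpus: Corpus, lexicon: GeneLexicon) -> list[AnnotatedAbstract]:
    return [annotate(rec, lexicon) for rec in corpus]


def filter_gene_bearing(annotated: list[AnnotatedAbstract]) -> list[AnnotatedAbstract]:
    """Keep exactly the records that mention at least one canonical gene."""
    return [a for a in annotated if a.genes]


# ---------------------------------------------------------------------------
# JSON-lines persistence of annotated corpora (extends the corpus schema)
# ---------------------------------------------------------------------------

def write_annotated_jsonl(annotated: list[AnnotatedAbstract], path) -> None:
    from .corpus_io import _record_to_dict

    with open(path, "w", encoding="utf-8") as fh:
        for ann in annotated:
            obj = _record_to_dict(ann.record)
            obj["genes"] = sorted(ann.genes)
            obj["countries"] = sorted(ann.countries)
            obj["mentions"] = [
                {
                    "start": m.start,
                    "end": m.end,
                    "surface": m.surface,
                    "symbol": m.symbol,
                    "field": m.field,
                }
                for m in ann.mentions
            ]
            fh.write(json.dumps(obj, sort_keys=True) + "\n")


def read_annotated_jsonl(path) -> list[AnnotatedAbstract]:
    from .corpus_io import CorpusFormatError, _record_from_dict

    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"line {lineno}: invalid JSON: {exc}") from exc
            rec = _record_from_dict(obj, lineno)
            mentions = [
                GeneMention(
                    start=m["start"],
                    end=m["end"],
                    surface=m["surface"],
                    symbol=m["symbol"],
                    field=m["field"],
                )
                for m in obj.get("mentions", [])
            ]
            out.append(
                AnnotatedAbstract(
                    record=rec,
                    mentions=mentions,
                    genes=set(obj.get("genes", [])),
                    countries=set(obj.get("countries", [])),
                )
            )
    return out
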