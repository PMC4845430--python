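"""Resolve raw author-affiliation strings to canonical countries.

Affiliation strings are comma-delimited sub-addresses whose rightmost
elements usually carry the country ("TOBB University, Ankara, Turkey").
Resolution starts from the rightmost sub-address and, while the query
matches zero or two-or-more countries in the gazetteer, escalates by
prepending the next sub-address to the left, stopping at exactly one
country. A keyword cache memoizes resolved query strings; it only skips
gazetteer work and can never change a result.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

from .corpus_io import AbstractRecord


class CountryGazetteer:
    """Offline lookup of country names, aliases and keyword hints.

    An alias (or hint keyword) matches a query string by case-insensitive,
    word-boundary-respecting substring containment, so "AB Canada" resolves
    through its "Canada" token without a geocoder.
    """

    def __init__(
        self,
        aliases: dict[str, str],
        hints: dict[str, str] | None = None,
    ) -> None:
        self.aliases = dict(aliases)
        self.hints = dict(hints or {})
        # canonical names are their own aliases
        for canon in set(self.aliases.values()):
            self.aliases.setdefault(canon, canon)
        self.canonical = set(self.aliases.values())
        pairs = set(self.aliases.items()) | set(self.hints.items())
        self._patterns = [
            (self._compile(alias), canon) for alias, canon in sorted(pairs)
        ]
        self._exact: dict[str, set[str]] = {}
        for alias, canon in pairs:
            self._exact.setdefault(alias.lower(), set()).add(canon)

    @staticmethod
    def _compile(alias: str) -> re.Pattern:
        return re.compile(
            r"(?<![0-9A-Za-z])" + re.escape(alias.lower()) + r"(?![0-9A-Za-z])"
        )

    def candidates(self, query: str) -> set[str]:
        """Distinct canonical countries supported by the query.

        A key that equals the whole query is the most specific evidence and
        takes priority (this is what lets escalation shrink an ambiguous
        candidate set: a longer query always keeps all containment matches
        of a shorter one, but may hit a more specific exact key). Otherwise
        every alias/hint contained in the query counts.
        """
        q = query.lower()
        exact = self._exact.get(q)
        if exact:
            return set(exact)
        return {canon for pat, canon in self._patterns if pat.search(q)}

    @classmethod
    def from_tsv(cls, path) -> "CountryGazetteer":
        """Read tab-separated (alias, canonical[, kind]) rows; kind "hint"
        marks city/institution keywords, anything else is an alias."""
        aliases: dict[str, str] = {}
        hints: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"gazetteer line not 2+ column TSV: {line!r}")
                alias, canon = parts[0].strip(), parts[1].strip()
                kind = parts[2].strip() if len(parts) > 2 else "alias"
                target = hints if kind == "hint" else aliases
                if alias in target and target[alias] != canon:
                    raise ValueError(f"alias {alias!r} maps to two countries")
                target[alias] = canon
        return cls(aliases, hints)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for alias, canon in sorted(self.aliases.items()):
                fh.write(f"{alias}\t{canon}\talias\n")
            for alias, canon in sorted(self.hints.items()):
                fh.write(f"{alias}\t{canon}\thint\n")


@dataclass
class ResolutionCache:
    """Memo of resolved query strings; a pure accelerator."""

    entries: dict[str, str] = field(default_factory=dict)
    hits: int = 0
    misses: int = 0

    @classmethod
    def from_tsv(cls, path) -> "ResolutionCache":
        cache = cls()
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                key, canon = line.split("\t")[:2]
                cache.entries[key] = canon
        return cache

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for key, canon in sorted(self.entries.items()):
                fh.write(f"{key}\t{canon}\n")


class ResolutionStatus(str, Enum):
    RESOLVED = "resolved"
    UNRESOLVED = "unresolved"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class CountryResolution:
    status: ResolutionStatus
    country: str | None = None
    consumed_subaddresses: int = 0

    def __post_init__(self) -> None:
        if (self.country is not None) != (self.status is ResolutionStatus.RESOLVED):
            raise ValueError("country present iff status is resolved")


def split_affiliation(raw: str) -> list[str]:
    """Split an affiliation on commas into trimmed, non-empty sub-addresses."""
    return [part.strip() for part in raw.split(",") if part.strip()]


def resolve_country(
    subaddresses: list[str],
    gazetteer: CountryGazetteer,
    cache: ResolutionCache | None = None,
) -> CountryResolution:
    """Rightmost sub-address escalation against the gazetteer.

    The query starts as the rightmost sub-address; while it matches zero or
    >=2 distinct countries the next sub-address to the left is prepended.
    Failure is a status, never an exception.
    """
    last_candidates: set[str] = set()
    for consumed in range(1, len(subaddresses) + 1):
        query = ", ".join(subaddresses[-consumed:])
        if cache is not None and query in cache.entries:
            cache.hits += 1
            return CountryResolution(
                ResolutionStatus.RESOLVED, cache.entries[query], consumed
            )
        if cache is not None:
            cache.misses += 1
        last_candidates = gazetteer.candidates(query)
        if len(last_candidates) == 1:
            country = next(iter(last_candidates))
            if cache is not None:
                cache.entries[query] = country
            return CountryResolution(ResolutionStatus.RESOLVED, country, consumed)
    status = (
        ResolutionStatus.AMBIGUOUS if len(last_candidates) >= 2
        else ResolutionStatus.UNRESOLVED
    )
    return CountryResolution(status, None, len(subaddresses))


def countries_of(
    record: AbstractRecord,
    gazetteer: CountryGazetteer,
    cache: ResolutionCache | None = None,
) -> set[str]:
    """Union of resolved countries over all affiliations of all authors.

    Unresolved or ambiguous affiliations contribute nothing.
    """
    found: set[str] = set()
    for author in record.authors:
        for raw in author.affiliations:
            res = resolve_country(split_affiliation(raw), gazetteer, cache)
            if res.status is ResolutionStatus.RESOLVED:
                found.add(res.country)
    return found


def resolve_corpus(annotated, gazetteer, cache=None):
    """Fill the ``countries`` set of every annotated abstract in place."""
    for ann in annotated:
        ann.countries = countries_of(ann.record, gazetteer, cache)
    return annotated
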