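"""Count-based statistics over an annotated, geo-resolved corpus.

Gene mention counting is per-abstract binary presence: a gene mentioned
five times in one abstract counts once, matching "number of abstracts which
mentioned the gene". Multi-country papers count fully toward each
affiliated country (no fractional attribution). Records whose country set
is empty are kept in a reserved ``(unresolved)`` row so that totals remain
checkable, but that row is excluded from effort and rankings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .gene_annotation import AnnotatedAbstract

#: reserved row label for records with no resolved country
UNRESOLVED = "(unresolved)"


@dataclass
class GeneCountryCounts:
    """country x gene abstract counts plus per-country / per-gene margins.

    ``matrix[c, g]`` = number of abstracts affiliated with country ``c``
    that mention gene ``g``; ``row_margin[c]`` = abstracts affiliated with
    ``c`` (mentioning any gene or none); ``col_margin[g]`` = abstracts
    mentioning ``g`` (counted once per abstract, regardless of countries).
    """

    matrix: pd.DataFrame
    row_margin: pd.Series
    col_margin: pd.Series

    def to_tidy(self) -> pd.DataFrame:
        tidy = self.matrix.stack().rename("count").reset_index()
        tidy.columns = ["country", "gene", "count"]
        return tidy[tidy["count"] > 0].reset_index(drop=True)


def gene_country_counts(annotated: list[AnnotatedAbstract]) -> GeneCountryCounts:
    """Cross-tabulate abstracts by country and gene.

    A record with countries {A, B} and genes {g} increments cells (A, g)
    and (B, g) once each.
    """
    countries = sorted({c for a in annotated for c in a.countries})
    genes = sorted({g for a in annotated for g in a.genes})
    rows = countries + [UNRESOLVED]
    matrix = pd.DataFrame(0, index=rows, columns=genes, dtype=int)
    row_margin = pd.Series(0, index=rows, dtype=int)
    col_margin = pd.Series(0, index=genes, dtype=int)
    for ann in annotated:
        record_rows = sorted(ann.countries) if ann.countries else [UNRESOLVED]
        for c in record_rows:
            row_margin[c] += 1
            for g in ann.genes:
                matrix.loc[c, g] += 1
        for g in ann.genes:
            col_margin[g] += 1
    return GeneCountryCounts(matrix=matrix, row_margin=row_margin, col_margin=col_margin)


def effort(counts: GeneCountryCounts) -> pd.DataFrame:
    """Fraction of a country's papers that mention each gene.

    effort(X, Y) = abstracts from X mentioning Y / papers from X. Rows need
    not sum to 1: an abstract mentioning several genes contributes to each
    of them, so a row sums to the mean number of distinct genes per paper.
    The unresolved row and countries with zero papers are excluded.
    """
    matrix = counts.matrix.drop(index=UNRESOLVED, errors="ignore")
    margin = counts.row_margin.drop(index=UNRESOLVED, errors="ignore")
    zero = margin[margin == 0].index
    if len(zero):
        warnings.warn(
            f"excluding countries with zero papers: {sorted(zero)}", stacklevel=2
        )
        matrix = matrix.drop(index=zero)
        margin = margin.drop(index=zero)
    return matrix.div(margin, axis=0)


@dataclass
class CollaborationCounts:
    """Symmetric unordered-country-pair -> number of co-affiliated papers."""

    pairs: dict[frozenset, int]

    def get(self, a: str, b: str) -> int:
        if a == b:
            return 0
        return self.pairs.get(frozenset((a, b)), 0)

    def to_tidy(self) -> pd.DataFrame:
        rows = [
            {"country_a": min(p), "country_b": max(p), "papers": n}
            for p, n in self.pairs.items()
        ]
        return (
            pd.DataFrame(rows, columns=["country_a", "country_b", "papers"])
            .sort_values(["country_a", "country_b"])
            .reset_index(drop=True)
        )


def collaborations(annotated: list[AnnotatedAbstract]) -> CollaborationCounts:
    """A paper affiliated with countries S (|S| >= 2) increments every
    unordered pair from S by one."""
    pairs: dict[frozenset, int] = {}
    for ann in annotated:
        for a, b in combinations(sorted(ann.countries), 2):
            key = frozenset((a, b))
            pairs[key] = pairs.get(key, 0) + 1
    return CollaborationCounts(pairs=pairs)


def top_k(counts: GeneCountryCounts, axis: str, k: int) -> list[tuple[str, int]]:
    """Top-k countries (by papers) or genes (by mentioning abstracts).

    Descending by count; ties broken lexicographically by label. The
    unresolved row never ranks.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if axis == "country":
        margin = counts.row_margin.drop(index=UNRESOLVED, errors="ignore")
    elif axis == "gene":
        margin = counts.col_margin
    else:
        raise ValueError(f"axis must be 'country' or 'gene', got {axis!r}")
    if k > len(margin):
        warnings.warn(
            f"k={k} exceeds axis size {len(margin)}; returning all", stacklevel=2
        )
        k = len(margin)
    ranked = sorted(margin.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]


def unmentioned_by(counts: GeneCountryCounts, countries: set[str]) -> set[str]:
    """Genes mentioned somewhere in the corpus but in none of the abstracts
    of the given countries."""
    unknown = set(countries) - set(counts.matrix.index)
    if unknown:
        raise ValueError(f"countries not in counts: {sorted(unknown)}")
    mentioned_total = counts.col_margin > 0
    if countries:
        over_rows = counts.matrix.loc[sorted(countries)].sum(axis=0)
    else:
        over_rows = pd.Series(0, index=counts.matrix.columns)
    return set(counts.matrix.columns[(over_rows == 0) & mentioned_total])
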