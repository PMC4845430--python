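"""Frequent gene itemset mining over country and year transactions.

A transaction is the set of all genes attributed to one country (or one
publication year); support of an itemset is the percentage of transactions
containing it. Two miners are provided:

* :func:`mine_frequent` enumerates every frequent itemset (Eclat-style
  depth-first search over vertical tid-sets). Exact but exponential on
  dense databases, so intended for small inputs and oracle checking.
* :func:`mine_closed` enumerates only the closed frequent itemsets
  (LCM-style closure extension), which stays small even when transactions
  are near-identical; closed itemsets determine all supports, and the
  maximal itemsets are exactly the closed ones without frequent closed
  supersets.

An itemset is maximal if no proper superset is frequent, and closed if no
proper superset has equal support.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal

import pandas as pd

from .gene_annotation import AnnotatedAbstract


@dataclass
class TransactionDB:
    """Transactions (id -> item set); ids unique, item sets non-empty."""

    transactions: list[tuple[str, frozenset]]

    def __post_init__(self) -> None:
        ids = [tid for tid, _ in self.transactions]
        if len(ids) != len(set(ids)):
            raise ValueError("transaction ids must be unique")
        for tid, items in self.transactions:
            if not items:
                raise ValueError(f"transaction {tid!r} has an empty item set")

    @property
    def n(self) -> int:
        return len(self.transactions)

    @property
    def items(self) -> set:
        out: set = set()
        for _, items in self.transactions:
            out |= items
        return out

    def to_basket(self, path) -> None:
        """One transaction per line: id TAB comma-joined sorted items."""
        with open(path, "w", encoding="utf-8") as fh:
            for tid, items in self.transactions:
                fh.write(f"{tid}\t{','.join(sorted(items))}\n")

    @classmethod
    def from_basket(cls, path) -> "TransactionDB":
        txns = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                tid, items = line.split("\t", 1)
                txns.append((tid, frozenset(i for i in items.split(",") if i)))
        return cls(transactions=txns)


def build_country_transactions(annotated: list[AnnotatedAbstract]) -> TransactionDB:
    """One transaction per resolved country: the union of genes over its
    abstracts. Countries whose abstracts carry no genes are dropped (item
    sets must be non-empty)."""
    per_country: dict[str, set] = {}
    for ann in annotated:
        for c in ann.countries:
            per_country.setdefault(c, set()).update(ann.genes)
    return TransactionDB(
        transactions=[
            (c, frozenset(genes))
            for c, genes in sorted(per_country.items())
            if genes
        ]
    )


def build_year_transactions(
    annotated: list[AnnotatedAbstract],
) -> tuple[TransactionDB, int]:
    """One transaction per distinct publication year; returns the database
    and the number of year-less records skipped."""
    per_year: dict[int, set] = {}
    skipped = 0
    for ann in annotated:
        year = ann.record.year
        if year is None:
            skipped += 1
            continue
        per_year.setdefault(year, set()).update(ann.genes)
    db = TransactionDB(
        transactions=[
            (str(y), frozenset(genes))
            for y, genes in sorted(per_year.items())
            if genes
        ]
    )
    return db, skipped


def support_pct(count: int, n: int) -> float:
    """100*count/n, rounded half-even to 2 decimals."""
    if n <= 0:
        raise ValueError("n must be > 0")
    if not 0 <= count <= n:
        raise ValueError("count must lie in [0, n]")
    return float(
        (Decimal(100 * count) / Decimal(n)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_EVEN
        )
    )


@dataclass
class MinedItemset:
    items: tuple  # sorted gene symbols
    support_count: int
    support_pct: float
    closed: bool = False
    maximal: bool = False

    @property
    def itemset(self) -> frozenset:
        return frozenset(self.items)


def _min_count(min_support_pct: float, n: int) -> int:
    """Smallest integer count whose exact percentage reaches the threshold."""
    if not 0 < min_support_pct <= 100:
        raise ValueError("min_support_pct must be in (0, 100]")
    count = 0
    while 100.0 * count / n < min_support_pct - 1e-9:
        count += 1
    return max(count, 1)


def mine_frequent(db: TransactionDB, min_support_pct: float) -> list[MinedItemset]:
    """All itemsets whose support percentage meets the threshold.

    Depth-first search over vertical tid-sets with anti-monotone pruning;
    output sorted by (-support, cardinality, items).
    """
    if db.n == 0:
        return []
    min_count = _min_count(min_support_pct, db.n)
    tidsets: dict[str, set[int]] = {}
    for idx, (_, items) in enumerate(db.transactions):
        for item in items:
            tidsets.setdefault(item, set()).add(idx)
    items = sorted(i for i, t in tidsets.items() if len(t) >= min_count)
    found: list[MinedItemset] = []

    def dfs(prefix: tuple, prefix_tids: set[int], start: int) -> None:
        for pos in range(start, len(items)):
            item = items[pos]
            tids = prefix_tids & tidsets[item] if prefix else tidsets[item]
            if len(tids) >= min_count:
                itemset = prefix + (item,)
                found.append(
                    MinedItemset(
                        items=itemset,
                        support_count=len(tids),
                        support_pct=support_pct(len(tids), db.n),
                    )
                )
                dfs(itemset, tids, pos + 1)

    dfs((), set(range(db.n)), 0)
    return sort_itemsets(found)


def mine_closed(db: TransactionDB, min_support_pct: float) -> list[MinedItemset]:
    """Closed frequent itemsets only, with closed/maximal flags set.

    Closure-based search: each candidate is extended to the intersection of
    its supporting transactions; duplicate closures are visited once.
    Tractable on dense databases where full enumeration explodes.
    """
    if db.n == 0:
        return []
    min_count = _min_count(min_support_pct, db.n)
    tidsets: dict[str, set[int]] = {}
    for idx, (_, items) in enumerate(db.transactions):
        for item in items:
            tidsets.setdefault(item, set()).add(idx)
    txn_items = [items for _, items in db.transactions]

    def closure(tids: set[int]) -> frozenset:
        it = iter(tids)
        out = set(txn_items[next(it)])
        for idx in it:
            out &= txn_items[idx]
        return frozenset(out)

    closed: dict[frozenset, int] = {}
    stack: list[set[int]] = []
    # seeds: closures of each frequent single item
    for item, tids in tidsets.items():
        if len(tids) >= min_count:
            stack.append(tids)
    seen_tids: set[frozenset] = set()
    while stack:
        tids = stack.pop()
        key = frozenset(tids)
        if key in seen_tids:
            continue
        seen_tids.add(key)
        clo = closure(tids)
        closed[clo] = len(tids)
        # extend with any frequent item outside the closure
        for item, item_tids in tidsets.items():
            if item in clo:
                continue
            new_tids = tids & item_tids
            if len(new_tids) >= min_count and frozenset(new_tids) not in seen_tids:
                stack.append(new_tids)
    result = []
    for itemset, count in closed.items():
        maximal = not any(
            itemset < other for other in closed if other is not itemset
        )
        result.append(
            MinedItemset(
                items=tuple(sorted(itemset)),
                support_count=count,
                support_pct=support_pct(count, db.n),
                closed=True,
                maximal=maximal,
            )
        )
    return sort_itemsets(result)


def filter_closed_maximal(itemsets: list[MinedItemset]) -> list[MinedItemset]:
    """Set closed/maximal flags on a complete frequent collection.

    Closed: no proper superset with equal support (a superset of a frequent
    itemset with equal support is itself frequent, so searching within the
    collection is exhaustive). Maximal: no frequent proper superset.
    """
    out = []
    for it in itemsets:
        supersets = [
            o for o in itemsets if it.itemset < o.itemset
        ]
        closed = not any(o.support_count == it.support_count for o in supersets)
        maximal = not supersets
        out.append(
            MinedItemset(
                items=it.items,
                support_count=it.support_count,
                support_pct=it.support_pct,
                closed=closed,
                maximal=maximal,
            )
        )
    return sort_itemsets(out)


def sort_itemsets(itemsets: list[MinedItemset]) -> list[MinedItemset]:
    """Descending support; ties by smaller cardinality, then lexicographic."""
    return sorted(
        itemsets, key=lambda it: (-it.support_count, len(it.items), it.items)
    )


def itemsets_to_frame(itemsets: list[MinedItemset]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "items": ",".join(it.items),
                "support_count": it.support_count,
                "support_pct": it.support_pct,
                "closed": it.closed,
                "maximal": it.maximal,
            }
            for it in itemsets
        ],
        columns=["items", "support_count", "support_pct", "closed", "maximal"],
    )
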