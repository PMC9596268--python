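"""Frequent-itemset mining by the Apriori algorithm.

Level-wise search: frequent k-itemsets are joined into (k+1)-candidates,
candidates with an infrequent k-subset are pruned (downward closure), and
survivors are counted against the database.  Support thresholds are applied
on exact integer counts — an itemset is frequent iff

    support_count >= ceil(min_support * N)

with the ceiling taken in rational arithmetic, never on rounded floats.
With N = 33 and min_support = 0.24 the threshold count is 8 (0.24*33 = 7.92).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .prescriptions import TransactionDB


def as_fraction(x: float | Fraction) -> Fraction:
    """Interpret a threshold as the decimal the caller wrote (0.24 -> 24/100)."""
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    return Fraction(str(float(x)))


@dataclass(frozen=True)
class Itemset:
    """An item combination with its exact support count in a database of size N."""

    items: frozenset[str]
    support_count: int
    n_transactions: int

    @property
    def support(self) -> Fraction:
        return Fraction(self.support_count, self.n_transactions)

    def sort_key(self) -> tuple:
        return (len(self.items), -self.support_count, tuple(sorted(self.items)))


@dataclass(frozen=True)
class MiningConfig:
    """Mining thresholds.

    Defaults are the analysis' reporting thresholds: minimum support 24%,
    minimum confidence 75%, top 10 rules.  Thresholds are inclusive.
    """

    min_support: float | Fraction = 0.24
    min_confidence: float | Fraction = 0.75
    max_len: int | None = None
    top_k_rules: int = 10

    def __post_init__(self) -> None:
        for name in ("min_support", "min_confidence"):
            v = as_fraction(getattr(self, name))
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {getattr(self, name)}")
        if self.max_len is not None and self.max_len < 1:
            raise ValueError(f"max_len must be >= 1, got {self.max_len}")


def min_count(min_support: float | Fraction, n: int) -> int:
    """Smallest integer support count c with c/n >= min_support."""
    return max(1, math.ceil(as_fraction(min_support) * n))


def support_count(db: TransactionDB, items: Iterable[str]) -> int:
    """Number of transactions containing every item of *items*."""
    itemset = frozenset(items)
    if not itemset:
        raise ValueError("empty itemset has no support count")
    return sum(1 for p in db.prescriptions if itemset <= p.items)


def generate_candidates(
    frequent_k: Sequence[frozenset[str]],
) -> list[frozenset[str]]:
    """Classical Apriori join + prune step.

    Joins pairs of frequent k-itemsets sharing k-1 items into (k+1)-candidates
    and prunes any candidate with an infrequent k-subset.  Output is
    duplicate-free, in sorted-tuple order.
    """
    frequent_k = list(frequent_k)
    if not frequent_k:
        return []
    sizes = {len(s) for s in frequent_k}
    if len(sizes) != 1:
        raise ValueError(f"mixed itemset sizes in candidate generation: {sorted(sizes)}")
    k = sizes.pop()
    frequent_set = set(frequent_k)
    # join on sorted-tuple prefixes: two k-itemsets sharing their first k-1 items
    sorted_tuples = sorted(tuple(sorted(s)) for s in frequent_set)
    candidates: list[frozenset[str]] = []
    for i, a in enumerate(sorted_tuples):
        for b in sorted_tuples[i + 1 :]:
            if a[: k - 1] != b[: k - 1]:
                break
            cand = frozenset(a) | frozenset(b)
            if all(
                frozenset(sub) in frequent_set for sub in combinations(sorted(cand), k)
            ):
                candidates.append(cand)
    return sorted(candidates, key=lambda s: tuple(sorted(s)))


def mine_frequent(
    db: TransactionDB, config: MiningConfig | None = None
) -> list[Itemset]:
    """All itemsets with support >= min_support (inclusive), sizes 1..max_len.

    Sorted by (size, descending support, lexicographic items).
    """
    config = config or MiningConfig()
    n = db.N
    threshold = min_count(config.min_support, n)
    transactions = db.itemsets()

    counts: dict[str, int] = {}
    for t in transactions:
        for item in t:
            counts[item] = counts.get(item, 0) + 1
    frequent: list[Itemset] = [
        Itemset(frozenset([item]), c, n)
        for item, c in counts.items()
        if c >= threshold
    ]
    level = [s.items for s in frequent]
    k = 1
    while level and (config.max_len is None or k < config.max_len):
        candidates = generate_candidates(level)
        next_level: list[Itemset] = []
        for cand in candidates:
            c = sum(1 for t in transactions if cand <= t)
            if c >= threshold:
                next_level.append(Itemset(cand, c, n))
        frequent.extend(next_level)
        level = [s.items for s in next_level]
        k += 1
    return sorted(frequent, key=Itemset.sort_key)


def itemset_table(itemsets: Sequence[Itemset], precision: int = 3) -> pd.DataFrame:
    """Report table: ``items`` (semicolon-joined, sorted), ``count``, ``support``."""
    return pd.DataFrame(
        {
            "items": [";".join(sorted(s.items)) for s in itemsets],
            "count": [s.support_count for s in itemsets],
            "support": [round(float(s.support), precision) for s in itemsets],
        }
    )


def write_itemset_tsv(
    itemsets: Sequence[Itemset], path: str | Path, precision: int = 3
) -> None:
    itemset_table(itemsets, precision).to_csv(path, sep="\t", index=False)
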