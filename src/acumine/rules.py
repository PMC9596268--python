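"""Association rules and their four kernel metrics.

A rule LHS => RHS (antecedent => consequent) over a transaction database is
scored by:

* support              = support(LHS u RHS)
* confidence           = support(LHS u RHS) / support(LHS)
* expected confidence  = support(RHS), the confidence expected if the
                         antecedent were independent of the consequent
* lift                 = confidence / expected confidence

All metrics are kept as exact rationals internally; rounding (half-up on the
exact fraction, so printed values never suffer binary-float boundary errors)
happens only in report tables.  Report precision follows the analysis'
convention: support/confidence/lift to 3 decimals, expected confidence to 2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import pandas as pd

from .apriori import Itemset, MiningConfig, as_fraction, support_count
from .prescriptions import TransactionDB


def round_frac(x: Fraction, ndigits: int) -> float:
    """Round an exact rational half-up to *ndigits* decimals."""
    scale = 10**ndigits
    return float((x * scale + Fraction(1, 2)).__floor__()) / scale


@dataclass(frozen=True)
class AssociationRule:
    """LHS => RHS with exact counts; metrics are derived rational properties."""

    lhs: frozenset[str]
    rhs: frozenset[str]
    joint_count: int       # support count of LHS u RHS
    lhs_count: int
    rhs_count: int
    n_transactions: int

    @property
    def support(self) -> Fraction:
        return Fraction(self.joint_count, self.n_transactions)

    @property
    def confidence(self) -> Fraction:
        return Fraction(self.joint_count, self.lhs_count)

    @property
    def expected_confidence(self) -> Fraction:
        return Fraction(self.rhs_count, self.n_transactions)

    @property
    def lift(self) -> Fraction:
        if self.rhs_count == 0:
            return Fraction(0)
        return self.confidence / self.expected_confidence

    def sort_key(self) -> tuple:
        """Ranking order: descending support, confidence, lift; then lexicographic."""
        return (
            -self.support,
            -self.confidence,
            -self.lift,
            tuple(sorted(self.lhs)),
            tuple(sorted(self.rhs)),
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return "{%s} => {%s}" % (
            ", ".join(sorted(self.lhs)),
            ", ".join(sorted(self.rhs)),
        )


def compute_metrics(
    db: TransactionDB, lhs: Sequence[str] | frozenset[str], rhs: Sequence[str] | frozenset[str]
) -> AssociationRule:
    """Score one rule directly against the database."""
    lhs_set, rhs_set = frozenset(lhs), frozenset(rhs)
    if not lhs_set or not rhs_set:
        raise ValueError("antecedent and consequent must be non-empty")
    if lhs_set & rhs_set:
        raise ValueError(f"antecedent and consequent overlap: {sorted(lhs_set & rhs_set)}")
    lhs_count = support_count(db, lhs_set)
    if lhs_count == 0:
        raise ValueError("antecedent never occurs; confidence undefined")
    return AssociationRule(
        lhs_set,
        rhs_set,
        joint_count=support_count(db, lhs_set | rhs_set),
        lhs_count=lhs_count,
        rhs_count=support_count(db, rhs_set),
        n_transactions=db.N,
    )


def generate_rules(
    frequent: Sequence[Itemset],
    db: TransactionDB,
    config: MiningConfig | None = None,
    *,
    max_rhs_len: int | None = None,
    min_lift: float | Fraction | None = None,
) -> list[AssociationRule]:
    """All rules L => Z\\L over frequent itemsets Z with confidence >= threshold.

    Every non-empty proper subset of each frequent itemset of size >= 2 is
    tried as the antecedent.  Supports are looked up from the frequent list
    (downward closure guarantees every subset is there).  *max_rhs_len*
    optionally restricts consequent size (single-consequent output matches
    the classical R ``arules`` behaviour); *min_lift* optionally drops
    low-lift rules.
    """
    config = config or MiningConfig()
    min_conf = as_fraction(config.min_confidence)
    lookup = {s.items: s.support_count for s in frequent}
    n = db.N
    rules: list[AssociationRule] = []
    for itemset in frequent:
        if len(itemset.items) < 2:
            continue
        members = sorted(itemset.items)
        # iterate proper subsets via bitmask
        for mask in range(1, 2 ** len(members) - 1):
            lhs = frozenset(m for i, m in enumerate(members) if mask >> i & 1)
            rhs = itemset.items - lhs
            if max_rhs_len is not None and len(rhs) > max_rhs_len:
                continue
            rule = AssociationRule(
                lhs,
                rhs,
                joint_count=itemset.support_count,
                lhs_count=lookup[lhs],
                rhs_count=lookup[rhs],
                n_transactions=n,
            )
            if rule.confidence < min_conf:
                continue
            if min_lift is not None and rule.lift < as_fraction(min_lift):
                continue
            rules.append(rule)
    return sorted(rules, key=AssociationRule.sort_key)


def rank_rules(rules: Sequence[AssociationRule], k: int) -> list[AssociationRule]:
    """Top-k rules by (descending support, confidence, lift), stable ties."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return sorted(rules, key=AssociationRule.sort_key)[:k]


def rules_table(
    rules: Sequence[AssociationRule],
    precision: int = 3,
    expected_confidence_precision: int = 2,
) -> pd.DataFrame:
    """Report table in the conventional column order.

    ``lhs``/``rhs`` are semicolon-joined sorted item lists; metrics rounded
    half-up on the exact rationals.
    """
    return pd.DataFrame(
        {
            "lhs": [";".join(sorted(r.lhs)) for r in rules],
            "rhs": [";".join(sorted(r.rhs)) for r in rules],
            "support": [round_frac(r.support, precision) for r in rules],
            "confidence": [round_frac(r.confidence, precision) for r in rules],
            "expected_confidence": [
                round_frac(r.expected_confidence, expected_confidence_precision)
                for r in rules
            ],
            "lift": [round_frac(r.lift, precision) for r in rules],
        }
    )


def write_rules_tsv(
    rules: Sequence[AssociationRule], path: str | Path, precision: int = 3
) -> None:
    rules_table(rules, precision).to_csv(path, sep="\t", index=False)


def rules_to_json(rules: Sequence[AssociationRule], path: str | Path) -> None:
    """Exact-rational export: each metric as a [numerator, denominator] pair."""

    def pair(x: Fraction) -> list[int]:
        return [x.numerator, x.denominator]

    records = [
        {
            "lhs": sorted(r.lhs),
            "rhs": sorted(r.rhs),
            "support": pair(r.support),
            "confidence": pair(r.confidence),
            "expected_confidence": pair(r.expected_confidence),
            "lift": pair(r.lift),
        }
        for r in rules
    ]
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1)
        fh.write("\n")
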