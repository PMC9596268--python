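"""Acupoint frequency profiling.

Counts, for each acupoint in the universe, the number of transactions
(prescriptions) that contain it; the proportion is the count divided by the
number of transactions N.  Proportions do not sum to one because acupoints
co-occur within prescriptions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .prescriptions import TransactionDB


@dataclass(frozen=True)
class FrequencyRecord:
    item: str
    count: int
    proportion: float


def item_counts(db: TransactionDB) -> list[FrequencyRecord]:
    """Per-item transaction counts, sorted by descending count then code.

    The lexicographic tie-break makes the order deterministic and invariant
    to transaction permutation.
    """
    counts: dict[str, int] = {item: 0 for item in db.universe}
    for p in db.prescriptions:
        for item in p.items:
            counts[item] += 1
    n = db.N
    records = [
        FrequencyRecord(item, c, c / n)
        for item, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return records


def top_k(records: list[FrequencyRecord], k: int) -> list[FrequencyRecord]:
    """First *k* records of a frequency list (all records if k exceeds it)."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return records[:k]


def frequency_table(records: list[FrequencyRecord], precision: int = 3) -> pd.DataFrame:
    """Report table with columns ``item``, ``count``, ``proportion``."""
    return pd.DataFrame(
        {
            "item": [r.item for r in records],
            "count": [r.count for r in records],
            "proportion": [round(r.proportion, precision) for r in records],
        }
    )


def write_frequency_tsv(
    records: list[FrequencyRecord], path: str | Path, precision: int = 3
) -> None:
    frequency_table(records, precision).to_csv(path, sep="\t", index=False)
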