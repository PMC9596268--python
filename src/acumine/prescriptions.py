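"""Data model and I/O for acupoint prescriptions.

A *prescription* (or formula) is the set of acupoints used together in one
treatment arm of a clinical trial, identified by codes in the WHO standard
nomenclature: a meridian prefix plus a point number, e.g. ``ST36`` (Zusanli,
Stomach meridian) or ``RN12`` (Zhongwan, Conception Vessel).  For mining
purposes a prescription is a *transaction* and an acupoint is an *item*.

Codes are opaque tokens: they are validated against the lexical pattern and
uppercased, but no nomenclature aliasing (e.g. RN vs CV for the Conception
Vessel) is attempted.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Lexical form of an acupoint code after normalization.
CODE_PATTERN = re.compile(r"^[A-Z]{2,3}[0-9]{1,2}$")


class TransactionError(ValueError):
    """Raised for malformed or inconsistent transaction input."""


def normalize_code(token: str) -> str:
    """Normalize an acupoint code: strip whitespace, uppercase, validate.

    Raises :class:`TransactionError` if the result does not match
    ``[A-Z]{2,3}[0-9]{1,2}``.
    """
    code = str(token).strip().upper()
    if not CODE_PATTERN.match(code):
        raise TransactionError(f"malformed acupoint code: {token!r}")
    return code


@dataclass(frozen=True)
class Prescription:
    """One acupoint formula: an identifier, its source study, and an item set."""

    prescription_id: str
    study_id: str
    items: frozenset[str]

    def __post_init__(self) -> None:
        if not self.items:
            raise TransactionError(
                f"prescription {self.prescription_id!r} has no items"
            )

    @classmethod
    def from_tokens(
        cls, prescription_id: str, study_id: str, tokens: Iterable[str]
    ) -> "Prescription":
        """Build a prescription from raw code tokens (normalized, deduplicated)."""
        codes: list[str] = []
        for tok in tokens:
            if not str(tok).strip():
                continue
            codes.append(normalize_code(tok))
        if len(set(codes)) < len(codes):
            logger.warning(
                "prescription %s: duplicate items deduplicated", prescription_id
            )
        return cls(prescription_id, study_id, frozenset(codes))


@dataclass(frozen=True)
class TransactionDB:
    """An ordered collection of prescriptions over a shared item universe.

    Order is preserved for reproducible I/O but carries no meaning: all
    mining results are invariant to permutation of the prescriptions.
    """

    prescriptions: tuple[Prescription, ...]

    def __post_init__(self) -> None:
        if not self.prescriptions:
            raise TransactionError("no transactions")
        seen: set[str] = set()
        for p in self.prescriptions:
            if p.prescription_id in seen:
                raise TransactionError(
                    f"duplicate prescription_id: {p.prescription_id!r}"
                )
            seen.add(p.prescription_id)

    @property
    def N(self) -> int:
        return len(self.prescriptions)

    @property
    def universe(self) -> tuple[str, ...]:
        """Sorted union of all item codes."""
        items: set[str] = set()
        for p in self.prescriptions:
            items |= p.items
        return tuple(sorted(items))

    def itemsets(self) -> list[frozenset[str]]:
        """Item sets in transaction order (convenience for mining code)."""
        return [p.items for p in self.prescriptions]


def _read_rows(rows: Iterable[dict], source: str) -> TransactionDB:
    prescriptions = []
    for i, row in enumerate(rows, start=1):
        try:
            pid = str(row["prescription_id"]).strip()
            sid = str(row["study_id"]).strip()
            items = row["items"]
        except (KeyError, TypeError) as exc:
            raise TransactionError(f"{source}: row {i} missing field: {exc}") from exc
        if isinstance(items, str):
            tokens: Sequence[str] = items.split(";")
        else:
            tokens = list(items)
        try:
            prescriptions.append(Prescription.from_tokens(pid, sid, tokens))
        except TransactionError as exc:
            raise TransactionError(f"{source}: row {i} ({pid!r}): {exc}") from exc
    if not prescriptions:
        raise TransactionError(f"{source}: no transactions")
    return TransactionDB(tuple(prescriptions))


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    return "json" if suffix == "json" else "csv"


def read_transactions(path: str | Path, fmt: str | None = None) -> TransactionDB:
    """Read a transaction database from CSV or JSON.

    CSV: header ``prescription_id,study_id,items`` with the items field a
    semicolon-separated code list.  JSON: an array of objects with the same
    keys, items as an array of strings.  The format is inferred from the file
    suffix unless *fmt* is given.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "json":
        with open(path) as fh:
            data = json.load(fh)
        if not isinstance(data, list):
            raise TransactionError(f"{path}: expected a JSON array of records")
        return _read_rows(data, str(path))
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        return _read_rows(reader, str(path))


def write_transactions(
    db: TransactionDB, path: str | Path, fmt: str | None = None
) -> None:
    """Write a transaction database; ``read(write(db))`` round-trips exactly.

    Item sets are serialized in sorted order.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "json":
        records = [
            {
                "prescription_id": p.prescription_id,
                "study_id": p.study_id,
                "items": sorted(p.items),
            }
            for p in db.prescriptions
        ]
        with open(path, "w") as fh:
            json.dump(records, fh, indent=1)
            fh.write("\n")
        return
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["prescription_id", "study_id", "items"])
        for p in db.prescriptions:
            writer.writerow([p.prescription_id, p.study_id, ";".join(sorted(p.items))])


def to_binary_matrix(db: TransactionDB) -> pd.DataFrame:
    """One-hot incidence matrix: N rows (prescriptions) x |universe| columns.

    Entry (i, j) is 1 iff prescription i contains universe item j, so row
    sums are prescription sizes and column sums are item support counts.
    """
    universe = db.universe
    index = [p.prescription_id for p in db.prescriptions]
    data = [
        [1 if item in p.items else 0 for item in universe] for p in db.prescriptions
    ]
    return pd.DataFrame(data, index=index, columns=list(universe), dtype=int)
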