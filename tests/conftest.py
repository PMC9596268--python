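"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from acumine import fixture as fixture_mod
from acumine.apriori import min_count
from acumine.prescriptions import Prescription, TransactionDB


def make_db(itemsets, ids=None, studies=None) -> TransactionDB:
    """Build a TransactionDB from bare item collections."""
    itemsets = list(itemsets)
    ids = ids or [f"p{i + 1}" for i in range(len(itemsets))]
    studies = studies or [f"s{i + 1}" for i in range(len(itemsets))]
    return TransactionDB(
        tuple(
            Prescription(pid, sid, frozenset(items))
            for pid, sid, items in zip(ids, studies, itemsets)
        )
    )


def random_db(rng: np.random.Generator, n_items=8, n_tx=12, p=0.4) -> TransactionDB:
    """Random transaction database; empty transactions get one random item."""
    items = [f"IT{i + 1}" for i in range(n_items)]
    sets = []
    for _ in range(n_tx):
        s = {it for it in items if rng.random() < p}
        if not s:
            s = {items[rng.integers(n_items)]}
        sets.append(s)
    return make_db(sets)


def enumerate_frequent(db: TransactionDB, min_support) -> dict[frozenset, int]:
    """Oracle frequent-itemset miner: tally every subset of every transaction.

    Independent of both Apriori and FP-growth: exact support counts come
    from direct subset enumeration, feasible for the small DBs used in tests.
    """
    counts: dict[frozenset, int] = {}
    for t in db.itemsets():
        members = sorted(t)
        for r in range(1, len(members) + 1):
            for combo in combinations(members, r):
                key = frozenset(combo)
                counts[key] = counts.get(key, 0) + 1
    threshold = min_count(min_support, db.N)
    return {k: v for k, v in counts.items() if v >= threshold}


def naive_agglomerate_heights(dist: np.ndarray, linkage: str) -> list[float]:
    """O(n^3) reference agglomeration; returns the merge heights in order.

    Linkage values are recomputed from the original pairwise distances at
    every step (no Lance-Williams update), so this is an independent check
    of the clustering implementation.
    """
    n = dist.shape[0]
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    active = list(range(n))
    next_id = n
    heights: list[float] = []

    def linkage_value(a: int, b: int) -> float:
        vals = [dist[i, j] for i in clusters[a] for j in clusters[b]]
        if linkage == "average":
            return float(np.mean(vals))
        if linkage == "complete":
            return float(np.max(vals))
        return float(np.min(vals))

    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                v = linkage_value(active[ai], active[bi])
                if best is None or v < best[0]:
                    best = (v, active[ai], active[bi])
        h, a, b = best
        heights.append(h)
        clusters[next_id] = clusters[a] + clusters[b]
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1
    return heights


@pytest.fixture(scope="session")
def constraint_set():
    return fixture_mod.ca_constraints()


@pytest.fixture(scope="session")
def fixture_db(constraint_set):
    db = fixture_mod.solve(constraint_set, fixture_mod.DEFAULT_SEED)
    assert fixture_mod.verify(db, constraint_set).ok
    return db
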