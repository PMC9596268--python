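"""Frequent-pattern mining with FP-growth.

An FP-tree compresses the database into a prefix tree whose paths are
transactions restricted to frequent items and sorted by descending item
frequency (ties broken lexicographically).  Mining proceeds recursively over
conditional pattern bases, with the usual single-path shortcut.

This is an independent second implementation of frequent-itemset mining: for
any database and threshold it must produce exactly the same (itemset,
support count) collection as :func:`acumine.apriori.mine_frequent`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations

from .apriori import Itemset, min_count
from .prescriptions import TransactionDB


class FPNode:
    """A node of the FP-tree: an item, its path count, children and parent."""

    __slots__ = ("item", "count", "children", "parent")

    def __init__(self, item: str | None, count: int = 0, parent: "FPNode | None" = None):
        self.item = item
        self.count = count
        self.children: dict[str, FPNode] = {}
        self.parent = parent


@dataclass
class FPTree:
    root: FPNode
    header: dict[str, list[FPNode]]
    item_order: list[str]
    item_counts: dict[str, int]
    n_transactions: int
    min_support: float | Fraction

    def header_total(self, item: str) -> int:
        """Sum of counts over all nodes carrying *item* (= its support count)."""
        return sum(node.count for node in self.header.get(item, []))


def _insert(root: FPNode, header: dict[str, list[FPNode]], items, count: int) -> None:
    node = root
    for item in items:
        child = node.children.get(item)
        if child is None:
            child = FPNode(item, 0, parent=node)
            node.children[item] = child
            header.setdefault(item, []).append(child)
        child.count += count
        node = child


def _condense(weighted, threshold: int):
    """Build (root, header, counts, order) from weighted item tuples."""
    counts: dict[str, int] = {}
    for items, c in weighted:
        for it in items:
            counts[it] = counts.get(it, 0) + c
    keep = {it: c for it, c in counts.items() if c >= threshold}
    order = sorted(keep, key=lambda it: (-keep[it], it))
    rank = {it: i for i, it in enumerate(order)}
    root = FPNode(None)
    header: dict[str, list[FPNode]] = {}
    for items, c in weighted:
        filtered = sorted((it for it in items if it in rank), key=rank.__getitem__)
        if filtered:
            _insert(root, header, filtered, c)
    return root, header, keep, order


def build_tree(db: TransactionDB, min_support: float | Fraction = 0.24) -> FPTree:
    """Build the FP-tree of a database at the given support threshold.

    Infrequent items are dropped before insertion; each transaction is
    inserted as its frequent items in tree order; shared prefixes merge with
    count accumulation.
    """
    threshold = min_count(min_support, db.N)
    weighted = [(tuple(t), 1) for t in db.itemsets()]
    root, header, keep, order = _condense(weighted, threshold)
    return FPTree(root, header, order, keep, db.N, min_support)


def _single_path(root: FPNode) -> list[tuple[str, int]] | None:
    """If the tree is one chain, its (item, count) list from the top; else None."""
    path = []
    node = root
    while node.children:
        if len(node.children) > 1:
            return None
        (node,) = node.children.values()
        path.append((node.item, node.count))
    return path


def _mine(root, header, counts, order, suffix, threshold, out, shortcut) -> None:
    if shortcut:
        path = _single_path(root)
        if path is not None:
            for r in range(1, len(path) + 1):
                for combo in combinations(path, r):
                    out[frozenset(it for it, _ in combo) | suffix] = min(
                        c for _, c in combo
                    )
            return
    for item in reversed(order):  # least frequent first, as usual
        new_suffix = suffix | {item}
        out[frozenset(new_suffix)] = counts[item]
        base = []
        for node in header[item]:
            prefix = []
            p = node.parent
            while p is not None and p.item is not None:
                prefix.append(p.item)
                p = p.parent
            if prefix:
                base.append((tuple(prefix), node.count))
        if base:
            sub = _condense(base, threshold)
            if sub[3]:  # any conditionally frequent item
                _mine(*sub, new_suffix, threshold, out, shortcut)


def mine_patterns(
    tree: FPTree,
    min_support: float | Fraction | None = None,
    *,
    use_single_path_shortcut: bool = True,
) -> list[Itemset]:
    """All frequent itemsets with exact support counts, mined from the tree.

    *min_support* defaults to the threshold the tree was built with (passing
    a different value is an error waiting to happen and is rejected).
    Output order matches :func:`acumine.apriori.mine_frequent`.
    """
    if min_support is not None and as_key(min_support) != as_key(tree.min_support):
        raise ValueError(
            "mine_patterns must use the same min_support the tree was built with"
        )
    threshold = min_count(tree.min_support, tree.n_transactions)
    out: dict[frozenset[str], int] = {}
    _mine(
        tree.root,
        tree.header,
        tree.item_counts,
        tree.item_order,
        frozenset(),
        threshold,
        out,
        use_single_path_shortcut,
    )
    itemsets = [
        Itemset(items, c, tree.n_transactions) for items, c in out.items()
    ]
    return sorted(itemsets, key=Itemset.sort_key)


def as_key(min_support: float | Fraction) -> Fraction:
    from .apriori import as_fraction

    return as_fraction(min_support)


def dump_tree(tree: FPTree) -> str:
    """Indented text rendering of the tree, for debugging."""
    lines: list[str] = []

    def walk(node: FPNode, depth: int) -> None:
        if node.item is not None:
            lines.append(f"{'  ' * depth}{node.item}:{node.count}")
        for item in sorted(node.children):
            walk(node.children[item], depth + (node.item is not None))

    walk(tree.root, 0)
    return "\n".join(lines)
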