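"""Frequent-itemset mining: first pass, apriori-gen, hash-tree counting.

This is a faithful level-wise Apriori implementation.  Pass one counts
single items; candidate k-itemsets are generated from the frequent
(k-1)-itemsets by the classic join (agree on the first k-2 items) and prune
(every (k-1)-subset must itself be frequent) steps; candidate occurrences
per transaction are counted through a hash tree whose interior nodes route
item ``i`` to bucket ``i mod T`` and whose leaves hold candidate references
with counters.  Mining stops at the first empty level.

Support is a fraction of the transaction count N; an itemset is "large"
(frequent) when count/N >= min_support.  Results are exact and independent
of transaction order and of the hash-tree parameters, which only affect the
counting data structure, never the counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence


@dataclass
class TransactionDB:
    """A set of transactions over an integer item vocabulary.

    ``transactions`` holds one frozenset of item ids per transaction;
    ``id_to_item`` maps each id back to its ``attribute=value`` string.
    """

    transactions: list[frozenset[int]]
    id_to_item: tuple[str, ...]

    def __post_init__(self) -> None:
        m = len(self.id_to_item)
        for t in self.transactions:
            if any(i < 0 or i >= m for i in t):
                raise ValueError("transaction contains item id outside vocabulary")

    @property
    def N(self) -> int:
        return len(self.transactions)

    @property
    def m(self) -> int:
        return len(self.id_to_item)

    @property
    def item_to_id(self) -> dict[str, int]:
        return {item: i for i, item in enumerate(self.id_to_item)}

    def labels(self, items: Iterable[int]) -> tuple[str, ...]:
        return tuple(self.id_to_item[i] for i in items)


@dataclass(frozen=True)
class ItemSet:
    """An itemset (strictly increasing item ids) with its occurrence count."""

    items: tuple[int, ...]
    count: int = 0

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.items, self.items[1:])):
            raise ValueError(f"items must be strictly increasing: {self.items}")
        if self.count < 0:
            raise ValueError("negative count")

    @property
    def k(self) -> int:
        return len(self.items)


@dataclass
class FrequentItemsets:
    """The mined levels L_1..L_K: map from itemset size to frequent itemsets."""

    levels: dict[int, list[ItemSet]]
    min_support: float
    N: int
    _counts: dict[tuple[int, ...], int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._counts = {s.items: s.count for level in self.levels.values() for s in level}

    def count(self, items: Sequence[int]) -> int:
        """Exact occurrence count of a mined frequent itemset."""
        return self._counts[tuple(items)]

    def __contains__(self, items: Sequence[int]) -> bool:
        return tuple(items) in self._counts

    def itemsets(self, min_size: int = 1) -> list[ItemSet]:
        return [s for k in sorted(self.levels) if k >= min_size for s in self.levels[k]]


def first_pass(db: TransactionDB, min_support: float) -> FrequentItemsets:
    """Count item occurrences and keep the frequent single items (level 1)."""
    _check_min_support(min_support)
    counts: Counter[int] = Counter()
    for t in db.transactions:
        counts.update(t)
    n = db.N
    level1 = [
        ItemSet((i,), counts[i])
        for i in sorted(counts)
        if n > 0 and counts[i] / n >= min_support
    ]
    return FrequentItemsets(levels={1: level1}, min_support=min_support, N=n)


def apriori_gen(L_prev: Sequence[ItemSet]) -> list[ItemSet]:
    """Generate candidate k-itemsets from the frequent (k-1)-itemsets.

    Join: pairs of (k-1)-itemsets agreeing on their first k-2 items (item
    order is ascending id order) produce a k-itemset.  Prune: a candidate
    is discarded unless every (k-1)-subset is itself in ``L_prev``.  The
    result is duplicate-free, sorted, with counts initialized to zero.
    """
    if not L_prev:
        return []
    k_prev = L_prev[0].k
    if k_prev == 0:
        raise ValueError("apriori_gen requires level >= 1 (first_pass owns level 1)")
    prev = sorted(s.items for s in L_prev)
    prev_set = set(prev)
    candidates: list[ItemSet] = []
    for p_idx, p in enumerate(prev):
        for q in prev[p_idx + 1 :]:
            if p[:-1] != q[:-1]:
                break  # sorted order: no later q shares the (k-2)-prefix
            joined = p + (q[-1],)
            # prune: all (k-1)-subsets must be frequent
            if all(
                joined[:i] + joined[i + 1 :] in prev_set for i in range(len(joined))
            ):
                candidates.append(ItemSet(joined, 0))
    return candidates


class _Node:
    __slots__ = ("children", "bucket", "depth")

    def __init__(self, depth: int) -> None:
        self.children: dict[int, _Node] | None = None  # None while leaf
        self.bucket: list[int] = []  # candidate indices (leaf only)
        self.depth = depth


class HashTree:
    """Hash tree over a candidate set, for per-transaction subset counting.

    Interior nodes at depth d route a candidate (or transaction item) by
    ``hash(i) = i mod T`` applied to the d-th item; leaves store candidate
    references and their counters.  A leaf splits once it holds more than
    ``max_leaf_size`` candidates, unless it already sits at depth k (all
    items consumed), where it absorbs overflow.
    """

    def __init__(
        self,
        candidates: Sequence[ItemSet],
        T: int = 3,
        max_leaf_size: int = 8,
    ) -> None:
        if T < 2:
            raise ValueError(f"hash-tree branching constant T must be >= 2, got {T}")
        if max_leaf_size < 1:
            raise ValueError("max_leaf_size must be >= 1")
        self.T = T
        self.max_leaf_size = max_leaf_size
        self.candidates = [c.items for c in candidates]
        self.k = len(self.candidates[0]) if self.candidates else 0
        if any(len(c) != self.k for c in self.candidates):
            raise ValueError("all candidates must have equal size")
        self.counters = [0] * len(self.candidates)
        self.root = _Node(depth=0)
        for idx in range(len(self.candidates)):
            self._insert(idx)

    def _insert(self, idx: int) -> None:
        items = self.candidates[idx]
        node = self.root
        while node.children is not None:
            node = node.children.setdefault(
                items[node.depth] % self.T, _Node(node.depth + 1)
            )
        node.bucket.append(idx)
        if len(node.bucket) > self.max_leaf_size and node.depth < self.k:
            self._split(node)

    def _split(self, node: _Node) -> None:
        node.children = {}
        overflow, node.bucket = node.bucket, []
        for idx in overflow:
            child = node.children.setdefault(
                self.candidates[idx][node.depth] % self.T, _Node(node.depth + 1)
            )
            child.bucket.append(idx)
            if len(child.bucket) > self.max_leaf_size and child.depth < self.k:
                self._split(child)

    def count_subsets(self, t: Sequence[int]) -> None:
        """Increment the counter of every candidate contained in transaction t.

        ``t`` must be sorted ascending.  The recursion mirrors the subset
        function: at every tree level each remaining item of t is tried as
        the next routed item; reached leaves check their candidates against
        t.  A visited-leaf set guards against double counting when several
        routes reach the same leaf.
        """
        tset = frozenset(t)
        visited: set[int] = set()

        def descend(node: _Node, start: int) -> None:
            if node.children is None:
                if id(node) in visited:
                    return
                visited.add(id(node))
                for idx in node.bucket:
                    if tset.issuperset(self.candidates[idx]):
                        self.counters[idx] += 1
                return
            for pos in range(start, len(t)):
                child = node.children.get(t[pos] % self.T)
                if child is not None:
                    descend(child, pos + 1)

        descend(self.root, 0)

    def counted(self) -> list[ItemSet]:
        return [ItemSet(c, n) for c, n in zip(self.candidates, self.counters)]


def build_hash_tree(
    candidates: Sequence[ItemSet], T: int = 3, max_leaf_size: int = 8
) -> HashTree:
    """Store a candidate set in a hash tree (see :class:`HashTree`)."""
    return HashTree(candidates, T=T, max_leaf_size=max_leaf_size)


def count_subsets(tree: HashTree, t: Sequence[int]) -> None:
    """Update the tree's counters for one (ascending-sorted) transaction."""
    tree.count_subsets(t)


def mine_frequent(
    db: TransactionDB,
    min_support: float,
    T: int = 3,
    max_leaf_size: int = 8,
) -> FrequentItemsets:
    """Mine all frequent itemsets level by level; stop at the first empty level.

    Counts are exact: the result equals brute-force enumeration of every
    itemset with support >= ``min_support``.
    """
    _check_min_support(min_support)
    result = first_pass(db, min_support)
    n = db.N
    sorted_transactions = [tuple(sorted(t)) for t in db.transactions]
    k = 2
    while result.levels.get(k - 1):
        candidates = apriori_gen(result.levels[k - 1])
        if not candidates:
            break
        tree = build_hash_tree(candidates, T=T, max_leaf_size=max_leaf_size)
        for t in sorted_transactions:
            if len(t) >= k:  # shorter transactions hold no k-subset
                tree.count_subsets(t)
        level = [s for s in tree.counted() if s.count / n >= min_support]
        if not level:
            break
        result.levels[k] = level
        k += 1
    return FrequentItemsets(levels=result.levels, min_support=min_support, N=n)


def _check_min_support(min_support: float) -> None:
    if not 0 < min_support <= 1:
        raise ValueError(f"min_support must be in (0, 1], got {min_support}")
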