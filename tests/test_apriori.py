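"""Frequent-itemset engine: first pass, candidate generation, hash tree,
full mining against an exhaustive-enumeration oracle."""

from __future__ import annotations

import numpy as np
import pytest

from clinrules import (
    ItemSet,
    TransactionDB,
    apriori_gen,
    build_hash_tree,
    count_subsets,
    first_pass,
    mine_frequent,
)

from conftest import brute_force_frequent, random_db


def _db(transactions, m):
    return TransactionDB(
        transactions=[frozenset(t) for t in transactions],
        id_to_item=tuple(f"item=v{i}" for i in range(m)),
    )


class TestFirstPass:
    def test_toy_counting(self):
        # item 0 in 4 of 5 transactions, item 1 in 2, item 2 in 1
        db = _db([{0, 1}, {0}, {0, 1, 2}, {0}, set()], m=3)
        level1 = first_pass(db, 0.4).levels[1]
        assert [(s.items, s.count) for s in level1] == [((0,), 4), ((1,), 2)]

    def test_empty_db(self):
        db = _db([], m=0)
        assert first_pass(db, 0.5).levels[1] == []

    def test_fixture_tongue_count(self, fixture_db):
        level1 = first_pass(fixture_db, 0.09).levels[1]
        counts = {fixture_db.id_to_item[s.items[0]]: s.count for s in level1}
        assert counts["primary_site=tongue"] == 88
        assert counts["grade=02"] == 60

    def test_invalid_support(self, fixture_db):
        with pytest.raises(ValueError):
            first_pass(fixture_db, 0.0)


class TestAprioriGen:
    def test_join_produces_four_itemset(self):
        # A=0 B=1 C=2 D=3: all four 3-subsets frequent -> the 4-itemset joins
        L3 = [ItemSet(t, 5) for t in [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]]
        assert [c.items for c in apriori_gen(L3)] == [(0, 1, 2, 3)]

    def test_single_itemset_no_pair(self):
        assert apriori_gen([ItemSet((0,), 3)]) == []

    def test_prune_removes_candidate_with_infrequent_subset(self):
        # AB, AC join to ABC, but BC is not frequent -> pruned
        L2 = [ItemSet(t, 5) for t in [(0, 1), (0, 2), (1, 3)]]
        assert apriori_gen(L2) == []

    def test_superset_of_true_frequent(self):
        # candidates are a superset of the frequent k-itemsets on random dbs
        for seed in range(20):
            db = random_db(seed)
            truth = brute_force_frequent(db, 0.2)
            by_k: dict[int, list] = {}
            for items, count in truth.items():
                by_k.setdefault(len(items), []).append(ItemSet(items, count))
            for k in sorted(by_k):
                if k + 1 in by_k:
                    candidates = {c.items for c in apriori_gen(sorted(by_k[k], key=lambda s: s.items))}
                    frequent_next = {s.items for s in by_k[k + 1]}
                    assert frequent_next <= candidates


class TestHashTree:
    def test_single_candidate_reachable(self):
        tree = build_hash_tree([ItemSet((1, 4), 0)], T=3)
        count_subsets(tree, (1, 4))
        assert tree.counters == [1]

    def test_empty_candidate_set(self):
        tree = build_hash_tree([], T=3)
        count_subsets(tree, (0, 1, 2))  # no-op, no error
        assert tree.counters == []

    def test_branching_below_two_fatal(self):
        with pytest.raises(ValueError):
            build_hash_tree([ItemSet((0, 1), 0)], T=1)

    def test_every_candidate_reachable_after_splits(self):
        rng = np.random.default_rng(5)
        candidates = []
        seen = set()
        while len(candidates) < 10:
            items = tuple(sorted(rng.choice(30, size=3, replace=False).tolist()))
            if items not in seen:
                seen.add(items)
                candidates.append(ItemSet(items, 0))
        tree = build_hash_tree(candidates, T=3, max_leaf_size=2)
        for c in candidates:
            count_subsets(tree, c.items)
        # each candidate matched exactly by its own transaction (plus any
        # other candidate transactions that happen to contain it: none, k=3)
        assert tree.counters == [1] * 10

    def test_empty_transaction_no_change(self):
        tree = build_hash_tree([ItemSet((0, 1), 0)], T=2)
        count_subsets(tree, ())
        assert tree.counters == [0]

    def test_subset_counting_direct_oracle(self):
        # C2 = {AB, AC, BC, BD}; t = {A,B,C} contains AB, AC, BC but not BD
        candidates = [ItemSet(t, 0) for t in [(0, 1), (0, 2), (1, 2), (1, 3)]]
        tree = build_hash_tree(candidates, T=3, max_leaf_size=1)
        count_subsets(tree, (0, 1, 2))
        assert tree.counters == [1, 1, 1, 0]

    def test_no_double_counting_on_deep_trees(self):
        # many shared prefixes force multiple routes to the same leaves
        candidates = [ItemSet((a, a + 3, a + 6), 0) for a in range(3)]
        tree = build_hash_tree(candidates, T=3, max_leaf_size=1)
        count_subsets(tree, tuple(range(9)))
        assert tree.counters == [1, 1, 1]


class TestMineFrequent:
    def test_min_support_one(self):
        db = _db([{0, 1}, {0}, {0, 2}], m=3)
        result = mine_frequent(db, 1.0)
        assert {k: [(s.items, s.count) for s in v] for k, v in result.levels.items()} == {
            1: [((0,), 3)]
        }

    def test_fixture_four_itemset(self, fixture_db):
        result = mine_frequent(fixture_db, 0.09)
        ids = tuple(sorted(
            fixture_db.item_to_id[label]
            for label in ("grade=02", "clinical_stage_group=early",
                          "primary_site=tongue", "group=OP")
        ))
        assert result.count(ids) == 27

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_exhaustive_enumeration(self, seed):
        db = random_db(seed)
        result = mine_frequent(db, 0.2)
        mined = {s.items: s.count for level in result.levels.values() for s in level}
        assert mined == brute_force_frequent(db, 0.2)

    def test_anti_monotonicity(self, fixture_db):
        result = mine_frequent(fixture_db, 0.09)
        for level in result.levels.values():
            for s in level:
                for i in range(len(s.items)):
                    subset = s.items[:i] + s.items[i + 1 :]
                    if subset:
                        assert result.count(subset) >= s.count

    @pytest.mark.parametrize("T", [2, 3, 5])
    @pytest.mark.parametrize("max_leaf_size", [1, 4, 16])
    def test_hash_tree_parameter_neutrality(self, fixture_db, T, max_leaf_size):
        baseline = mine_frequent(fixture_db, 0.09)
        other = mine_frequent(fixture_db, 0.09, T=T, max_leaf_size=max_leaf_size)
        as_dict = lambda r: {s.items: s.count for lv in r.levels.values() for s in lv}
        assert as_dict(other) == as_dict(baseline)

    def test_transaction_order_invariance(self):
        db = random_db(42)
        rng = np.random.default_rng(0)
        shuffled = list(db.transactions)
        rng.shuffle(shuffled)
        db2 = TransactionDB(transactions=shuffled, id_to_item=db.id_to_item)
        as_dict = lambda r: {s.items: s.count for lv in r.levels.values() for s in lv}
        assert as_dict(mine_frequent(db, 0.2)) == as_dict(mine_frequent(db2, 0.2))
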