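"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from clinrules import TransactionDB, build_reference_fixture


@pytest.fixture(scope="session")
def fixture_db() -> TransactionDB:
    """The deterministic 271-transaction benchmark database."""
    return build_reference_fixture()


def brute_force_frequent(db: TransactionDB, min_support: float) -> dict[tuple, int]:
    """Independent oracle: exhaustive enumeration of all frequent itemsets.

    Counts every subset of the vocabulary directly against the transactions;
    intended for small instances (m <= ~10).
    """
    out: dict[tuple, int] = {}
    for k in range(1, db.m + 1):
        for combo in combinations(range(db.m), k):
            cset = frozenset(combo)
            count = sum(1 for t in db.transactions if cset <= t)
            if db.N > 0 and count / db.N >= min_support:
                out[combo] = count
    return out


def random_db(seed: int, max_transactions: int = 25, max_items: int = 8) -> TransactionDB:
    """Small random transaction database (seed-indexed, reproducible)."""
    rng = np.random.default_rng(seed)
    m = int(rng.integers(2, max_items + 1))
    n = int(rng.integers(5, max_transactions + 1))
    transactions = [
        frozenset(int(i) for i in range(m) if rng.random() < 0.4) for _ in range(n)
    ]
    return TransactionDB(
        transactions=transactions,
        id_to_item=tuple(f"item=v{i}" for i in range(m)),
    )
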