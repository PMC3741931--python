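"""Association-rule generation, interestingness metrics, and ranking.

A rule X => Y partitions a frequent itemset into a non-empty body X and
head Y.  With N transactions, n_X body occurrences, n_Y head occurrences
and n_XY joint occurrences, the metrics are

    confidence = n_XY / n_X
    support    = n_XY / N
    lift       = (n_XY / n_X) / (n_Y / N)          (1 under independence)
    leverage   = n_XY/N - (n_X/N)(n_Y/N)           (0 under independence)
    conviction = (1 - n_Y/N) / (1 - confidence)

Conviction is implemented in two variants.  The ``standard`` variant is the
textbook count form n_X (N - n_Y) / (N (n_X - n_XY)), infinite for exact
rules.  The ``laplace`` variant adds one to the body-without-head count in
the denominator, n_X (N - n_Y) / (N (n_X - n_XY + 1)), a smoothing used by
common rule-mining toolkits; it is the default because it is the variant
under which the reference cohort's published rule table reproduces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd

from .apriori import FrequentItemsets, TransactionDB

CONVICTION_VARIANTS = ("standard", "laplace")
SORT_METRICS = ("lift", "confidence", "leverage", "conviction")


class RuleMetrics(NamedTuple):
    confidence: float
    support: float
    lift: float
    leverage: float
    conviction: float


def rule_metrics(
    n_body: int,
    n_head: int,
    n_joint: int,
    N: int,
    conviction_variant: str = "laplace",
) -> RuleMetrics:
    """Compute the interestingness metrics of one rule from its four counts."""
    if conviction_variant not in CONVICTION_VARIANTS:
        raise ValueError(f"conviction_variant must be one of {CONVICTION_VARIANTS}")
    if N < 1:
        raise ValueError("N must be >= 1")
    if n_body <= 0 or n_head <= 0:
        raise ValueError("undefined rule: body and head counts must be positive")
    if not 0 <= n_joint <= min(n_body, n_head):
        raise ValueError(
            f"joint count {n_joint} outside [0, min({n_body}, {n_head})]"
        )
    confidence = n_joint / n_body
    support = n_joint / N
    # symmetric form: bitwise-equal for a rule and its mirror, so that
    # mathematically tied lifts compare as exact ties when ranking
    lift = n_joint * N / (n_body * n_head)
    leverage = support - (n_body / N) * (n_head / N)
    if conviction_variant == "laplace":
        conviction = n_body * (N - n_head) / (N * (n_body - n_joint + 1))
    elif n_body == n_joint:
        conviction = math.inf if n_head < N else 1.0
    else:
        conviction = n_body * (N - n_head) / (N * (n_body - n_joint))
    return RuleMetrics(confidence, support, lift, leverage, conviction)


@dataclass(frozen=True)
class AssociationRule:
    """A rule body => head with its exact population counts and metrics."""

    body: tuple[int, ...]
    head: tuple[int, ...]
    body_labels: tuple[str, ...]
    head_labels: tuple[str, ...]
    n_body: int
    n_head: int
    n_joint: int
    N: int
    confidence: float
    support: float
    lift: float
    leverage: float
    conviction: float

    @property
    def itemset(self) -> tuple[int, ...]:
        return tuple(sorted(self.body + self.head))


def generate_rules(
    frequent: FrequentItemsets,
    db: TransactionDB,
    head_mode: str = "free",
    class_attribute: str | None = None,
    conviction_variant: str = "laplace",
) -> list[AssociationRule]:
    """Emit every rule derivable from the mined frequent itemsets.

    In ``free`` mode each frequent k-itemset (k >= 2) yields all 2^k - 2
    ordered body/head partitions.  In ``class-constrained`` mode only rules
    whose head is the single item of ``class_attribute`` are emitted (the
    class-association-rule semantics).  Bodies are enumerated per itemset
    by ascending bitmask over the itemset's id-sorted items; together with
    the stable ranking sort this fixes a deterministic, reproducible rule
    order within metric ties.

    Body and head counts are exact population counts; both are subsets of a
    frequent itemset and hence frequent themselves, so their counts are
    looked up from the mined table.
    """
    if head_mode not in ("free", "class-constrained"):
        raise ValueError(f"unknown head_mode: {head_mode!r}")
    class_items: set[int] | None = None
    if head_mode == "class-constrained":
        if class_attribute is None:
            raise ValueError("class-constrained mode requires class_attribute")
        class_items = {
            i
            for i, label in enumerate(db.id_to_item)
            if label.partition("=")[0] == class_attribute
        }
        if not class_items:
            raise ValueError(f"class attribute {class_attribute!r} not in vocabulary")

    rules: list[AssociationRule] = []
    for itemset in frequent.itemsets(min_size=2):
        items = itemset.items
        k = len(items)
        for mask in range(1, 2**k - 1):
            body = tuple(items[j] for j in range(k) if mask >> j & 1)
            head = tuple(items[j] for j in range(k) if not mask >> j & 1)
            if class_items is not None and not (
                len(head) == 1 and head[0] in class_items
            ):
                continue
            n_body = frequent.count(body)
            n_head = frequent.count(head)
            metrics = rule_metrics(
                n_body, n_head, itemset.count, frequent.N, conviction_variant
            )
            rules.append(
                AssociationRule(
                    body=body,
                    head=head,
                    body_labels=db.labels(body),
                    head_labels=db.labels(head),
                    n_body=n_body,
                    n_head=n_head,
                    n_joint=itemset.count,
                    N=frequent.N,
                    **metrics._asdict(),
                )
            )
    return rules


def round_display(x: float, digits: int = 2) -> float:
    """Round half away from zero for display (0.045 -> 0.05, not 0.04)."""
    if math.isinf(x):
        return x
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class RuleReport:
    """Ranked rule table plus the run parameters that produced it."""

    rules: list[AssociationRule]
    sort_metric: str
    min_lift: float
    top_k: int
    N: int

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)

    def to_frame(self, digits: int = 2) -> pd.DataFrame:
        """Display table: labels, counts, and metrics rounded to ``digits``."""
        rows = [
            {
                "body": ", ".join(r.body_labels),
                "n_body": r.n_body,
                "head": ", ".join(r.head_labels),
                "n_joint": r.n_joint,
                "confidence": round_display(r.confidence, digits),
                "lift": round_display(r.lift, digits),
                "leverage": round_display(r.leverage, digits),
                "conviction": round_display(r.conviction, digits),
            }
            for r in self.rules
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "body",
                "n_body",
                "head",
                "n_joint",
                "confidence",
                "lift",
                "leverage",
                "conviction",
            ],
        )

    def to_tsv(self, path: str | Path) -> None:
        """Write the report as TSV with run metadata in comment lines."""
        header = (
            f"# population size N = {self.N}\n"
            f"# sort = {self.sort_metric}, min_lift = {self.min_lift}, "
            f"top_k = {self.top_k}\n"
        )
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(header)
            self.to_frame().to_csv(fh, sep="\t", index=False)


def rank_rules(
    rules: Iterable[AssociationRule],
    sort_metric: str = "lift",
    min_lift: float = 1.5,
    top_k: int = 10,
) -> RuleReport:
    """Filter by minimum lift, sort by the chosen metric, truncate to top_k.

    The sort is descending and stable: rules tied on the metric keep their
    generation order (itemsets by level then id order, bodies by ascending
    bitmask), which makes the report deterministic.
    """
    if sort_metric not in SORT_METRICS:
        raise ValueError(f"sort_metric must be one of {SORT_METRICS}")
    rules = list(rules)
    kept = [r for r in rules if r.lift > min_lift]
    kept.sort(key=lambda r: -getattr(r, sort_metric))
    n = rules[0].N if rules else 0
    return RuleReport(
        rules=kept[:top_k], sort_metric=sort_metric, min_lift=min_lift,
        top_k=top_k, N=n,
    )
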