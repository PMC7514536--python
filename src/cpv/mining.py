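"""Apriori association-rule mining for clinical features and treatments.

Each case is a *transaction*: the set of clinical-feature items observed for
one patient (and, for the treatment analysis, the treatment items applied).
Frequent itemsets are mined level-wise with support-based pruning — the
Apriori property that every subset of a frequent itemset is frequent — and
rules with a single-item consequent are generated from them with exact

- support    = fraction of transactions containing antecedent ∪ consequent,
- confidence = support(antecedent ∪ consequent) / support(antecedent),
- lift       = confidence / support(consequent).

Three named presets reproduce the published mining protocols:

``double-factor``    min support 0.05, min confidence 0.5, min lift 0.9;
                     one cause item implying another (e.g. abnormal fetal
                     position → uterine atony).
``triple-factor``    min support 0.12, min confidence 0.5, min lift 0.9;
                     two-item antecedents.
``treatment``        min support 0.05, min confidence 0.15, min lift 1;
                     cause-item antecedents, treatment-item consequents,
                     requiring an item-class map.

Transactions are counted with set semantics (duplicate items within one case
collapse) and item labels are normalised — case-folded, trimmed, internal
whitespace collapsed — because free-text treatment descriptions vary across
physicians.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Transaction",
    "ItemsetRecord",
    "AssociationRule",
    "MiningConfig",
    "PRESETS",
    "normalize_item",
    "read_transactions",
    "read_item_classes",
    "frequent_itemsets",
    "generate_rules",
    "mine_protocol",
    "rules_to_frame",
]

logger = logging.getLogger(__name__)

_EPS = 1e-12  # threshold comparisons tolerate float representation error


def normalize_item(label: str) -> str:
    """Canonical item label: case-folded, trimmed, whitespace collapsed."""
    return re.sub(r"\s+", " ", str(label).strip()).casefold()


@dataclass(frozen=True)
class Transaction:
    """One case: an opaque identifier and its non-empty set of items."""

    case_id: str
    items: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", frozenset(self.items))
        if not self.items:
            raise ValueError(f"transaction {self.case_id!r} has no items")


@dataclass(frozen=True)
class ItemsetRecord:
    """A frequent itemset with its exact support (fraction of transactions)."""

    items: frozenset[str]
    support: float


@dataclass(frozen=True)
class AssociationRule:
    """antecedent → consequent with exact support, confidence and lift."""

    antecedent: frozenset[str]
    consequent: frozenset[str]
    support: float
    confidence: float
    lift: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        ant = " + ".join(sorted(self.antecedent))
        cons = " + ".join(sorted(self.consequent))
        return (
            f"{ant} -> {cons} "
            f"(supp={self.support:.3f}, conf={self.confidence:.3f}, lift={self.lift:.3f})"
        )


@dataclass(frozen=True)
class MiningConfig:
    """Thresholds and rule-shape constraints for one mining run.

    ``consequent_mode`` is ``"any-single-item"`` (mine freely) or
    ``"fixed-item-class"`` (antecedent items must belong to
    ``antecedent_class`` and the consequent to ``consequent_class`` under an
    item-class map).  ``consequent_items``, if given, additionally restricts
    the consequent to a fixed set of items.  ``count_support`` switches
    reported supports (not thresholds) from fractions to raw counts.
    """

    min_support: float
    min_confidence: float = 0.0
    min_lift: float = 0.0
    max_antecedent_size: int = 3
    min_antecedent_size: int = 1
    consequent_mode: str = "any-single-item"
    antecedent_class: str | None = None
    consequent_class: str | None = None
    consequent_items: frozenset[str] | None = None
    count_support: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.min_support <= 1.0):
            raise ValueError(f"min_support must be in (0, 1], got {self.min_support}")
        for name in ("min_confidence", "min_lift"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.max_antecedent_size < 1 or self.min_antecedent_size < 1:
            raise ValueError("antecedent size bounds must be positive")
        if self.consequent_mode not in ("any-single-item", "fixed-item-class"):
            raise ValueError(f"unknown consequent_mode {self.consequent_mode!r}")


#: Named presets for the three published mining protocols.
PRESETS: dict[str, MiningConfig] = {
    "double-factor": MiningConfig(
        min_support=0.05, min_confidence=0.5, min_lift=0.9,
        max_antecedent_size=1,
    ),
    "triple-factor": MiningConfig(
        min_support=0.12, min_confidence=0.5, min_lift=0.9,
        min_antecedent_size=2, max_antecedent_size=2,
    ),
    "treatment": MiningConfig(
        min_support=0.05, min_confidence=0.15, min_lift=1.0,
        max_antecedent_size=2,
        consequent_mode="fixed-item-class",
        antecedent_class="cause", consequent_class="treatment",
    ),
}


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_transactions(path: str | Path) -> list[Transaction]:
    """Read a transactions CSV in either documented dialect.

    Wide dialect: a ``case_id`` column plus one 0/1 column per item; a case's
    items are the columns holding 1.  Long dialect: exactly two columns
    ``case_id,item``, one row per (case, item) pair.  Duplicate items within
    a case collapse; empty cases are dropped with a logged count.
    """
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a case_id column plus item columns")
    id_col = df.columns[0]
    value_cols = df.columns[1:]
    stripped = df[value_cols].apply(lambda c: c.astype(str).str.strip())
    is_wide = stripped.isin(["0", "1"]).all().all()
    tx: list[Transaction] = []
    n_empty = 0
    if is_wide:
        item_names = [normalize_item(c) for c in value_cols]
        flags = stripped.to_numpy() == "1"
        for case_id, row in zip(df[id_col], flags):
            items = frozenset(name for name, f in zip(item_names, row) if f)
            if not items:
                n_empty += 1
                continue
            tx.append(Transaction(str(case_id), items))
    else:
        if df.shape[1] != 2:
            raise ValueError(
                f"{path}: not wide (non-0/1 values) and not long (needs "
                f"exactly 2 columns, has {df.shape[1]})"
            )
        item_col = df.columns[1]
        for case_id, group in df.groupby(id_col, sort=False):
            items = frozenset(
                normalize_item(i) for i in group[item_col].dropna() if str(i).strip()
            )
            if not items:
                n_empty += 1
                continue
            tx.append(Transaction(str(case_id), items))
    if n_empty:
        logger.info("dropped %d empty case(s) from %s", n_empty, path)
    if not tx:
        raise ValueError(f"{path}: no non-empty transactions")
    return tx


def read_item_classes(path: str | Path) -> dict[str, str]:
    """Two-column CSV ``item,class`` mapping items to e.g. cause/treatment."""
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: item-class map needs exactly 2 columns")
    return {
        normalize_item(i): str(c).strip().casefold()
        for i, c in zip(df.iloc[:, 0], df.iloc[:, 1])
    }


# ---------------------------------------------------------------------------
# Apriori
# ---------------------------------------------------------------------------


def _encode(transactions: Sequence[Transaction]) -> tuple[list[str], list[int]]:
    """Map items to bit positions; each transaction becomes a bitmask."""
    items = sorted({i for t in transactions for i in t.items})
    pos = {item: 1 << k for k, item in enumerate(items)}
    masks = [sum(pos[i] for i in t.items) for t in transactions]
    return items, masks


def frequent_itemsets(
    transactions: Sequence[Transaction], config: MiningConfig
) -> list[ItemsetRecord]:
    """All itemsets with support >= ``min_support``, with exact supports.

    Level-wise Apriori: frequent 1-itemsets first, then candidate k-itemsets
    joined from frequent (k-1)-itemsets sharing a (k-2)-prefix, pruned by the
    subset property before counting.
    """
    if not transactions:
        raise ValueError("need at least one transaction")
    n = len(transactions)
    items, masks = _encode(transactions)
    min_count = config.min_support * n - _EPS

    def count(mask: int) -> int:
        return sum(1 for m in masks if m & mask == mask)

    records: list[tuple[frozenset[str], float]] = []
    # level 1
    frequent: list[tuple[int, ...]] = []  # sorted bit-index tuples
    supports: dict[tuple[int, ...], int] = {}
    for k, item in enumerate(items):
        c = count(1 << k)
        if c >= min_count:
            frequent.append((k,))
            supports[(k,)] = c
    level = frequent
    while level:
        for key in level:
            itemset = frozenset(items[k] for k in key)
            records.append((itemset, supports[key] / n))
        # join step: pairs sharing all but the last index
        level_set = set(level)
        candidates: set[tuple[int, ...]] = set()
        for a, b in combinations(sorted(level), 2):
            if a[:-1] == b[:-1]:
                candidates.add(a + (b[-1],))
        next_level: list[tuple[int, ...]] = []
        for cand in sorted(candidates):
            # prune: every (k-1)-subset must be frequent
            if any(
                cand[:i] + cand[i + 1 :] not in level_set for i in range(len(cand))
            ):
                continue
            mask = sum(1 << k for k in cand)
            c = count(mask)
            if c >= min_count:
                next_level.append(cand)
                supports[cand] = c
        level = next_level

    out = [ItemsetRecord(itemset, s) for itemset, s in records]
    out.sort(key=lambda r: (-r.support, len(r.items), tuple(sorted(r.items))))
    return out


def _support_map(transactions: Sequence[Transaction]) -> "_SupportCounter":
    return _SupportCounter(transactions)


class _SupportCounter:
    """Exact support of arbitrary itemsets via bitmask containment."""

    def __init__(self, transactions: Sequence[Transaction]):
        self.n = len(transactions)
        self._items, self._masks = _encode(transactions)
        self._pos = {item: 1 << k for k, item in enumerate(self._items)}
        self._cache: dict[frozenset[str], float] = {}

    def __call__(self, itemset: Iterable[str]) -> float:
        key = frozenset(itemset)
        if key not in self._cache:
            try:
                mask = sum(self._pos[i] for i in key)
            except KeyError as e:
                raise KeyError(f"item {e.args[0]!r} not present in transactions") from None
            self._cache[key] = (
                sum(1 for m in self._masks if m & mask == mask) / self.n
            )
        return self._cache[key]


def generate_rules(
    itemsets: Sequence[ItemsetRecord],
    transactions: Sequence[Transaction],
    config: MiningConfig,
    item_classes: Mapping[str, str] | None = None,
) -> list[AssociationRule]:
    """All rules ``antecedent → single-item consequent`` passing the
    thresholds, with support/confidence/lift computed exactly from the
    transactions.

    For every frequent itemset I of size >= 2 and every item c in I, the
    candidate rule is ``I \\ {c} → {c}``; smaller antecedents arise from the
    smaller frequent itemsets, so this enumerates every rule whose item
    union is frequent.
    """
    support = _support_map(transactions)
    if config.consequent_mode == "fixed-item-class" and item_classes is None:
        raise ValueError("fixed-item-class mining requires an item-class map")
    rules: list[AssociationRule] = []
    for rec in itemsets:
        if len(rec.items) < 2:
            continue
        for cons_item in rec.items:
            ant = rec.items - {cons_item}
            if not (config.min_antecedent_size <= len(ant) <= config.max_antecedent_size):
                continue
            if config.consequent_items is not None and cons_item not in config.consequent_items:
                continue
            if config.consequent_mode == "fixed-item-class":
                if item_classes.get(cons_item) != config.consequent_class:
                    continue
                if config.antecedent_class is not None and any(
                    item_classes.get(a) != config.antecedent_class for a in ant
                ):
                    continue
            supp = support(rec.items)
            supp_ant = support(ant)
            supp_cons = support(frozenset([cons_item]))
            confidence = supp / supp_ant
            lift = confidence / supp_cons
            if supp < config.min_support - _EPS:
                continue
            if confidence < config.min_confidence - _EPS:
                continue
            if lift < config.min_lift - _EPS:
                continue
            scale = support.n if config.count_support else 1.0
            rules.append(
                AssociationRule(
                    antecedent=frozenset(ant),
                    consequent=frozenset([cons_item]),
                    support=supp * scale,
                    confidence=confidence,
                    lift=lift,
                )
            )
    rules.sort(
        key=lambda r: (
            -r.support,
            -r.confidence,
            tuple(sorted(r.antecedent)),
            tuple(sorted(r.consequent)),
        )
    )
    return rules


def mine_protocol(
    transactions: Sequence[Transaction],
    preset: str | MiningConfig,
    item_classes: Mapping[str, str] | None = None,
) -> list[AssociationRule]:
    """Run a full protocol: frequent itemsets then rules, preset thresholds.

    Output is sorted by support descending, then confidence descending,
    then lexicographically — stable across runs.
    """
    if isinstance(preset, MiningConfig):
        config = preset
    else:
        try:
            config = PRESETS[preset]
        except KeyError:
            raise ValueError(
                f"unknown preset {preset!r}; choose from {sorted(PRESETS)}"
            ) from None
    itemsets = frequent_itemsets(transactions, config)
    return generate_rules(itemsets, transactions, config, item_classes=item_classes)


def rules_to_frame(rules: Sequence[AssociationRule], decimals: int | None = 3) -> pd.DataFrame:
    """Rules as a DataFrame (antecedent, consequent, support, confidence,
    lift), metrics optionally rounded for report output."""
    rows = []
    for r in rules:
        rows.append(
            {
                "antecedent": " + ".join(sorted(r.antecedent)),
                "consequent": " + ".join(sorted(r.consequent)),
                "support": round(r.support, decimals) if decimals else r.support,
                "confidence": round(r.confidence, decimals) if decimals else r.confidence,
                "lift": round(r.lift, decimals) if decimals else r.lift,
            }
        )
    return pd.DataFrame(
        rows, columns=["antecedent", "consequent", "support", "confidence", "lift"]
    )
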