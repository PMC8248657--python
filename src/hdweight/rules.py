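"""Class association rule mining over the categorical knowledge base.

Rules X => Y are mined with a level-wise Apriori in which the consequent Y
is constrained to a single weight-category item (class association rules).
Each rule carries six interest/validation measures:

* support            s = sigma(X u Y) / N
* confidence         c = sigma(X u Y) / sigma(X)
* lift               s(X u Y) / (s(X) * s(Y));  1 means independence
* conviction         (1 - s(Y)) / (1 - c);  1 independence, +inf when c = 1
* chi-square, p      Pearson test (1 df, no continuity correction) on the
                     2x2 table {X, not-X} x {Y, not-Y}
* strength           odds ratio of that table: 0 for rules whose antecedent
                     and consequent never co-occur, 1 at independence, +inf
                     for perfectly positive association

Redundancy pruning drops any rule for which a strictly more general rule
(same consequent, antecedent a proper subset) reaches at least the same
confidence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .scheme import WTCAT

log = logging.getLogger(__name__)

#: Non-item columns of a categorical dataset.
META_COLUMNS = ("subjid", "group")


class Item(NamedTuple):
    """One (factor, category-code) attribute-value pair."""

    factor: str
    category: int

    def __str__(self) -> str:  # "irascore=4"
        return f"{self.factor}={self.category}"


@dataclass(frozen=True)
class RuleMetrics:
    support_count: int
    support: float
    confidence: float
    lift: float
    conviction: float
    chi2: float
    p_value: float
    strength: float


@dataclass(frozen=True)
class ClassRule:
    antecedent: frozenset[Item]
    consequent: Item
    metrics: RuleMetrics

    @property
    def length(self) -> int:
        """Total rule length, counting the consequent."""
        return len(self.antecedent) + 1

    def antecedent_sorted(self) -> tuple[Item, ...]:
        return tuple(sorted(self.antecedent))

    def __str__(self) -> str:
        lhs = ", ".join(map(str, self.antecedent_sorted()))
        return f"{{{lhs}}} => {self.consequent}"


def compute_metrics(antecedent_count: int, consequent_count: int,
                    joint_count: int, n: int) -> RuleMetrics:
    """All six interest measures from the four 2x2 counts.

    ``antecedent_count`` = sigma(X), ``consequent_count`` = sigma(Y),
    ``joint_count`` = sigma(X u Y), ``n`` = N.  Degenerate ratios follow the
    conventions 0/0 = 1 and x/0 = +inf (x > 0).
    """
    if not (0 <= joint_count <= min(antecedent_count, consequent_count) <= n):
        raise ValueError(
            f"inconsistent counts: joint={joint_count}, X={antecedent_count}, "
            f"Y={consequent_count}, N={n}")
    if antecedent_count == 0:
        raise ValueError("antecedent count must be positive")
    a = joint_count
    b = antecedent_count - joint_count
    c_ = consequent_count - joint_count
    d = n - antecedent_count - consequent_count + joint_count
    support = a / n
    confidence = a / antecedent_count
    s_y = consequent_count / n

    if s_y > 0:
        lift = confidence / s_y
    else:
        lift = 1.0 if confidence == 0 else float("inf")
    conviction = float("inf") if confidence == 1.0 else (1.0 - s_y) / (1.0 - confidence)
    chi2, p = _chi2_2x2(a, b, c_, d, n)
    num, den = a * d, b * c_
    if den == 0:
        strength = 1.0 if num == 0 else float("inf")
    else:
        strength = num / den
    return RuleMetrics(support_count=a, support=support, confidence=confidence,
                       lift=lift, conviction=conviction, chi2=chi2,
                       p_value=p, strength=strength)


def _chi2_2x2(a: int, b: int, c: int, d: int, n: int) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table."""
    margins = ((a + b), (c + d), (a + c), (b + d))
    if 0 in margins:
        return 0.0, 1.0
    chi2 = n * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


# -- Apriori ---------------------------------------------------------------

def _item_columns(dataset: pd.DataFrame) -> list[str]:
    return [c for c in dataset.columns if c not in META_COLUMNS]


def _item_vectors(dataset: pd.DataFrame,
                  columns: Iterable[str]) -> dict[Item, np.ndarray]:
    vectors: dict[Item, np.ndarray] = {}
    for col in columns:
        values = dataset[col].to_numpy()
        for v in np.unique(values):
            vectors[Item(col, int(v))] = values == v
    return vectors


def mine_frequent_itemsets(dataset: pd.DataFrame, min_support: float,
                           max_len: int | None = None,
                           item_vectors: Mapping[Item, np.ndarray] | None = None,
                           ) -> dict[frozenset[Item], int]:
    """Level-wise Apriori over the one-item-per-factor transaction matrix.

    Returns every itemset with support >= ``min_support`` (fraction of rows)
    together with its exact support count.  Candidate (k)-itemsets are formed
    by joining (k-1)-itemsets sharing a (k-2)-prefix and pruned when any
    (k-1)-subset is infrequent (anti-monotonicity).
    """
    if len(dataset) == 0:
        raise ValueError("cannot mine an empty dataset")
    if not 0.0 < min_support <= 1.0:
        raise ValueError("min_support must lie in (0, 1]")
    n = len(dataset)
    min_count = min_support * n - 1e-9
    if item_vectors is None:
        item_vectors = _item_vectors(dataset, _item_columns(dataset))

    frequent: dict[frozenset[Item], int] = {}
    # level 1
    level: list[tuple[tuple[Item, ...], np.ndarray]] = []
    for item in sorted(item_vectors):
        vec = item_vectors[item]
        count = int(vec.sum())
        if count >= min_count:
            frequent[frozenset((item,))] = count
            level.append(((item,), vec))
    k = 2
    while level and (max_len is None or k <= max_len):
        next_level: list[tuple[tuple[Item, ...], np.ndarray]] = []
        level_keys = {key for key, _ in level}
        for i in range(len(level)):
            key_i, vec_i = level[i]
            for j in range(i + 1, len(level)):
                key_j, vec_j = level[j]
                if key_i[:-1] != key_j[:-1]:
                    break  # sorted prefix join exhausted
                candidate = key_i + (key_j[-1],)
                if any(candidate[:m] + candidate[m + 1:] not in level_keys
                       for m in range(len(candidate) - 2)):
                    continue  # an infrequent (k-1)-subset exists
                vec = vec_i & vec_j
                count = int(vec.sum())
                if count >= min_count:
                    frequent[frozenset(candidate)] = count
                    next_level.append((candidate, vec))
        next_level.sort(key=lambda kv: kv[0])
        level = next_level
        k += 1
    return frequent


def mine_class_rules(dataset: pd.DataFrame, consequent: Item,
                     min_confidence: float = 0.9, min_len: int = 2,
                     max_len: int = 5, min_support: float = 0.01,
                     ) -> list[ClassRule]:
    """Mine rules X => consequent meeting the support/confidence/length filters.

    Length counts the consequent, so ``min_len=2, max_len=5`` admits
    antecedents of one to four items.  The antecedent never contains the
    consequent's factor.  Output is deterministically ordered by lift
    (descending), then confidence (descending), then the lexicographic
    antecedent.
    """
    if consequent.factor not in dataset.columns:
        raise KeyError(f"consequent factor {consequent.factor!r} not in dataset")
    n = len(dataset)
    if n == 0:
        raise ValueError("cannot mine an empty dataset")
    y_vec = dataset[consequent.factor].to_numpy() == consequent.category
    sigma_y = int(y_vec.sum())
    if sigma_y == 0:
        warnings.warn(f"consequent {consequent} absent from dataset; no rules",
                      stacklevel=2)
        return []
    antecedent_cols = [c for c in _item_columns(dataset) if c != consequent.factor]
    vectors = _item_vectors(dataset, antecedent_cols)
    vectors[consequent] = y_vec
    frequent = mine_frequent_itemsets(dataset, min_support, max_len=max_len,
                                      item_vectors=vectors)
    rules: list[ClassRule] = []
    for itemset, joint in frequent.items():
        if consequent not in itemset:
            continue
        if not (min_len <= len(itemset) <= max_len) or len(itemset) == 1:
            continue
        antecedent = itemset - {consequent}
        sigma_x = frequent[antecedent]  # guaranteed by anti-monotonicity
        if joint / sigma_x < min_confidence - 1e-12:
            continue
        metrics = compute_metrics(sigma_x, sigma_y, joint, n)
        rules.append(ClassRule(antecedent=frozenset(antecedent),
                               consequent=consequent, metrics=metrics))
    rules.sort(key=lambda r: (-r.metrics.lift, -r.metrics.confidence,
                              r.antecedent_sorted()))
    return rules


def eliminate_redundant(rules: Iterable[ClassRule]) -> list[ClassRule]:
    """Drop every rule with a strictly more general, at-least-as-confident peer.

    A rule r is redundant iff some rule r' in the input shares its consequent,
    has antecedent(r') a proper subset of antecedent(r), and
    confidence(r') >= confidence(r).  Input order is preserved.
    """
    rules = list(rules)
    kept = []
    for r in rules:
        redundant = any(
            o.consequent == r.consequent
            and o.antecedent < r.antecedent
            and o.metrics.confidence >= r.metrics.confidence
            for o in rules)
        if not redundant:
            kept.append(r)
    return kept


def antecedent_histogram(rules: Iterable[ClassRule]) -> dict[Item, int]:
    """Occurrence count of each antecedent item across a rule set."""
    hist: dict[Item, int] = {}
    for rule in rules:
        for item in rule.antecedent:
            hist[item] = hist.get(item, 0) + 1
    return hist


# -- serialization ---------------------------------------------------------

def rules_to_frame(rules: Iterable[ClassRule]) -> pd.DataFrame:
    """Tabular rule report (one row per rule, antecedent semicolon-joined)."""
    rows = [{
        "antecedent": ";".join(map(str, r.antecedent_sorted())),
        "consequent": str(r.consequent),
        "support_count": r.metrics.support_count,
        "support": r.metrics.support,
        "confidence": r.metrics.confidence,
        "lift": r.metrics.lift,
        "conviction": r.metrics.conviction,
        "chi2": r.metrics.chi2,
        "p_value": r.metrics.p_value,
        "strength": r.metrics.strength,
    } for r in rules]
    return pd.DataFrame(rows, columns=[
        "antecedent", "consequent", "support_count", "support", "confidence",
        "lift", "conviction", "chi2", "p_value", "strength"])


def _parse_item(text: str) -> Item:
    factor, _, category = text.partition("=")
    return Item(factor.strip(), int(category))


def rules_from_frame(frame: pd.DataFrame) -> list[ClassRule]:
    """Inverse of :func:`rules_to_frame`."""
    out = []
    for _, row in frame.iterrows():
        metrics = RuleMetrics(
            support_count=int(row["support_count"]),
            support=float(row["support"]),
            confidence=float(row["confidence"]),
            lift=float(row["lift"]),
            conviction=float(row["conviction"]),
            chi2=float(row["chi2"]),
            p_value=float(row["p_value"]),
            strength=float(row["strength"]))
        antecedent = frozenset(_parse_item(t) for t in str(row["antecedent"]).split(";"))
        out.append(ClassRule(antecedent=antecedent,
                             consequent=_parse_item(row["consequent"]),
                             metrics=metrics))
    return out
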