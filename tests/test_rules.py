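"""Rule mining: hand-computed metrics, Apriori vs brute force, pruning."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import hdweight as hw
from hdweight.rules import Item, ClassRule, RuleMetrics, rules_to_frame, rules_from_frame


# -- independent oracle ----------------------------------------------------

def oracle_metrics(sx, sy, joint, n):
    """Six measures from first principles (closed-form chi-square p via erfc)."""
    a, b, c_, d = joint, sx - joint, sy - joint, n - sx - sy + joint
    support = joint / n
    conf = joint / sx
    lift = conf / (sy / n) if sy else (1.0 if conf == 0 else math.inf)
    conv = math.inf if conf == 1 else (1 - sy / n) / (1 - conf)
    if 0 in (a + b, c_ + d, a + c_, b + d):
        chi2, p = 0.0, 1.0
    else:
        chi2 = n * (a * d - b * c_) ** 2 / ((a + b) * (c_ + d) * (a + c_) * (b + d))
        p = math.erfc(math.sqrt(chi2 / 2))  # upper tail of chi2 with 1 df
    if b * c_ == 0:
        strength = 1.0 if a * d == 0 else math.inf
    else:
        strength = a * d / (b * c_)
    return support, conf, lift, conv, chi2, p, strength


def brute_force_class_rules(kb, consequent, min_confidence, min_len, max_len,
                            min_support):
    """Exhaustively enumerate every antecedent subset and filter."""
    n = len(kb)
    cols = [c for c in kb.columns if c not in ("subjid", "group", consequent.factor)]
    items = [Item(c, int(v)) for c in cols for v in sorted(kb[c].unique())]
    vecs = {it: (kb[it.factor].to_numpy() == it.category) for it in items}
    y = kb[consequent.factor].to_numpy() == consequent.category
    sy = int(y.sum())
    found = {}
    for size in range(max(min_len - 1, 1), max_len):
        for combo in combinations(items, size):
            if len({it.factor for it in combo}) < size:
                continue
            mask = np.ones(n, dtype=bool)
            for it in combo:
                mask &= vecs[it]
            sx = int(mask.sum())
            if sx == 0:
                continue
            joint = int((mask & y).sum())
            if joint < min_support * n - 1e-9:
                continue
            if joint / sx < min_confidence - 1e-12:
                continue
            found[frozenset(combo)] = oracle_metrics(sx, sy, joint, n)
    return found


def random_kb(rng, n_rows, n_factors):
    data = {"wtCat": rng.choice([-3, -2, 0, 2], size=n_rows, p=[0.2, 0.2, 0.5, 0.1])}
    for j in range(n_factors - 1):
        k = rng.integers(2, 5)
        data[f"f{j}"] = rng.integers(0, k, size=n_rows)
    return pd.DataFrame(data)


# -- compute_metrics -------------------------------------------------------

def test_metrics_perfect_confidence():
    m = hw.compute_metrics(4, 5, 4, 10)
    assert (m.support, m.confidence, m.lift) == (0.4, 1.0, 2.0)
    assert m.conviction == math.inf and m.strength == math.inf
    assert m.chi2 == pytest.approx(10 * (4 * 5 - 0 * 1) ** 2 / (4 * 6 * 5 * 5))


def test_metrics_exact_independence():
    m = hw.compute_metrics(50, 40, 20, 100)
    assert m.lift == 1.0 and m.conviction == 1.0
    assert m.chi2 == 0.0 and m.strength == 1.0


def test_metrics_odds_ratio_hand_case():
    # a=3, b=1, c=2, d=4  ->  strength = (3*4)/(1*2) = 6
    m = hw.compute_metrics(4, 5, 3, 10)
    assert m.strength == pytest.approx(6.0)


def test_metrics_never_cooccurring():
    m = hw.compute_metrics(30, 40, 0, 100)
    assert m.strength == 0.0 and m.confidence == 0.0


def test_metrics_contract_errors():
    with pytest.raises(ValueError):
        hw.compute_metrics(4, 5, 6, 10)   # joint > min(X, Y)
    with pytest.raises(ValueError):
        hw.compute_metrics(0, 5, 0, 10)   # empty antecedent


@given(st.data())
@settings(max_examples=300, deadline=None)
def test_metric_algebra(data):
    """s <= min(sX,sY); c >= s; lift*s(Y) = c; chi2 = 0 iff lift = 1."""
    n = data.draw(st.integers(2, 500))
    sx = data.draw(st.integers(1, n))
    sy = data.draw(st.integers(0, n))
    joint = data.draw(st.integers(max(0, sx + sy - n), min(sx, sy)))
    m = hw.compute_metrics(sx, sy, joint, n)
    assert m.support <= min(sx / n, sy / n) + 1e-12
    assert m.confidence >= m.support - 1e-12
    if sy > 0:
        assert m.lift * (sy / n) == pytest.approx(m.confidence, abs=1e-12)
    assert m.chi2 >= 0
    if 0 < sx < n and 0 < sy < n:
        assert (m.chi2 == 0) == (m.lift == pytest.approx(1.0))
    # agreement with the independent formulation
    exp = oracle_metrics(sx, sy, joint, n)
    for got, want in zip((m.support, m.confidence, m.lift, m.conviction,
                          m.chi2, m.p_value, m.strength), exp):
        if math.isinf(want):
            assert math.isinf(got)
        else:
            assert got == pytest.approx(want, rel=1e-9, abs=1e-12)


# -- Apriori ---------------------------------------------------------------

def test_apriori_tiny_enumeration():
    """Transactions {A},{A,B},{A,B},{B} as two binary columns, min support 0.5."""
    kb = pd.DataFrame({"A": [1, 1, 1, 0], "B": [0, 1, 1, 1]})
    freq = hw.mine_frequent_itemsets(kb, min_support=0.5)
    counts = {tuple(sorted(str(i) for i in k)): v for k, v in freq.items()}
    assert counts[("A=1",)] == 3
    assert counts[("B=1",)] == 3
    assert counts[("A=1", "B=1")] == 2
    # A=0 occurs once (support .25): absent
    assert ("A=0",) not in counts


def test_apriori_min_support_one():
    kb = pd.DataFrame({"A": [1, 1], "B": [1, 0]})
    freq = hw.mine_frequent_itemsets(kb, min_support=1.0)
    assert frozenset({Item("A", 1)}) in freq
    assert frozenset({Item("A", 1), Item("B", 1)}) not in freq


def test_apriori_anti_monotone(planted_kb):
    freq = hw.mine_frequent_itemsets(planted_kb.sample(300, random_state=0),
                                     min_support=0.1, max_len=3)
    for itemset, count in freq.items():
        for item in itemset:
            sub = itemset - {item}
            if sub:
                assert sub in freq and freq[sub] >= count


def test_apriori_rejects_empty_or_bad_support():
    with pytest.raises(ValueError):
        hw.mine_frequent_itemsets(pd.DataFrame({"A": []}), 0.5)
    with pytest.raises(ValueError):
        hw.mine_frequent_itemsets(pd.DataFrame({"A": [1]}), 0.0)


# -- class rules -----------------------------------------------------------

def test_planted_rule_is_mined(planted_kb):
    rules = hw.mine_class_rules(planted_kb, Item("wtCat", -3), min_support=0.05)
    target = frozenset({Item("tfcscore", 1), Item("irascore", 4)})
    match = [r for r in rules if r.antecedent == target]
    assert len(match) == 1
    assert match[0].metrics.confidence == pytest.approx(0.95, abs=0.03)
    assert match[0].metrics.lift > 1


def test_min_confidence_one_without_perfect_rule():
    rng = np.random.default_rng(0)
    kb = random_kb(rng, 200, 4)
    rules = hw.mine_class_rules(kb, Item("wtCat", -3), min_confidence=1.0,
                                min_support=0.3)
    for r in rules:
        assert r.metrics.confidence == 1.0


def test_absent_consequent_warns_and_returns_empty(planted_kb):
    kb = planted_kb[planted_kb["wtCat"] != 3]
    with pytest.warns(UserWarning):
        assert hw.mine_class_rules(kb, Item("wtCat", 3)) == []


def test_rule_lengths_and_disjointness(planted_kb):
    rules = hw.mine_class_rules(planted_kb, Item("wtCat", -3), min_support=0.02)
    for r in rules:
        assert 2 <= r.length <= 5
        assert all(it.factor != "wtCat" for it in r.antecedent)


@pytest.mark.parametrize("seed", range(12))
def test_miner_matches_brute_force(seed):
    """Mined rules and all six metrics equal exhaustive enumeration."""
    rng = np.random.default_rng(seed)
    kb = random_kb(rng, int(rng.integers(100, 500)), int(rng.integers(3, 8)))
    min_support = float(rng.uniform(0.02, 0.08))
    min_confidence = float(rng.uniform(0.2, 0.6))
    consequent = Item("wtCat", int(rng.choice([-3, -2])))
    mined = hw.mine_class_rules(kb, consequent, min_confidence=min_confidence,
                                min_support=min_support)
    expected = brute_force_class_rules(kb, consequent, min_confidence, 2, 5,
                                       min_support)
    got = {r.antecedent: r.metrics for r in mined}
    assert set(got) == set(expected)
    for ant, want in expected.items():
        m = got[ant]
        for g, w in zip((m.support, m.confidence, m.lift, m.conviction,
                         m.chi2, m.p_value, m.strength), want):
            if math.isinf(w):
                assert math.isinf(g)
            else:
                assert g == pytest.approx(w, rel=1e-9, abs=1e-12)


def test_rule_order_is_deterministic(planted_kb):
    a = hw.mine_class_rules(planted_kb, Item("wtCat", -3), min_support=0.02)
    b = hw.mine_class_rules(planted_kb.sample(frac=1, random_state=1),
                            Item("wtCat", -3), min_support=0.02)
    assert [(r.antecedent, r.metrics) for r in a] == \
           [(r.antecedent, r.metrics) for r in b]


# -- redundancy ------------------------------------------------------------

def _rule(antecedent, confidence, consequent=Item("wtCat", -3)):
    m = RuleMetrics(support_count=10, support=0.1, confidence=confidence,
                    lift=2.0, conviction=2.0, chi2=1.0, p_value=0.1, strength=2.0)
    return ClassRule(frozenset(Item(f, 1) for f in antecedent), consequent, m)


def test_redundant_rule_removed():
    specific = _rule({"A", "B"}, 0.92)
    general = _rule({"A"}, 0.95)
    assert hw.eliminate_redundant([specific, general]) == [general]


def test_more_confident_specific_rule_kept():
    specific = _rule({"A", "B"}, 0.97)
    general = _rule({"A"}, 0.95)
    assert hw.eliminate_redundant([specific, general]) == [specific, general]


def test_redundancy_predicate_on_mined_rules(planted_kb):
    rules = hw.mine_class_rules(planted_kb, Item("wtCat", -3), min_support=0.02)
    kept = hw.eliminate_redundant(rules)
    # quadratic brute-force check of the predicate on the output
    for r in kept:
        for o in kept:
            assert not (o.consequent == r.consequent
                        and o.antecedent < r.antecedent
                        and o.metrics.confidence >= r.metrics.confidence)
    assert hw.eliminate_redundant(kept) == kept  # idempotence


def test_antecedent_histogram():
    rules = [_rule({"A", "B"}, 0.95), _rule({"A", "C"}, 0.95)]
    hist = hw.antecedent_histogram(rules)
    assert hist == {Item("A", 1): 2, Item("B", 1): 1, Item("C", 1): 1}
    assert sum(hist.values()) == sum(len(r.antecedent) for r in rules)
    assert hw.antecedent_histogram([]) == {}


def test_rule_frame_round_trip(planted_kb):
    rules = hw.mine_class_rules(planted_kb, Item("wtCat", -3), min_support=0.05)
    back = rules_from_frame(rules_to_frame(rules))
    assert [(r.antecedent, r.consequent) for r in back] == \
           [(r.antecedent, r.consequent) for r in rules]
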