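"""Apriori mining: itemsets, rules, presets, and brute-force agreement."""

import textwrap
from itertools import combinations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpv.mining import (
    MiningConfig,
    PRESETS,
    Transaction,
    frequent_itemsets,
    generate_rules,
    mine_protocol,
    normalize_item,
    read_item_classes,
    read_transactions,
)
from cpv.simulate import random_transactions

from oracles import brute_frequent_itemsets, brute_rules


def fs(*items):
    return frozenset(items)


class TestTransactionsIO:
    def test_wide_csv(self, tmp_path):
        p = tmp_path / "wide.csv"
        p.write_text(
            textwrap.dedent(
                """\
                case_id,Uterine atony,Macrosomia,Diabetes,Anemia
                c1,1,0,1,0
                c2,0,1,0,0
                c3,1,1,0,1
                """
            )
        )
        tx = read_transactions(p)
        assert len(tx) == 3
        assert tx[0].items == fs("uterine atony", "diabetes")
        assert tx[2].items == fs("uterine atony", "macrosomia", "anemia")

    def test_long_csv_collapses_duplicates(self, tmp_path):
        p = tmp_path / "long.csv"
        p.write_text(
            "case_id,item\nc1,Uterine  Atony\nc1,uterine atony\nc1,Diabetes\nc2,Anemia\n"
        )
        tx = read_transactions(p)
        assert tx[0].items == fs("uterine atony", "diabetes")
        assert tx[1].items == fs("anemia")

    def test_all_empty_cases_is_an_error(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("case_id,a,b\nc1,0,0\nc2,0,0\n")
        with pytest.raises(ValueError, match="no non-empty"):
            read_transactions(p)

    def test_item_class_map(self, tmp_path):
        p = tmp_path / "classes.csv"
        p.write_text("item,class\nUterine atony,cause\nCefotiam,Treatment\n")
        classes = read_item_classes(p)
        assert classes == {"uterine atony": "cause", "cefotiam": "treatment"}

    def test_empty_transaction_rejected(self):
        with pytest.raises(ValueError, match="no items"):
            Transaction("c1", frozenset())

    def test_normalize_item(self):
        assert normalize_item("  Uterine   Atony ") == "uterine atony"


class TestFrequentItemsets:
    def test_four_transaction_fixture(self, four_transactions):
        got = {
            r.items: r.support
            for r in frequent_itemsets(four_transactions, MiningConfig(min_support=0.5))
        }
        assert got == {
            fs("a"): 0.75,
            fs("b"): 0.75,
            fs("c"): 0.5,
            fs("a", "b"): 0.5,
            fs("a", "c"): 0.5,
        }

    def test_threshold_above_every_support_gives_empty(self, four_transactions):
        assert frequent_itemsets(four_transactions, MiningConfig(min_support=0.99)) == []

    def test_min_support_one_over_n_returns_all_occurring(self, four_transactions):
        got = {r.items for r in frequent_itemsets(four_transactions, MiningConfig(min_support=0.25))}
        expected = set()
        for t in four_transactions:
            items = sorted(t.items)
            for size in range(1, len(items) + 1):
                expected |= {frozenset(c) for c in combinations(items, size)}
        assert got == expected

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("min_support", [0.1, 0.3, 0.6])
    def test_matches_powerset_oracle(self, seed, min_support):
        tx = random_transactions(60, 8, seed=seed, rate=0.4)
        got = {
            r.items: r.support
            for r in frequent_itemsets(tx, MiningConfig(min_support=min_support))
        }
        expected = brute_frequent_itemsets(tx, min_support)
        assert got.keys() == expected.keys()
        for k in got:
            assert got[k] == pytest.approx(expected[k], abs=1e-12)

    def test_anti_monotonicity_of_output(self):
        tx = random_transactions(80, 9, seed=11, rate=0.45)
        records = frequent_itemsets(tx, MiningConfig(min_support=0.05))
        supp = {r.items: r.support for r in records}
        for a in supp:
            for b in supp:
                if a < b:
                    assert supp[b] <= supp[a] + 1e-12


class TestGenerateRules:
    def test_fixture_rule_metrics(self, four_transactions):
        config = MiningConfig(min_support=0.5, min_confidence=0.0, min_lift=0.0)
        itemsets = frequent_itemsets(four_transactions, config)
        rules = generate_rules(itemsets, four_transactions, config)
        ab = next(r for r in rules if r.antecedent == fs("a") and r.consequent == fs("b"))
        assert ab.support == pytest.approx(0.5, abs=1e-12)
        assert ab.confidence == pytest.approx(2 / 3, abs=1e-12)
        assert ab.lift == pytest.approx(8 / 9, abs=1e-12)

    def test_universal_consequent_forces_lift_one(self):
        tx = [
            Transaction("c1", fs("x", "y")),
            Transaction("c2", fs("y")),
            Transaction("c3", fs("x", "y", "z")),
        ]
        config = MiningConfig(min_support=0.3, min_confidence=0.0, min_lift=0.0)
        rules = generate_rules(frequent_itemsets(tx, config), tx, config)
        for r in rules:
            if r.consequent == fs("y"):
                assert r.lift == pytest.approx(1.0, abs=1e-12)
                assert r.confidence == pytest.approx(1.0, abs=1e-12)

    def test_deterministic_implication_has_confidence_one(self):
        tx = [Transaction(f"c{i}", fs("x", "y")) for i in range(3)] + [
            Transaction("c3", fs("z"))
        ]
        config = MiningConfig(min_support=0.5, min_confidence=0.0, min_lift=0.0)
        rules = generate_rules(frequent_itemsets(tx, config), tx, config)
        xy = next(r for r in rules if r.antecedent == fs("x"))
        assert xy.confidence == 1.0

    def test_lift_support_confidence_identity(self):
        tx = random_transactions(100, 8, seed=5, rate=0.4)
        config = MiningConfig(min_support=0.05, min_confidence=0.1, min_lift=0.0)
        rules = generate_rules(frequent_itemsets(tx, config), tx, config)
        assert rules
        supp = {r.items: r.support for r in frequent_itemsets(tx, MiningConfig(min_support=1 / len(tx)))}
        for r in rules:
            assert r.antecedent.isdisjoint(r.consequent)
            assert r.lift * supp[r.consequent] == pytest.approx(r.confidence, abs=1e-9)
            assert r.support <= min(supp[r.antecedent], supp[r.consequent]) + 1e-12

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        ds=st.floats(0.0, 0.3),
        dc=st.floats(0.0, 0.3),
        dl=st.floats(0.0, 0.3),
    )
    def test_raising_thresholds_never_adds_rules(self, ds, dc, dl):
        tx = random_transactions(50, 6, seed=9, rate=0.5)
        base = MiningConfig(min_support=0.05, min_confidence=0.2, min_lift=0.5)
        tight = MiningConfig(
            min_support=base.min_support + ds,
            min_confidence=base.min_confidence + dc,
            min_lift=base.min_lift + dl,
        )

        def key(rules):
            return {(r.antecedent, r.consequent) for r in rules}

        loose_rules = key(mine_protocol(tx, base))
        tight_rules = key(mine_protocol(tx, tight))
        assert tight_rules <= loose_rules


class TestProtocols:
    def test_preset_thresholds(self):
        assert (PRESETS["double-factor"].min_support,
                PRESETS["double-factor"].min_confidence,
                PRESETS["double-factor"].min_lift) == (0.05, 0.5, 0.9)
        assert PRESETS["triple-factor"].min_support == 0.12
        assert (PRESETS["treatment"].min_support,
                PRESETS["treatment"].min_confidence,
                PRESETS["treatment"].min_lift) == (0.05, 0.15, 1.0)

    def test_unknown_preset(self, four_transactions):
        with pytest.raises(ValueError, match="unknown preset"):
            mine_protocol(four_transactions, "quadruple-factor")

    def test_triple_factor_deterministic_co_occurrence(self):
        # three cause items always co-occur with bleeding -> confidence 1
        always = fs("soft birth canal damage", "abnormal fetal position", "uterine atony")
        tx = [Transaction(f"c{i}", always | fs("bleeding")) for i in range(40)] + [
            Transaction(f"d{i}", fs("bleeding", "diabetes")) for i in range(60)
        ]
        rules = mine_protocol(tx, "triple-factor")
        two_cause = [
            r for r in rules
            if r.antecedent < always and r.consequent < always
        ]
        assert two_cause
        assert all(r.confidence == 1.0 for r in two_cause)

    def test_empty_result_when_nothing_passes_support(self):
        tx = [Transaction(f"c{i}", fs(f"i{i}", f"j{i}")) for i in range(20)]
        assert mine_protocol(tx, "triple-factor") == []

    def test_treatment_preset_requires_and_uses_classes(self):
        tx = [
            Transaction(f"c{i}", fs("uterine atony", "cefotiam")) for i in range(30)
        ] + [Transaction(f"d{i}", fs("uterine atony")) for i in range(70)]
        classes = {"uterine atony": "cause", "cefotiam": "treatment"}
        with pytest.raises(ValueError, match="item-class map"):
            mine_protocol(tx, "treatment")
        rules = mine_protocol(tx, "treatment", item_classes=classes)
        assert len(rules) == 1
        r = rules[0]
        assert r.antecedent == fs("uterine atony")
        assert r.consequent == fs("cefotiam")
        assert r.support == pytest.approx(0.3, abs=1e-12)
        assert r.confidence == pytest.approx(0.3, abs=1e-12)
        assert r.lift == pytest.approx(1.0, abs=1e-12)

    def test_sorted_by_support_then_confidence(self):
        tx = random_transactions(120, 7, seed=21, rate=0.5)
        rules = mine_protocol(
            tx, MiningConfig(min_support=0.05, min_confidence=0.1, min_lift=0.0)
        )
        keys = [(-r.support, -r.confidence) for r in rules]
        assert keys == sorted(keys)

    @pytest.mark.parametrize("seed", range(4))
    def test_rules_match_brute_force(self, seed):
        tx = random_transactions(70, 7, seed=400 + seed, rate=0.45)
        config = MiningConfig(
            min_support=0.08, min_confidence=0.3, min_lift=0.8, max_antecedent_size=6
        )
        got = {
            (r.antecedent, r.consequent): (r.support, r.confidence, r.lift)
            for r in mine_protocol(tx, config)
        }
        expected = brute_rules(tx, 0.08, 0.3, 0.8)
        assert got.keys() == expected.keys()
        for k, (s, c, l) in expected.items():
            assert got[k] == pytest.approx((s, c, l), abs=1e-12)
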