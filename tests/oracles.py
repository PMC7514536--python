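"""Independent brute-force oracles used only by the tests.

These deliberately share no code path with the package implementation:
inference is checked against direct summation of the fully enumerated joint
table, and mining against a powerset scan.  Both are exponential and only
ever applied to small instances.
"""

from __future__ import annotations

import itertools
from itertools import combinations


def full_joint_table(net):
    """Every full assignment -> its chain-rule probability, via direct CPT
    row lookups only."""
    ids = list(net.nodes)
    table = {}
    for combo in itertools.product(*(net.nodes[n].states for n in ids)):
        asg = dict(zip(ids, combo))
        p = 1.0
        for nid in ids:
            t = net.tables[nid]
            row = t.row(asg)
            p *= float(row[net.nodes[nid].states.index(asg[nid])])
        table[combo] = p
    return ids, table


def brute_posterior(net, query, evidence):
    """P(query | evidence) by summing the enumerated joint; returns a dict
    state -> probability.  Raises ZeroDivisionError on zero evidence."""
    ids, table = full_joint_table(net)
    qi = ids.index(query)
    totals = {s: 0.0 for s in net.nodes[query].states}
    for combo, p in table.items():
        asg = dict(zip(ids, combo))
        if all(asg[k] == v for k, v in evidence.items()):
            totals[combo[qi]] += p
    z = sum(totals.values())
    return {s: t / z for s, t in totals.items()}


def brute_frequent_itemsets(transactions, min_support):
    """All itemsets meeting min_support, by scanning the powerset of the
    item universe."""
    items = sorted({i for t in transactions for i in t.items})
    n = len(transactions)
    out = {}
    for size in range(1, len(items) + 1):
        for subset in combinations(items, size):
            s = frozenset(subset)
            count = sum(1 for t in transactions if s <= t.items)
            if count / n >= min_support - 1e-12:
                out[s] = count / n
    return out


def brute_rules(transactions, min_support, min_confidence, min_lift,
                min_ant=1, max_ant=12):
    """All single-consequent rules meeting the thresholds, by brute force.

    Returns a dict (antecedent, consequent) -> (support, confidence, lift).
    """
    freq = brute_frequent_itemsets(transactions, min_support)
    # supports of every itemset, not just frequent ones, for denominators
    all_supp = brute_frequent_itemsets(transactions, 1e-12)
    rules = {}
    for itemset, supp in freq.items():
        if len(itemset) < 2:
            continue
        for cons in itemset:
            ant = itemset - {cons}
            if not (min_ant <= len(ant) <= max_ant):
                continue
            conf = supp / all_supp[ant]
            lift = conf / all_supp[frozenset([cons])]
            if conf >= min_confidence - 1e-12 and lift >= min_lift - 1e-12:
                rules[(ant, frozenset([cons]))] = (supp, conf, lift)
    return rules
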