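import numpy as np
import pytest

from cpv.mining import Transaction
from cpv.network import (
    BayesianNetwork,
    ConditionalTable,
    DEFAULT_STATES,
    NodeSpec,
    build_pph_fixture,
)


@pytest.fixture(scope="session")
def pph():
    return build_pph_fixture()


@pytest.fixture(scope="session")
def pph_sub(pph):
    """The fully specified coagulopathy sub-network {C6, C11, B4}."""
    return pph.subnetwork({"C6", "C11", "B4"})


def make_net(priors, cpts, layers=None, metadata=None):
    """Compact binary-network builder for tests.

    ``priors``: {node: P(State1)}; ``cpts``: {node: (parent_order, {parent
    State1-tuple of 0/1: P(node=State1)})}.
    """
    nodes, tables = [], []
    layers = layers or {}
    for nid, p1 in priors.items():
        nodes.append(NodeSpec(id=nid, layer=layers.get(nid), states=DEFAULT_STATES))
        tables.append(
            ConditionalTable(nid, (), (), DEFAULT_STATES, np.array([1 - p1, p1]))
        )
    for nid, (parents, rows) in cpts.items():
        parents = tuple(parents)
        nodes.append(
            NodeSpec(id=nid, layer=layers.get(nid), states=DEFAULT_STATES, parents=parents)
        )
        values = np.empty((2,) * len(parents) + (2,))
        for combo, p1 in rows.items():
            values[tuple(combo)] = (1 - p1, p1)
        tables.append(
            ConditionalTable(
                nid, parents, tuple(DEFAULT_STATES for _ in parents),
                DEFAULT_STATES, values,
            )
        )
    return BayesianNetwork.from_parts(nodes, tables, metadata or {})


@pytest.fixture
def two_node_net():
    """C -> B with P(C=1)=0.5, P(B=1|C=1)=0.78, P(B=1|C=0)=0.1."""
    return make_net({"C": 0.5}, {"B": (("C",), {(0,): 0.1, (1,): 0.78})})


@pytest.fixture
def collider_net():
    """Two independent causes C1, C2 of one effect E (noisy-OR-ish)."""
    return make_net(
        {"C1": 0.3, "C2": 0.3},
        {"E": (("C1", "C2"), {(0, 0): 0.05, (1, 0): 0.6, (0, 1): 0.6, (1, 1): 0.9})},
    )


@pytest.fixture
def four_transactions():
    """The classic {ab, abc, ac, b} miner fixture."""
    return [
        Transaction("t1", frozenset("ab")),
        Transaction("t2", frozenset("abc")),
        Transaction("t3", frozenset("ac")),
        Transaction("t4", frozenset("b")),
    ]
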