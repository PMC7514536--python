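"""Synthetic cohorts and transaction sets with known ground truth.

The real study data (hospital charts and treatment records) are not
deposited anywhere, so every pipeline stage is exercised against synthetic
data whose generating process is known exactly:

* :func:`sample_cohort` draws full patient configurations from a Bayesian
  network by ancestral sampling, so empirical frequencies converge to the
  network's exact marginals;
* :func:`fit_cpts` recovers CPTs from a cohort by (smoothed) maximum
  likelihood, closing the sample→fit round trip;
* :func:`synthesize_transactions` builds case/item transaction tables with
  planted association rules whose realized support and confidence converge
  to chosen targets, closing the generate→mine round trip.

All randomness flows through one ``numpy.random.default_rng`` seeded
explicitly; identical inputs give identical outputs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import (
    BayesianNetwork,
    ConditionalTable,
    NodeSpec,
    UnspecifiedTableError,
    validate_network,
)

__all__ = [
    "Cohort",
    "PlantedRuleSpec",
    "sample_cohort",
    "fit_cpts",
    "synthesize_transactions",
    "random_network",
    "random_layered_network",
    "random_transactions",
]


@dataclass
class Cohort:
    """Simulated patients: one full state assignment per record.

    ``data`` is a DataFrame with one column per network node holding state
    names; ``source_network`` records provenance; ``seed`` the generator
    seed used.
    """

    data: pd.DataFrame
    source_network: str = ""
    seed: int | None = None

    @property
    def records(self) -> list[dict[str, str]]:
        return self.data.to_dict(orient="records")

    def __len__(self) -> int:
        return len(self.data)

    def to_binary_frame(self, net: BayesianNetwork) -> pd.DataFrame:
        """Wide 0/1 frame: state index per node (State0 -> 0, State1 -> 1)."""
        out = {}
        for nid in self.data.columns:
            states = list(net.nodes[nid].states)
            out[nid] = self.data[nid].map({s: i for i, s in enumerate(states)})
        return pd.DataFrame(out, index=self.data.index)


def sample_cohort(net: BayesianNetwork, n: int, seed: int) -> Cohort:
    """Draw ``n`` full configurations by ancestral sampling.

    Nodes are visited in topological order; each is drawn from its CPT row
    given the already-sampled parent states.  Refuses networks with
    UNSPECIFIED placeholder tables — samples from placeholders would carry
    no information about the modeled cohort.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    unspec = net.unspecified_nodes()
    if unspec:
        raise UnspecifiedTableError(
            f"cannot sample: nodes {sorted(unspec)} have UNSPECIFIED tables"
        )
    rng = np.random.default_rng(seed)
    order = net.topological_order()
    idx: dict[str, np.ndarray] = {}
    for nid in order:
        table = net.tables[nid]
        if table.parent_order:
            probs = table.values[tuple(idx[p] for p in table.parent_order)]
        else:
            probs = np.broadcast_to(table.values, (n, len(table.states)))
        cum = np.cumsum(probs, axis=1)
        u = rng.random(n)
        idx[nid] = np.minimum(
            (u[:, None] >= cum).sum(axis=1), len(table.states) - 1
        )
    cols = {
        nid: np.asarray(net.nodes[nid].states, dtype=object)[idx[nid]]
        for nid in order
    }
    return Cohort(
        data=pd.DataFrame(cols, columns=order),
        source_network=net.metadata.get("name", "unnamed"),
        seed=seed,
    )


def fit_cpts(
    cohort: Cohort,
    structure: BayesianNetwork | list[NodeSpec],
    smoothing: float = 1.0,
) -> BayesianNetwork:
    """Estimate every CPT from a cohort by smoothed maximum likelihood.

    Each entry is ``(count + smoothing) / (row_total + smoothing * k)`` for a
    node with ``k`` states (Laplace smoothing by default, so small clinical
    strata never yield 0/0 rows).  With ``smoothing=0``, parent rows never
    observed in the cohort fall back to uniform with a warning.
    """
    if smoothing < 0:
        raise ValueError("smoothing must be >= 0")
    nodes = (
        list(structure.nodes.values())
        if isinstance(structure, BayesianNetwork)
        else list(structure)
    )
    missing = {nd.id for nd in nodes} - set(cohort.data.columns)
    if missing:
        raise ValueError(f"cohort does not cover structure nodes {sorted(missing)}")
    node_map = {nd.id: nd for nd in nodes}

    # state-index view of the cohort
    idx: dict[str, np.ndarray] = {}
    for nd in nodes:
        lookup = {s: i for i, s in enumerate(nd.states)}
        col = cohort.data[nd.id].map(lookup)
        if col.isna().any():
            bad = cohort.data[nd.id][col.isna()].iloc[0]
            raise ValueError(f"cohort has unknown state {bad!r} for node {nd.id!r}")
        idx[nd.id] = col.to_numpy(dtype=int)

    tables: list[ConditionalTable] = []
    for nd in nodes:
        k = len(nd.states)
        parent_states = tuple(node_map[p].states for p in nd.parents)
        shape = tuple(len(s) for s in parent_states) + (k,)
        counts = np.zeros(shape)
        np.add.at(counts, tuple(idx[p] for p in nd.parents) + (idx[nd.id],), 1.0)
        row_totals = counts.sum(axis=-1, keepdims=True)
        if smoothing == 0:
            empty = row_totals[..., 0] == 0
            if np.any(empty):
                warnings.warn(
                    f"node {nd.id!r}: {int(empty.sum())} unobserved parent "
                    f"row(s) set to uniform (smoothing=0)",
                    UserWarning,
                    stacklevel=2,
                )
            with np.errstate(invalid="ignore", divide="ignore"):
                values = counts / row_totals
            values[empty] = 1.0 / k
        else:
            values = (counts + smoothing) / (row_totals + smoothing * k)
        tables.append(
            ConditionalTable(
                node=nd.id,
                parent_order=nd.parents,
                parent_states=parent_states,
                states=nd.states,
                values=values,
                note=f"fitted from cohort (n={len(cohort)}, smoothing={smoothing})",
            )
        )
    fitted = BayesianNetwork.from_parts(
        nodes,
        tables,
        {
            "name": "fitted",
            "fitted_from": cohort.source_network,
            "n_records": len(cohort),
            "smoothing": smoothing,
        },
    )
    problems = validate_network(fitted)
    if problems:  # pragma: no cover - estimator bug guard
        raise AssertionError("fitted network invalid: " + "; ".join(problems))
    return fitted


# ---------------------------------------------------------------------------
# Transactions with planted association rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedRuleSpec:
    """A rule to plant in synthetic transactions.

    With probability ``target_support`` a transaction carries
    antecedent ∪ {consequent}; with probability
    ``target_support * (1 - c) / c`` (c = ``target_confidence``) it carries
    the antecedent alone; the remaining mass draws background items
    independently at ``background_item_rate``.  The planted rule's realized
    support and confidence therefore converge to the targets as n grows.
    """

    antecedent: frozenset[str]
    consequent: str
    target_support: float
    target_confidence: float
    background_item_rate: float = 0.2

    def __post_init__(self) -> None:
        object.__setattr__(self, "antecedent", frozenset(self.antecedent))
        if not self.antecedent:
            raise ValueError("antecedent must be non-empty")
        if self.consequent in self.antecedent:
            raise ValueError("consequent must not appear in the antecedent")
        for name in ("target_support", "target_confidence"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.target_support > self.target_confidence:
            raise ValueError("target_support must not exceed target_confidence")
        if not (0.0 <= self.background_item_rate < 1.0):
            raise ValueError("background_item_rate must be in [0, 1)")

    @property
    def planted_mass(self) -> float:
        """Total fraction of transactions devoted to this rule."""
        return self.target_support / self.target_confidence


def synthesize_transactions(
    specs: list[PlantedRuleSpec],
    n: int,
    vocabulary: list[str],
    seed: int,
):
    """Generate ``n`` transactions with the given rules planted.

    Constraints for mutual consistency: rule antecedents must be pairwise
    disjoint, all specs must share one ``background_item_rate``, and the
    total planted mass must leave room for background transactions.
    Background draws exclude all antecedent items (so realized confidences
    are not diluted) and each rule's own consequent; empty background
    transactions are redrawn, since a case with no items carries no
    information.  Returns a list of :class:`~cpv.mining.Transaction`.
    """
    from .mining import Transaction, normalize_item

    if n < 1:
        raise ValueError(f"need n >= 1 transactions, got {n}")
    if not specs:
        raise ValueError("need at least one planted rule spec")
    vocab = [normalize_item(v) for v in vocabulary]
    if len(set(vocab)) != len(vocab):
        raise ValueError("vocabulary has duplicate items after normalization")
    specs = [
        PlantedRuleSpec(
            frozenset(normalize_item(a) for a in s.antecedent),
            normalize_item(s.consequent),
            s.target_support,
            s.target_confidence,
            s.background_item_rate,
        )
        for s in specs
    ]
    all_items = set(vocab)
    for s in specs:
        missing = (s.antecedent | {s.consequent}) - all_items
        if missing:
            raise ValueError(f"rule items {sorted(missing)} not in vocabulary")
    for a, b in itertools.combinations(specs, 2):
        if a.antecedent & b.antecedent:
            raise ValueError(
                "inconsistent specs: antecedents overlap "
                f"({sorted(a.antecedent & b.antecedent)})"
            )
    rates = {s.background_item_rate for s in specs}
    if len(rates) > 1:
        raise ValueError("inconsistent specs: background_item_rate differs")
    bg_rate = rates.pop()
    total_mass = sum(s.planted_mass for s in specs)
    if total_mass > 1.0 + 1e-9:
        raise ValueError(
            f"inconsistent specs: planted mass {total_mass:.3f} exceeds 1"
        )

    all_antecedent_items = frozenset(i for s in specs for i in s.antecedent)
    rng = np.random.default_rng(seed)

    # category per transaction: (spec_i with consequent), (spec_i without),
    # or pure background
    probs: list[float] = []
    for s in specs:
        probs.append(s.target_support)
        probs.append(s.planted_mass - s.target_support)
    probs.append(max(0.0, 1.0 - total_mass))
    categories = rng.choice(len(probs), size=n, p=np.asarray(probs) / sum(probs))

    def draw_background(exclude: frozenset[str], require_nonempty: bool) -> set[str]:
        pool = [v for v in vocab if v not in exclude]
        while True:
            picked = {v for v in pool if rng.random() < bg_rate}
            if picked or not require_nonempty or not pool:
                return picked

    out: list[Transaction] = []
    for i, cat in enumerate(categories):
        cat = int(cat)
        if cat < 2 * len(specs):
            s = specs[cat // 2]
            with_consequent = cat % 2 == 0
            items = set(s.antecedent)
            if with_consequent:
                items.add(s.consequent)
            exclude = all_antecedent_items | {s.consequent}
            items |= draw_background(exclude, require_nonempty=False)
        else:
            items = draw_background(all_antecedent_items, require_nonempty=True)
            if not items:
                # vocabulary is nothing but antecedent items; fall back to a
                # single random non-rule-breaking item is impossible, so the
                # transaction becomes one uniform vocabulary draw
                items = {vocab[int(rng.integers(len(vocab)))]}
        out.append(Transaction(case_id=f"case{i:06d}", items=frozenset(items)))
    return out


# ---------------------------------------------------------------------------
# Random model generators (calibration / benchmark harnesses)
# ---------------------------------------------------------------------------


def random_network(
    n_nodes: int,
    seed: int,
    max_parents: int = 3,
    concentration: float = 1.0,
) -> BayesianNetwork:
    """A random binary-node DAG with Dirichlet-distributed CPT rows.

    Nodes ``X1..Xn`` are ordered; each draws up to ``max_parents`` parents
    uniformly from its predecessors, so the graph is acyclic by
    construction.  ``concentration`` is the symmetric Dirichlet parameter of
    each CPT row (1 = uniform over the simplex; smaller values give more
    extreme rows).  Used to exercise inference and fitting against networks
    with no special structure.
    """
    if n_nodes < 1:
        raise ValueError("need at least one node")
    rng = np.random.default_rng(seed)
    from .network import DEFAULT_STATES

    nodes: list[NodeSpec] = []
    tables: list[ConditionalTable] = []
    ids = [f"X{i + 1}" for i in range(n_nodes)]
    for i, nid in enumerate(ids):
        k = min(max_parents, i)
        n_par = int(rng.integers(0, k + 1)) if k else 0
        parents = tuple(
            sorted(rng.choice(ids[:i], size=n_par, replace=False), key=ids.index)
        ) if n_par else ()
        nodes.append(NodeSpec(id=nid, states=DEFAULT_STATES, parents=parents))
        shape = (2,) * len(parents)
        values = rng.dirichlet([concentration, concentration], size=shape or None)
        values = values.reshape(shape + (2,))
        tables.append(
            ConditionalTable(
                node=nid,
                parent_order=parents,
                parent_states=tuple(DEFAULT_STATES for _ in parents),
                states=DEFAULT_STATES,
                values=values,
            )
        )
    net = BayesianNetwork.from_parts(nodes, tables, {"name": f"random-{seed}"})
    problems = validate_network(net)
    if problems:  # pragma: no cover - generator bug guard
        raise AssertionError("random network invalid: " + "; ".join(problems))
    return net


def random_layered_network(
    seed: int,
    n_primary: int = 4,
    n_secondary_per_primary: int = 2,
    dominant_primary: int = 0,
    dominant_effect: float = 0.82,
    background_effect: float = 0.04,
) -> tuple[BayesianNetwork, str]:
    """A random three-layer risk network with one dominant primary cause.

    Shape mirrors the postpartum-hemorrhage model: one variance node ``A``
    whose parents are primary factors ``B1..Bp``, each with its own
    secondary-factor parents ``C*``.  The variance CPT is additive:
    ``P(A=1 | b) = 0.08 + dominant_effect * b_dom + sum(w_i * b_i)`` with
    small random ``w_i <= background_effect`` for the other primaries, so
    the dominant factor's posterior given ``A=State1`` exceeds the others
    by construction.  Returns the network and the dominant node id.
    """
    rng = np.random.default_rng(seed)
    from .network import DEFAULT_STATES

    nodes: list[NodeSpec] = []
    tables: list[ConditionalTable] = []

    def prior(nid: str, layer: str, p1: float) -> None:
        nodes.append(NodeSpec(id=nid, layer=layer, states=DEFAULT_STATES))
        tables.append(
            ConditionalTable(nid, (), (), DEFAULT_STATES, np.array([1 - p1, p1]))
        )

    b_ids = [f"B{i + 1}" for i in range(n_primary)]
    for bi, b in enumerate(b_ids):
        c_ids = tuple(
            f"C{bi * n_secondary_per_primary + j + 1}"
            for j in range(n_secondary_per_primary)
        )
        for c in c_ids:
            prior(c, "secondary", float(rng.uniform(0.3, 0.6)))
        nodes.append(
            NodeSpec(id=b, layer="primary", states=DEFAULT_STATES, parents=c_ids)
        )
        base = rng.uniform(0.1, 0.25)
        weights = rng.uniform(0.1, 0.35, size=len(c_ids))
        rows = np.empty((2,) * len(c_ids) + (2,))
        for combo in itertools.product((0, 1), repeat=len(c_ids)):
            p1 = float(np.clip(base + np.dot(weights, combo), 0.0, 1.0))
            rows[combo] = (1 - p1, p1)
        tables.append(
            ConditionalTable(
                b, c_ids, tuple(DEFAULT_STATES for _ in c_ids), DEFAULT_STATES, rows
            )
        )

    dom = b_ids[dominant_primary]
    weights = rng.uniform(0.0, background_effect, size=n_primary)
    nodes.append(
        NodeSpec(id="A", layer="variance", states=DEFAULT_STATES, parents=tuple(b_ids))
    )
    rows = np.empty((2,) * n_primary + (2,))
    for combo in itertools.product((0, 1), repeat=n_primary):
        p1 = 0.08 + sum(
            (dominant_effect if b == dom else weights[i]) * combo[i]
            for i, b in enumerate(b_ids)
        )
        p1 = float(np.clip(p1, 0.0, 1.0))
        rows[combo] = (1 - p1, p1)
    tables.append(
        ConditionalTable(
            "A", tuple(b_ids), tuple(DEFAULT_STATES for _ in b_ids),
            DEFAULT_STATES, rows,
        )
    )
    net = BayesianNetwork.from_parts(
        nodes, tables, {"name": f"layered-{seed}", "layered": True}
    )
    problems = validate_network(net)
    if problems:  # pragma: no cover - generator bug guard
        raise AssertionError("layered network invalid: " + "; ".join(problems))
    return net, dom


def random_transactions(
    n: int, n_items: int, seed: int, rate: float = 0.35
):
    """Unstructured random transactions: each of ``n_items`` generic items
    appears independently with probability ``rate``; empty cases are
    redrawn.  Items are named ``i01, i02, ...``."""
    from .mining import Transaction

    if n < 1 or n_items < 1:
        raise ValueError("need n >= 1 and n_items >= 1")
    rng = np.random.default_rng(seed)
    items = [f"i{k + 1:02d}" for k in range(n_items)]
    out = []
    for i in range(n):
        while True:
            picked = frozenset(it for it in items if rng.random() < rate)
            if picked:
                break
        out.append(Transaction(case_id=f"case{i:06d}", items=picked))
    return out
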