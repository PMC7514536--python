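"""Layered discrete Bayesian networks for clinical-pathway variance analysis.

The model family here is the three-layer risk-factor network used for
postpartum hemorrhage (PPH) after cesarean section: a single *variance* node
(the pathway deviation, PPH itself), a middle layer of *primary* risk factors
(uterine atony, laceration of the birth canal, placental factors,
coagulopathy) and a root layer of *secondary* risk factors (prolonged labor,
placenta previa, ...).  All nodes are binary with states ``State0`` (factor
absent) and ``State1`` (factor present).  Arbitrary discrete DAGs are also
supported; the layering constraint is only enforced for networks that declare
``metadata["layered"] = True``.

Conditional probability tables (CPTs) are stored densely as numpy arrays with
one axis per parent (in ``parent_order``) plus a trailing axis for the node's
own states.  Serialization uses a single JSON document per network; table rows
are keyed by parent-state strings such as ``"C6=State1,C11=State0"`` with
parents listed in ``parent_order`` and states enumerated lexicographically
with ``State0`` before ``State1``.

Root priors can be elicited from expert input via :func:`elicit_prior`, the
multiplicative combination p = R x Pd of an expert occurrence degree R and a
data-derived possibility Pd.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "LAYERS",
    "DEFAULT_STATES",
    "NetworkFormatError",
    "UnspecifiedTableError",
    "NodeSpec",
    "ConditionalTable",
    "BayesianNetwork",
    "ElicitationInput",
    "elicit_prior",
    "validate_network",
    "load_network",
    "save_network",
    "build_pph_fixture",
]

#: Recognised layer names, top of the hierarchy first.
LAYERS = ("variance", "primary", "secondary")

#: Default binary state names; State0 = factor absent, State1 = present.
DEFAULT_STATES = ("State0", "State1")

#: Tolerance for a CPT row to count as a probability distribution.
PROB_TOL = 1e-9


class NetworkFormatError(ValueError):
    """A network spec file could not be parsed into a valid network."""


class UnspecifiedTableError(RuntimeError):
    """A computation would read a placeholder (UNSPECIFIED) table."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NodeSpec:
    """One network variable.

    Parameters
    ----------
    id : str
        Short symbol, e.g. ``"A"``, ``"B1"``, ``"C11"``.
    label : str
        Human-readable factor name, e.g. ``"Uterine atony"``.
    layer : str or None
        ``"variance"``, ``"primary"`` or ``"secondary"`` for layered
        networks; ``None`` for general DAGs.
    states : tuple of str
        Ordered state names; at least two.
    parents : tuple of str
        Ordered parent node ids.
    """

    id: str
    label: str = ""
    layer: str | None = None
    states: tuple[str, ...] = DEFAULT_STATES
    parents: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        object.__setattr__(self, "parents", tuple(self.parents))


@dataclass
class ConditionalTable:
    """The distribution of one node for every combination of parent states.

    ``values`` has shape ``(*parent_cardinalities, node_cardinality)`` with
    axes in ``parent_order``.  A root node has ``parent_order == ()`` and
    ``values`` of shape ``(k,)`` — its prior.  Tables the source data do not
    determine are flagged ``unspecified`` and filled with uniform rows;
    inference and sampling refuse to read them unless explicitly allowed.
    """

    node: str
    parent_order: tuple[str, ...]
    parent_states: tuple[tuple[str, ...], ...]
    states: tuple[str, ...]
    values: np.ndarray
    unspecified: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        self.parent_order = tuple(self.parent_order)
        self.parent_states = tuple(tuple(s) for s in self.parent_states)
        self.states = tuple(self.states)
        self.values = np.asarray(self.values, dtype=float)
        expected = tuple(len(s) for s in self.parent_states) + (len(self.states),)
        if self.values.shape != expected:
            raise ValueError(
                f"table for {self.node!r}: values shape {self.values.shape} "
                f"does not match parent/node cardinalities {expected}"
            )

    @classmethod
    def from_entries(
        cls,
        node: str,
        parent_order: Sequence[str],
        parent_states: Sequence[Sequence[str]],
        states: Sequence[str],
        entries: Mapping[tuple[str, ...], Sequence[float]],
        **kwargs,
    ) -> "ConditionalTable":
        """Build a table from a mapping of parent-state tuples to rows."""
        parent_states = tuple(tuple(s) for s in parent_states)
        states = tuple(states)
        shape = tuple(len(s) for s in parent_states) + (len(states),)
        values = np.full(shape, np.nan)
        for key, row in entries.items():
            key = tuple(key)
            if len(key) != len(parent_order):
                raise ValueError(
                    f"table for {node!r}: entry key {key} does not match "
                    f"parent_order {tuple(parent_order)}"
                )
            idx = tuple(ps.index(s) for ps, s in zip(parent_states, key))
            values[idx] = np.asarray(row, dtype=float)
        if np.isnan(values).any():
            raise ValueError(
                f"table for {node!r}: missing entries for some parent-state "
                f"combinations"
            )
        return cls(node, tuple(parent_order), parent_states, states, values, **kwargs)

    def entries(self) -> dict[tuple[str, ...], np.ndarray]:
        """Mapping parent-state tuple -> distribution row, in lexicographic
        enumeration order (State0 before State1 for binary nodes)."""
        out: dict[tuple[str, ...], np.ndarray] = {}
        for combo in itertools.product(*self.parent_states):
            idx = tuple(ps.index(s) for ps, s in zip(self.parent_states, combo))
            out[combo] = self.values[idx]
        return out

    def row(self, parent_assignment: Mapping[str, str]) -> np.ndarray:
        """Distribution over the node's states given a parent assignment."""
        idx = tuple(
            self.parent_states[i].index(parent_assignment[p])
            for i, p in enumerate(self.parent_order)
        )
        return self.values[idx]


@dataclass(frozen=True)
class ElicitationInput:
    """Expert-prior input for one root node: occurrence degree ``R`` assessed
    by clinical experts and data-derived possibility ``Pd``, both in [0, 1]."""

    node: str
    R: float
    Pd: float

    def __post_init__(self) -> None:
        for name, v in (("R", self.R), ("Pd", self.Pd)):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def elicit_prior(r: float | ElicitationInput, pd: float | None = None) -> float:
    """Combine an expert occurrence degree and a data-derived possibility
    into a root prior: ``p = R * Pd``.

    The product is used as the State1 prior of a root node; State0 receives
    the complement.  Accepts either an :class:`ElicitationInput` or the two
    numbers directly.
    """
    if isinstance(r, ElicitationInput):
        r, pd = r.R, r.Pd
    if pd is None:
        raise TypeError("elicit_prior requires both R and Pd")
    for name, v in (("R", r), ("Pd", pd)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return float(r) * float(pd)


# ---------------------------------------------------------------------------
# The network container
# ---------------------------------------------------------------------------


@dataclass
class BayesianNetwork:
    """A discrete Bayesian network: node specs, one CPT per node, metadata."""

    nodes: dict[str, NodeSpec]
    tables: dict[str, ConditionalTable]
    metadata: dict = field(default_factory=dict)

    @classmethod
    def from_parts(
        cls,
        nodes: Iterable[NodeSpec],
        tables: Iterable[ConditionalTable],
        metadata: dict | None = None,
    ) -> "BayesianNetwork":
        node_map: dict[str, NodeSpec] = {}
        for n in nodes:
            if n.id in node_map:
                raise ValueError(f"duplicate node id {n.id!r}")
            node_map[n.id] = n
        table_map: dict[str, ConditionalTable] = {}
        for t in tables:
            if t.node in table_map:
                raise ValueError(f"duplicate table for node {t.node!r}")
            table_map[t.node] = t
        return cls(node_map, table_map, dict(metadata or {}))

    # -- graph structure ----------------------------------------------------

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for n in self.nodes.values():
            for p in n.parents:
                g.add_edge(p, n.id)
        return g

    def topological_order(self) -> list[str]:
        return list(nx.topological_sort(self.graph()))

    def ancestral_closure(self, node_ids: Iterable[str]) -> set[str]:
        """The given nodes plus all their ancestors (the non-barren set for
        a query over them)."""
        g = self.graph()
        out: set[str] = set()
        for nid in node_ids:
            out.add(nid)
            out |= nx.ancestors(g, nid)
        return out

    def subnetwork(self, node_ids: Iterable[str]) -> "BayesianNetwork":
        """Restrict to a set of nodes that is closed under parents."""
        keep = set(node_ids)
        for nid in keep:
            missing = set(self.nodes[nid].parents) - keep
            if missing:
                raise ValueError(
                    f"subnetwork not closed under parents: {nid!r} needs "
                    f"{sorted(missing)}"
                )
        nodes = [self.nodes[nid] for nid in self.topological_order() if nid in keep]
        tables = [self.tables[nid] for nid in self.nodes if nid in keep and nid in self.tables]
        # layering metadata does not survive restriction (e.g. the variance
        # node may be dropped), so only provenance is carried over
        meta = {"subnetwork_of": self.metadata.get("name", "unnamed")}
        return BayesianNetwork.from_parts(nodes, tables, meta)

    # -- convenience --------------------------------------------------------

    def unspecified_nodes(self) -> set[str]:
        return {nid for nid, t in self.tables.items() if t.unspecified}

    def variance_node(self) -> str:
        hits = [nid for nid, n in self.nodes.items() if n.layer == "variance"]
        if len(hits) != 1:
            raise ValueError(
                f"expected exactly one variance-layer node, found {sorted(hits)}"
            )
        return hits[0]

    def state_index(self, node: str, state: str) -> int:
        try:
            return self.nodes[node].states.index(state)
        except ValueError:
            raise ValueError(
                f"unknown state {state!r} for node {node!r}; "
                f"states are {self.nodes[node].states}"
            ) from None


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_network(net: BayesianNetwork) -> list[str]:
    """Check all structural and probabilistic invariants.

    Returns a list of human-readable violation descriptions, empty iff the
    network is valid.  Violations name the offending node and the rule
    broken; nothing is raised.
    """
    problems: list[str] = []

    for nid, node in net.nodes.items():
        if node.id != nid:
            problems.append(f"node {nid!r}: key does not match spec id {node.id!r}")
        if len(node.states) < 2:
            problems.append(f"node {nid!r}: needs at least 2 states")
        if len(set(node.states)) != len(node.states):
            problems.append(f"node {nid!r}: duplicate state names")
        if len(set(node.parents)) != len(node.parents):
            problems.append(f"node {nid!r}: duplicate parents")
        for p in node.parents:
            if p not in net.nodes:
                problems.append(f"node {nid!r}: unknown parent {p!r}")

    g = nx.DiGraph()
    g.add_nodes_from(net.nodes)
    for node in net.nodes.values():
        for p in node.parents:
            if p in net.nodes:
                g.add_edge(p, node.id)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        problems.append(
            "acyclicity violated: cycle through "
            + " -> ".join(str(e[0]) for e in cycle)
        )

    for nid in net.tables:
        if nid not in net.nodes:
            problems.append(f"table for unknown node {nid!r}")

    for nid, node in net.nodes.items():
        table = net.tables.get(nid)
        if table is None:
            problems.append(f"node {nid!r}: missing conditional table")
            continue
        if sorted(table.parent_order) != sorted(node.parents):
            problems.append(
                f"node {nid!r}: table parent_order {table.parent_order} is not "
                f"a permutation of parents {node.parents}"
            )
            continue
        if table.states != node.states:
            problems.append(
                f"node {nid!r}: table states {table.states} differ from node "
                f"states {node.states}"
            )
            continue
        for p, ps in zip(table.parent_order, table.parent_states):
            if p in net.nodes and ps != net.nodes[p].states:
                problems.append(
                    f"node {nid!r}: table states for parent {p!r} do not match "
                    f"that node's states"
                )
        n_rows = int(np.prod([len(s) for s in table.parent_states], dtype=int))
        expected_rows = int(
            np.prod([len(net.nodes[p].states) for p in table.parent_order if p in net.nodes], dtype=int)
        )
        if n_rows != expected_rows:
            problems.append(
                f"node {nid!r}: table has {n_rows} rows, expected one per "
                f"parent-state combination ({expected_rows})"
            )
        vals = table.values
        if np.any(vals < -PROB_TOL) or np.any(vals > 1 + PROB_TOL):
            problems.append(f"node {nid!r}: table has probabilities outside [0, 1]")
        sums = vals.sum(axis=-1)
        if np.any(np.abs(sums - 1.0) > PROB_TOL):
            bad = float(sums.flat[int(np.argmax(np.abs(sums - 1.0)))])
            problems.append(
                f"node {nid!r}: table row sums to {bad!r}, not 1 (tol {PROB_TOL})"
            )

    if net.metadata.get("layered"):
        allowed_parent_layer = {"variance": "primary", "primary": "secondary"}
        n_variance = 0
        for nid, node in net.nodes.items():
            if node.layer not in LAYERS:
                problems.append(
                    f"node {nid!r}: layered network requires a layer in {LAYERS}, "
                    f"got {node.layer!r}"
                )
                continue
            if node.layer == "variance":
                n_variance += 1
            if node.layer == "secondary" and node.parents:
                problems.append(f"node {nid!r}: secondary-layer node must be a root")
            want = allowed_parent_layer.get(node.layer)
            if want is not None:
                for p in node.parents:
                    pl = net.nodes[p].layer if p in net.nodes else None
                    if pl != want:
                        problems.append(
                            f"node {nid!r}: {node.layer}-layer node has parent "
                            f"{p!r} in layer {pl!r}, expected {want!r}"
                        )
        if n_variance != 1:
            problems.append(
                f"layered network must have exactly one variance node, found {n_variance}"
            )

    return problems


# ---------------------------------------------------------------------------
# Serialization (JSON, one document per network)
# ---------------------------------------------------------------------------

_ENTRY_SEP = ","


def _entry_key(parent_order: Sequence[str], combo: Sequence[str]) -> str:
    return _ENTRY_SEP.join(f"{p}={s}" for p, s in zip(parent_order, combo))


def _parse_entry_key(key: str, parent_order: Sequence[str], node: str) -> tuple[str, ...]:
    if key == "":
        if parent_order:
            raise NetworkFormatError(
                f"table for {node!r}: empty entry key but node has parents"
            )
        return ()
    parts = key.split(_ENTRY_SEP)
    combo: dict[str, str] = {}
    for part in parts:
        if "=" not in part:
            raise NetworkFormatError(
                f"table for {node!r}: malformed entry key component {part!r}"
            )
        p, s = part.split("=", 1)
        combo[p.strip()] = s.strip()
    if set(combo) != set(parent_order):
        raise NetworkFormatError(
            f"table for {node!r}: entry key {key!r} does not cover parents "
            f"{tuple(parent_order)}"
        )
    return tuple(combo[p] for p in parent_order)


def network_to_dict(net: BayesianNetwork) -> dict:
    """JSON-serializable form; parent-state rows enumerated lexicographically
    in ``parent_order`` with State0 before State1."""
    doc: dict = {"metadata": dict(net.metadata), "nodes": [], "tables": []}
    for nid in net.topological_order():
        node = net.nodes[nid]
        doc["nodes"].append(
            {
                "id": node.id,
                "label": node.label,
                "layer": node.layer,
                "states": list(node.states),
                "parents": list(node.parents),
            }
        )
        table = net.tables.get(nid)
        if table is None:
            continue
        entries = {
            _entry_key(table.parent_order, combo): [float(x) for x in row]
            for combo, row in table.entries().items()
        }
        tdoc = {
            "node": nid,
            "parent_order": list(table.parent_order),
            "entries": entries,
        }
        if table.unspecified:
            tdoc["unspecified"] = True
        if table.note:
            tdoc["note"] = table.note
        doc["tables"].append(tdoc)
    return doc


def network_from_dict(doc: Mapping) -> BayesianNetwork:
    try:
        raw_nodes = doc["nodes"]
        raw_tables = doc["tables"]
    except KeyError as e:
        raise NetworkFormatError(f"missing top-level key {e.args[0]!r}") from None
    nodes: list[NodeSpec] = []
    for nd in raw_nodes:
        try:
            nodes.append(
                NodeSpec(
                    id=nd["id"],
                    label=nd.get("label", ""),
                    layer=nd.get("layer"),
                    states=tuple(nd.get("states", DEFAULT_STATES)),
                    parents=tuple(nd.get("parents", ())),
                )
            )
        except KeyError as e:
            raise NetworkFormatError(
                f"node entry {nd!r} missing key {e.args[0]!r}"
            ) from None
    node_map = {n.id: n for n in nodes}
    tables: list[ConditionalTable] = []
    for td in raw_tables:
        nid = td.get("node")
        if nid not in node_map:
            raise NetworkFormatError(f"table for unknown node {nid!r}")
        node = node_map[nid]
        parent_order = tuple(td.get("parent_order", node.parents))
        if sorted(parent_order) != sorted(node.parents):
            raise NetworkFormatError(
                f"table for {nid!r}: parent_order {parent_order} is not a "
                f"permutation of parents {node.parents}"
            )
        parent_states = tuple(node_map[p].states for p in parent_order)
        entries: dict[tuple[str, ...], Sequence[float]] = {}
        for key, row in td["entries"].items():
            combo = _parse_entry_key(key, parent_order, nid)
            for p, s in zip(parent_order, combo):
                if s not in node_map[p].states:
                    raise NetworkFormatError(
                        f"table for {nid!r}: unknown state {s!r} of parent {p!r}"
                    )
            entries[combo] = row
        try:
            table = ConditionalTable.from_entries(
                nid,
                parent_order,
                parent_states,
                node.states,
                entries,
                unspecified=bool(td.get("unspecified", False)),
                note=td.get("note", ""),
            )
        except ValueError as e:
            raise NetworkFormatError(str(e)) from None
        tables.append(table)
    net = BayesianNetwork.from_parts(nodes, tables, doc.get("metadata", {}))
    problems = validate_network(net)
    if problems:
        raise NetworkFormatError("invalid network:\n  " + "\n  ".join(problems))
    return net


def save_network(net: BayesianNetwork, path: str | Path) -> None:
    """Write a network as a single JSON document."""
    Path(path).write_text(json.dumps(network_to_dict(net), indent=1) + "\n")


def load_network(path: str | Path) -> BayesianNetwork:
    """Load and validate a network from a JSON spec file.

    ``path`` may also be the name of a bundled network (currently ``"pph"``,
    the postpartum-hemorrhage fixture).
    """
    p = Path(path)
    if not p.exists():
        name = str(path)
        if name.isidentifier():
            ref = resources.files("cpv") / "data" / f"{name}.json"
            if ref.is_file():
                return network_from_dict(json.loads(ref.read_text()))
        raise FileNotFoundError(f"no network file or bundled network {path!r}")
    try:
        doc = json.loads(p.read_text())
    except json.JSONDecodeError as e:
        raise NetworkFormatError(f"{path}: not valid JSON ({e})") from None
    return network_from_dict(doc)


# ---------------------------------------------------------------------------
# The bundled postpartum-hemorrhage network
# ---------------------------------------------------------------------------

_PPH_LABELS = {
    "A": "Postpartum hemorrhage in cesarean section",
    "B1": "Uterine atony",
    "B2": "Laceration of birth canal",
    "B3": "Placental factors",
    "B4": "Coagulopathy",
    "C1": "Prolonged labor",
    "C2": "Multifetation",
    "C3": "Effect of oxytocin",
    "C4": "Macrosomia",
    "C5": "Abnormal fetal position",
    "C6": "Complications of pregnancy",
    "C7": "Placenta implantation",
    "C8": "Placenta previa",
    "C9": "Placental abruption",
    "C10": "Placental adhesion",
    "C11": "Pregnancy associated with coagulopathy",
}

_PPH_PARENTS = {
    "A": ("B1", "B2", "B3", "B4"),
    "B1": ("C1", "C2", "C3", "C4"),
    "B2": ("C3", "C4", "C5", "C6"),
    "B3": ("C7", "C8", "C9", "C10"),
    "B4": ("C6", "C11"),
}

# Published root priors (State1), from the risk-factor probability table for
# the parents of uterine atony.
_PPH_PRIORS = {"C1": 0.505, "C2": 0.369, "C3": 0.268, "C4": 0.41}

# Derived root priors: the source prints neither P(C6) nor P(C11), but both
# are recoverable from its worked numbers through the published coagulopathy
# CPT.  P(B4=1|C11=1) = (1-p6)*0.264 + p6*0.78 = 0.49 gives p6 = 0.438;
# P(B4=1) = (1-p11)*[(1-p6)*0.1 + p6*0.4] + p11*0.49 = 0.3636 then gives
# p11 = 0.5112.  Shipped as derived values, not published data.
_PPH_DERIVED_PRIORS = {
    "C6": (0.438, "derived by inverting the worked value P(B4=State1|C11=State1)=0.49 through the coagulopathy CPT"),
    "C11": (0.5112, "derived by inverting the worked marginal P(B4=State1)=0.3636 given P(C6=State1)=0.438"),
}

# Published coagulopathy CPT: P(B4 | C6, C11).
_PPH_B4_CPT = {
    ("State0", "State0"): (0.9, 0.1),
    ("State1", "State0"): (0.6, 0.4),
    ("State0", "State1"): (0.736, 0.264),
    ("State1", "State1"): (0.22, 0.78),
}


def build_pph_fixture() -> BayesianNetwork:
    """The 16-node postpartum-hemorrhage risk-factor network.

    Structure: variance node A (postpartum hemorrhage) with primary-factor
    parents B1-B4; each primary factor with its secondary-factor parents
    (note C3, C4 and C6 each feed two primary factors).  Published content:
    root priors for C1-C4, the full coagulopathy CPT P(B4|C6,C11), and two
    derived priors P(C6=State1)=0.438 and P(C11=State1)=0.5112.  All other
    tables (A, B1-B3 and the priors of C5, C7-C10) are not published; they
    ship as uniform placeholders flagged ``unspecified`` and are never read
    silently.
    """
    nodes: list[NodeSpec] = []
    tables: list[ConditionalTable] = []
    root_ids = [f"C{i}" for i in range(1, 12)]
    for nid in ["A", "B1", "B2", "B3", "B4"] + root_ids:
        layer = "variance" if nid == "A" else ("primary" if nid.startswith("B") else "secondary")
        nodes.append(
            NodeSpec(
                id=nid,
                label=_PPH_LABELS[nid],
                layer=layer,
                states=DEFAULT_STATES,
                parents=_PPH_PARENTS.get(nid, ()),
            )
        )

    def prior_table(nid: str, p1: float, note: str = "", unspecified: bool = False):
        return ConditionalTable.from_entries(
            nid, (), (), DEFAULT_STATES, {(): (1.0 - p1, p1)},
            note=note, unspecified=unspecified,
        )

    for nid, p1 in _PPH_PRIORS.items():
        tables.append(prior_table(nid, p1, note="published State1 prior"))
    for nid, (p1, note) in _PPH_DERIVED_PRIORS.items():
        tables.append(prior_table(nid, p1, note=note))
    for nid in ("C5", "C7", "C8", "C9", "C10"):
        tables.append(
            prior_table(nid, 0.5, note="UNSPECIFIED: prior not published; uniform placeholder", unspecified=True)
        )

    tables.append(
        ConditionalTable.from_entries(
            "B4", ("C6", "C11"), (DEFAULT_STATES, DEFAULT_STATES), DEFAULT_STATES,
            _PPH_B4_CPT, note="published coagulopathy CPT",
        )
    )
    for nid in ("A", "B1", "B2", "B3"):
        parents = _PPH_PARENTS[nid]
        entries = {
            combo: (0.5, 0.5)
            for combo in itertools.product(DEFAULT_STATES, repeat=len(parents))
        }
        tables.append(
            ConditionalTable.from_entries(
                nid, parents, tuple(DEFAULT_STATES for _ in parents), DEFAULT_STATES,
                entries,
                note="UNSPECIFIED: CPT not published; uniform placeholder",
                unspecified=True,
            )
        )

    metadata = {
        "name": "pph",
        "layered": True,
        "description": (
            "Postpartum-hemorrhage risk-factor network for the cesarean "
            "section clinical pathway; all nodes binary, State1 = factor "
            "present"
        ),
        "unspecified": sorted(
            nid for nid in _PPH_LABELS
            if nid in ("A", "B1", "B2", "B3", "C5", "C7", "C8", "C9", "C10")
        ),
        "derived_priors": {
            nid: {"p_state1": p1, "provenance": note}
            for nid, (p1, note) in _PPH_DERIVED_PRIORS.items()
        },
    }
    net = BayesianNetwork.from_parts(nodes, tables, metadata)
    problems = validate_network(net)
    if problems:  # pragma: no cover - construction bug guard
        raise AssertionError("fixture invalid: " + "; ".join(problems))
    return net
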