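"""Exact probabilistic inference on discrete Bayesian networks.

Two interchangeable exact algorithms are provided:

``method="ve"`` (default)
    Variable elimination with a min-degree elimination heuristic — the fast
    path.  Factors are dense numpy arrays, one axis per variable.

``method="enumerate"``
    Direct summation of the full joint over all free variables — the
    reference path, kept deliberately simple.

Both operate on the *relevant* sub-network only: barren nodes (nodes that
are neither queried, observed, nor ancestors of either) sum out of any
posterior, so they are pruned before computation.  A practical consequence
for the bundled postpartum-hemorrhage network is that queries confined to
the published region (e.g. coagulopathy given its parents) never touch the
placeholder tables of the unpublished region, and therefore trigger no
warning.

Diagnostic reasoning is backward inference: fix the effect (the variance
node in State1, i.e. hemorrhage occurred) and rank candidate causes by
their posterior probability of State1,
``P(Y_m | X) = P(Y_m) P(X | Y_m) / sum_i P(Y_i) P(X | Y_i)``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import BayesianNetwork, UnspecifiedTableError

__all__ = [
    "Evidence",
    "ZeroEvidenceError",
    "PosteriorRanking",
    "joint_probability",
    "marginal",
    "posterior",
    "predict_variance",
    "diagnostic_ranking",
]

#: Evidence is a plain mapping node id -> observed state name.
Evidence = dict[str, str]


class ZeroEvidenceError(ValueError):
    """The supplied evidence has probability zero under the model."""


def _check_evidence(net: BayesianNetwork, evidence: Evidence) -> None:
    for nid, state in evidence.items():
        if nid not in net.nodes:
            raise KeyError(f"evidence names unknown node {nid!r}")
        net.state_index(nid, state)  # raises on unknown state


def _check_specified(
    net: BayesianNetwork, relevant: set[str], allow_unspecified: bool
) -> None:
    bad = sorted(relevant & net.unspecified_nodes())
    if not bad:
        return
    msg = (
        f"query touches UNSPECIFIED placeholder tables for nodes {bad}; "
        "results reflect the uniform placeholders, not published data"
    )
    if not allow_unspecified:
        raise UnspecifiedTableError(msg + " (pass allow_unspecified=True to proceed)")
    warnings.warn(msg, UserWarning, stacklevel=3)


# ---------------------------------------------------------------------------
# Joint probability of a full assignment
# ---------------------------------------------------------------------------


def joint_probability(net: BayesianNetwork, assignment: Evidence) -> float:
    """Chain-rule joint probability of one full assignment.

    ``P(x_1, ..., x_n) = prod_i P(x_i | parents(x_i))`` — the product over
    all nodes of the CPT entry selected by the assignment.  The assignment
    must cover every node exactly once.
    """
    missing = set(net.nodes) - set(assignment)
    if missing:
        raise ValueError(f"assignment misses nodes {sorted(missing)}")
    extra = set(assignment) - set(net.nodes)
    if extra:
        raise KeyError(f"assignment names unknown nodes {sorted(extra)}")
    _check_evidence(net, assignment)
    p = 1.0
    for nid, table in net.tables.items():
        row = table.row(assignment)
        p *= float(row[net.state_index(nid, assignment[nid])])
    return p


# ---------------------------------------------------------------------------
# Enumeration (reference path)
# ---------------------------------------------------------------------------


def _enumerate_query(
    net: BayesianNetwork, query: str, evidence: Evidence, relevant: list[str]
) -> np.ndarray:
    """Unnormalized P(query, evidence) by brute-force summation over the
    relevant sub-network."""
    free = [n for n in relevant if n != query and n not in evidence]
    q_states = net.nodes[query].states
    out = np.zeros(len(q_states))
    for qi, q_state in enumerate(q_states):
        base = dict(evidence)
        base[query] = q_state
        total = 0.0
        for combo in itertools.product(*(net.nodes[n].states for n in free)):
            asg = base | dict(zip(free, combo))
            p = 1.0
            for nid in relevant:
                table = net.tables[nid]
                p *= float(table.row(asg)[net.state_index(nid, asg[nid])])
                if p == 0.0:
                    break
            total += p
        out[qi] = total
    return out


# ---------------------------------------------------------------------------
# Variable elimination (fast path)
# ---------------------------------------------------------------------------


@dataclass
class _Factor:
    vars: tuple[str, ...]
    values: np.ndarray


def _factor_product(a: _Factor, b: _Factor) -> _Factor:
    all_vars = a.vars + tuple(v for v in b.vars if v not in a.vars)

    def expand(f: _Factor) -> np.ndarray:
        # permute f's axes into all_vars order, inserting size-1 axes
        src = {v: i for i, v in enumerate(f.vars)}
        arr = np.transpose(f.values, [src[v] for v in all_vars if v in src])
        shape = tuple(
            arr.shape[[v for v in all_vars if v in src].index(v)] if v in src else 1
            for v in all_vars
        )
        return arr.reshape(shape)

    return _Factor(all_vars, expand(a) * expand(b))


def _sum_out(f: _Factor, var: str) -> _Factor:
    i = f.vars.index(var)
    return _Factor(f.vars[:i] + f.vars[i + 1 :], f.values.sum(axis=i))


def _min_degree_order(nodes: list[str], factor_scopes: list[tuple[str, ...]]) -> list[str]:
    """Greedy min-degree elimination ordering on the interaction graph."""
    neighbors: dict[str, set[str]] = {n: set() for n in nodes}
    for scope in factor_scopes:
        for u, v in itertools.combinations(scope, 2):
            if u in neighbors and v in neighbors:
                neighbors[u].add(v)
                neighbors[v].add(u)
    order: list[str] = []
    remaining = set(nodes)
    while remaining:
        var = min(remaining, key=lambda n: (len(neighbors[n] & remaining), n))
        order.append(var)
        remaining.discard(var)
        nbrs = neighbors[var] & remaining
        for u, v in itertools.combinations(nbrs, 2):
            neighbors[u].add(v)
            neighbors[v].add(u)
    return order


def _ve_query(
    net: BayesianNetwork, query: str, evidence: Evidence, relevant: list[str]
) -> np.ndarray:
    """Unnormalized P(query, evidence) by variable elimination."""
    factors: list[_Factor] = []
    for nid in relevant:
        table = net.tables[nid]
        f = _Factor(table.parent_order + (nid,), table.values)
        # reduce observed variables by slicing
        for v in f.vars:
            if v in evidence:
                idx = net.state_index(v, evidence[v])
                axis = f.vars.index(v)
                f = _Factor(
                    f.vars[:axis] + f.vars[axis + 1 :],
                    np.take(f.values, idx, axis=axis),
                )
        factors.append(f)

    to_eliminate = [n for n in relevant if n != query and n not in evidence]
    order = _min_degree_order(to_eliminate, [f.vars for f in factors])
    for var in order:
        touched = [f for f in factors if var in f.vars]
        untouched = [f for f in factors if var not in f.vars]
        if not touched:
            continue
        prod = touched[0]
        for f in touched[1:]:
            prod = _factor_product(prod, f)
        factors = untouched + [_sum_out(prod, var)]

    result = _Factor((), np.array(1.0))
    for f in factors:
        result = _factor_product(result, f)
    if result.vars == ():
        # query was observed: scalar likelihood, caller handles degeneracy
        return np.array([float(result.values)])
    assert result.vars == (query,)
    return np.asarray(result.values, dtype=float)


# ---------------------------------------------------------------------------
# Public queries
# ---------------------------------------------------------------------------


def posterior(
    net: BayesianNetwork,
    query: str,
    evidence: Evidence | None = None,
    *,
    method: str = "ve",
    allow_unspecified: bool = False,
) -> dict[str, float]:
    """Exact posterior distribution ``P(query | evidence)``.

    With empty evidence this is the marginal.  If the query node is itself
    observed, the degenerate point distribution on the observed state is
    returned.  Evidence of probability zero raises
    :class:`ZeroEvidenceError`.
    """
    evidence = dict(evidence or {})
    if query not in net.nodes:
        raise KeyError(f"unknown query node {query!r}")
    _check_evidence(net, evidence)
    states = net.nodes[query].states

    if query in evidence:
        return {s: (1.0 if s == evidence[query] else 0.0) for s in states}

    relevant_set = net.ancestral_closure(set(evidence) | {query})
    _check_specified(net, relevant_set, allow_unspecified)
    relevant = [n for n in net.topological_order() if n in relevant_set]

    if method == "ve":
        unnorm = _ve_query(net, query, evidence, relevant)
    elif method == "enumerate":
        unnorm = _enumerate_query(net, query, evidence, relevant)
    else:
        raise ValueError(f"unknown inference method {method!r}")

    z = float(unnorm.sum())
    if z <= 0.0:
        raise ZeroEvidenceError(
            f"evidence {evidence} has probability zero under the model"
        )
    dist = unnorm / z
    return {s: float(p) for s, p in zip(states, dist)}


def marginal(
    net: BayesianNetwork,
    node: str,
    *,
    method: str = "ve",
    allow_unspecified: bool = False,
) -> dict[str, float]:
    """Exact marginal distribution of one node (posterior with no evidence)."""
    return posterior(
        net, node, {}, method=method, allow_unspecified=allow_unspecified
    )


def predict_variance(
    net: BayesianNetwork,
    evidence: Evidence,
    *,
    method: str = "ve",
    allow_unspecified: bool = False,
) -> float:
    """Probability of the variance node being in State1 given evidence.

    This is forward risk prediction: given a patient's observed risk
    factors, the probability that the pathway variance (postpartum
    hemorrhage) occurs.  Requires the network to contain exactly one
    variance-layer node.
    """
    vnode = net.variance_node()
    dist = posterior(
        net, vnode, evidence, method=method, allow_unspecified=allow_unspecified
    )
    return dist[net.nodes[vnode].states[1]]


@dataclass
class PosteriorRanking:
    """Causes ranked by posterior probability of State1 under fixed evidence.

    ``entries`` is a list of ``(node id, layer, posterior of State1)``
    sorted by probability descending, ties broken by node id.
    """

    evidence: Evidence
    entries: list[tuple[str, str | None, float]] = field(default_factory=list)

    def to_frame(self, net: BayesianNetwork | None = None) -> pd.DataFrame:
        rows = [
            {
                "node": nid,
                "label": net.nodes[nid].label if net is not None else "",
                "layer": layer,
                "posterior_state1": p,
            }
            for nid, layer, p in self.entries
        ]
        return pd.DataFrame(rows, columns=["node", "label", "layer", "posterior_state1"])


def diagnostic_ranking(
    net: BayesianNetwork,
    evidence: Evidence,
    targets: list[str],
    *,
    method: str = "ve",
    allow_unspecified: bool = False,
) -> PosteriorRanking:
    """Rank candidate causes by their posterior under the observed effect.

    For each target node the exact posterior of State1 given the evidence is
    computed; the ranking is sorted descending, ties broken by node id.  The
    layer annotation lets callers split primary from secondary factors.
    """
    if not targets:
        raise ValueError("targets must be non-empty")
    overlap = set(targets) & set(evidence)
    if overlap:
        raise ValueError(f"targets overlap evidence: {sorted(overlap)}")
    entries = []
    for t in targets:
        dist = posterior(
            net, t, evidence, method=method, allow_unspecified=allow_unspecified
        )
        p1 = dist[net.nodes[t].states[1]]
        entries.append((t, net.nodes[t].layer, p1))
    entries.sort(key=lambda e: (-e[2], e[0]))
    return PosteriorRanking(evidence=dict(evidence), entries=entries)
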