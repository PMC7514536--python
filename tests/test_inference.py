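"""Exact inference: joint, marginal, posterior, prediction, diagnosis."""

import itertools

import numpy as np
import pytest

from cpv.inference import (
    ZeroEvidenceError,
    diagnostic_ranking,
    joint_probability,
    marginal,
    posterior,
    predict_variance,
)
from cpv.network import UnspecifiedTableError
from cpv.simulate import random_network

from conftest import make_net
from oracles import brute_posterior, full_joint_table


class TestJointProbability:
    def test_two_node_product(self, two_node_net):
        p = joint_probability(two_node_net, {"C": "State1", "B": "State1"})
        assert p == pytest.approx(0.5 * 0.78, abs=1e-15)

    def test_zero_entry_annihilates(self):
        net = make_net({"C": 1.0}, {"B": (("C",), {(0,): 0.3, (1,): 0.9})})
        assert joint_probability(net, {"C": "State0", "B": "State1"}) == 0.0

    @pytest.mark.parametrize("seed", [0, 7])
    def test_joint_sums_to_one(self, seed):
        net = random_network(6, seed=seed)
        total = sum(
            joint_probability(net, dict(zip(net.nodes, combo)))
            for combo in itertools.product(
                *(net.nodes[n].states for n in net.nodes)
            )
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_partial_assignment_rejected(self, two_node_net):
        with pytest.raises(ValueError, match="misses"):
            joint_probability(two_node_net, {"C": "State1"})
        with pytest.raises(KeyError):
            joint_probability(
                two_node_net, {"C": "State1", "B": "State1", "Z": "State0"}
            )


class TestMarginal:
    def test_root_marginal_is_its_prior(self, pph):
        assert marginal(pph, "C1")["State1"] == pytest.approx(0.505, abs=1e-12)

    def test_coagulopathy_marginal(self, pph_sub):
        # exact marginalization over both parents with the derived priors
        dist = marginal(pph_sub, "B4")
        assert dist["State1"] == pytest.approx(0.3636, abs=0.0005)
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_ve_equals_enumeration(self, seed):
        net = random_network(8, seed=100 + seed)
        for node in net.nodes:
            ve = marginal(net, node, method="ve")
            en = marginal(net, node, method="enumerate")
            for s in ve:
                assert ve[s] == pytest.approx(en[s], abs=1e-9)

    def test_unspecified_ancestor_refused_then_warns(self, pph):
        with pytest.raises(UnspecifiedTableError, match="B1"):
            marginal(pph, "B1")
        with pytest.warns(UserWarning, match="UNSPECIFIED"):
            dist = marginal(pph, "B1", allow_unspecified=True)
        assert dist["State1"] == pytest.approx(0.5, abs=1e-9)


class TestPosterior:
    def test_cpt_row_recovered_when_both_parents_observed(self, pph):
        dist = posterior(pph, "B4", {"C6": "State1", "C11": "State1"})
        assert dist["State1"] == 0.78

    def test_worked_conditional_given_c11(self, pph_sub):
        dist = posterior(pph_sub, "B4", {"C11": "State1"})
        assert dist["State1"] == pytest.approx(0.49, abs=0.005)

    def test_query_in_evidence_is_degenerate(self, pph_sub):
        dist = posterior(pph_sub, "B4", {"B4": "State0"})
        assert dist == {"State0": 1.0, "State1": 0.0}

    def test_zero_probability_evidence_raises(self):
        net = make_net({"C": 1.0}, {"B": (("C",), {(0,): 0.5, (1,): 0.5})})
        with pytest.raises(ZeroEvidenceError):
            posterior(net, "B", {"C": "State0"})

    def test_no_evidence_posterior_equals_marginal(self):
        net = random_network(7, seed=42)
        for node in net.nodes:
            p = posterior(net, node, {})
            m = marginal(net, node)
            for s in p:
                assert p[s] == pytest.approx(m[s], abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        net = random_network(7, seed=200 + seed)
        rng = np.random.default_rng(seed)
        ids = list(net.nodes)
        ev_nodes = rng.choice(ids, size=2, replace=False)
        evidence = {n: net.nodes[n].states[int(rng.integers(2))] for n in ev_nodes}
        query = next(n for n in ids if n not in evidence)
        try:
            expected = brute_posterior(net, query, evidence)
        except ZeroDivisionError:
            pytest.skip("zero-probability evidence drawn")
        got = posterior(net, query, evidence)
        for s in expected:
            assert got[s] == pytest.approx(expected[s], abs=1e-9)

    def test_likelihood_monotonicity(self):
        # raising P(A=1|C=1) never decreases P(C=1|A=1)
        last = -1.0
        for p in np.linspace(0.1, 0.95, 10):
            net = make_net({"C": 0.4}, {"A": (("C",), {(0,): 0.3, (1,): float(p)})})
            cur = posterior(net, "C", {"A": "State1"})["State1"]
            assert cur >= last - 1e-12
            last = cur

    def test_implied_evidence_is_idempotent(self):
        # B is deterministically 1 when C=1; adding B=1 changes nothing
        net = make_net(
            {"C": 0.5},
            {
                "B": (("C",), {(0,): 0.0, (1,): 1.0}),
                "D": (("B",), {(0,): 0.2, (1,): 0.7}),
            },
        )
        base = posterior(net, "D", {"C": "State1"})
        extra = posterior(net, "D", {"C": "State1", "B": "State1"})
        for s in base:
            assert base[s] == pytest.approx(extra[s], abs=1e-9)


class TestPredictVariance:
    def test_deterministic_propagation(self):
        net = make_net(
            {"C": 1.0},
            {
                "B": (("C",), {(0,): 0.0, (1,): 1.0}),
                "A": (("B",), {(0,): 0.0, (1,): 1.0}),
            },
            layers={"C": "secondary", "B": "primary", "A": "variance"},
        )
        assert predict_variance(net, {"C": "State1"}) == 1.0

    def test_equals_brute_force_on_layered_net(self):
        net = make_net(
            {"C1": 0.505, "C2": 0.369},
            {
                "B1": (("C1", "C2"), {(0, 0): 0.1, (1, 0): 0.5, (0, 1): 0.4, (1, 1): 0.8}),
                "A": (("B1",), {(0,): 0.1, (1,): 0.7}),
            },
            layers={"C1": "secondary", "C2": "secondary", "B1": "primary", "A": "variance"},
        )
        expected = brute_posterior(net, "A", {"C1": "State1"})["State1"]
        assert predict_variance(net, {"C1": "State1"}) == pytest.approx(
            expected, abs=1e-9
        )

    def test_requires_unique_variance_node(self, two_node_net):
        with pytest.raises(ValueError, match="variance"):
            predict_variance(two_node_net, {})


class TestDiagnosticRanking:
    def test_symmetric_collider_ties_break_by_id(self, collider_net):
        r = diagnostic_ranking(collider_net, {"E": "State1"}, ["C2", "C1"])
        assert [e[0] for e in r.entries] == ["C1", "C2"]
        assert r.entries[0][2] == pytest.approx(r.entries[1][2], abs=1e-12)

    def test_asymmetric_collider_matches_oracle(self):
        net = make_net(
            {"C1": 0.3, "C2": 0.3},
            {"E": (("C1", "C2"), {(0, 0): 0.05, (1, 0): 0.8, (0, 1): 0.3, (1, 1): 0.9})},
        )
        r = diagnostic_ranking(net, {"E": "State1"}, ["C1", "C2"])
        expected = {
            c: brute_posterior(net, c, {"E": "State1"})["State1"]
            for c in ("C1", "C2")
        }
        assert [e[0] for e in r.entries] == sorted(
            expected, key=lambda c: -expected[c]
        )
        for nid, _, p in r.entries:
            assert p == pytest.approx(expected[nid], abs=1e-9)

    def test_rejects_bad_targets(self, collider_net):
        with pytest.raises(ValueError, match="non-empty"):
            diagnostic_ranking(collider_net, {"E": "State1"}, [])
        with pytest.raises(ValueError, match="overlap"):
            diagnostic_ranking(collider_net, {"E": "State1"}, ["E"])

    def test_frame_layout(self, collider_net):
        r = diagnostic_ranking(collider_net, {"E": "State1"}, ["C1", "C2"])
        frame = r.to_frame(collider_net)
        assert list(frame.columns) == ["node", "label", "layer", "posterior_state1"]
        assert frame["posterior_state1"].is_monotonic_decreasing


class TestNormalization:
    @pytest.mark.parametrize("seed", range(5))
    def test_all_distributions_normalized(self, seed):
        net = random_network(9, seed=300 + seed)
        rng = np.random.default_rng(seed)
        nid = list(net.nodes)[int(rng.integers(len(net.nodes)))]
        ev_node = next(n for n in net.nodes if n != nid)
        dist = posterior(net, nid, {ev_node: "State1"})
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(0.0 <= p <= 1.0 for p in dist.values())
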