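"""Constraint-based structure learning with the genome tier as instruments.

The oracle tests feed exact population covariances so algorithmic behaviour
is separated from sampling noise; the finite-sample tests check statistical
behaviour (type-I error of edge removal, recovery improving with n)."""

import numpy as np
import pandas as pd
import pytest

from gdagnet import (
    INSTRUMENT,
    TRAIT,
    CausalGraph,
    DEFAULT_EDGE_WEIGHTS,
    FATTY_ACIDS,
    default_trait_graph,
    estimate_skeleton,
    joint_covariance,
    learn_structure,
    orient_edges,
    sem_covariance,
    trait_subgraph,
)
from conftest import SOURCE_INSTRUMENTS, fixture_tiers


def _simulate_from_cov(cov: pd.DataFrame, n: int, rng) -> pd.DataFrame:
    x = rng.multivariate_normal(np.zeros(len(cov)), cov.to_numpy(), size=n)
    return pd.DataFrame(x, columns=list(cov.columns))


class TestSkeleton:
    def test_chain_skeleton_and_separation_set(self, rng):
        cov = sem_covariance(
            ["A", "B", "C"], {("A", "B"): 1.0, ("B", "C"): 1.0}, {"A": 1, "B": 1, "C": 1}
        )
        data = _simulate_from_cov(cov, 5000, rng)
        skel, seps = estimate_skeleton(data=data, alpha=0.001)
        assert set(map(frozenset, skel.edges())) == {
            frozenset({"A", "B"}),
            frozenset({"B", "C"}),
        }
        assert seps.get("A", "C") == ("B",)

    def test_independent_traits_false_edge_rate_near_alpha(self, rng):
        edges = 0
        pairs = 0
        for _ in range(40):
            data = pd.DataFrame(rng.standard_normal((800, 5)), columns=list("ABCDE"))
            skel, _ = estimate_skeleton(data=data, alpha=0.001)
            edges += skel.number_of_edges()
            pairs += 10
        assert edges / pairs < 0.01

    def test_oracle_skeleton_equals_true_adjacency(self, fixture_joint_cov):
        skel, _ = estimate_skeleton(
            cov=fixture_joint_cov, tiers=fixture_tiers(), max_cond=None
        )
        true = default_trait_graph()
        expected = {frozenset(e) for e in true.edges()}
        expected |= {
            frozenset((iv, t))
            for iv, targets in SOURCE_INSTRUMENTS.items()
            for t in targets
        }
        assert {frozenset(e) for e in skel.edges()} == expected

    def test_instrument_pairs_never_adjacent(self, fixture_joint_cov):
        skel, _ = estimate_skeleton(
            cov=fixture_joint_cov, tiers=fixture_tiers(), max_cond=None
        )
        assert not skel.has_edge("IV_Palmitoleate", "IV_Margarate")

    def test_requires_exactly_one_input(self):
        with pytest.raises(ValueError, match="exactly one"):
            estimate_skeleton()


class TestOrientation:
    def test_mendelian_randomization_core_three_nodes(self):
        # IV -> A -> B: IV and B are separated by {A}, so A is no collider
        # and the closure rule orients A -> B.
        cov = joint_covariance(["A", "B"], {("A", "B"): 0.8}, {"IV": {"A": 0.6}})
        tiers = {"IV": INSTRUMENT, "A": TRAIT, "B": TRAIT}
        res = learn_structure(cov=cov, tiers=tiers, max_cond=None)
        assert ("A", "B") in res.graph.edges()
        assert ("IV", "A") in res.graph.edges()
        assert res.provenance[("A", "B")] == "meek"

    def test_single_undirected_edge_falls_back_deterministically(self, rng):
        # no instruments, one edge: the fallback fires, direction fixed by name
        cov = sem_covariance(["B", "A"], {("B", "A"): 0.8}, {"A": 1, "B": 1})
        data = _simulate_from_cov(cov, 4000, rng)
        res = learn_structure(data=data, alpha=0.001)
        assert res.graph.edges() == [("A", "B")]
        assert res.provenance[("A", "B")] == "fallback"

    def test_oracle_recovery_of_generating_network(self, oracle_result):
        learned = trait_subgraph(oracle_result.graph)
        true = default_trait_graph()
        assert set(learned.edges()) == set(true.edges())
        assert len(learned.edges()) == 29
        assert not oracle_result.dropped
        assert not any(r == "fallback" for r in oracle_result.provenance.values())

    def test_output_always_acyclic_and_fully_directed(self, rng):
        # noisy finite-sample runs must still produce a DAG with no residue
        for i in range(5):
            data = pd.DataFrame(
                rng.standard_normal((300, 6)) @ rng.uniform(-1, 1, size=(6, 6)),
                columns=list("ABCDEF"),
            )
            res = learn_structure(data=data, alpha=0.01)
            res.graph.validate()  # raises on a cycle
            assert not res.graph.undirected

    def test_instruments_add_orientation_information(self, fixture_joint_cov, oracle_result):
        cov_traits = fixture_joint_cov.loc[list(FATTY_ACIDS), list(FATTY_ACIDS)]
        no_iv = learn_structure(cov=cov_traits, max_cond=None)
        sound = lambda res: sum(
            1
            for (u, v), rule in res.provenance.items()
            if rule != "fallback" and res.graph.tier(u) == TRAIT
        )
        assert sound(no_iv) < sound(oracle_result)

    def test_conflicting_v_structures_drop_edge(self):
        # path u-a-b-v with empty separation sets: the collider u->a<-b wants
        # b->a while a->b<-v wants a->b; the contested edge must be dropped
        import networkx as nx
        from gdagnet import SeparationSets

        skel = nx.Graph([("u", "a"), ("a", "b"), ("b", "v")])
        seps = SeparationSets()
        for pair in (("u", "b"), ("a", "v"), ("u", "v")):
            seps.record(*pair, ())
        res = orient_edges(skel, seps, tiers={n: TRAIT for n in skel})
        res.graph.validate()
        assert res.dropped
        assert ("a", "b") not in res.graph.edges()
        assert ("b", "a") not in res.graph.edges()


class TestTraitSubgraph:
    def test_instrument_only_graph_becomes_empty(self):
        g = CausalGraph(nodes={"IV1": INSTRUMENT, "IV2": INSTRUMENT})
        assert trait_subgraph(g).nodes() == []

    def test_fixture_two_tier_graph_reduces_to_15_traits(self, oracle_result):
        assert len(oracle_result.graph.nodes()) == 17
        assert len(trait_subgraph(oracle_result.graph).nodes()) == 15

    def test_trait_edge_count_preserved_by_deletion(self, oracle_result):
        full = oracle_result.graph
        traits = set(full.trait_nodes())
        expected = [e for e in full.edges() if set(e) <= traits]
        assert sorted(trait_subgraph(full).edges()) == sorted(expected)


class TestRecoveryWithSampleSize:
    def _f1(self, learned: CausalGraph, true: CausalGraph) -> float:
        got, want = set(learned.edges()), set(true.edges())
        if not got or not want:
            return 0.0
        tp = len(got & want)
        precision, recall = tp / len(got), tp / len(want)
        if precision + recall == 0:
            return 0.0
        return 2 * precision * recall / (precision + recall)

    def test_oriented_edge_f1_nondecreasing_in_n(self):
        cov = joint_covariance(FATTY_ACIDS, DEFAULT_EDGE_WEIGHTS, SOURCE_INSTRUMENTS)
        tiers = fixture_tiers()
        true = default_trait_graph()
        rng = np.random.default_rng(2024)
        means = []
        for n in (500, 2000, 8000):
            scores = []
            for _ in range(20):
                data = _simulate_from_cov(cov, n, rng)
                res = learn_structure(data=data, tiers=tiers, alpha=0.001, max_cond=3)
                scores.append(self._f1(trait_subgraph(res.graph), true))
            means.append(np.mean(scores))
        # non-decreasing within Monte-Carlo tolerance
        assert means[1] >= means[0] - 0.03
        assert means[2] >= means[1] - 0.03
        assert means[2] > means[0]
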