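"""Affinity score, rewiring null, method ranking, coherence, hypergeometric."""

import math
from math import comb

import numpy as np
import pytest

from scmodules import (
    AssessmentResult,
    GeneNetwork,
    Partition,
    affinity_score,
    as_pvalue,
    clustering_coherence,
    gen_planted_network,
    homologous_edges,
    hypergeom_literature,
    rank_methods,
    rewire,
)


def _net(pairs):
    return GeneNetwork.from_edge_iter([(a, b, 1.0) for a, b in pairs])


class TestAffinity:
    def test_identity(self, two_cliques_bridge):
        assert homologous_edges(two_cliques_bridge, two_cliques_bridge) == 13
        assert affinity_score(two_cliques_bridge, two_cliques_bridge) == 1.0

    def test_disjoint_zero(self):
        assert affinity_score(_net([("A", "B")]), _net([("C", "D")])) == 0.0

    def test_undirected_match(self):
        n = _net([("A", "B"), ("B", "C"), ("C", "D")])
        gtn = _net([("B", "A"), ("C", "E")])
        assert homologous_edges(n, gtn) == 1

    def test_direct_substitution(self):
        n = _net([("A", "B"), ("C", "D"), ("E", "F"), ("G", "H")])
        gtn = _net(
            [("A", "B"), ("C", "D"), ("I", "J"), ("K", "L"),
             ("M", "N"), ("O", "P"), ("Q", "R"), ("S", "T")]
        )
        assert affinity_score(n, gtn) == pytest.approx(4 / 32)

    def test_symmetry(self, two_cliques_bridge, two_cliques):
        assert affinity_score(two_cliques_bridge, two_cliques) == pytest.approx(
            affinity_score(two_cliques, two_cliques_bridge)
        )

    def test_empty_network_rejected(self):
        empty = GeneNetwork({}, {"A"})
        with pytest.raises(ValueError):
            affinity_score(empty, _net([("A", "B")]))


class TestRewire:
    def test_preserves_degree_sequence_node_set_edge_count(self):
        for seed in range(10):
            net, _ = gen_planted_network((15, 15), 0.3, 0.1, seed=seed)
            rew = rewire(net, seed=seed + 100)
            assert rew.nodes == net.nodes
            assert rew.n_edges == net.n_edges
            assert rew.degrees() == net.degrees()

    def test_triangle_unchanged(self):
        tri = _net([("A", "B"), ("B", "C"), ("A", "C")])
        assert rewire(tri, seed=1).edge_set() == tri.edge_set()

    def test_single_edge_returned_with_warning(self, caplog):
        net = _net([("A", "B")])
        with caplog.at_level("WARNING"):
            out = rewire(net, seed=0)
        assert out.edge_set() == net.edge_set()
        assert any("rewired" in r.message for r in caplog.records)

    def test_different_seeds_give_different_edges(self):
        net, _ = gen_planted_network((25, 25), 0.2, 0.2 - 1e-9, seed=3)
        a = rewire(net, seed=1)
        b = rewire(net, seed=2)
        assert a.edge_set() != b.edge_set()
        assert a.degrees() == b.degrees() == net.degrees()

    def test_same_seed_deterministic(self):
        net, _ = gen_planted_network((20, 20), 0.3, 0.05, seed=4)
        assert rewire(net, seed=9).edge_set() == rewire(net, seed=9).edge_set()


class TestAsPvalue:
    def test_self_comparison_attains_minimum(self):
        # heterogeneous-degree network: rewired replicates lose edges vs itself
        net = gen_planted_network((20, 20), 0.5, 0.02, seed=5)[0]
        res = as_pvalue(net, net, n_perm=49, seed=1)
        assert res.p_value == pytest.approx(1 / 50)

    def test_p_bounds(self):
        net, _ = gen_planted_network((10, 10), 0.4, 0.1, seed=6)
        gtn, _ = gen_planted_network((10, 10), 0.4, 0.1, seed=7)
        res = as_pvalue(net, gtn, n_perm=19, seed=2)
        assert 1 / 20 <= res.p_value <= 1.0

    def test_records_seed_and_nperm(self):
        net, _ = gen_planted_network((10, 10), 0.5, 0.1, seed=8)
        res = as_pvalue(net, net, n_perm=19, seed=42)
        assert res.seed == 42 and res.n_permutations == 19

    def test_too_few_permutations_rejected(self, two_cliques):
        with pytest.raises(ValueError):
            as_pvalue(two_cliques, two_cliques, n_perm=5, seed=0)


class TestRankMethods:
    def _res(self, cell, method, p):
        return AssessmentResult(method, 0.5, p, 99, 0, cell_type=cell)

    def test_single_method_row_is_one(self):
        r = rank_methods([self._res("ct1", "m1", 0.05)])
        assert r.per_row_rescaled.loc["ct1", "m1"] == 1.0

    def test_order_preserved(self):
        r = rank_methods(
            [self._res("ct", "a", 0.01), self._res("ct", "b", 0.1), self._res("ct", "c", 1.0)]
        )
        row = r.per_row_rescaled.loc["ct"]
        assert row["a"] == 1.0 and row["c"] == 0.0 and 0 < row["b"] < 1

    def test_best_per_row_independent(self):
        r = rank_methods(
            [
                self._res("ct1", "a", 0.01), self._res("ct1", "b", 0.5),
                self._res("ct2", "a", 0.9), self._res("ct2", "b", 0.02),
            ]
        )
        assert r.best_per_row == {"ct1": ["a"], "ct2": ["b"]}

    def test_rescaled_in_unit_interval(self):
        r = rank_methods(
            [self._res("ct", m, p) for m, p in [("a", 0.03), ("b", 0.2), ("c", 0.7)]]
        )
        vals = r.per_row_rescaled.to_numpy()
        assert ((vals >= 0) & (vals <= 1)).all()


class TestClusteringCoherence:
    def _part(self, genes, terms_by_gene):
        assignment = {}
        module_terms = {}
        term_to_idx = {}
        for g in genes:
            t = terms_by_gene[g]
            if t not in term_to_idx:
                term_to_idx[t] = len(term_to_idx)
                module_terms[term_to_idx[t]] = t
            assignment[g] = term_to_idx[t]
        return Partition(assignment, module_terms=module_terms)

    def test_identical_partitions(self):
        genes = [f"g{i}" for i in range(10)]
        p = self._part(genes, {g: "T1" for g in genes})
        assert clustering_coherence(p, p) == 1.0

    def test_disjoint_gene_sets(self):
        a = self._part(["g1", "g2"], {"g1": "T1", "g2": "T1"})
        b = self._part(["h1", "h2"], {"h1": "T1", "h2": "T1"})
        assert clustering_coherence(a, b) == 0.0

    def test_half_agreement(self):
        genes = [f"g{i}" for i in range(10)]
        a = self._part(genes, {g: "T1" for g in genes})
        b = self._part(genes, {g: ("T1" if i < 5 else "T2") for i, g in enumerate(genes)})
        assert clustering_coherence(a, b) == pytest.approx(0.5)


class TestHypergeom:
    def test_zero_overlap_is_one(self):
        assert hypergeom_literature(0, 10, 10, 50) == pytest.approx(1.0)

    def test_saturated_table_is_one(self):
        assert hypergeom_literature(10, 10, 10, 10) == pytest.approx(1.0)

    def test_exact_enumeration(self):
        p = hypergeom_literature(5, 10, 10, 50)
        exact = sum(comb(10, k) * comb(40, 10 - k) for k in range(5, 11)) / comb(50, 10)
        assert p == pytest.approx(exact, abs=1e-12)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_literature(11, 10, 10, 50)
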