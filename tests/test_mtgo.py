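"""Module detection: modularity and annotation-agreement oracles, term
selection, initialization, and full runs on planted structure."""

import numpy as np
import pytest
from sympy.utilities.iterables import multiset_partitions

from scmodules import (
    AnnotationDictionary,
    GeneNetwork,
    MtgoParams,
    Partition,
    UNLABELED,
    gen_annotation_dict,
    gen_planted_network,
    initialize_partition,
    modularity_Q,
    quality_QGO,
    run_mtgo,
    selection_gamma,
)


def _partition_from_blocks(blocks):
    assignment = {}
    for h, block in enumerate(blocks):
        for g in block:
            assignment[g] = h
    return Partition(assignment)


class TestModularityQ:
    def test_single_module_is_zero(self, two_cliques_bridge):
        part = _partition_from_blocks([sorted(two_cliques_bridge.nodes)])
        assert modularity_Q(part, two_cliques_bridge) == pytest.approx(0.0, abs=1e-15)

    def test_all_singletons_negative_closed_form(self, two_cliques_bridge):
        part = _partition_from_blocks([[n] for n in sorted(two_cliques_bridge.nodes)])
        m = two_cliques_bridge.n_edges
        expected = -sum(
            (k / (2 * m)) ** 2 for k in two_cliques_bridge.degrees().values()
        )
        assert modularity_Q(part, two_cliques_bridge) == pytest.approx(expected, abs=1e-14)

    def test_matches_networkx_on_random_partitions(self, two_cliques_bridge):
        import networkx as nx

        g = two_cliques_bridge.to_networkx()
        rng = np.random.default_rng(0)
        nodes = sorted(two_cliques_bridge.nodes)
        for _ in range(25):
            labels = rng.integers(0, 3, size=len(nodes))
            blocks = [
                [n for n, l in zip(nodes, labels) if l == h]
                for h in range(3)
                if (labels == h).any()
            ]
            part = _partition_from_blocks(blocks)
            expected = nx.community.modularity(g, [set(b) for b in blocks])
            assert modularity_Q(part, two_cliques_bridge) == pytest.approx(
                expected, abs=1e-12
            )

    def test_uncovered_node_named_in_error(self, two_cliques_bridge):
        part = _partition_from_blocks([["A", "B", "C", "D", "E", "F", "G"]])
        with pytest.raises(ValueError, match="H"):
            modularity_Q(part, two_cliques_bridge)

    def test_bridge_split_is_brute_force_maximum(self, two_cliques_bridge):
        nodes = sorted(two_cliques_bridge.nodes)
        best_q, best_part = -2.0, None
        for blocks in multiset_partitions(nodes):
            q = modularity_Q(_partition_from_blocks(blocks), two_cliques_bridge)
            if q > best_q:
                best_q, best_part = q, blocks
        assert sorted(map(sorted, best_part)) == [list("ABCD"), list("EFGH")]
        split = _partition_from_blocks([list("ABCD"), list("EFGH")])
        assert modularity_Q(split, two_cliques_bridge) == pytest.approx(best_q)


class TestQualityQGO:
    def test_perfect_agreement(self, three_term_dict):
        genes = [f"G{i:02d}" for i in range(20)]
        net = GeneNetwork.from_edge_iter(
            [(genes[i], genes[i + 1], 1.0) for i in range(19)]
        )
        part = _partition_from_blocks([genes[:7], genes[7:14], genes[14:]])
        part.module_terms = {0: "T1", 1: "T2", 2: "T3"}
        assert quality_QGO(part, three_term_dict, net) == pytest.approx(1.0)

    def test_no_overlap_is_zero(self, three_term_dict):
        genes = [f"G{i:02d}" for i in range(20)]
        net = GeneNetwork.from_edge_iter(
            [(genes[i], genes[i + 1], 1.0) for i in range(19)]
        )
        part = _partition_from_blocks([genes[:7], genes[7:14], genes[14:]])
        part.module_terms = {0: "T2", 1: "T3", 2: "T1"}
        # every module labeled with a disjoint term -> zero intersections
        assert quality_QGO(part, three_term_dict, net) == pytest.approx(0.0)

    def test_unannotated_nodes_rejected(self):
        net = GeneNetwork.from_edge_iter([("X", "Y", 1.0)])
        d = AnnotationDictionary({"T": ("t", frozenset({"Z"}))})
        part = _partition_from_blocks([["X", "Y"]])
        part.module_terms = {0: UNLABELED}
        with pytest.raises(ValueError, match="N_AnnSo"):
            quality_QGO(part, d, net)


class TestSelectionGamma:
    def test_exact_match_unique(self, three_term_dict):
        assert selection_gamma(set(three_term_dict.genes_of("T2")), three_term_dict) == "T2"

    def test_specificity_tie_break(self):
        members = {"A", "B", "C"}
        d = AnnotationDictionary(
            {
                "BIG": ("big", frozenset({"A", "B", "C"} | {f"x{i}" for i in range(47)})),
                "SMALL": ("small", frozenset({"A", "B", "C", "D", "E"})),
            }
        )
        assert selection_gamma(members, d) == "SMALL"

    def test_lexicographic_tie_break(self):
        d = AnnotationDictionary(
            {"TB": ("b", frozenset({"A", "B"})), "TA": ("a", frozenset({"A", "C"}))}
        )
        assert selection_gamma({"A"}, d) == "TA"

    def test_disjoint_members_unlabeled(self, three_term_dict):
        assert selection_gamma({"ZZZ"}, three_term_dict) is UNLABELED


class TestInitializePartition:
    def test_disjoint_terms_spawn_modules(self, two_cliques):
        d = AnnotationDictionary(
            {
                "L": ("left", frozenset({"A", "B", "C", "D"})),
                "R": ("right", frozenset({"E", "F", "G", "H"})),
            }
        )
        part = initialize_partition(two_cliques, d, seed=0)
        assert part.H == 2
        assert {frozenset(m) for m in part.members().values()} == {
            frozenset("ABCD"), frozenset("EFGH"),
        }

    def test_empty_dictionary_gives_singletons(self, two_cliques):
        part = initialize_partition(two_cliques, AnnotationDictionary({}), seed=0)
        # unannotated genes attach to assigned neighbors; with nothing
        # assigned yet, the first gene seeds a module its neighbors join
        assert part.H >= 1
        part.validate(two_cliques)

    def test_seed_determinism(self, two_cliques_bridge, three_term_dict):
        a = initialize_partition(two_cliques_bridge, three_term_dict, seed=5)
        b = initialize_partition(two_cliques_bridge, three_term_dict, seed=5)
        assert a.assignment == b.assignment


class TestRunMtgo:
    def test_planted_blocks_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        aris = []
        for seed in range(10):
            net, truth = gen_planted_network((30, 30, 30, 30), 0.4, 0.02, seed=seed)
            d = gen_annotation_dict(truth, coverage=1.0, contamination=0.0, seed=seed)
            part = run_mtgo(net, d, MtgoParams(seed=seed))
            genes = sorted(net.nodes)
            aris.append(
                adjusted_rand_score(
                    [truth.block_assignment[g] for g in genes],
                    [part.assignment[g] for g in genes],
                )
            )
        assert np.median(aris) >= 0.9

    def test_pure_topology_on_two_cliques_matches_brute_force(self, two_cliques):
        nodes = sorted(two_cliques.nodes)
        best_q = max(
            modularity_Q(_partition_from_blocks(blocks), two_cliques)
            for blocks in multiset_partitions(nodes)
        )
        part = run_mtgo(two_cliques, AnnotationDictionary({}), MtgoParams(seed=0, topology_weight=1.0))
        assert {frozenset(m) for m in part.members().values()} == {
            frozenset("ABCD"), frozenset("EFGH"),
        }
        assert modularity_Q(part, two_cliques) == pytest.approx(best_q, abs=1e-12)

    def test_trajectory_matches_recomputation(self, two_cliques_bridge):
        d = AnnotationDictionary(
            {
                "L": ("left", frozenset({"A", "B", "C", "D"})),
                "R": ("right", frozenset({"E", "F", "G", "H"})),
            }
        )
        part = run_mtgo(two_cliques_bridge, d, MtgoParams(seed=1))
        q, qgo = part.trajectory[-1]
        assert modularity_Q(part, two_cliques_bridge) == pytest.approx(q, abs=1e-10)
        assert quality_QGO(part, d, two_cliques_bridge) == pytest.approx(qgo, abs=1e-10)

    def test_convergence_contract(self):
        net, truth = gen_planted_network((20, 20, 20), 0.4, 0.03, seed=3)
        d = gen_annotation_dict(truth, seed=3)
        part = run_mtgo(net, d, MtgoParams(seed=3))
        assert part.converged
        (q1, g1), (q2, g2) = part.trajectory[-2:]
        assert abs(q2 - q1) < 1e-4 and abs(g2 - g1) < 1e-4

    def test_bounds_at_every_iteration(self):
        net, truth = gen_planted_network((15, 15), 0.5, 0.1, seed=4)
        d = gen_annotation_dict(truth, coverage=0.6, contamination=0.2, seed=4)
        part = run_mtgo(net, d, MtgoParams(seed=4))
        for q, qgo in part.trajectory:
            assert -1.0 <= q <= 1.0
            assert 0.0 <= qgo <= 1.0

    def test_seed_determinism(self):
        net, truth = gen_planted_network((20, 20), 0.4, 0.05, seed=5)
        d = gen_annotation_dict(truth, seed=5)
        a = run_mtgo(net, d, MtgoParams(seed=11))
        b = run_mtgo(net, d, MtgoParams(seed=11))
        assert a.assignment == b.assignment
        assert a.trajectory == b.trajectory

    def test_local_optimum_beats_most_enumerated_partitions(self, two_cliques_bridge):
        d = AnnotationDictionary(
            {
                "L": ("left", frozenset({"A", "B", "C", "D"})),
                "R": ("right", frozenset({"E", "F", "G", "H"})),
            }
        )
        w = 0.5
        part = run_mtgo(two_cliques_bridge, d, MtgoParams(seed=0, topology_weight=w))
        achieved = w * modularity_Q(part, two_cliques_bridge) + (1 - w) * quality_QGO(
            part, d, two_cliques_bridge
        )
        nodes = sorted(two_cliques_bridge.nodes)
        scores = []
        for blocks in multiset_partitions(nodes):
            p = _partition_from_blocks(blocks)
            p.module_terms = {
                h: selection_gamma(mem, d) for h, mem in p.members().items()
            }
            scores.append(
                w * modularity_Q(p, two_cliques_bridge)
                + (1 - w) * quality_QGO(p, d, two_cliques_bridge)
            )
        frac_beaten = np.mean([achieved >= s - 1e-12 for s in scores])
        assert frac_beaten >= 0.95

    def test_shuffled_dictionary_never_beats_true_one(self):
        """Annotation ablation: random same-size gene sets give lower QGO."""
        rng = np.random.default_rng(99)
        true_qgos, shuf_qgos = [], []
        for seed in range(10):
            net, truth = gen_planted_network((30, 30, 30, 30), 0.4, 0.02, seed=seed)
            d = gen_annotation_dict(truth, seed=seed)
            genes = sorted(net.nodes)
            shuffled = {}
            for tid, (label, gset) in d.terms.items():
                picked = rng.choice(genes, size=len(gset), replace=False)
                shuffled[tid] = (label, frozenset(picked))
            d_shuf = AnnotationDictionary(shuffled)
            true_qgos.append(run_mtgo(net, d, MtgoParams(seed=seed)).trajectory[-1][1])
            shuf_qgos.append(
                run_mtgo(net, d_shuf, MtgoParams(seed=seed)).trajectory[-1][1]
            )
        assert np.median(shuf_qgos) <= np.median(true_qgos)

    def test_density_mode_returns_valid_partition(self):
        net, truth = gen_planted_network((20, 20), 0.4, 0.05, seed=6)
        d = gen_annotation_dict(truth, seed=6)
        part = run_mtgo(net, d, MtgoParams(seed=6, density_mode=True))
        part.validate(net)
        assert part.H >= 1
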