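"""Shared fixtures: tiny hand-built networks, dictionaries, matrices."""

import numpy as np
import pytest

from scmodules import (
    AnnotationDictionary,
    CoexpressionMatrix,
    ExpressionMatrix,
    GeneNetwork,
)


def clique_edges(nodes):
    return {
        (a, b): 1.0
        for i, a in enumerate(nodes)
        for b in nodes[i + 1 :]
    }


@pytest.fixture
def two_cliques_bridge() -> GeneNetwork:
    """Two 4-cliques joined by a single bridge edge (8 nodes, 13 edges)."""
    left = ["A", "B", "C", "D"]
    right = ["E", "F", "G", "H"]
    edges = {**clique_edges(left), **clique_edges(right), ("D", "E"): 1.0}
    return GeneNetwork(edges, set(left + right))


@pytest.fixture
def two_cliques() -> GeneNetwork:
    """Two disconnected 4-cliques (8 nodes, 12 edges)."""
    left = ["A", "B", "C", "D"]
    right = ["E", "F", "G", "H"]
    return GeneNetwork(
        {**clique_edges(left), **clique_edges(right)}, set(left + right)
    )


@pytest.fixture
def three_term_dict() -> AnnotationDictionary:
    """Three disjoint terms over 20 genes G00..G19 (sizes 7, 7, 6)."""
    genes = [f"G{i:02d}" for i in range(20)]
    return AnnotationDictionary(
        {
            "T1": ("term one", frozenset(genes[:7])),
            "T2": ("term two", frozenset(genes[7:14])),
            "T3": ("term three", frozenset(genes[14:])),
        }
    )


@pytest.fixture
def random_coexpr() -> CoexpressionMatrix:
    """Symmetric random coexpression matrix over 10 genes, all |c| distinct."""
    rng = np.random.default_rng(42)
    n = 10
    genes = [f"G{i:02d}" for i in range(n)]
    w = np.zeros((n, n))
    iu, ku = np.triu_indices(n, k=1)
    vals = rng.permutation(np.linspace(0.01, 0.99, len(iu)))
    signs = rng.choice([-1.0, 1.0], size=len(iu))
    w[iu, ku] = vals * signs
    w = w + w.T
    np.fill_diagonal(w, 1.0)
    return CoexpressionMatrix(w, genes, "pearson")


@pytest.fixture
def small_expression() -> ExpressionMatrix:
    rng = np.random.default_rng(7)
    values = rng.poisson(5.0, size=(5, 20)).astype(float)
    return ExpressionMatrix(
        values,
        [f"G{i}" for i in range(5)],
        [f"C{j}" for j in range(20)],
        ["all"] * 20,
    )
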