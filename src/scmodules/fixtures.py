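"""Seed-deterministic synthetic data with planted structure.

Every stage of the pipeline is testable without downloads through these
generators:

* :func:`gen_planted_network` — stochastic block model over named genes;
* :func:`gen_planted_expression` — a log-normal latent-factor expression
  model: genes of a block share a per-cell latent factor, so
  within-block coexpression exceeds cross-block coexpression; values are
  exponentiated, rounded to nonnegative integer counts, and a
  quantile-based dropout step zeroes the low tail, emulating the
  sparsity of normalized scRNA-seq counts (no library-size or batch
  effects are modeled);
* :func:`gen_annotation_dict` — one term per planted block with
  configurable coverage and contamination, plus optional decoys;
* :func:`gen_power_law_network` — configuration-model network whose
  degrees are an exact zeta (discrete power law) sample.

The :class:`PlantedTruth` record stores the generating parameters and
block structure verbatim, so every downstream test can be re-derived.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import networkx as nx
from scipy.stats import zipf

from .io_formats import AnnotationDictionary, ExpressionMatrix, GeneNetwork


@dataclass
class PlantedTruth:
    """Ground truth of a planted fixture: block structure + generation params."""

    block_assignment: dict[str, int]
    block_terms: dict[int, str] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def blocks(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for gene, b in self.block_assignment.items():
            out.setdefault(b, []).append(gene)
        return {b: sorted(g) for b, g in sorted(out.items())}

    def write(self, path) -> None:
        payload = asdict(self)
        payload["block_terms"] = {str(k): v for k, v in self.block_terms.items()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


def gen_planted_network(
    block_sizes: tuple[int, ...],
    p_in: float,
    p_out: float,
    seed: int = 0,
) -> tuple[GeneNetwork, PlantedTruth]:
    """Stochastic block model over named genes; edge weights 1.0.

    Within-block pairs connect with probability ``p_in``, cross-block
    pairs with ``p_out`` (< p_in).
    """
    if not all(s >= 2 for s in block_sizes):
        raise ValueError("every block needs >= 2 genes")
    if not (0 <= p_out < p_in <= 1):
        raise ValueError("need 0 <= p_out < p_in <= 1")
    rng = np.random.default_rng(seed)
    n = sum(block_sizes)
    genes = _gene_names(n)
    block_of: dict[str, int] = {}
    idx = 0
    for b, size in enumerate(block_sizes):
        for _ in range(size):
            block_of[genes[idx]] = b
            idx += 1
    edges: dict[tuple[str, str], float] = {}
    nodes = set(genes)
    for i in range(n):
        for j in range(i + 1, n):
            p = p_in if block_of[genes[i]] == block_of[genes[j]] else p_out
            if rng.random() < p:
                edges[(genes[i], genes[j])] = 1.0
    truth = PlantedTruth(
        block_assignment=block_of,
        block_terms={b: f"TERM{b}" for b in range(len(block_sizes))},
        params={
            "generator": "planted_network",
            "block_sizes": list(block_sizes),
            "p_in": p_in,
            "p_out": p_out,
            "seed": seed,
        },
    )
    net = GeneNetwork(edges, nodes, {"source": "planted_sbm", "seed": seed})
    return net, truth


def gen_planted_expression(
    block_sizes: tuple[int, ...],
    n_cells: int = 200,
    base_corr: float = 0.8,
    noise_sd: float = 0.3,
    dropout_rate: float = 0.3,
    seed: int = 0,
) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Log-normal latent-factor expression matrix with block-correlated genes.

    Each block has one latent factor per cell; gene i of the block reads
    ``loading_i * factor + noise`` on the log scale (loading scaled so
    the factor explains a ``base_corr`` share of the log-variance), then
    counts = round(exp(.)). Entries below the ``dropout_rate`` quantile
    are zeroed, emulating dropouts.
    """
    if n_cells < 10:
        raise ValueError("need at least 10 cells")
    if not (0 < base_corr < 1):
        raise ValueError("base_corr must be in (0, 1)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    n_genes = sum(block_sizes)
    genes = _gene_names(n_genes)
    log_expr = np.empty((n_genes, n_cells))
    block_of: dict[str, int] = {}
    row = 0
    # at noise_sd = 1 the within-block log-scale correlation equals
    # base_corr exactly; smaller noise_sd pushes it toward 1
    loading = np.sqrt(base_corr)
    eps_sd = noise_sd * np.sqrt(1.0 - base_corr)
    for b, size in enumerate(block_sizes):
        factor = rng.normal(0.0, 1.0, size=n_cells)
        for _ in range(size):
            gene_mean = rng.uniform(0.5, 2.5)
            noise = rng.normal(0.0, eps_sd, size=n_cells)
            log_expr[row] = gene_mean + loading * factor + noise
            block_of[genes[row]] = b
            row += 1
    counts = np.round(np.exp(log_expr))
    if dropout_rate > 0:
        cut = np.quantile(counts, dropout_rate)
        counts = np.where(counts <= cut, 0.0, counts)
    counts = np.maximum(counts, 0.0)
    cells = [f"C{j:04d}" for j in range(n_cells)]
    truth = PlantedTruth(
        block_assignment=block_of,
        block_terms={b: f"TERM{b}" for b in range(len(block_sizes))},
        params={
            "generator": "planted_expression",
            "block_sizes": list(block_sizes),
            "n_cells": n_cells,
            "base_corr": base_corr,
            "noise_sd": noise_sd,
            "dropout_rate": dropout_rate,
            "seed": seed,
        },
    )
    expr = ExpressionMatrix(counts, genes, cells, ["all"] * n_cells)
    return expr, truth


def gen_annotation_dict(
    truth: PlantedTruth,
    coverage: float = 1.0,
    contamination: float = 0.0,
    n_decoys: int = 0,
    decoy_size: int = 10,
    seed: int = 0,
) -> AnnotationDictionary:
    """One annotation term per planted block.

    Each term holds a ``coverage`` fraction of its block's genes; a
    ``contamination`` fraction of the term is then replaced by genes
    from other blocks. Optional decoy terms are random gene draws.
    """
    if not (0 < coverage <= 1):
        raise ValueError("coverage must be in (0, 1]")
    if not (0 <= contamination < 1):
        raise ValueError("contamination must be in [0, 1)")
    rng = np.random.default_rng(seed)
    blocks = truth.blocks()
    all_genes = sorted(truth.block_assignment)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for b, genes in blocks.items():
        term_id = truth.block_terms.get(b, f"TERM{b}")
        n_keep = max(1, round(coverage * len(genes)))
        kept = list(rng.choice(genes, size=n_keep, replace=False))
        if contamination > 0:
            n_foreign = round(contamination * len(kept))
            if n_foreign:
                foreign_pool = [g for g in all_genes if truth.block_assignment[g] != b]
                foreign = list(rng.choice(foreign_pool, size=n_foreign, replace=False))
                kept = kept[: len(kept) - n_foreign] + foreign
        terms[term_id] = (f"planted block {b}", frozenset(kept))
    for d in range(n_decoys):
        picked = rng.choice(all_genes, size=min(decoy_size, len(all_genes)), replace=False)
        terms[f"DECOY{d}"] = (f"decoy {d}", frozenset(picked))
    return AnnotationDictionary(terms)


def gen_power_law_network(
    n_nodes: int, gamma: float = 2.5, seed: int = 0
) -> GeneNetwork:
    """Configuration-model network with an exact discrete power-law degree sample.

    Degrees are drawn from the zeta distribution with exponent ``gamma``
    (support starting at 1), capped at ``n_nodes - 1``; the sequence sum
    is made even by incrementing one degree; self-loops and parallel
    edges from the wiring are discarded.
    """
    if n_nodes < 100:
        raise ValueError("need at least 100 nodes for a meaningful degree fit")
    if not (2.0 < gamma < 3.5):
        raise ValueError("gamma must be in (2, 3.5)")
    rng = np.random.default_rng(seed)
    degrees = zipf(gamma).rvs(size=n_nodes, random_state=rng)
    degrees = np.minimum(degrees, n_nodes - 1)
    if degrees.sum() % 2:
        degrees[int(rng.integers(n_nodes))] += 1
    g = nx.configuration_model(degrees.tolist(), seed=int(rng.integers(2**31)))
    g = nx.Graph(g)  # collapse parallel edges
    g.remove_edges_from(nx.selfloop_edges(g))
    genes = _gene_names(n_nodes)
    edges = {}
    for u, v in g.edges():
        a, b = genes[u], genes[v]
        key = (a, b) if a <= b else (b, a)
        edges[key] = 1.0
    return GeneNetwork(
        edges,
        set(genes),
        {"source": "power_law_configuration_model", "gamma": gamma, "seed": seed},
    )
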