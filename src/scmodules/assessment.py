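"""Benchmarking extracted networks against a ground-truth network.

An extracted network N is compared with a ground-truth network (GTN) —
any user-supplied edge list of experimentally supported gene/protein
associations — through the affinity score

    AS(N, GTN) = h(N, GTN)^2 / (N_EN * N_EGTN)

where h is the number of homologous edges (unordered gene pairs present
in both networks) and N_EN, N_EGTN the two edge counts. AS alone is hard
to interpret, so it is referred to a degree-preserving null: N is
repeatedly rewired by double-edge swaps (keeping every node's degree
exact) and the AS of each rewired replicate against the GTN forms the
null distribution. The permutation p-value uses the add-one estimator
p = (1 + #{AS_rewired >= AS_observed}) / (1 + n_perm), which can never
be zero.

Rankings over (cell type x extraction method) grids are summarized as
-log(p) matrices, min-max rescaled within each cell type, with the best
method per cell type flagged — the tabular equivalent of the usual
heatmap-with-dots display.

Also here: the clustering-coherence score comparing the module labels two
independently extracted networks assign to their shared genes, and the
upper-tail hypergeometric test for literature co-occurrence counts.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io_formats import GeneNetwork

logger = logging.getLogger(__name__)


@dataclass
class AssessmentResult:
    """Affinity score of one (cell type, extraction method) pair with its null p-value."""

    method_id: str
    affinity: float
    p_value: float
    n_permutations: int
    seed: int
    cell_type: str = ""


@dataclass
class MethodRanking:
    """-log(p) scores per (cell type, method) with per-row min-max rescaling."""

    scores: pd.DataFrame
    per_row_rescaled: pd.DataFrame
    best_per_row: dict[str, list[str]] = field(default_factory=dict)


def homologous_edges(N: GeneNetwork, GTN: GeneNetwork) -> int:
    """Number of unordered gene pairs present in both edge sets (weights ignored)."""
    if N.n_edges == 0 or GTN.n_edges == 0:
        raise ValueError("both networks must be nonempty")
    return len(N.edge_set() & GTN.edge_set())


def affinity_score(N: GeneNetwork, GTN: GeneNetwork) -> float:
    """AS = h^2 / (N_EN * N_EGTN), in [0, 1]; symmetric in its arguments."""
    h = homologous_edges(N, GTN)
    return h * h / (N.n_edges * GTN.n_edges)


def rewire(
    N: GeneNetwork, n_swap_multiplier: float = 10.0, seed: int = 0
) -> GeneNetwork:
    """Randomize edge identities while preserving every node's degree.

    Performs ``n_swap_multiplier * n_edges`` attempted double-edge swaps:
    two random edges (a, b), (c, d) are replaced by (a, d), (c, b);
    attempts that would create a self-loop or duplicate edge are
    rejected. Node set, edge count, and degree sequence are preserved
    exactly. A network admitting no valid swap (e.g. a single edge or a
    triangle) is returned unchanged with a warning.
    """
    if n_swap_multiplier <= 0:
        raise ValueError("n_swap_multiplier must be positive")
    if N.n_edges < 2:
        logger.warning("network with %d edge(s) cannot be rewired", N.n_edges)
        return GeneNetwork(dict(N.edges), set(N.nodes), dict(N.metadata))
    rng = random.Random(seed)
    edges = list(N.edges)  # canonical (a, b) tuples
    edge_set = set(edges)
    m = len(edges)
    attempts = int(round(n_swap_multiplier * m))
    accepted = 0
    for _ in range(attempts):
        i = rng.randrange(m)
        j = rng.randrange(m)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        # randomly choose which endpoints to exchange
        if rng.random() < 0.5:
            c, d = d, c
        # propose (a, d), (c, b)
        if a == d or c == b:
            continue
        new1 = (a, d) if a <= d else (d, a)
        new2 = (c, b) if c <= b else (b, c)
        if new1 in edge_set or new2 in edge_set or new1 == new2:
            continue
        edge_set.remove(edges[i])
        edge_set.remove(edges[j])
        edge_set.add(new1)
        edge_set.add(new2)
        edges[i] = new1
        edges[j] = new2
        accepted += 1
    if accepted == 0:
        logger.warning(
            "no valid degree-preserving swap found in %d attempts; "
            "returning the input network unchanged",
            attempts,
        )
    out_edges = {e: 1.0 for e in edges}
    meta = dict(N.metadata)
    meta.update(rewired=True, seed=seed, swaps_accepted=accepted)
    return GeneNetwork(out_edges, set(N.nodes), meta)


def as_pvalue(
    N: GeneNetwork,
    GTN: GeneNetwork,
    n_perm: int = 100,
    seed: int = 0,
    n_swap_multiplier: float = 10.0,
    method_id: str = "",
    cell_type: str = "",
) -> AssessmentResult:
    """Permutation p-value of AS(N, GTN) under the degree-preserving rewiring null.

    Replicate i rewires N with seed ``seed + i + 1``; ties (rewired AS
    equal to the observed AS) count toward the numerator, and the add-one
    estimator keeps p in [1/(n_perm+1), 1].
    """
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19 for a meaningful p-value")
    gtn_edges = GTN.edge_set()
    observed = affinity_score(N, GTN)
    n_e_gtn = GTN.n_edges
    n_e_n = N.n_edges
    exceed = 0
    for i in range(n_perm):
        rew = rewire(N, n_swap_multiplier=n_swap_multiplier, seed=seed + i + 1)
        h = len(rew.edge_set() & gtn_edges)
        as_rew = h * h / (n_e_n * n_e_gtn)
        if as_rew >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return AssessmentResult(
        method_id=method_id,
        affinity=observed,
        p_value=p,
        n_permutations=n_perm,
        seed=seed,
        cell_type=cell_type,
    )


def rank_methods(results: list[AssessmentResult]) -> MethodRanking:
    """Arrange -log(p) scores as cell-type x method matrix with per-row rescale.

    Rows (cell types) are min-max rescaled to [0, 1] so each row spans
    the full color range of a heatmap; a single-method or constant row is
    set to 1 by convention. All methods tied at a row's maximum are
    flagged as best.
    """
    if not results:
        raise ValueError("no assessment results to rank")
    rows = sorted({r.cell_type for r in results})
    cols = sorted({r.method_id for r in results})
    scores = pd.DataFrame(np.nan, index=rows, columns=cols)
    for r in results:
        if r.p_value <= 0:
            raise ValueError("p-values must be positive")
        scores.loc[r.cell_type, r.method_id] = -math.log(r.p_value)
    rescaled = scores.copy()
    best: dict[str, list[str]] = {}
    for row in rows:
        vals = scores.loc[row]
        lo, hi = vals.min(), vals.max()
        if not np.isfinite(hi):
            raise ValueError(f"cell type {row!r} has no scores")
        if hi == lo:
            rescaled.loc[row] = np.where(vals.notna(), 1.0, np.nan)
        else:
            rescaled.loc[row] = (vals - lo) / (hi - lo)
        best[row] = [c for c in cols if vals[c] == hi]
    return MethodRanking(scores=scores, per_row_rescaled=rescaled, best_per_row=best)


def clustering_coherence(part_a, part_b) -> float:
    """Fraction of shared genes assigned the same module label by two runs.

    Two partitions of independently extracted networks are comparable
    only through their annotation labels, so the numerator counts genes
    present in both networks whose assigned term id is identical; the
    denominator is the average of the two gene counts. Capped at 1.
    """
    genes_a = set(part_a.assignment)
    genes_b = set(part_b.assignment)
    if not genes_a or not genes_b:
        raise ValueError("both partitions must be nonempty")
    same = 0
    for g in genes_a & genes_b:
        ta = part_a.module_terms.get(part_a.assignment[g])
        tb = part_b.module_terms.get(part_b.assignment[g])
        if ta is not None and ta == tb:
            same += 1
    denom = (len(genes_a) + len(genes_b)) / 2.0
    return min(1.0, same / denom)


def hypergeom_literature(
    hits_both: int, hits_celltype: int, hits_pathway: int, total_papers: int
) -> float:
    """Upper-tail hypergeometric P(X >= hits_both) for literature co-occurrence.

    Population = papers about the tissue, successes = papers hitting the
    pathway, draws = papers hitting the cell type; tests whether the
    observed number of papers hitting both exceeds chance.
    """
    if not (0 <= hits_both <= min(hits_celltype, hits_pathway) <= total_papers):
        raise ValueError(
            "need 0 <= hits_both <= min(hits_celltype, hits_pathway) <= total_papers"
        )
    if max(hits_celltype, hits_pathway) > total_papers:
        raise ValueError("category hits cannot exceed the total paper count")
    return float(hypergeom.sf(hits_both - 1, total_papers, hits_pathway, hits_celltype))


def write_assessment_report(results: list[AssessmentResult], path) -> None:
    """Delimited report: cell_type, method, affinity, p_value, n_perm, seed."""
    df = pd.DataFrame(
        [
            {
                "cell_type": r.cell_type,
                "method": r.method_id,
                "affinity": r.affinity,
                "p_value": r.p_value,
                "n_permutations": r.n_permutations,
                "seed": r.seed,
            }
            for r in results
        ]
    )
    df.to_csv(path, sep="\t", index=False)
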