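"""Iterative topology + annotation module detection on a gene network.

The algorithm partitions an extracted gene network into functional
modules by jointly optimizing two quantities:

* **Q**, the Newman modularity of the partition,

      Q = sum_h [ e_h / |E|  -  (d_h / 2|E|)^2 ]

  with e_h the number of edges inside module h and d_h the sum of the
  degrees of its nodes. Q in [-1, 1]; positive Q means more within-module
  edges than a degree-matched random graph would give.

* **QGO**, the agreement between the partition and the annotation terms
  selected to describe it,

      QGO = sum_h |delta(term_h) ∩ members_h| / N_AnnSo

  where term_h is the annotation term assigned to module h by the
  Selection-gamma rule (the term with maximal overlap with the module,
  ties resolved toward the more specific, i.e. smaller, term) and
  N_AnnSo is the number of network nodes carrying at least one term.
  QGO in [0, 1].

Each iteration (1) reassigns every module its best term, (2) sweeps the
nodes in a seed-shuffled order, moving each node to the adjacent module
(or a fresh singleton) that maximizes the blended gain
``topology_weight * dQ + (1 - topology_weight) * dQGO``, and (3) drops
emptied modules. Iteration stops when two consecutive iterations change
both Q and QGO by less than the threshold T (default 1e-4), or at
``max_iter``. With ``density_mode`` the returned partition is the
iterate maximizing mean within-module edge density rather than the final
one, weighting adherence to the network structure over the annotation
source.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

from .io_formats import AnnotationDictionary, GeneNetwork

logger = logging.getLogger(__name__)

#: Sentinel term id for modules that overlap no dictionary term.
UNLABELED: None = None


@dataclass
class MtgoParams:
    """Tunable parameters of the module-detection iteration."""

    T: float = 1e-4
    max_iter: int = 200
    seed: int = 0
    topology_weight: float = 0.5
    density_mode: bool = False

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("convergence threshold T must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not (0.0 <= self.topology_weight <= 1.0):
            raise ValueError("topology_weight must be in [0, 1]")


@dataclass
class Partition:
    """A module assignment over a network's genes with per-module term labels.

    ``assignment`` maps every network gene to a module index;
    ``module_terms`` maps each module index to its annotation term id
    (``None`` = unlabeled); ``trajectory`` records the per-iteration
    (Q, QGO) pairs of the run that produced the partition.
    """

    assignment: dict[str, int]
    module_terms: dict[int, str | None] = field(default_factory=dict)
    trajectory: list[tuple[float, float]] = field(default_factory=list)
    converged: bool = True

    @property
    def H(self) -> int:
        return len(set(self.assignment.values()))

    def members(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for gene, h in self.assignment.items():
            out.setdefault(h, set()).add(gene)
        return out

    def validate(self, net: GeneNetwork) -> None:
        for node in net.nodes:
            if node not in self.assignment:
                raise ValueError(f"network node {node!r} is not covered by the partition")
        for h, mem in self.members().items():
            if not mem:
                raise ValueError(f"module {h} is empty")

    def module_colors(self) -> dict[int, int]:
        """Stable color indices: 0 for the largest module, 1 for the next, ..."""
        sizes = {h: len(m) for h, m in self.members().items()}
        order = sorted(sizes, key=lambda h: (-sizes[h], h))
        return {h: i for i, h in enumerate(order)}


def modularity_Q(part: Partition, net: GeneNetwork) -> float:
    """Newman modularity of a partition: sum_h e_h/|E| - (d_h/2|E|)^2."""
    if net.n_edges == 0:
        raise ValueError("modularity is undefined on an edgeless network")
    part.validate(net)
    m = net.n_edges
    assign = part.assignment
    e_h: dict[int, int] = {}
    for a, b in net.edges:
        if assign[a] == assign[b]:
            e_h[assign[a]] = e_h.get(assign[a], 0) + 1
    d_h: dict[int, int] = {}
    for node, k in net.degrees().items():
        h = assign[node]
        d_h[h] = d_h.get(h, 0) + k
    q = 0.0
    for h in set(assign.values()):
        q += e_h.get(h, 0) / m - (d_h.get(h, 0) / (2 * m)) ** 2
    return q


def annotated_nodes(net: GeneNetwork, dictionary: AnnotationDictionary) -> set[str]:
    """Network nodes carrying at least one annotation term (the N_AnnSo set)."""
    universe = dictionary.universe
    return {n for n in net.nodes if n in universe}


def quality_QGO(
    part: Partition, dictionary: AnnotationDictionary, net: GeneNetwork
) -> float:
    """Annotation agreement: sum over modules of |delta(term_h) ∩ members_h| / N_AnnSo."""
    part.validate(net)
    if len(dictionary) == 0:
        raise ValueError("annotation dictionary is empty")
    n_annso = len(annotated_nodes(net, dictionary))
    if n_annso == 0:
        raise ValueError("no network node carries an annotation term (N_AnnSo = 0)")
    total = 0
    for h, mem in part.members().items():
        term = part.module_terms.get(h)
        if term is None:
            continue
        total += len(dictionary.genes_of(term) & mem)
    return total / n_annso


def selection_gamma(
    members: set[str], dictionary: AnnotationDictionary
) -> str | None:
    """Choose the annotation term modeling a module: maximal overlap with the
    member set, ties broken toward the smaller (more specific) term, then
    lexicographically. Returns ``None`` when no term intersects the module."""
    if not members:
        raise ValueError("members set is empty")
    best: tuple[int, int, str] | None = None
    for term_id, (_, genes) in dictionary.terms.items():
        overlap = len(genes & members)
        if overlap == 0:
            continue
        key = (-overlap, len(genes), term_id)
        if best is None or key < best:
            best = key
    return best[2] if best is not None else UNLABELED


def initialize_partition(
    net: GeneNetwork, dictionary: AnnotationDictionary, seed: int = 0
) -> Partition:
    """Seed-deterministic term-based initial partition.

    Terms greedily claim their yet-unassigned member genes, largest
    residual overlap first (ties: smaller term, then term id) — the same
    preference order the Selection-gamma rule uses. Unannotated genes
    join the module of their highest-weight already-assigned neighbor,
    or become singletons.
    """
    if not net.nodes:
        raise ValueError("network is empty")
    assignment: dict[str, int] = {}
    next_module = 0
    nodes = set(net.nodes)
    unassigned = set(nodes)

    if len(dictionary) > 0:
        candidates = {
            term_id: genes & nodes
            for term_id, (_, genes) in dictionary.terms.items()
            if genes & nodes
        }
        while True:
            best = None
            for term_id, genes in candidates.items():
                overlap = len(genes & unassigned)
                if overlap == 0:
                    continue
                key = (-overlap, len(dictionary.genes_of(term_id)), term_id)
                if best is None or key < best:
                    best = key
            if best is None:
                break
            term_id = best[2]
            claim = candidates[term_id] & unassigned
            for gene in claim:
                assignment[gene] = next_module
            unassigned -= claim
            next_module += 1

    # neighbor adjacency with weights, for attaching unannotated genes
    adj: dict[str, list[tuple[str, float]]] = {n: [] for n in nodes}
    for (a, b), w in net.edges.items():
        adj[a].append((b, abs(w)))
        adj[b].append((a, abs(w)))

    rng = random.Random(seed)
    leftovers = sorted(unassigned)
    rng.shuffle(leftovers)
    for gene in leftovers:
        assigned_nbrs = [(w, nb) for nb, w in adj[gene] if nb in assignment]
        if assigned_nbrs:
            _, nb = max(assigned_nbrs, key=lambda t: (t[0], t[1]))
            assignment[gene] = assignment[nb]
        else:
            assignment[gene] = next_module
            next_module += 1

    part = Partition(assignment)
    part.module_terms = {
        h: selection_gamma(mem, dictionary) if len(dictionary) else UNLABELED
        for h, mem in part.members().items()
    }
    return part


def _mean_density(members: dict[int, set[str]], e_h: dict[int, int]) -> float:
    """Mean within-module edge density; singleton modules count as 0."""
    total = 0.0
    for h, mem in members.items():
        n = len(mem)
        pairs = n * (n - 1) // 2
        total += e_h.get(h, 0) / pairs if pairs else 0.0
    return total / len(members)


def run_mtgo(
    net: GeneNetwork,
    dictionary: AnnotationDictionary,
    params: MtgoParams | None = None,
) -> Partition:
    """Detect annotated functional modules by blended local optimization.

    See the module docstring for the iteration scheme. With an empty
    dictionary the run degenerates to pure modularity optimization (QGO
    is recorded as 0).
    """
    params = params or MtgoParams()
    if net.n_edges == 0:
        raise ValueError("cannot detect modules on an edgeless network")

    # --- static structures -------------------------------------------------
    nodes = sorted(net.nodes)
    adj: dict[str, dict[str, float]] = {n: {} for n in nodes}
    for (a, b), w in net.edges.items():
        adj[a][b] = w
        adj[b][a] = w
    degree = {n: len(adj[n]) for n in nodes}
    m = net.n_edges

    have_anno = len(dictionary) > 0
    if have_anno:
        ann = annotated_nodes(net, dictionary)
        n_annso = len(ann)
        have_anno = n_annso > 0
    if have_anno:
        # per-gene term membership for O(1) "is node in delta(term)" checks
        gene_terms: dict[str, set[str]] = {n: set() for n in nodes}
        for term_id, (_, genes) in dictionary.terms.items():
            for g in genes:
                if g in gene_terms:
                    gene_terms[g].add(term_id)

    w_top = params.topology_weight if have_anno else 1.0
    w_ann = 1.0 - w_top

    # --- mutable state -----------------------------------------------------
    init = initialize_partition(net, dictionary, seed=params.seed)
    comm = dict(init.assignment)
    members: dict[int, set[str]] = {h: set(mem) for h, mem in init.members().items()}
    d_h: dict[int, int] = {h: sum(degree[g] for g in mem) for h, mem in members.items()}
    e_h: dict[int, int] = {h: 0 for h in members}
    for a, b in net.edges:
        if comm[a] == comm[b]:
            e_h[comm[a]] += 1
    next_module = max(members) + 1 if members else 0

    def assign_terms() -> dict[int, str | None]:
        if not have_anno:
            return {h: UNLABELED for h in members}
        return {h: selection_gamma(mem, dictionary) for h, mem in members.items()}

    def score_state() -> tuple[float, float]:
        q = sum(e_h[h] / m - (d_h[h] / (2 * m)) ** 2 for h in members)
        if not have_anno:
            return q, 0.0
        total = 0
        for h, mem in members.items():
            t = terms.get(h)
            if t is not None:
                total += len(dictionary.genes_of(t) & mem)
        return q, total / n_annso

    rng = random.Random(params.seed)
    trajectory: list[tuple[float, float]] = []
    converged = False
    best_density = -1.0
    best_snapshot: dict[str, int] | None = None

    for _iteration in range(params.max_iter):
        terms = assign_terms()
        order = list(nodes)
        rng.shuffle(order)

        for node in order:
            a = comm[node]
            k_i = degree[node]
            # edges from node into each adjacent module (excluding itself)
            k_to: dict[int, int] = {}
            for nb in adj[node]:
                k_to[comm[nb]] = k_to.get(comm[nb], 0) + 1
            k_ia = k_to.get(a, 0)
            in_term_a = (
                1.0
                if have_anno and terms.get(a) is not None and terms[a] in gene_terms[node]
                else 0.0
            )

            best_gain = 0.0
            best_target: int | None = None  # None = stay
            # candidate: adjacent modules
            for b_mod, k_ib in k_to.items():
                if b_mod == a:
                    continue
                dq = (k_ib - k_ia) / m - k_i * (d_h[b_mod] - d_h[a] + k_i) / (
                    2 * m * m
                )
                gain = w_top * dq
                if have_anno and w_ann > 0:
                    in_term_b = (
                        1.0
                        if terms.get(b_mod) is not None
                        and terms[b_mod] in gene_terms[node]
                        else 0.0
                    )
                    gain += w_ann * (in_term_b - in_term_a) / n_annso
                if gain > best_gain + 1e-15:
                    best_gain = gain
                    best_target = b_mod
            # candidate: fresh singleton module (only useful if node not alone)
            if len(members[a]) > 1:
                dq = (0 - k_ia) / m - k_i * (0 - d_h[a] + k_i) / (2 * m * m)
                gain = w_top * dq
                if have_anno and w_ann > 0:
                    alone = 1.0 if gene_terms[node] else 0.0
                    gain += w_ann * (alone - in_term_a) / n_annso
                if gain > best_gain + 1e-15:
                    best_gain = gain
                    best_target = -1  # marker for "new module"

            if best_target is None:
                continue
            if best_target == -1:
                best_target = next_module
                next_module += 1
                members[best_target] = set()
                d_h[best_target] = 0
                e_h[best_target] = 0
                terms[best_target] = (
                    selection_gamma({node}, dictionary) if have_anno else UNLABELED
                )
            # apply the move
            members[a].discard(node)
            d_h[a] -= k_i
            e_h[a] -= k_ia
            members[best_target].add(node)
            d_h[best_target] += k_i
            e_h[best_target] += k_to.get(best_target, 0)
            comm[node] = best_target
            if not members[a]:
                del members[a], d_h[a], e_h[a]
                terms.pop(a, None)

        terms = assign_terms()
        q, qgo = score_state()
        trajectory.append((q, qgo))

        if params.density_mode:
            dens = _mean_density(members, e_h)
            if dens > best_density:
                best_density = dens
                best_snapshot = dict(comm)

        if len(trajectory) >= 2:
            dq_it = abs(trajectory[-1][0] - trajectory[-2][0])
            dqgo_it = abs(trajectory[-1][1] - trajectory[-2][1])
            if dq_it < params.T and dqgo_it < params.T:
                converged = True
                break

    if not converged:
        logger.warning(
            "module detection did not converge in %d iterations", params.max_iter
        )

    final_assign = (
        best_snapshot if (params.density_mode and best_snapshot is not None) else comm
    )
    # compact module indices for a tidy output
    relabel: dict[int, int] = {}
    for node in nodes:
        h = final_assign[node]
        if h not in relabel:
            relabel[h] = len(relabel)
    assignment = {node: relabel[final_assign[node]] for node in nodes}
    part = Partition(assignment, trajectory=trajectory, converged=converged)
    part.module_terms = {
        h: selection_gamma(mem, dictionary) if have_anno else UNLABELED
        for h, mem in part.members().items()
    }
    part.validate(net)
    return part


def write_partition(part: Partition, dictionary: AnnotationDictionary, path) -> None:
    """TSV table gene, module_index, term_id, term_label (sorted by module, gene)."""
    from .io_formats import UNLABELED_SENTINEL

    rows = sorted(part.assignment.items(), key=lambda t: (t[1], t[0]))
    with open(path, "w") as fh:
        fh.write("gene\tmodule_index\tterm_id\tterm_label\n")
        for gene, h in rows:
            term = part.module_terms.get(h)
            if term is None:
                tid = label = UNLABELED_SENTINEL
            else:
                tid = term
                label = dictionary.label_of(term) if term in dictionary else term
            fh.write(f"{gene}\t{h}\t{tid}\t{label}\n")


def write_trajectory(part: Partition, path) -> None:
    """CSV table iteration, Q, QGO."""
    with open(path, "w") as fh:
        fh.write("iteration,Q,QGO\n")
        for i, (q, qgo) in enumerate(part.trajectory, start=1):
            fh.write(f"{i},{q:.12g},{qgo:.12g}\n")
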