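"""Core containers and readers/writers for all external formats.

Formats handled: dense delimited and Matrix Market expression matrices
(with one-id-per-line sidecar files for gene and cell names), GMT
annotation dictionaries, tab-separated edge lists (including ground-truth
networks), and GraphML / JSON / edge-TSV network exports.

Gene identifiers are matched after uppercasing and whitespace stripping so
that joins across files (expression matrix vs. GMT vs. ground-truth
network) never fail on case conventions; pass ``normalize_ids=False`` to
any reader to disable this.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import networkx as nx
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

UNLABELED_SENTINEL = "unlabeled"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def normalize_gene_id(gene: str) -> str:
    return gene.strip().upper()


def _maybe_normalize(ids: Iterable[str], normalize: bool) -> list[str]:
    return [normalize_gene_id(g) if normalize else str(g).strip() for g in ids]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Nonnegative genes x cells expression values with cluster labels.

    ``values[i, j]`` is the expression of gene ``gene_ids[i]`` in cell
    ``cell_ids[j]``; ``cluster_labels[j]`` names the cell cluster (cell
    type/state) that cell ``j`` belongs to.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cluster_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.cluster_labels = [str(c) for c in self.cluster_labels]
        if self.values.ndim != 2:
            raise FormatError("expression values must be a 2-D matrix")
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if len(self.cell_ids) != n_cells:
            raise FormatError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix columns"
            )
        if len(self.cluster_labels) != n_cells:
            raise FormatError(
                f"{len(self.cluster_labels)} cluster labels for {n_cells} cells"
            )
        if self.values.size and self.values.min() < 0:
            i, j = np.unravel_index(int(np.argmin(self.values)), self.values.shape)
            raise FormatError(
                f"negative expression value {self.values[i, j]} at gene "
                f"{self.gene_ids[i]!r}, cell {self.cell_ids[j]!r}"
            )
        seen: dict[str, str] = {}
        dups = []
        for g in self.gene_ids:
            key = normalize_gene_id(g)
            if key in seen:
                dups.append(g)
            seen[key] = g
        if dups:
            raise FormatError(f"duplicate gene ids (after case normalization): {dups}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def clusters(self) -> list[str]:
        """Distinct cluster labels in order of first appearance."""
        out: list[str] = []
        for c in self.cluster_labels:
            if c not in out:
                out.append(c)
        return out

    def subset_cluster(self, cluster: str) -> "ExpressionMatrix":
        mask = [lbl == cluster for lbl in self.cluster_labels]
        if not any(mask):
            raise KeyError(f"no cells with cluster label {cluster!r}")
        idx = np.flatnonzero(mask)
        return ExpressionMatrix(
            self.values[:, idx],
            list(self.gene_ids),
            [self.cell_ids[j] for j in idx],
            [self.cluster_labels[j] for j in idx],
        )

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in genes]
        return ExpressionMatrix(
            self.values[rows, :],
            [self.gene_ids[i] for i in rows],
            list(self.cell_ids),
            list(self.cluster_labels),
        )


@dataclass
class AnnotationDictionary:
    """Map from annotation term id to (human label, gene set).

    The gene sets are the delta_p of the module-detection objective: the
    genes a term annotates. ``universe`` is every gene appearing in any
    term.
    """

    terms: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for term_id, (label, genes) in self.terms.items():
            if not genes:
                raise FormatError(f"term {term_id!r} has an empty gene set")
            self.terms[term_id] = (str(label), frozenset(genes))

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for _, genes in self.terms.values():
            out |= genes
        return frozenset(out)

    def genes_of(self, term_id: str) -> frozenset[str]:
        return self.terms[term_id][1]

    def label_of(self, term_id: str) -> str:
        return self.terms[term_id][0]

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms


def _canon_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class GeneNetwork:
    """Undirected weighted network over named gene nodes.

    Edges are stored under canonically ordered pairs; no self-loops.
    ``metadata`` records the extraction method and its parameters.
    """

    edges: dict[tuple[str, str], float] = field(default_factory=dict)
    nodes: set[str] = field(default_factory=set)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        canon: dict[tuple[str, str], float] = {}
        for (a, b), w in self.edges.items():
            if a == b:
                raise FormatError(f"self-loop edge on node {a!r}")
            key = _canon_pair(a, b)
            if key in canon:
                raise FormatError(f"duplicate edge {key}")
            canon[key] = float(w)
        self.edges = canon
        self.nodes = set(self.nodes)
        for a, b in self.edges:
            if a not in self.nodes or b not in self.nodes:
                raise FormatError(f"edge ({a!r}, {b!r}) has endpoint outside node set")

    @classmethod
    def from_edge_iter(
        cls,
        pairs: Iterable[tuple[str, str, float]],
        extra_nodes: Iterable[str] = (),
        metadata: Mapping | None = None,
    ) -> "GeneNetwork":
        """Build from (a, b, weight) triples with undirected deduplication.

        Duplicate pairs keep the first weight seen (a warning is logged on
        conflict); self-pairs are skipped with a warning.
        """
        edges: dict[tuple[str, str], float] = {}
        nodes: set[str] = set(extra_nodes)
        for a, b, w in pairs:
            if a == b:
                logger.warning("skipping self-loop edge on %r", a)
                continue
            key = _canon_pair(a, b)
            nodes.add(a)
            nodes.add(b)
            if key in edges:
                if edges[key] != w:
                    logger.warning(
                        "duplicate edge %s with conflicting weight "
                        "(%g kept, %g ignored)",
                        key,
                        edges[key],
                        w,
                    )
                continue
            edges[key] = float(w)
        return cls(edges, nodes, dict(metadata or {}))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def edge_set(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.edges)

    def degrees(self) -> dict[str, int]:
        deg = {n: 0 for n in self.nodes}
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def has_edge(self, a: str, b: str) -> bool:
        return _canon_pair(a, b) in self.edges

    def weight(self, a: str, b: str) -> float:
        return self.edges[_canon_pair(a, b)]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_weighted_edges_from((a, b, w) for (a, b), w in self.edges.items())
        return g


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------


def _read_id_file(path: Path, normalize: bool) -> list[str]:
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    return _maybe_normalize(ids, normalize)


def read_cluster_labels(path: str | Path) -> list[str]:
    """Read one cluster label per line (optionally ``cell_id<TAB>label``)."""
    labels: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            labels.append(parts[-1].strip())
    return labels


def read_expression(
    path: str | Path,
    format: str = "dense",
    cluster_labels: Sequence[str] | str | Path | None = None,
    normalize_ids: bool = True,
    transpose: bool = False,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a genes x cells expression matrix.

    Parameters
    ----------
    format
        ``"dense"``: delimited text with gene ids in the first column and
        cell ids in the header row. ``"mtx"``: Matrix Market coordinate
        file with sidecar id files (default ``<path>.rows`` for genes and
        ``<path>.cols`` for cells); set ``transpose=True`` if the matrix
        is stored cells x genes.
    cluster_labels
        A sequence of per-cell labels, or a path to a label file (one
        label per line, same order as the cells). When omitted all cells
        share a single cluster ``"all"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format in ("dense", "dense-delimited"):
        import pandas as pd

        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        values = df.to_numpy(dtype=float)
        gene_ids = _maybe_normalize(df.index.astype(str), normalize_ids)
        cell_ids = [str(c).strip() for c in df.columns]
    elif format in ("mtx", "matrix-market", "matrix-market-triplet"):
        genes_path = Path(genes_path) if genes_path else path.with_name(path.name + ".rows")
        cells_path = Path(cells_path) if cells_path else path.with_name(path.name + ".cols")
        for sidecar in (genes_path, cells_path):
            if not sidecar.exists():
                raise FileNotFoundError(f"missing sidecar id file {sidecar}")
        mat = scipy.io.mmread(str(path))
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        values = np.asarray(mat, dtype=float)
        if transpose:
            values = values.T
        gene_ids = _read_id_file(genes_path, normalize_ids)
        cell_ids = _read_id_file(cells_path, normalize=False)
    else:
        raise FormatError(f"unknown expression format {format!r}; use 'dense' or 'mtx'")

    if cluster_labels is None:
        labels = ["all"] * len(cell_ids)
    elif isinstance(cluster_labels, (str, Path)):
        labels = read_cluster_labels(cluster_labels)
    else:
        labels = [str(c) for c in cluster_labels]
    return ExpressionMatrix(values, gene_ids, cell_ids, labels)


def write_expression(expr: ExpressionMatrix, path: str | Path, format: str = "dense") -> None:
    """Write an expression matrix as delimited text or Matrix Market + sidecars."""
    path = Path(path)
    if format in ("dense", "dense-delimited"):
        import pandas as pd

        pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.cell_ids).to_csv(
            path, sep="\t"
        )
    elif format in ("mtx", "matrix-market", "matrix-market-triplet"):
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(expr.values))
        path.with_name(path.name + ".rows").write_text(
            "".join(g + "\n" for g in expr.gene_ids)
        )
        path.with_name(path.name + ".cols").write_text(
            "".join(c + "\n" for c in expr.cell_ids)
        )
    else:
        raise FormatError(f"unknown expression format {format!r}")


# ---------------------------------------------------------------------------
# GMT dictionaries
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path, normalize_ids: bool = True) -> AnnotationDictionary:
    """Read a GMT file: one term per line, ``id<TAB>description<TAB>genes...``."""
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields "
                    f"(term, description, genes...), got {len(fields)}"
                )
            term_id, label = fields[0].strip(), fields[1].strip()
            if term_id in terms:
                raise FormatError(f"{path}:{lineno}: duplicate term id {term_id!r}")
            genes = frozenset(
                _maybe_normalize((g for g in fields[2:] if g.strip()), normalize_ids)
            )
            if not genes:
                raise FormatError(f"{path}:{lineno}: term {term_id!r} has no genes")
            terms[term_id] = (label, genes)
    return AnnotationDictionary(terms)


def write_dictionary(dictionary: AnnotationDictionary, path: str | Path) -> None:
    """Write an annotation dictionary in GMT format (genes sorted for stability)."""
    with open(path, "w") as fh:
        for term_id in sorted(dictionary.terms):
            label, genes = dictionary.terms[term_id]
            fh.write("\t".join([term_id, label, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# edge lists
# ---------------------------------------------------------------------------


def read_edge_list(path: str | Path, normalize_ids: bool = True) -> GeneNetwork:
    """Read a tab/space-separated edge list ``gene_a gene_b [weight]``.

    Missing weights default to 1.0. Pairs are deduplicated without regard
    to order; self-pairs are skipped with a warning.
    """
    triples: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: need at least two gene ids")
            a, b = parts[0], parts[1]
            if normalize_ids:
                a, b = normalize_gene_id(a), normalize_gene_id(b)
            else:
                a, b = a.strip(), b.strip()
            w = 1.0
            if len(parts) >= 3 and parts[2].strip():
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise FormatError(
                        f"{path}:{lineno}: unparseable weight {parts[2]!r}"
                    ) from exc
            triples.append((a, b, w))
    return GeneNetwork.from_edge_iter(triples, metadata={"source": str(path)})


def write_edge_list(net: GeneNetwork, path: str | Path) -> None:
    """Write a network as ``gene_a<TAB>gene_b<TAB>weight`` (sorted pairs)."""
    with open(path, "w") as fh:
        for (a, b) in sorted(net.edges):
            fh.write(f"{a}\t{b}\t{net.edges[(a, b)]:.12g}\n")


# ---------------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------------

_EXPORT_FORMATS = ("graphml", "json", "edge-tsv")


def _network_to_nx(net, partition=None) -> nx.Graph:
    """Convert a GeneNetwork or ModuleNetwork into an annotated nx graph."""
    g = nx.Graph()
    # ModuleNetwork duck-typing: has self_loops
    if hasattr(net, "self_loops"):
        for node in net.node_table():
            g.add_node(
                node["id"],
                label=node["label"],
                module=node["id"],
                size=node["size"],
                color=node["color"],
            )
        for (a, b), w in net.edges.items():
            g.add_edge(a, b, weight=float(w))
        for h, w in net.self_loops.items():
            g.add_edge(h, h, weight=float(w))
        return g
    g.add_nodes_from(sorted(net.nodes))
    if partition is not None:
        colors = partition.module_colors()
        for gene in net.nodes:
            h = partition.assignment[gene]
            term = partition.module_terms.get(h)
            g.nodes[gene]["module"] = int(h)
            g.nodes[gene]["label"] = term if term is not None else UNLABELED_SENTINEL
            g.nodes[gene]["color"] = int(colors[h])
    for (a, b), w in net.edges.items():
        g.add_edge(a, b, weight=float(w))
    return g


def export_network(
    net,
    path: str | Path,
    format: str = "graphml",
    partition=None,
) -> None:
    """Export a gene or module network as GraphML, JSON, or edge TSV.

    When a :class:`~scmodules.mtgo.Partition` is attached, gene nodes carry
    ``module``, ``label`` and ``color`` attributes so standard graph tools
    can color-code the functional modules. Module-network self-loops are
    preserved in every format.
    """
    if (getattr(net, "n_edges", 0) == 0 and not getattr(net, "self_loops", None)) and not net.nodes:
        raise FormatError("refusing to export an empty network")
    if format not in _EXPORT_FORMATS:
        raise FormatError(
            f"unknown export format {format!r}; supported: {', '.join(_EXPORT_FORMATS)}"
        )
    path = Path(path)
    g = _network_to_nx(net, partition)
    if format == "graphml":
        nx.write_graphml(g, str(path), named_key_ids=True)
    elif format == "json":
        payload = {
            "nodes": [
                {
                    "id": str(n),
                    "module": d.get("module"),
                    "label": d.get("label"),
                }
                for n, d in g.nodes(data=True)
            ],
            "edges": [
                {"source": str(a), "target": str(b), "weight": d.get("weight", 1.0)}
                for a, b, d in g.edges(data=True)
            ],
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    else:  # edge-tsv
        with open(path, "w") as fh:
            for a, b, d in sorted(g.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
                fh.write(f"{a}\t{b}\t{d.get('weight', 1.0):.12g}\n")
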