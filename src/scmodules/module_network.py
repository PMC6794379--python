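"""Collapse a partitioned gene network into the module-module network.

Each functional module becomes one node; a gene-edge with endpoints in
two different modules contributes its absolute weight to the edge
between those modules, and a gene-edge internal to a module contributes
to that module's self-loop. The aggregate therefore conserves total
absolute weight: sum over module-edges and self-loops equals
sum(|w|) over gene-edges. A ``mean`` aggregation mode (average absolute
weight per contributing gene-edge) is available for displays where edge
thickness should not scale with module size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import GeneNetwork, UNLABELED_SENTINEL
from .mtgo import Partition


@dataclass
class ModuleNetwork:
    """Module-level network: nodes are modules, self-loops hold within-module weight."""

    node_labels: dict[int, str]
    node_sizes: dict[int, int]
    edges: dict[tuple[int, int], float] = field(default_factory=dict)
    self_loops: dict[int, float] = field(default_factory=dict)
    aggregation: str = "sum"

    @property
    def nodes(self) -> set[int]:
        return set(self.node_labels)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def total_weight(self) -> float:
        return sum(self.edges.values()) + sum(self.self_loops.values())

    def node_table(self) -> list[dict]:
        colors = {
            h: i
            for i, h in enumerate(
                sorted(self.node_sizes, key=lambda h: (-self.node_sizes[h], h))
            )
        }
        return [
            {
                "id": h,
                "label": self.node_labels[h],
                "size": self.node_sizes[h],
                "color": colors[h],
            }
            for h in sorted(self.node_labels)
        ]


def collapse_modules(
    net: GeneNetwork, part: Partition, aggregation: str = "sum"
) -> ModuleNetwork:
    """Aggregate gene-edges into module-edges and self-loops by absolute weight.

    ``aggregation='sum'`` (default) conserves total absolute weight;
    ``'mean'`` divides each aggregate by its contributing edge count.
    """
    if aggregation not in ("sum", "mean"):
        raise ValueError("aggregation must be 'sum' or 'mean'")
    part.validate(net)
    members = part.members()
    sums: dict[tuple[int, int], float] = {}
    loops: dict[int, float] = {}
    counts_e: dict[tuple[int, int], int] = {}
    counts_l: dict[int, int] = {}
    for (a, b), w in net.edges.items():
        ha, hb = part.assignment[a], part.assignment[b]
        if ha == hb:
            loops[ha] = loops.get(ha, 0.0) + abs(w)
            counts_l[ha] = counts_l.get(ha, 0) + 1
        else:
            key = (ha, hb) if ha <= hb else (hb, ha)
            sums[key] = sums.get(key, 0.0) + abs(w)
            counts_e[key] = counts_e.get(key, 0) + 1
    if aggregation == "mean":
        sums = {k: v / counts_e[k] for k, v in sums.items()}
        loops = {k: v / counts_l[k] for k, v in loops.items()}
    labels = {
        h: part.module_terms.get(h) or UNLABELED_SENTINEL for h in members
    }
    sizes = {h: len(mem) for h, mem in members.items()}
    return ModuleNetwork(
        node_labels=labels,
        node_sizes=sizes,
        edges=sums,
        self_loops=loops,
        aggregation=aggregation,
    )


def module_gene_lists(
    part: Partition, dictionary=None
) -> list[tuple[int, str, str, list[str]]]:
    """Per-module ordered gene lists: (module_index, term_id, term_label, genes).

    Lists are disjoint and their union is the full gene set of the
    partition; unlabeled modules carry the sentinel label.
    """
    out = []
    for h, mem in sorted(part.members().items()):
        term = part.module_terms.get(h)
        if term is None:
            tid = label = UNLABELED_SENTINEL
        else:
            tid = term
            label = (
                dictionary.label_of(term)
                if dictionary is not None and term in dictionary
                else term
            )
        out.append((h, tid, label, sorted(mem)))
    return out


def write_module_gene_lists(lists, path) -> None:
    """TSV: module_index, term_id, term_label, gene (one row per gene)."""
    with open(path, "w") as fh:
        fh.write("module_index\tterm_id\tterm_label\tgene\n")
        for h, tid, label, genes in lists:
            for g in genes:
                fh.write(f"{h}\t{tid}\t{label}\t{g}\n")


def read_module_gene_lists(path) -> list[tuple[int, str, str, list[str]]]:
    """Inverse of :func:`write_module_gene_lists`."""
    acc: dict[int, tuple[str, str, list[str]]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("module_index"):
            raise ValueError("not a module gene-list table")
        for line in fh:
            if not line.strip():
                continue
            h, tid, label, gene = line.rstrip("\n").split("\t")
            acc.setdefault(int(h), (tid, label, []))[2].append(gene)
    return [(h, tid, label, genes) for h, (tid, label, genes) in sorted(acc.items())]
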