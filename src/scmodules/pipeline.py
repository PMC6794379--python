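"""End-to-end per-cluster orchestration.

For every retained cell cluster the pipeline runs
QC -> variable-gene selection -> coexpression -> thinning -> module
detection -> module collapse, writing each stage's artifact plus a run
log recording seeds and parameters. When a ground-truth network is
supplied, an assessment row (affinity score + rewiring-null p-value) is
produced per cluster.

Cell QC mirrors common scRNA-seq practice: a cell is kept when it
expresses at least ``min_genes_per_cell`` genes (default 500), totals at
most ``max_umi_per_cell`` UMIs (default 10,000) and has a mitochondrial
fraction of at most ``max_mito_fraction`` (default 0.1, mitochondrial
genes recognized by id prefix, default "MT-"); the three criteria are
evaluated jointly on the input matrix. Clusters with fewer than
``min_cluster_size`` cells (default 50, strict) are dropped entirely.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .assessment import as_pvalue, write_assessment_report
from .coexpression import compute_coexpression
from .io_formats import (
    AnnotationDictionary,
    ExpressionMatrix,
    GeneNetwork,
    export_network,
    normalize_gene_id,
    read_edge_list,
    read_expression,
    read_gmt,
    write_edge_list,
)
from .module_network import collapse_modules, module_gene_lists, write_module_gene_lists
from .mtgo import MtgoParams, run_mtgo, write_partition, write_trajectory
from .thinning import ThinningConfig, thin_abs_threshold, thin_percentile, thin_scale_free

logger = logging.getLogger(__name__)

MITO_PREFIXES = ("MT-",)


@dataclass
class QCThresholds:
    min_genes_per_cell: int = 500
    max_umi_per_cell: float = 10_000
    max_mito_fraction: float = 0.1
    min_cluster_size: int = 50


@dataclass
class RunConfig:
    """Everything one pipeline run needs, serializable for provenance."""

    expression_path: str = ""
    expression_format: str = "dense"
    cluster_labels_path: str | None = None
    gmt_path: str = ""
    gtn_path: str | None = None
    output_dir: str = "scmodules_out"
    metric: str = "spearman"
    pseudocount: float = 1.0
    n_top_genes: int = 0  # 0 = keep all genes
    qc: QCThresholds = field(default_factory=QCThresholds)
    mito_prefixes: tuple[str, ...] = MITO_PREFIXES
    thinning: ThinningConfig = field(default_factory=ThinningConfig)
    mtgo: MtgoParams = field(default_factory=MtgoParams)
    n_perm: int = 100
    seed: int = 0

    def config_hash(self) -> str:
        """Hash of the analysis-relevant parameters (output location excluded)."""
        payload = asdict(self)
        payload.pop("output_dir", None)
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def qc_filter_cells(
    expr: ExpressionMatrix,
    qc: QCThresholds | None = None,
    mito_prefixes: tuple[str, ...] = MITO_PREFIXES,
) -> ExpressionMatrix:
    """Retain cells passing all three QC criteria, evaluated jointly.

    Kept: expressed-gene count >= ``min_genes_per_cell``, UMI total <=
    ``max_umi_per_cell`` (inclusive), mitochondrial fraction <=
    ``max_mito_fraction``. Raises with per-criterion removal counts when
    nothing survives.
    """
    qc = qc or QCThresholds()
    prefixes = tuple(normalize_gene_id(p) for p in mito_prefixes)
    mito_mask = np.array(
        [normalize_gene_id(g).startswith(prefixes) for g in expr.gene_ids]
    )
    expressed = (expr.values > 0).sum(axis=0)
    umi = expr.values.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(umi > 0, expr.values[mito_mask, :].sum(axis=0) / umi, 0.0)
    ok_genes = expressed >= qc.min_genes_per_cell
    ok_umi = umi <= qc.max_umi_per_cell
    ok_mito = mito_frac <= qc.max_mito_fraction
    keep = ok_genes & ok_umi & ok_mito
    if not keep.any():
        raise ValueError(
            "no cell passed QC: "
            f"{int((~ok_genes).sum())} below the expressed-gene minimum, "
            f"{int((~ok_umi).sum())} above the UMI maximum, "
            f"{int((~ok_mito).sum())} above the mitochondrial fraction"
        )
    removed = int((~keep).sum())
    if removed:
        logger.info(
            "QC removed %d/%d cells (genes<min: %d, umi>max: %d, mito>max: %d)",
            removed, expr.n_cells, int((~ok_genes).sum()),
            int((~ok_umi).sum()), int((~ok_mito).sum()),
        )
    idx = np.flatnonzero(keep)
    return ExpressionMatrix(
        expr.values[:, idx],
        list(expr.gene_ids),
        [expr.cell_ids[j] for j in idx],
        [expr.cluster_labels[j] for j in idx],
    )


def filter_small_clusters(expr: ExpressionMatrix, min_cells: int = 50) -> ExpressionMatrix:
    """Drop whole clusters with fewer than ``min_cells`` cells (strict <)."""
    counts: dict[str, int] = {}
    for lbl in expr.cluster_labels:
        counts[lbl] = counts.get(lbl, 0) + 1
    keep_labels = {lbl for lbl, n in counts.items() if n >= min_cells}
    dropped = sorted(set(counts) - keep_labels)
    if dropped:
        logger.warning("dropping small clusters: %s", dropped)
    mask = [lbl in keep_labels for lbl in expr.cluster_labels]
    if not any(mask):
        logger.warning("all clusters below the minimum size; result is empty")
        return ExpressionMatrix(
            expr.values[:, :0], list(expr.gene_ids), [], []
        )
    idx = np.flatnonzero(mask)
    return ExpressionMatrix(
        expr.values[:, idx],
        list(expr.gene_ids),
        [expr.cell_ids[j] for j in idx],
        [expr.cluster_labels[j] for j in idx],
    )


def select_variable_genes(
    expr: ExpressionMatrix, n_top: int, n_bins: int = 20
) -> list[str]:
    """Top ``n_top`` genes by binned variance-to-mean dispersion.

    Genes are binned (``n_bins`` quantile bins) by mean expression; the
    dispersion var/mean is z-scored within each bin so highly expressed
    genes do not dominate. Bin count is reduced when genes are few: a
    z-score inside a 2-gene bin is +-1 whatever the dispersions, so each
    bin keeps at least ~10 genes. Deterministic: ties resolved by gene id.
    """
    if n_top > expr.n_genes:
        raise ValueError("n_top exceeds the gene count")
    means = expr.values.mean(axis=1)
    variances = expr.values.var(axis=1, ddof=1) if expr.n_cells > 1 else np.zeros_like(means)
    with np.errstate(invalid="ignore", divide="ignore"):
        dispersion = np.where(means > 0, variances / means, 0.0)
    order = np.argsort(means, kind="stable")
    n_bins_eff = max(1, min(n_bins, expr.n_genes // 10))
    bins = np.array_split(order, n_bins_eff)
    z = np.zeros(expr.n_genes)
    for bin_idx in bins:
        if len(bin_idx) == 0:
            continue
        d = dispersion[bin_idx]
        sd = d.std(ddof=0)
        z[bin_idx] = (d - d.mean()) / sd if sd > 0 else 0.0
    ranked = sorted(
        range(expr.n_genes), key=lambda i: (-z[i], expr.gene_ids[i])
    )
    return [expr.gene_ids[i] for i in ranked[:n_top]]


def _thin(coexpr, cfg: ThinningConfig):
    if cfg.strategy == "abs_threshold":
        return thin_abs_threshold(coexpr, cfg.threshold), None
    if cfg.strategy == "percentile":
        return thin_percentile(coexpr, cfg.percentile), None
    net, fit = thin_scale_free(coexpr, cfg)
    return net, fit


def run_pipeline(
    cfg: RunConfig,
    expr: ExpressionMatrix | None = None,
    dictionary: AnnotationDictionary | None = None,
    gtn: GeneNetwork | None = None,
) -> dict[str, dict]:
    """Run the per-cluster pipeline; returns a per-cluster result summary.

    Inputs may be passed in-memory (``expr``/``dictionary``/``gtn``) or
    read from the paths in ``cfg``. Per-cluster failures are logged and
    skipped; the call raises only if every cluster fails.
    """
    if expr is None:
        expr = read_expression(
            cfg.expression_path,
            format=cfg.expression_format,
            cluster_labels=cfg.cluster_labels_path,
        )
    if dictionary is None:
        dictionary = read_gmt(cfg.gmt_path) if cfg.gmt_path else AnnotationDictionary({})
    if gtn is None and cfg.gtn_path:
        gtn = read_edge_list(cfg.gtn_path)

    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    run_tag = f"{cfg.config_hash()}_seed{cfg.seed}"
    log_lines = [f"config_hash={cfg.config_hash()}", f"seed={cfg.seed}"]

    expr = qc_filter_cells(expr, cfg.qc, cfg.mito_prefixes)
    expr = filter_small_clusters(expr, cfg.qc.min_cluster_size)
    if expr.n_cells == 0:
        raise ValueError("no cluster survived the minimum-size filter")

    results: dict[str, dict] = {}
    assessments = []
    failures = []
    for cluster in expr.clusters():
        try:
            sub = expr.subset_cluster(cluster)
            if cfg.n_top_genes:
                sub = sub.subset_genes(select_variable_genes(sub, cfg.n_top_genes))
            coexpr = compute_coexpression(sub, cfg.metric, cfg.pseudocount)
            prefix = out_dir / f"{cluster}_{run_tag}"
            coexpr.write(f"{prefix}_coexpression.tsv")
            net, fit = _thin(coexpr, cfg.thinning)
            if net.n_edges == 0:
                raise ValueError("thinning produced an empty network")
            write_edge_list(net, f"{prefix}_network.tsv")
            part = run_mtgo(net, dictionary, cfg.mtgo)
            write_partition(part, dictionary, f"{prefix}_modules.tsv")
            write_trajectory(part, f"{prefix}_trajectory.csv")
            modnet = collapse_modules(net, part)
            export_network(modnet, f"{prefix}_module_network.graphml", "graphml")
            export_network(net, f"{prefix}_gene_network.json", "json", partition=part)
            write_module_gene_lists(
                module_gene_lists(part, dictionary), f"{prefix}_module_genes.tsv"
            )
            summary = {
                "n_cells": sub.n_cells,
                "n_genes": sub.n_genes,
                "n_network_nodes": net.n_nodes,
                "n_network_edges": net.n_edges,
                "n_modules": part.H,
                "converged": part.converged,
                "Q": part.trajectory[-1][0],
                "QGO": part.trajectory[-1][1],
            }
            if fit is not None:
                summary["gamma_hat"] = fit.gamma_hat
                summary["power_law_gof"] = fit.gof
            if gtn is not None:
                res = as_pvalue(
                    net, gtn, n_perm=cfg.n_perm, seed=cfg.seed,
                    method_id=f"{cfg.metric}+{cfg.thinning.strategy}",
                    cell_type=cluster,
                )
                assessments.append(res)
                summary["affinity"] = res.affinity
                summary["p_value"] = res.p_value
            results[cluster] = summary
            log_lines.append(f"cluster={cluster} ok {json.dumps(summary, sort_keys=True)}")
        except Exception as exc:  # noqa: BLE001 - per-cluster isolation
            logger.exception("cluster %r failed", cluster)
            failures.append(cluster)
            log_lines.append(f"cluster={cluster} FAILED {exc}")

    if assessments:
        write_assessment_report(assessments, out_dir / f"assessment_{run_tag}.tsv")
    (out_dir / f"run_{run_tag}.log").write_text("".join(l + "\n" for l in log_lines))
    if not results:
        raise RuntimeError(f"all clusters failed: {failures}")
    return results
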