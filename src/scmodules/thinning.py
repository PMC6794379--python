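"""Network thinning: extract a sparse subnetwork from the dense coexpression matrix.

The coexpression matrix is a fully connected weighted network; almost all
of its edges carry noise-level weights. Three strategies prune it:

* ``thin_abs_threshold`` keeps edges with \\|c_ik\\| >= t;
* ``thin_percentile`` keeps the top-q% of pairs by \\|c_ik\\| (boundary
  ties all retained);
* ``thin_scale_free`` grid-searches a cutoff so that the degree
  distribution of the surviving network best fits a power law
  P(k) ~ k^-gamma with gamma near a target (default 2.5, the middle of
  the gamma in [2, 3] band typical of biological networks).

The power-law fit is the discrete maximum-likelihood estimator at
x_min = 1 — i.e. the zeta (Zipf) distribution fitted to the degree
multiset — with a Kolmogorov–Smirnov distance between the empirical and
fitted degree CDFs as goodness of fit. A cutoff's score is
``gof + |gamma_hat - gamma_target|``; the minimizer wins, and all
per-cutoff fits are kept in the result's metadata so users can re-rank
under their own criterion.

Undefined (NaN) coexpression entries — zero-variance genes — are treated
as absent pairs by every strategy. Isolated genes are dropped from the
extracted network's node set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import zeta as _zeta
from scipy.stats import zipf

from .coexpression import CoexpressionMatrix
from .io_formats import GeneNetwork

logger = logging.getLogger(__name__)

DEFAULT_PERCENTILES = (10.0, 20.0, 30.0, 40.0, 50.0)


@dataclass
class ThinningConfig:
    """Which thinning strategy to run and its parameters."""

    strategy: str = "percentile"  # abs_threshold | percentile | scale_free
    threshold: float = 0.5
    percentile: float = 10.0
    gamma_target: float = 2.5
    cutoff_grid: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)

    def __post_init__(self) -> None:
        if self.strategy not in ("abs_threshold", "percentile", "scale_free"):
            raise ValueError(f"unknown thinning strategy {self.strategy!r}")
        if self.strategy == "percentile" and not (0 < self.percentile <= 100):
            raise ValueError("percentile must be in (0, 100]")
        if self.strategy == "scale_free" and not self.cutoff_grid:
            raise ValueError("scale_free thinning needs a nonempty cutoff grid")


@dataclass
class PowerLawFit:
    """Result of the discrete power-law MLE on a degree multiset."""

    gamma_hat: float = math.nan
    gof: float = math.nan
    n_nodes: int = 0
    n_edges: int = 0
    cutoff: float = math.nan
    defined: bool = False

    @property
    def score(self) -> float:
        return math.inf if not self.defined else self.gof

    def selection_score(self, gamma_target: float) -> float:
        if not self.defined:
            return math.inf
        return self.gof + abs(self.gamma_hat - gamma_target)


def _edge_candidates(C: CoexpressionMatrix) -> list[tuple[float, int, int]]:
    """All defined off-diagonal pairs as (|weight|, i, k) with i < k."""
    w = C.weights
    n = C.n_genes
    iu, ku = np.triu_indices(n, k=1)
    vals = w[iu, ku]
    ok = np.isfinite(vals)
    return list(zip(np.abs(vals[ok]), iu[ok], ku[ok]))


def _network_from_pairs(
    C: CoexpressionMatrix, pairs: list[tuple[int, int]], metadata: dict
) -> GeneNetwork:
    edges = {}
    nodes: set[str] = set()
    gid = C.gene_ids
    for i, k in pairs:
        a, b = gid[i], gid[k]
        key = (a, b) if a <= b else (b, a)
        edges[key] = float(C.weights[i, k])
        nodes.add(a)
        nodes.add(b)
    meta = {"metric": C.metric, **metadata}
    return GeneNetwork(edges, nodes, meta)


def thin_abs_threshold(C: CoexpressionMatrix, t: float) -> GeneNetwork:
    """Retain edges with \\|c_ik\\| >= t (weights keep their sign)."""
    if t < 0:
        raise ValueError("threshold must be nonnegative")
    pairs = [(i, k) for av, i, k in _edge_candidates(C) if av >= t]
    return _network_from_pairs(
        C, pairs, {"thinning": "abs_threshold", "threshold": t}
    )


def thin_percentile(C: CoexpressionMatrix, q: float) -> GeneNetwork:
    """Retain the top-q% of defined pairs by \\|c_ik\\|; boundary ties all kept."""
    if not (0 < q <= 100):
        raise ValueError("percentile must be in (0, 100]")
    cands = _edge_candidates(C)
    if not cands:
        return _network_from_pairs(C, [], {"thinning": "percentile", "percentile": q})
    k = math.ceil(q / 100.0 * len(cands))
    abs_sorted = np.sort(np.array([av for av, _, _ in cands]))[::-1]
    boundary = abs_sorted[k - 1]
    pairs = [(i, kk) for av, i, kk in cands if av >= boundary]
    return _network_from_pairs(
        C, pairs, {"thinning": "percentile", "percentile": q}
    )


def fit_power_law(degrees, cutoff: float = math.nan) -> PowerLawFit:
    """Fit P(k) ~ k^-gamma to a positive-integer degree multiset.

    Discrete MLE with x_min = 1: gamma_hat maximizes the zeta-distribution
    likelihood; ``gof`` is the KS distance between the empirical degree
    CDF and the fitted CDF (lower is better). Needs >= 3 distinct degree
    values, otherwise the fit is flagged undefined.
    """
    d = np.asarray(list(degrees), dtype=float)
    n_nodes = len(d)
    n_edges = int(round(d.sum() / 2)) if n_nodes else 0
    if n_nodes == 0 or len(np.unique(d[d > 0])) < 3:
        return PowerLawFit(n_nodes=n_nodes, n_edges=n_edges, cutoff=cutoff)
    d = d[d > 0].astype(int)
    log_sum = float(np.log(d).sum())
    n = len(d)

    def neg_loglik(g: float) -> float:
        # -log L = n * log(zeta(g)) + g * sum(log d)
        return n * math.log(_zeta(g, 1)) + g * log_sum

    res = minimize_scalar(neg_loglik, bounds=(1.05, 8.0), method="bounded")
    gamma_hat = float(res.x)

    values, counts = np.unique(d, return_counts=True)
    ecdf = np.cumsum(counts) / n
    fitted_cdf = zipf(gamma_hat).cdf(values)
    # both CDFs are right-continuous step functions jumping at the same
    # atoms, so the KS distance is attained at an observed degree
    gof = float(np.abs(ecdf - fitted_cdf).max())
    return PowerLawFit(
        gamma_hat=gamma_hat,
        gof=gof,
        n_nodes=n_nodes,
        n_edges=n_edges,
        cutoff=cutoff,
        defined=True,
    )


def thin_scale_free(
    C: CoexpressionMatrix, cfg: ThinningConfig
) -> tuple[GeneNetwork, PowerLawFit]:
    """Grid-search the cutoff whose surviving network best fits a power law.

    Every cutoff in ``cfg.cutoff_grid`` is applied as an absolute
    threshold; the power law is fitted to the resulting degree
    distribution; the cutoff minimizing
    ``gof + |gamma_hat - gamma_target|`` wins. Cutoffs yielding empty or
    degenerate networks are skipped (their fit is undefined). The winning
    network's metadata carries the full per-cutoff scan.
    """
    if not cfg.cutoff_grid:
        raise ValueError("cutoff grid is empty")
    scan: list[PowerLawFit] = []
    networks: list[GeneNetwork | None] = []
    for cutoff in cfg.cutoff_grid:
        net = thin_abs_threshold(C, float(cutoff))
        fit = fit_power_law(net.degrees().values(), cutoff=float(cutoff))
        scan.append(fit)
        networks.append(net)
        logger.info(
            "scale-free scan: cutoff=%.4g nodes=%d edges=%d gamma_hat=%.4g gof=%.4g",
            cutoff, fit.n_nodes, fit.n_edges, fit.gamma_hat, fit.gof,
        )
    scores = [f.selection_score(cfg.gamma_target) for f in scan]
    best_idx = int(np.argmin(scores))
    if not math.isfinite(scores[best_idx]):
        raise ValueError(
            "no cutoff in the grid produced a network with a defined "
            "power-law fit; try a denser or lower grid"
        )
    best_net = networks[best_idx]
    best_fit = scan[best_idx]
    best_net.metadata.update(
        thinning="scale_free",
        cutoff=best_fit.cutoff,
        gamma_target=cfg.gamma_target,
        scale_free_scan=[asdict(f) for f in scan],
    )
    return best_net, best_fit
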