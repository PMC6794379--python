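"""Gene-gene coexpression matrices for the cells of one cluster.

Given the expression submatrix of a cell cluster, a commutative similarity
metric f is applied to every pair of gene rows, giving the symmetric
matrix C with c_ik = c_ki = f(E_i, E_k). Available metrics:

``pearson``, ``spearman``, ``kendall``
    the classical correlation coefficients (Kendall is the tie-corrected
    tau-b); values in [-1, 1].
``rho``
    the proportionality coefficient rho(x, y) = 1 - var(log x - log y) /
    (var(log x) + var(log y)), a scale-invariant association measure for
    compositional data; values in [-1, 1], 1 iff y = c*x.
``phi``
    the proportionality metric phi(x, y) = var(log x - log y) /
    var(log x); 0 iff y = c*x, growing without bound as proportionality
    degrades. phi is asymmetric in its arguments, so the matrix builder
    stores the symmetrized variant var(log x - log y) /
    max(var(log x), var(log y)) = min(phi(x,y), phi(y,x)), which keeps
    the phi(x, c*x) = 0 identity. Note that for phi small values mean
    strong association; prefer ``rho`` when feeding threshold-based
    network thinning directly.

rho and phi operate on logs, so a pseudocount (default 1) is added when
zeros are present; dropout zeros are thereby retained as ties at the
floor rather than discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, FormatError

METRICS = ("pearson", "spearman", "kendall", "rho", "phi")


@dataclass
class CoexpressionMatrix:
    """Symmetric gene x gene similarity matrix with its metric tag.

    Entries involving zero-variance genes are NaN ("undefined") and are
    excluded by every thinning strategy. The diagonal is ignored
    downstream.
    """

    weights: np.ndarray
    gene_ids: list[str]
    metric: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.gene_ids)
        if self.weights.shape != (n, n):
            raise ValueError(
                f"weights shape {self.weights.shape} does not match "
                f"{n} gene ids"
            )
        finite = np.isfinite(self.weights)
        if not np.array_equal(
            np.where(finite, self.weights, 0.0),
            np.where(finite.T, self.weights.T, 0.0),
        ) or not np.array_equal(finite, finite.T):
            raise ValueError("coexpression matrix must be symmetric")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.gene_ids, columns=self.gene_ids)

    def write(self, path) -> None:
        """Persist as dense delimited text with gene ids as header row/column."""
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read(cls, path, metric: str = "unknown") -> "CoexpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(dtype=float), [str(g) for g in df.index], metric)


def _log_variances(values: np.ndarray, pseudocount: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene log-variance vector and gene x gene log-covariance matrix."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    if (values <= 0).any() and pseudocount == 0:
        raise FormatError(
            "rho/phi require strictly positive values: zeros present and "
            "pseudocount is 0"
        )
    logs = np.log(values + pseudocount)
    cov = np.cov(logs, ddof=1)
    cov = np.atleast_2d(cov)
    return np.diag(cov).copy(), cov


def phi(x: np.ndarray, y: np.ndarray, pseudocount: float = 0.0) -> float:
    """Proportionality metric var(log x - log y) / var(log x).

    Returns 0 iff y is a positive multiple of x; NaN when var(log x) = 0.
    Asymmetric: phi(x, y) != phi(y, x) in general.
    """
    x = np.asarray(x, dtype=float) + pseudocount
    y = np.asarray(y, dtype=float) + pseudocount
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("phi needs two equal-length vectors of length >= 3")
    if (x <= 0).any() or (y <= 0).any():
        raise FormatError("phi requires strictly positive values (add a pseudocount)")
    lx, ly = np.log(x), np.log(y)
    vx = float(np.var(lx, ddof=1))
    if vx == 0.0:
        return float("nan")
    return float(np.var(lx - ly, ddof=1) / vx)


def rho(x: np.ndarray, y: np.ndarray, pseudocount: float = 0.0) -> float:
    """Proportionality coefficient 1 - var(log x - log y)/(var(log x) + var(log y)).

    In [-1, 1]; equals 1 iff log y = log x + const. NaN when both
    log-variances vanish.
    """
    x = np.asarray(x, dtype=float) + pseudocount
    y = np.asarray(y, dtype=float) + pseudocount
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("rho needs two equal-length vectors of length >= 3")
    if (x <= 0).any() or (y <= 0).any():
        raise FormatError("rho requires strictly positive values (add a pseudocount)")
    lx, ly = np.log(x), np.log(y)
    denom = float(np.var(lx, ddof=1) + np.var(ly, ddof=1))
    if denom == 0.0:
        return float("nan")
    return float(1.0 - np.var(lx - ly, ddof=1) / denom)


def compute_coexpression(
    expr: ExpressionMatrix,
    metric: str = "spearman",
    pseudocount: float = 1.0,
    cluster: str | None = None,
) -> CoexpressionMatrix:
    """Compute the symmetric coexpression matrix C for one cell cluster.

    Parameters
    ----------
    expr
        Expression matrix; when ``cluster`` is given, only the cells of
        that cluster are used.
    metric
        One of ``pearson``, ``spearman``, ``kendall``, ``rho``, ``phi``.
    pseudocount
        Added before the log transform for ``rho``/``phi``; must be > 0
        when zeros are present.

    Genes with zero variance across the cluster's cells yield NaN
    (undefined) entries, which every downstream thinning step skips.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if cluster is not None:
        expr = expr.subset_cluster(cluster)
    if expr.n_cells < 3:
        raise ValueError(
            f"correlation over {expr.n_cells} cells is meaningless (need >= 3)"
        )
    if expr.n_genes < 2:
        raise ValueError("need at least 2 genes")

    if metric in ("pearson", "spearman", "kendall"):
        df = pd.DataFrame(expr.values.T, columns=expr.gene_ids)
        weights = df.corr(method=metric, min_periods=3).to_numpy(dtype=float)
        # pandas leaves the diagonal at 1 even for constant genes; flag them
        const = df.nunique().to_numpy() <= 1
        weights[const, :] = np.nan
        weights[:, const] = np.nan
        np.fill_diagonal(weights, np.where(const, np.nan, 1.0))
    else:
        var, cov = _log_variances(expr.values, pseudocount)
        vi = var[:, None]
        vk = var[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            var_lr = vi + vk - 2.0 * cov
            if metric == "rho":
                denom = vi + vk
                weights = np.where(denom > 0, 1.0 - var_lr / denom, np.nan)
            else:  # symmetrized phi
                denom = np.maximum(vi, vk)
                weights = np.where(denom > 0, var_lr / denom, np.nan)
        zero_var = var == 0
        weights[zero_var, :] = np.nan
        weights[:, zero_var] = np.nan
        np.fill_diagonal(weights, np.where(zero_var, np.nan, 1.0 if metric == "rho" else 0.0))
        # numerical floor: var_lr can dip just below 0 for proportional pairs
        if metric == "phi":
            weights = np.where(np.isfinite(weights), np.maximum(weights, 0.0), weights)
        else:
            weights = np.where(np.isfinite(weights), np.clip(weights, -1.0, 1.0), weights)

    weights = (weights + weights.T) / 2.0  # enforce exact symmetry
    return CoexpressionMatrix(
        weights,
        list(expr.gene_ids),
        metric,
        params={"pseudocount": pseudocount, "cluster": cluster, "n_cells": expr.n_cells},
    )
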