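# Methods

This note documents the models and procedures implemented in
`scmodules`, the design choices made where the design was genuinely
open, and what the synthetic benchmarks do and do not demonstrate.

## Coexpression metrics

For one cell cluster the package computes `c_ik = f(E_i, E_k)` over all
gene pairs. Pearson/Spearman/Kendall are the classical estimators
(Kendall is the tie-corrected τ-b, appropriate because integer counts
are heavily tied). ρ and φ are proportionality measures designed for
compositional data:

    φ(x, y) = var(log x − log y) / var(log x)
    ρ(x, y) = 1 − var(log x − log y) / (var(log x) + var(log y))

Both are invariant to rescaling either vector, which matters when
library-size normalization leaves only relative abundances. Sample
variances use ddof = 1. Zeros (dropouts) are handled by a pseudocount
added before the log (default 1 count); the pseudocount must be
positive whenever zeros are present, otherwise the computation refuses
to proceed rather than silently dropping cells.

φ is asymmetric in its arguments. The pairwise function `phi` keeps the
textbook asymmetric definition; the matrix builder must deliver a
symmetric matrix, so it stores

    φ_s(x, y) = var(log x − log y) / max(var(log x), var(log y))
              = min(φ(x, y), φ(y, x)),

which preserves the defining identity φ(x, c·x) = 0 and the ordering of
"proportionality strength". Note that φ is a *dissimilarity* (0 = perfectly
proportional); threshold-based thinning keeps large `|c|`, so for
φ-based extraction users should either invert the grid logic manually
or prefer ρ, which orients like a correlation. This asymmetry of
conventions is inherent to the metric menu and is deliberately not
papered over.

Genes with zero variance across the cluster (zero log-variance for
ρ/φ) produce undefined (NaN) entries; every thinning strategy treats
those pairs as absent. A cluster must have at least 3 cells — below
that, any correlation estimate is meaningless.

## Thinning

* **Absolute threshold**: keep `|c_ik| ≥ t`. Retention is non-strict so
  that `t = 0` keeps every defined pair and the percentile/threshold
  equivalences are exact; strict vs non-strict is unobservable on
  continuous data.
* **Percentile**: keep the top q% of defined pairs ranked by `|c_ik|`
  (k = ⌈q/100 · n_pairs⌉); all pairs tied with the boundary value are
  kept, so the result can slightly exceed k edges.
* **Scale-free grid search**: for each cutoff in an ascending grid the
  thresholded network's degree multiset is fitted with the discrete
  power law at x_min = 1 — i.e. the zeta (Zipf) distribution, whose
  exponent is estimated by numerically maximizing the exact likelihood
  (bounded search on γ ∈ [1.05, 8]). Goodness of fit is the
  Kolmogorov–Smirnov distance between the empirical and fitted degree
  CDFs, evaluated at the observed degrees (both CDFs are step functions
  jumping at the same atoms). The selected cutoff minimizes
  `KS + |γ̂ − γ_target|`; both ingredients — fit quality and closeness
  to a target exponent — enter with equal weight, and the full
  per-cutoff scan is stored in the network's metadata so users can
  re-rank under a different criterion. A fit needs at least 3 distinct
  positive degrees; degenerate cutoffs are skipped, and the call fails
  only if the whole grid is degenerate.

Isolated genes are dropped from the extracted node set: downstream
modularity is undefined for degree-0 nodes and an unconnected gene
carries no module information.

Fixing x_min = 1 rather than estimating it keeps the estimator stable
on the small networks typical of per-cluster analysis; exposing x_min
estimation is deferred.

## Assessment against a ground-truth network

`AS(N, GTN) = h²/(N_EN · N_EGTN)` with `h` the number of edges (as
unordered gene pairs, weights ignored) common to both networks. AS is
symmetric and lies in [0, 1], reaching 1 only when the edge sets
coincide. Its null distribution is generated by degree-preserving
rewiring of N: repeated double-edge swaps, `10 × N_EN` attempted swaps
per replicate, rejecting swaps that would create self-loops or
duplicate edges. The permutation p-value uses the add-one estimator
`p = (1 + #{AS_null ≥ AS_obs}) / (1 + n_perm)` (default n_perm = 100),
which is never 0 and counts ties conservatively toward the numerator.
Calibration under a true null (N itself a rewiring of the GTN) is
verified in the acceptance suite: the rejection rate at α = 0.05 over
200 replicates stays within binomial tolerance of 0.05.

Method rankings arrange −log(p) as a cell-type × method matrix; each
row is min-max rescaled to [0, 1] (a constant or single-entry row maps
to 1 by convention) and all methods tied at the row maximum are flagged
best. Min-max is chosen so that each cell type spans the full color
range of whatever heatmap tool consumes the table.

Clustering coherence between two independently extracted networks
counts genes present in both whose assigned annotation term is
identical, over the average of the two gene counts. The term label is
the only module identity comparable across independent runs; a
pairwise co-membership variant would also be defensible but measures a
different thing (agreement of shapes rather than of labels).

The hypergeometric literature statistic is the exact upper tail
P(X ≥ hits_both) with population = papers on the tissue, successes =
papers hitting the pathway, draws = papers hitting the cell type. Hit
counts are inputs; no literature querying is performed.

## Module detection

The objective couples network topology and annotation:

    Q   = Σ_h [ e_h/|E| − (d_h/2|E|)² ]          (Newman modularity)
    QGO = Σ_h |δ(term_h) ∩ members_h| / N_AnnSo   (annotation agreement)

`term_h` is chosen by the selection rule: the term with maximal overlap
with the module, ties resolved toward the smaller (more specific) term,
then lexicographically; a module intersecting no term is "unlabeled"
and contributes 0 to QGO. `N_AnnSo` is the number of network nodes with
at least one term, so QGO ∈ [0, 1].

The iteration is a blended local-move scheme:

1. **Initialization** — every term present in the network seeds a
   candidate module from its member genes, terms claiming genes in
   order of residual overlap (ties as in the selection rule);
   unannotated genes join their highest-|weight| assigned neighbor or
   become singletons.
2. **Sweep** — nodes are visited in a seed-shuffled order; each node
   may move to an adjacent module or to a fresh singleton, taking the
   move with the largest blended gain
   `ΔS = w·ΔQ + (1 − w)·ΔQGO` (topology weight w, default 0.5). ΔQ uses
   the standard incremental formula; ΔQGO is the change in term
   membership of the node under the terms fixed at the sweep's start.
   Ties (gain ≤ 0 within 1e-15) keep the node where it is.
3. **Bookkeeping** — emptied modules dissolve; terms are reassigned;
   (Q, QGO) are recomputed *from integer state* and appended to the
   trajectory.

Convergence: |ΔQ| < T and |ΔQGO| < T between consecutive iterations,
T = 1e-4, with a max_iter guard (default 200; non-convergence is
flagged, not raised). Because per-iteration scores are recomputed from
the exact integer edge/degree counts rather than accumulated
incrementally, the final trajectory entry matches a from-scratch
recomputation to 1e-10 by construction — this audit is asserted in the
tests.

With an empty dictionary the scheme degenerates to pure modularity
optimization and QGO is recorded as 0. With `density_mode` the returned
partition is the iterate with the highest mean within-module edge
density (singleton modules count as density 0) — this weights adherence
to topology over the annotation source, at the cost that the returned
partition need not be the final iterate, so its (Q, QGO) can differ
from the last trajectory entry.

The concrete move schedule (term seeding, blended local moves,
per-iteration term reassignment) is this package's realization of the
general principle — topology and annotation co-driving an iterative
partition refinement with Q/QGO convergence — and is not claimed to
match any external implementation move-for-move.

## Module collapse

Cross-module edge weight is the sum of |w| over gene-edges spanning the
two modules; self-loop weight sums |w| over internal edges. Absolute
values are used because a strong negative correlation is still a strong
interaction for display purposes, and summation makes the conservation
identity exact: total collapsed weight = Σ|w| over gene-edges. A mean
mode divides by the contributing edge count. Module colors are assigned
by descending member count for stable output.

## Cell QC and gene selection

QC keeps cells with ≥ 500 expressed genes, ≤ 10,000 total UMIs
(inclusive bound) and ≤ 0.1 mitochondrial fraction (genes recognized by
configurable id prefix, default "MT-" after case normalization). The
three criteria are evaluated jointly on the input matrix, not
sequentially, so removal counts per criterion are reported against the
same baseline. Clusters below 50 cells are dropped (strict: a 50-cell
cluster stays). These defaults suit UMI-based mouse atlas data and
carry no claim of generality — they are plain parameters.

Variable-gene selection ranks genes by variance/mean dispersion
z-scored within mean-expression bins (20 bins, reduced so each bin
keeps ~10 genes; a z-score inside a 2-gene bin is ±1 regardless of the
dispersions and would destroy the ranking).

## Synthetic generators

* `gen_planted_network` — stochastic block model (defaults used in the
  benchmarks: 4 blocks × 30 genes, p_in = 0.4, p_out = 0.02), the
  regime of clearly assortative but noisy modules.
* `gen_planted_expression` — per block one latent factor per cell;
  gene = mean + √(base_corr)·factor + noise on the log scale, then
  exp() and integer rounding, then quantile dropout (default rate 0.3).
  At noise_sd = 1 the within-block log-scale correlation equals
  base_corr (default 0.8) exactly; smaller noise pushes it toward 1.
  The generator emulates block-correlated, sparse, overdispersed counts;
  it does **not** model library-size variation, batch effects, doublets
  or mean-variance trends, so passing benchmarks demonstrates correct
  mechanics and recoverability under planted structure, not performance
  on any real tissue.
* `gen_annotation_dict` — one term per block with coverage /
  contamination knobs and optional decoy terms.
* `gen_power_law_network` — configuration model wired from an exact
  zeta-distribution degree sample (self-loops and multi-edges removed;
  the removal slightly truncates the largest hubs, which is why the
  exponent-recovery tolerance is ±0.15 rather than the sampling-only
  error).

All generators are deterministic given their seed.

## Problem sizes in the shipped benchmarks

The test and acceptance runs use 8-node exhaustive oracles (all 4,140
partitions), 120-gene planted networks over 10 seeds, 100-node null
calibration with 200 replicates × 99 permutations, and one 5,000-node
configuration model per seed. These sizes give stable statistics at
interactive runtimes; all of them are ordinary function arguments and
scale up directly.

## Known limitations

* φ-based thinning needs manual inversion of the threshold logic (see
  above); ρ is the recommended proportionality metric for extraction.
* The local-move optimizer finds local optima of the blended objective;
  restarting over seeds and keeping the best (Q, QGO) is the intended
  usage on hard instances.
* Rewiring by rejection sampling mixes slowly on very dense networks
  (few legal swaps); the swap multiplier is exposed.
* The percentile and threshold strategies treat |c| uniformly across
  metrics; mixed-sign networks are collapsed to magnitude at collapse
  time, losing activation/repression polarity in the module view.
* Ground-truth networks are inherently biased toward well-studied
  genes; the affinity p-value ranks extraction methods relative to the
  chosen GTN, not absolutely.
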