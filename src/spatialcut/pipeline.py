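"""Genome-scale SV-gene calling pipeline.

Ties the modules together: load -> filter -> depth-normalize -> log2 ->
Delaunay graph -> per gene (BIC-selected Gaussian mixture, data penalties,
smooth-factor search over graph cuts, CSR segment tests) -> genome-wide
Benjamini-Hochberg correction.

Per-gene work is embarrassingly parallel and fully deterministic: each gene
gets a seed derived from the global seed and its index, so the result table
is identical for any worker count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import data_io, expression_states, graphcut, significance
from .data_io import SpatialExpressionMatrix
from .spatial_graph import NeighborGraph, build_delaunay_graph, prune_long_edges

logger = logging.getLogger("spatialcut")


@dataclass
class PipelineConfig:
    """All pipeline knobs with their default values.

    The defaults of the statistical core (smooth-factor search starting at
    10 with step 10, mixture components 2-10, noise segments at <= 9 nodes
    with p >= 0.1, FDR 0.05) are the method's standard operating point.
    ``F`` scales the pairwise penalty relative to the data penalty; the
    default 0.1 makes the alpha grid 10..100 correspond to effective
    smoothing weights 1..10 against log2-scale data penalties, the balance
    at which region-scale segments survive the cut.
    """

    normalize: bool = True
    pseudocount: float = 1.0
    min_spots: int = 10
    k_min: int = 2
    k_max: int = 10
    F: float = 0.1
    alpha_start: float = 10.0
    alpha_step: float = 10.0
    alpha_max: float = 100.0
    noise_max_size: int = 9
    noise_min_p: float = 0.1
    tail: bool = True
    exclude_noise: bool = True
    fdr: float = 0.05
    prune_percentile: float = 100.0
    seed: int = 0
    workers: int = 1


@dataclass
class GeneResult:
    gene: str
    best_p: float
    q_value: float
    smooth_factor: float
    n_segments: int
    hidden_labels: np.ndarray
    exp_states: np.ndarray
    K: int
    error: str | None = None


@dataclass
class PipelineResult:
    table: pd.DataFrame
    genes: dict[str, GeneResult]
    graph: NeighborGraph
    matrix: SpatialExpressionMatrix
    config: PipelineConfig

    def significant(self) -> pd.DataFrame:
        return self.table[self.table.q_value < self.config.fdr]


def gene_seed(global_seed: int, gene_index: int) -> int:
    """Deterministic per-gene seed, independent of scheduling order."""
    ss = np.random.SeedSequence(entropy=int(global_seed), spawn_key=(int(gene_index),))
    return int(ss.generate_state(1)[0] % (2**31))


def preprocess(m: SpatialExpressionMatrix, cfg: PipelineConfig) -> SpatialExpressionMatrix:
    """Gene filter on raw counts, then normalization, then log2."""
    if not m.log_transformed:
        m = data_io.filter_genes(m, cfg.min_spots)
        if cfg.normalize and not m.normalized:
            m = data_io.normalize_counts(m)
        m = data_io.log_transform(m, cfg.pseudocount)
    return m


def analyze_gene(
    values: np.ndarray,
    g: NeighborGraph,
    cfg: PipelineConfig,
    seed: int,
    gene: str = "",
) -> GeneResult:
    """Run the per-gene core: GMM states, smooth-factor search, best p."""
    try:
        gmm = expression_states.select_gmm(values, cfg.k_min, cfg.k_max, seed=seed)
        labels = expression_states.initial_labels(gmm, values)
        if gmm.K == 1:
            return GeneResult(
                gene=gene,
                best_p=1.0,
                q_value=np.nan,
                smooth_factor=0.0,
                n_segments=1,
                hidden_labels=np.zeros(len(values), dtype=int),
                exp_states=labels,
                K=1,
            )
        U = expression_states.data_penalties(values, gmm)
        S = graphcut.interaction_matrix(gmm.K, cfg.F)
        res = graphcut.search_smooth_factor(
            g,
            U,
            S,
            init=labels,
            observed_labels=labels,
            start=cfg.alpha_start,
            step=cfg.alpha_step,
            max_alpha=cfg.alpha_max,
            exclude_noise=cfg.exclude_noise,
            tail=cfg.tail,
            seed=seed,
        )
        return GeneResult(
            gene=gene,
            best_p=res.best_p,
            q_value=np.nan,
            smooth_factor=res.best_alpha,
            n_segments=res.best_segmentation.n_segments,
            hidden_labels=res.best_labels,
            exp_states=labels,
            K=gmm.K,
        )
    except Exception as exc:  # failure isolation: one bad gene never aborts
        logger.warning("gene %s failed: %s", gene, exc)
        return GeneResult(
            gene=gene,
            best_p=1.0,
            q_value=np.nan,
            smooth_factor=0.0,
            n_segments=0,
            hidden_labels=np.zeros(len(values), dtype=int),
            exp_states=np.zeros(len(values), dtype=int),
            K=0,
            error=str(exc),
        )


def run_pipeline(m: SpatialExpressionMatrix, cfg: PipelineConfig | None = None) -> PipelineResult:
    """Call SV genes on a spatial expression matrix."""
    cfg = cfg or PipelineConfig()
    m = preprocess(m, cfg)
    g = build_delaunay_graph(m.coords)
    if cfg.prune_percentile < 100:
        g = prune_long_edges(g, cfg.prune_percentile)
    seeds = [gene_seed(cfg.seed, j) for j in range(m.n_genes)]
    if cfg.workers > 1:
        results = Parallel(n_jobs=cfg.workers)(
            delayed(analyze_gene)(m.counts[:, j], g, cfg, seeds[j], m.gene_ids[j])
            for j in range(m.n_genes)
        )
    else:
        results = [
            analyze_gene(m.counts[:, j], g, cfg, seeds[j], m.gene_ids[j])
            for j in range(m.n_genes)
        ]
    pvals = np.array([r.best_p for r in results])
    qvals = significance.bh_adjust(pvals)
    for r, q in zip(results, qvals):
        r.q_value = float(q)
    n_failed = sum(1 for r in results if r.error is not None)
    if n_failed:
        logger.warning("%d genes failed and were reported with p = 1", n_failed)
    table = pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "p_value": pvals,
            "q_value": qvals,
            "smooth_factor": [r.smooth_factor for r in results],
            "n_segments": [r.n_segments for r in results],
        }
    )
    return PipelineResult(
        table=table,
        genes={r.gene: r for r in results},
        graph=g,
        matrix=m,
        config=cfg,
    )


def run_pipeline_from_file(
    path: str | Path, fmt: str = "tsv", cfg: PipelineConfig | None = None
) -> PipelineResult:
    return run_pipeline(data_io.load_expression(path, fmt), cfg)


def plot_gene(
    m: SpatialExpressionMatrix,
    g: NeighborGraph,
    hidden_labels: np.ndarray,
    gene_id: str,
    path: str | Path,
) -> None:
    """Voronoi-cell rendering of one gene with segmentation boundaries.

    Cells are colored by the gene's expression; ridges separating spots with
    different hidden labels are drawn thick.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.spatial import Voronoi, voronoi_plot_2d

    from .spatial_graph import voronoi_boundaries

    values = m.gene(gene_id)
    fig, ax = plt.subplots(figsize=(6, 6))
    vor = Voronoi(m.coords)
    voronoi_plot_2d(
        vor, ax=ax, show_points=False, show_vertices=False, line_width=0.3
    )
    sc = ax.scatter(m.coords[:, 0], m.coords[:, 1], c=values, s=12, cmap="viridis")
    for (x1, y1), (x2, y2) in voronoi_boundaries(g, hidden_labels):
        ax.plot([x1, x2], [y1, y2], color="black", linewidth=2.0)
    lo, hi = m.coords.min(axis=0), m.coords.max(axis=0)
    pad = 0.05 * np.maximum(hi - lo, 1e-12)
    ax.set_xlim(lo[0] - pad[0], hi[0] + pad[0])
    ax.set_ylim(lo[1] - pad[1], hi[1] + pad[1])
    fig.colorbar(sc, ax=ax, label=f"{gene_id} expression")
    ax.set_title(gene_id)
    fig.savefig(path, dpi=120)
    plt.close(fig)
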