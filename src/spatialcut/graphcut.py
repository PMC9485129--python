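"""HMRF energy minimization by alpha-expansion over exact binary min-cuts.

The hidden label field over the spot graph is estimated by minimizing

    E(X) = sum_p U[p, x_p] + alpha * sum_{(p,q) in edges} S[x_p, x_q]

where ``U`` is the per-spot data penalty (distance to each expression-state
mean), ``S`` the ordinal interaction penalty ``S[i, j] = |i - j| * F`` and
``alpha`` the smooth factor weighting spatial coherence against data
fidelity. Binary (two-label) problems are solved exactly by s-t min-cut;
multi-label problems use the alpha-expansion move-making scheme, which
repeatedly solves an exact binary "keep current label vs. switch to alpha"
cut for each label until no move lowers the energy. Because ``S`` is a
metric, every expansion subproblem is regular (submodular) and the cut is
exact; the multi-label result is a strong local minimum (global minimization
for K >= 3 is NP-hard).

The smooth factor is tuned per gene by a sequential search maximizing a
signal-to-noise score: the best segment's -log10 p-value under complete
spatial randomness, penalized by the count of noise segments (<= 9 nodes
with p >= 0.1) normalized to a 200-node graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, connected_components, maximum_flow

from .significance import NOISE_MAX_SIZE, NOISE_MIN_P, SegmentTest, gene_pvalue
from .spatial_graph import NeighborGraph, boundary_edges

#: preferred fixed-point scale for float -> integer capacities fed to the
#: max-flow solver; reduced adaptively when capacities are large, since the
#: solver arithmetic is 32-bit (every capacity and the total flow must stay
#: well below 2**31)
CAPACITY_SCALE = 10**7
_FLOW_LIMIT = 2**30


class RegularityError(ValueError):
    """Interaction energy violates the regularity (submodularity) condition."""


@dataclass(frozen=True)
class InteractionMatrix:
    """Ordinal label-difference penalty ``S[i, j] = |i - j| * F``."""

    S: np.ndarray
    F: float


def interaction_matrix(K: int, F: float = 1.0) -> InteractionMatrix:
    if K < 1:
        raise ValueError("K must be >= 1")
    if F <= 0:
        raise ValueError("F must be positive")
    idx = np.arange(K)
    S = np.abs(idx[:, None] - idx[None, :]).astype(float) * F
    return InteractionMatrix(S=S, F=float(F))


def total_energy(
    g: NeighborGraph,
    labels: np.ndarray,
    U: np.ndarray,
    S: InteractionMatrix | np.ndarray,
    alpha: float,
) -> float:
    """Evaluate the HMRF energy of a label configuration.

    Each undirected edge contributes once.
    """
    Smat = S.S if isinstance(S, InteractionMatrix) else np.asarray(S)
    labels = np.asarray(labels, dtype=int)
    data = U[np.arange(len(labels)), labels].sum()
    if len(g.edges):
        i, j = g.edges[:, 0], g.edges[:, 1]
        pair = Smat[labels[i], labels[j]].sum()
    else:
        pair = 0.0
    return float(data + alpha * pair)


def min_cut(
    source_capacities: np.ndarray,
    sink_capacities: np.ndarray,
    pair_capacities: list[tuple[int, int, float, float]],
) -> tuple[np.ndarray, float]:
    """Exact global minimum s-t cut of a small capacitated graph.

    Parameters
    ----------
    source_capacities, sink_capacities : length-m arrays
        Terminal capacities: ``source_capacities[i]`` is severed when node
        ``i`` ends on the sink side, ``sink_capacities[i]`` when it ends on
        the source side.
    pair_capacities : list of (i, j, cap_ij, cap_ji)
        Directed capacities between ordinary nodes.

    Returns
    -------
    assignment : length-m int array, 0 = source side, 1 = sink side
    cut_value : float, the minimum cut / maximum flow value

    Float capacities are converted to fixed-point integers (scale
    ``CAPACITY_SCALE``) for the exact integer max-flow solver; the returned
    cut value is mapped back to the original scale.
    """
    src = np.asarray(source_capacities, dtype=float)
    snk = np.asarray(sink_capacities, dtype=float)
    if np.any(src < 0) or np.any(snk < 0):
        raise ValueError("capacities must be non-negative")
    pairs = np.asarray(pair_capacities, dtype=float).reshape(-1, 4)
    if np.any(pairs[:, 2:] < 0):
        raise ValueError("capacities must be non-negative")
    m = len(src)
    s, t = m, m + 1
    nodes = np.arange(m)
    pi = pairs[:, 0].astype(np.int64)
    pj = pairs[:, 1].astype(np.int64)
    rows = np.concatenate([np.full(m, s), nodes, pi, pj])
    cols = np.concatenate([nodes, np.full(m, t), pj, pi])
    fcaps = np.concatenate([src, snk, pairs[:, 2], pairs[:, 3]])
    # the max flow is bounded by the cheaper terminal side; keep both the
    # largest capacity and that bound inside the solver's 32-bit range
    max_cap = fcaps.max() if len(fcaps) else 0.0
    flow_bound = min(src.sum(), snk.sum()) + 1.0
    scale = min(
        CAPACITY_SCALE,
        _FLOW_LIMIT / max(max_cap, 1e-12),
        _FLOW_LIMIT / flow_bound,
    )
    caps = np.round(fcaps * scale).astype(np.int64)
    nz = caps > 0
    graph = csr_matrix(
        (caps[nz], (rows[nz], cols[nz])), shape=(m + 2, m + 2)
    )
    graph.sum_duplicates()
    result = maximum_flow(graph, s, t)
    # residual graph: nodes still reachable from the source stay source-side
    residual = graph - result.flow
    residual.data = np.maximum(residual.data, 0)
    residual.eliminate_zeros()
    reach = breadth_first_order(residual, s, directed=True, return_predecessors=False)
    assignment = np.ones(m, dtype=int)
    assignment[[r for r in reach if r < m]] = 0
    return assignment, result.flow_value / scale


@dataclass
class LabelField:
    """Result of one energy minimization."""

    labels: np.ndarray
    energy: float
    alpha: float


def _expansion_move(
    g: NeighborGraph,
    U: np.ndarray,
    Smat: np.ndarray,
    alpha: float,
    labels: np.ndarray,
    expand_label: int,
) -> np.ndarray:
    """One exact alpha-expansion move; returns the proposed labeling.

    Binary variable per node: 0 = keep current label, 1 = take
    ``expand_label``. The pairwise term for an edge (p, q),

        A = V(lp, lq), B = V(lp, a), C = V(a, lq), D = V(a, a) = 0,

    is reparameterized into terminal capacities plus one directed edge of
    capacity B + C - A - D, which is non-negative exactly when the energy is
    regular (triangle inequality for the metric S).
    """
    n = g.n
    V = alpha * Smat
    a = expand_label
    src = U[:, a].astype(float).copy()  # cost of switching (sink side = 1)
    snk = U[np.arange(n), labels].astype(float)  # cost of keeping
    if len(g.edges):
        ep, eq = g.edges[:, 0], g.edges[:, 1]
        lp, lq = labels[ep], labels[eq]
        A = V[lp, lq]
        B = V[lp, a]
        C = V[a, lq]
        edge_cap = B + C - A
        if np.any(edge_cap < -1e-9):
            raise RegularityError("interaction energy is not regular")
        # E = A + (C - A) x_p - C x_q + (B + C - A) (1 - x_p) x_q, up to a
        # constant; negative unary coefficients move to the opposite terminal
        c_p = C - A
        np.add.at(src, ep[c_p > 0], c_p[c_p > 0])
        np.add.at(snk, ep[c_p < 0], -c_p[c_p < 0])
        np.add.at(snk, eq, C)
        pos = edge_cap > 0
        pairs = np.column_stack(
            [ep[pos], eq[pos], edge_cap[pos], np.zeros(pos.sum())]
        )
    else:
        pairs = np.zeros((0, 4))
    assignment, _ = min_cut(src, snk, pairs)
    proposal = labels.copy()
    proposal[assignment == 1] = a
    return proposal


def alpha_expansion(
    g: NeighborGraph,
    U: np.ndarray,
    S: InteractionMatrix | np.ndarray,
    alpha: float,
    init: np.ndarray,
    max_sweeps: int = 20,
    seed: int = 0,
) -> LabelField:
    """Minimize the HMRF energy by iterated expansion moves.

    Sweeps over labels in ascending order; each move is solved exactly by
    min-cut and accepted only if the recomputed (exact, float) energy
    strictly decreases. Terminates when a full sweep makes no move or after
    ``max_sweeps``. The final energy never exceeds the initial energy. For
    two labels a single expansion is globally optimal.
    """
    Smat = S.S if isinstance(S, InteractionMatrix) else np.asarray(S, dtype=float)
    _check_regular(Smat)
    K = U.shape[1]
    labels = np.asarray(init, dtype=int).copy()
    if labels.min() < 0 or labels.max() >= K:
        raise ValueError("initial labels out of range")
    energy = total_energy(g, labels, U, Smat, alpha)
    if alpha == 0 or len(g.edges) == 0:
        labels = np.argmin(U, axis=1)
        return LabelField(labels=labels, energy=total_energy(g, labels, U, Smat, alpha), alpha=alpha)
    for _ in range(max_sweeps):
        improved = False
        for a in range(K):
            proposal = _expansion_move(g, U, Smat, alpha, labels, a)
            e_new = total_energy(g, proposal, U, Smat, alpha)
            if e_new < energy - 1e-12:
                labels = proposal
                energy = e_new
                improved = True
        if not improved:
            break
    return LabelField(labels=labels, energy=energy, alpha=alpha)


def _check_regular(Smat: np.ndarray) -> None:
    """Every binary restriction must satisfy E(0,0)+E(1,1) <= E(0,1)+E(1,0)."""
    K = Smat.shape[0]
    for i in range(K):
        for j in range(K):
            for k in range(K):
                if Smat[i, k] > Smat[i, j] + Smat[j, k] + 1e-9:
                    raise RegularityError(
                        "interaction matrix violates the triangle inequality"
                    )


@dataclass
class Segmentation:
    """Partition of the graph into connected, uniformly labeled segments."""

    segments: list[tuple[np.ndarray, int]]
    boundary: np.ndarray

    @property
    def n_segments(self) -> int:
        return len(self.segments)


def extract_segments(g: NeighborGraph, labels: np.ndarray) -> Segmentation:
    """Connected components of the same-label subgraph.

    Adjacent segments always carry different labels; segment node sets
    partition the graph.
    """
    labels = np.asarray(labels, dtype=int)
    same = labels[g.edges[:, 0]] == labels[g.edges[:, 1]] if len(g.edges) else np.zeros(0, bool)
    kept = g.edges[same]
    sub = NeighborGraph(n=g.n, edges=kept, coords=g.coords)
    _, comp = connected_components(sub.adjacency_matrix(), directed=False)
    segments = []
    for c in np.unique(comp):
        nodes = np.flatnonzero(comp == c)
        segments.append((nodes, int(labels[nodes[0]])))
    return Segmentation(segments=segments, boundary=boundary_edges(g, labels))


def count_noise_segments(
    tests: list[SegmentTest],
    max_size: int = NOISE_MAX_SIZE,
    min_p: float = NOISE_MIN_P,
) -> int:
    return sum(1 for t in tests if t.V <= max_size and t.p >= min_p)


def score_segmentation(best_p: float, n_noise_segments: int, n: int) -> float:
    """Signal-to-noise score of a graph-cuts result.

    ``-log10(best_p) - n_noise_segments * (200 / n)``: the evidence of the
    strongest segment against complete spatial randomness, minus the number
    of noise segments normalized to a 200-node graph.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    return float(-np.log10(best_p) - n_noise_segments * (200.0 / n))


@dataclass
class SmoothFactorSearchResult:
    best_alpha: float
    best_score: float
    best_segmentation: Segmentation
    best_p: float
    best_labels: np.ndarray
    best_tests: list[SegmentTest] = field(default_factory=list)
    trace: list[tuple[float, float]] = field(default_factory=list)


def search_smooth_factor(
    g: NeighborGraph,
    U: np.ndarray,
    S: InteractionMatrix | np.ndarray,
    init: np.ndarray,
    observed_labels: np.ndarray | None = None,
    start: float = 10.0,
    step: float = 10.0,
    max_alpha: float = 100.0,
    exclude_noise: bool = True,
    tail: bool = True,
    seed: int = 0,
) -> SmoothFactorSearchResult:
    """Sequential search for the smooth factor maximizing the SNR score.

    Evaluates alpha = start, start + step, ...: runs alpha-expansion from
    the initial (observed-state) labels, extracts segments, computes each
    segment's CSR p-value against the observed labels, takes the gene-level
    best p (noise segments excluded by default) and scores the result. The
    search stops at the first alpha scoring strictly worse than its
    predecessor, or at ``max_alpha``; the best-scoring state seen is
    returned. Observed labels stay fixed across alphas.
    """
    if observed_labels is None:
        observed_labels = np.asarray(init, dtype=int)
    best: SmoothFactorSearchResult | None = None
    prev_score = None
    trace: list[tuple[float, float]] = []
    alpha = start
    while alpha <= max_alpha + 1e-9:
        lf = alpha_expansion(g, U, S, alpha, init, seed=seed)
        segm = extract_segments(g, lf.labels)
        best_p, tests = gene_pvalue(
            segm.segments, observed_labels, exclude_noise=exclude_noise, tail=tail
        )
        n_noise = count_noise_segments(tests)
        score = score_segmentation(best_p, n_noise, g.n)
        trace.append((alpha, score))
        if best is None or score > best.best_score:
            best = SmoothFactorSearchResult(
                best_alpha=alpha,
                best_score=score,
                best_segmentation=segm,
                best_p=best_p,
                best_labels=lf.labels,
                best_tests=tests,
            )
        if prev_score is not None and score < prev_score:
            break
        prev_score = score
        alpha += step
    assert best is not None
    best.trace = trace
    return best
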