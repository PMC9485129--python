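"""Spot coordinates -> neighbor graph, via Delaunay triangulation.

Delaunay triangulation connects only mutually nearest spots (no spot sits
inside the circumcircle of a triangle), so the resulting sparse graph is a
natural neighborhood system for a Markov random field over the tissue: each
node interacts directly with its geometric neighbors and with nothing else.
The Voronoi diagram, its dual, is used to draw cell territories and to
highlight segmentation boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay, QhullError, Voronoi


class GeometryError(ValueError):
    """Degenerate point configuration (collinear, too few points, ...)."""


@dataclass
class NeighborGraph:
    """Undirected planar graph over spots.

    ``edges`` is an (m, 2) int array with ``edges[:, 0] < edges[:, 1]``,
    each undirected edge listed once. ``adjacency`` maps node -> sorted
    neighbor list.
    """

    n: int
    edges: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=int)
        if self.edges.size == 0:
            self.edges = self.edges.reshape(0, 2)
        self.adjacency: list[list[int]] = [[] for _ in range(self.n)]
        for i, j in self.edges:
            self.adjacency[i].append(int(j))
            self.adjacency[j].append(int(i))
        for nbrs in self.adjacency:
            nbrs.sort()

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_lengths(self) -> np.ndarray:
        d = self.coords[self.edges[:, 0]] - self.coords[self.edges[:, 1]]
        return np.hypot(d[:, 0], d[:, 1])

    def adjacency_matrix(self) -> coo_matrix:
        i, j = self.edges[:, 0], self.edges[:, 1]
        ones = np.ones(len(self.edges))
        return coo_matrix(
            (np.r_[ones, ones], (np.r_[i, j], np.r_[j, i])), shape=(self.n, self.n)
        )

    def is_connected(self) -> bool:
        if self.n == 1:
            return True
        ncomp, _ = connected_components(self.adjacency_matrix(), directed=False)
        return ncomp == 1


def build_delaunay_graph(coords: np.ndarray) -> NeighborGraph:
    """Triangulate spot coordinates and return the edge graph.

    Raises
    ------
    GeometryError
        If there are fewer than 3 points or all points are collinear.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 3:
        raise GeometryError("Delaunay triangulation needs at least 3 points")
    try:
        tri = Delaunay(coords)
    except QhullError as exc:
        raise GeometryError(f"degenerate point configuration: {exc}") from exc
    if tri.simplices.size == 0:
        raise GeometryError("all points are collinear")
    # union of triangle edges, deduplicated with each pair ordered (i < j)
    s = tri.simplices
    pairs = np.vstack([s[:, [0, 1]], s[:, [1, 2]], s[:, [0, 2]]])
    pairs = np.sort(pairs, axis=1)
    edges = np.unique(pairs, axis=0)
    g = NeighborGraph(n=coords.shape[0], edges=edges, coords=coords)
    if not g.is_connected():  # pragma: no cover - Delaunay output is connected
        warnings.warn("Delaunay graph is not connected", stacklevel=2)
    return g


def prune_long_edges(g: NeighborGraph, percentile: float = 100.0) -> NeighborGraph:
    """Drop edges longer than the given length percentile.

    Guards against spurious convex-hull edges on concave tissue sections.
    An edge whose removal would disconnect the graph is retained, so the
    output is always as connected as the input. ``percentile=100`` is the
    identity.
    """
    if not 0 < percentile <= 100:
        raise ValueError("percentile must be in (0, 100]")
    lengths = g.edge_lengths()
    cutoff = np.percentile(lengths, percentile)
    too_long = lengths > cutoff
    if not too_long.any():
        return NeighborGraph(n=g.n, edges=g.edges.copy(), coords=g.coords)
    base_ncomp = _n_components(g.n, g.edges)
    kept = [tuple(e) for e in g.edges]
    # try the longest edges first so the shortest removable ones survive
    for idx in sorted(np.flatnonzero(too_long), key=lambda i: -lengths[i]):
        e = tuple(g.edges[idx])
        trial = [x for x in kept if x != e]
        if _n_components(g.n, np.array(trial)) == base_ncomp:
            kept = trial
    return NeighborGraph(n=g.n, edges=np.array(kept), coords=g.coords)


def _n_components(n: int, edges: np.ndarray) -> int:
    g = NeighborGraph(n=n, edges=edges, coords=np.zeros((n, 2)))
    ncomp, _ = connected_components(g.adjacency_matrix(), directed=False)
    return ncomp


def boundary_edges(g: NeighborGraph, labels: np.ndarray) -> np.ndarray:
    """Graph edges whose endpoints carry different labels."""
    labels = np.asarray(labels)
    discord = labels[g.edges[:, 0]] != labels[g.edges[:, 1]]
    return g.edges[discord]


def voronoi_boundaries(
    g: NeighborGraph, labels: np.ndarray, clip_margin: float = 0.05
) -> list[tuple[tuple[float, float], tuple[float, float]]]:
    """Voronoi ridge segments separating differently labeled spots.

    Each Delaunay edge is dual to one Voronoi ridge; the ridges dual to
    label-discordant edges trace the segmentation boundary. Infinite ridges
    (between hull cells) are clipped to the coordinate bounding box expanded
    by ``clip_margin`` — this affects drawing only, never statistics.
    Uniform labels yield an empty list.
    """
    labels = np.asarray(labels)
    discord_pairs = {tuple(e) for e in boundary_edges(g, labels)}
    if not discord_pairs:
        return []
    vor = Voronoi(g.coords)
    lo = g.coords.min(axis=0)
    hi = g.coords.max(axis=0)
    span = np.maximum(hi - lo, 1e-12)
    lo = lo - clip_margin * span
    hi = hi + clip_margin * span
    radius = float(np.hypot(*(hi - lo)))
    center = g.coords.mean(axis=0)

    segments = []
    for (p, q), (v1, v2) in zip(vor.ridge_points, vor.ridge_vertices):
        key = (p, q) if p < q else (q, p)
        if key not in discord_pairs:
            continue
        if v1 >= 0 and v2 >= 0:
            a, b = vor.vertices[v1], vor.vertices[v2]
        else:
            # semi-infinite ridge: extend from the finite vertex along the
            # outward normal of the (p, q) midline, then clip
            finite = vor.vertices[v2 if v1 < 0 else v1]
            t = g.coords[q] - g.coords[p]
            t /= np.linalg.norm(t)
            normal = np.array([-t[1], t[0]])
            midpoint = (g.coords[p] + g.coords[q]) / 2
            if np.dot(midpoint - center, normal) < 0:
                normal = -normal
            a, b = finite, finite + normal * radius
        clipped = _clip_segment(a, b, lo, hi)
        if clipped is not None:
            segments.append(clipped)
    return segments


def _clip_segment(a, b, lo, hi):
    """Liang-Barsky clipping of segment a-b to the axis-aligned box."""
    d = b - a
    t0, t1 = 0.0, 1.0
    # (p, q) per boundary: inside iff p*t <= q
    checks = (
        (-d[0], a[0] - lo[0]),
        (d[0], hi[0] - a[0]),
        (-d[1], a[1] - lo[1]),
        (d[1], hi[1] - a[1]),
    )
    for p, q in checks:
        if p == 0:
            if q < 0:
                return None
            continue
        r = q / p
        if p < 0:
            t0 = max(t0, r)
        else:
            t1 = min(t1, r)
        if t0 > t1:
            return None
    pa = a + t0 * d
    pb = a + t1 * d
    return ((float(pa[0]), float(pa[1])), (float(pb[0]), float(pb[1])))
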