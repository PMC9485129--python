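"""Benchmark metrics and tissue-structure comparison.

Covers three tasks: scoring SV-gene calls against simulation ground truth
(confusion metrics), comparing spatial patterns to annotated layer
references (normalized Hamming, Jaccard and Hausdorff distances on per-spot
bit vectors), and reconstructing tissue structure from a set of SV genes
(k-means initialization refined by graph cuts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import directed_hausdorff
from shapely.geometry import Point, Polygon
from sklearn.cluster import KMeans

from .data_io import SpatialExpressionMatrix
from .graphcut import InteractionMatrix, alpha_expansion, interaction_matrix
from .spatial_graph import NeighborGraph

UNASSIGNED = -1


@dataclass(frozen=True)
class EvalReport:
    TP: int
    FP: int
    TN: int
    FN: int
    accuracy: float
    sensitivity: float
    fpr: float
    f1: float
    degenerate: bool = False


def confusion_metrics(truth: np.ndarray, called: np.ndarray) -> EvalReport:
    """Accuracy, sensitivity, FPR and F1 from boolean truth/call vectors.

    accuracy = (TP+TN)/(TP+TN+FP+FN), sensitivity = TP/(TP+FN),
    FPR = FP/(FP+TN), F1 = 2 TP/(2 TP+FN+FP). A zero denominator yields
    metric 0 with the ``degenerate`` flag set.
    """
    truth = np.asarray(truth, dtype=bool)
    called = np.asarray(called, dtype=bool)
    if truth.shape != called.shape:
        raise ValueError("truth and called must have equal length")
    TP = int(np.sum(truth & called))
    FP = int(np.sum(~truth & called))
    TN = int(np.sum(~truth & ~called))
    FN = int(np.sum(truth & ~called))
    degenerate = False

    def ratio(num: int, den: int) -> float:
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 0.0
        return num / den

    return EvalReport(
        TP=TP,
        FP=FP,
        TN=TN,
        FN=FN,
        accuracy=ratio(TP + TN, TP + TN + FP + FN),
        sensitivity=ratio(TP, TP + FN),
        fpr=ratio(FP, FP + TN),
        f1=ratio(2 * TP, 2 * TP + FN + FP),
        degenerate=degenerate,
    )


def assign_points_to_layers(
    coords: np.ndarray, polygons: list[tuple[int, np.ndarray]]
) -> np.ndarray:
    """Point-in-polygon layer assignment.

    ``polygons`` is a list of (layer id, (m, 2) vertex ring). Boundary
    points go to the first matching layer in listed order; points outside
    every polygon get the ``UNASSIGNED`` sentinel (-1).
    """
    coords = np.asarray(coords, dtype=float)
    shapes = [(layer, Polygon(ring)) for layer, ring in polygons]
    labels = np.full(coords.shape[0], UNASSIGNED, dtype=int)
    for i, (x, y) in enumerate(coords):
        pt = Point(x, y)
        for layer, poly in shapes:
            if poly.covers(pt):
                labels[i] = layer
                break
    return labels


def match_segments_to_layers(
    seg_vectors: list[np.ndarray], ref_vectors: list[np.ndarray]
) -> list[int]:
    """Map each segment bit-vector to the reference layer it overlaps most.

    Ties (including the degenerate all-zero-overlap case) resolve to the
    lower layer index.
    """
    mapping = []
    for v in seg_vectors:
        v = np.asarray(v, dtype=bool)
        overlaps = [int(np.sum(v & np.asarray(u, dtype=bool))) for u in ref_vectors]
        mapping.append(int(np.argmax(overlaps)))
    return mapping


def normalized_hamming(u: np.ndarray, v: np.ndarray, a: float = 10.0) -> float:
    """``|XOR(u, v)| / (|AND(u, v)| + a)`` with stabilizer ``a`` (default 10)."""
    u = np.asarray(u, dtype=bool)
    v = np.asarray(v, dtype=bool)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    return float(np.sum(u ^ v) / (np.sum(u & v) + a))


def structure_distances(
    u: np.ndarray, v: np.ndarray, coords: np.ndarray
) -> tuple[float, float, bool]:
    """Jaccard and symmetric Hausdorff distance between two spot sets.

    Returns (jaccard, hausdorff, degenerate). Jaccard is 1 - |u&v|/|u|v|
    (0 by convention when both sets are empty). Hausdorff uses the
    coordinates of the set bits; if either side is empty it returns the
    dataset diameter as a sentinel with the degenerate flag set.
    """
    u = np.asarray(u, dtype=bool)
    v = np.asarray(v, dtype=bool)
    coords = np.asarray(coords, dtype=float)
    union = int(np.sum(u | v))
    inter = int(np.sum(u & v))
    jaccard = 0.0 if union == 0 else 1.0 - inter / union
    pu, pv = coords[u], coords[v]
    if len(pu) == 0 or len(pv) == 0:
        lo, hi = coords.min(axis=0), coords.max(axis=0)
        return jaccard, float(np.hypot(*(hi - lo))), True
    h = max(
        directed_hausdorff(pu, pv)[0],
        directed_hausdorff(pv, pu)[0],
    )
    return jaccard, float(h), False


def distance_threshold(reference_distances: np.ndarray, coverage: float = 0.95) -> float:
    """Distance cutoff classifying the given share of reference genes as true.

    The ``coverage`` quantile of a reference set's distance distribution;
    genes below the cutoff pass.
    """
    return float(np.quantile(np.asarray(reference_distances, dtype=float), coverage))


def reconstruct_tissue(
    m: SpatialExpressionMatrix,
    sv_genes: list[str],
    g: NeighborGraph,
    k: int,
    alpha: float = 10.0,
    F: float = 0.1,
    potts: bool = True,
    seed: int = 0,
) -> np.ndarray:
    """Reconstruct tissue layers from an SV gene set.

    Spots are clustered by k-means on their SV-gene expression vectors; the
    cluster assignment initializes a hidden-label field that graph cuts then
    smooths spatially. The data penalty is the Euclidean distance of each
    spot's expression vector to each centroid. Cluster labels are nominal,
    so the interaction defaults to a Potts penalty (F for any differing
    pair); the ordinal form is available via ``potts=False``. The default
    ``alpha * F = 1`` weights one discordant edge like one unit of
    centroid distance — smoothing that cleans ragged boundaries without
    erasing layer-scale structure.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    missing = [gene for gene in sv_genes if gene not in m.gene_ids]
    if missing:
        raise ValueError(f"unknown genes: {missing}")
    if k == 1:
        return np.zeros(m.n_spots, dtype=int)
    idx = [m.gene_ids.index(gene) for gene in sv_genes]
    X = m.counts[:, idx]
    km = KMeans(n_clusters=k, n_init=10, random_state=int(seed) % (2**31))
    init = km.fit_predict(X)
    U = np.linalg.norm(X[:, None, :] - km.cluster_centers_[None, :, :], axis=2)
    if potts:
        S = InteractionMatrix(S=F * (1.0 - np.eye(k)), F=F)
    else:
        S = interaction_matrix(k, F)
    if alpha == 0:
        return init
    return alpha_expansion(g, U, S, alpha, init, seed=seed).labels


def overlap_matched_accuracy(truth: np.ndarray, labels: np.ndarray) -> float:
    """Share of spots assigned to the truth class their cluster overlaps most.

    Each predicted cluster is mapped to the true class with maximal overlap
    (several clusters may map to one class), mirroring how segments are
    matched to annotated layers.
    """
    truth = np.asarray(truth, dtype=int)
    labels = np.asarray(labels, dtype=int)
    correct = 0
    for c in np.unique(labels):
        members = labels == c
        classes, counts = np.unique(truth[members], return_counts=True)
        correct += counts.max()
    return correct / len(truth)
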