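"""Reading, writing and preprocessing of spatial expression matrices.

The universal input object is :class:`SpatialExpressionMatrix`: ``n`` spots
(or single cells) with planar coordinates and an ``n x g`` count matrix.
Counts are stored dense; the matrices this package targets are desk-scale
(hundreds to tens of thousands of spots, thousands of genes).

Supported on-disk layouts:

* TSV/CSV — rows are spots. The first column holds the spot id; if it looks
  like ``"16.92x9.015"`` the two coordinates are parsed out of it, otherwise
  explicit ``x`` and ``y`` columns are expected. All remaining columns are
  genes.
* MatrixMarket — a triplet ``.mtx`` (spots x genes) plus two sidecar text
  files: one gene id per line, and a coordinate table (spot id, x, y).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix


class InputTooSmallError(ValueError):
    """Fewer spots than the minimum the spatial model supports."""


class CoordinateParseError(ValueError):
    """A spot label could not be parsed into planar coordinates."""


class DuplicateCoordinateError(ValueError):
    """Two or more spots share a coordinate (breaks the triangulation)."""


@dataclass
class SpatialExpressionMatrix:
    """Spots with 2-D coordinates and a genes-in-columns expression matrix.

    Attributes
    ----------
    coords : (n, 2) float array
        Planar spot/cell positions in arbitrary units.
    counts : (n, g) float array
        Non-negative expression values; raw counts unless ``normalized``.
    gene_ids, spot_ids : lists of unique strings.
    normalized : bool
        Whether depth normalization has been applied.
    log_transformed : bool
        Whether values are on the log2 scale.
    """

    coords: np.ndarray
    counts: np.ndarray
    gene_ids: list[str]
    spot_ids: list[str]
    normalized: bool = False
    log_transformed: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        n = self.coords.shape[0]
        if n < 3:
            raise InputTooSmallError(f"need at least 3 spots, got {n}")
        if self.coords.shape != (n, 2):
            raise ValueError("coords must be an (n, 2) matrix")
        if self.counts.shape[0] != n:
            raise ValueError("counts rows must match number of spots")
        if len(self.spot_ids) != n:
            raise ValueError("spot_ids length must match number of spots")
        if len(self.gene_ids) != self.counts.shape[1]:
            raise ValueError("gene_ids length must match counts columns")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        _reject_duplicate_coords(self.coords, self.spot_ids)

    @property
    def n_spots(self) -> int:
        return self.coords.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def gene(self, gene_id: str) -> np.ndarray:
        """Expression vector of one gene across all spots."""
        return self.counts[:, self.gene_ids.index(gene_id)]


def _reject_duplicate_coords(coords: np.ndarray, spot_ids: list[str]) -> None:
    _, inverse, counts = np.unique(
        coords, axis=0, return_inverse=True, return_counts=True
    )
    if np.any(counts > 1):
        dup_groups = np.flatnonzero(counts > 1)
        offenders = [
            spot_ids[i] for i in range(len(spot_ids)) if inverse[i] in dup_groups
        ]
        raise DuplicateCoordinateError(
            "duplicate coordinates for spots: " + ", ".join(offenders)
        )


def _parse_coord_label(label: str, row: int) -> tuple[float, float]:
    parts = str(label).split("x")
    if len(parts) != 2:
        raise CoordinateParseError(
            f"row {row}: spot label {label!r} is not of the form '<x>x<y>'"
        )
    try:
        return float(parts[0]), float(parts[1])
    except ValueError as exc:
        raise CoordinateParseError(
            f"row {row}: cannot parse coordinates from label {label!r}"
        ) from exc


def load_expression(path: str | Path, fmt: str = "tsv") -> SpatialExpressionMatrix:
    """Load a spatial expression dataset.

    Parameters
    ----------
    path : file path
        For ``tsv``/``csv``: the table itself. For ``mtx``: the ``.mtx``
        file; sidecars ``<stem>.genes.txt`` and ``<stem>.coords.tsv`` are
        looked up next to it.
    fmt : {"tsv", "csv", "mtx"}

    Genes with all-zero counts are retained; filtering is an explicit,
    separate step (:func:`filter_genes`).
    """
    path = Path(path)
    if fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        spot_ids = [str(s) for s in df.index]
        cols = list(df.columns)
        if "x" in cols and "y" in cols:
            coords = df[["x", "y"]].to_numpy(dtype=float)
            gene_cols = [c for c in cols if c not in ("x", "y")]
        else:
            coords = np.array(
                [_parse_coord_label(s, i) for i, s in enumerate(spot_ids)]
            )
            gene_cols = cols
        counts = df[gene_cols].to_numpy(dtype=float)
        return SpatialExpressionMatrix(
            coords=coords,
            counts=counts,
            gene_ids=[str(g) for g in gene_cols],
            spot_ids=spot_ids,
        )
    if fmt == "mtx":
        mat = mmread(path).toarray().astype(float)
        stem = path.with_suffix("")
        gene_ids = Path(f"{stem}.genes.txt").read_text().split()
        coord_df = pd.read_csv(f"{stem}.coords.tsv", sep="\t", index_col=0)
        coords = coord_df[["x", "y"]].to_numpy(dtype=float)
        return SpatialExpressionMatrix(
            coords=coords,
            counts=mat,
            gene_ids=gene_ids,
            spot_ids=[str(s) for s in coord_df.index],
        )
    raise ValueError(f"unknown format {fmt!r}")


def write_expression(m: SpatialExpressionMatrix, path: str | Path, fmt: str = "tsv") -> None:
    """Write a dataset in one of the supported layouts (see module docs)."""
    path = Path(path)
    if fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        df = pd.DataFrame(m.counts, columns=m.gene_ids, index=m.spot_ids)
        df.insert(0, "x", m.coords[:, 0])
        df.insert(1, "y", m.coords[:, 1])
        df.to_csv(path, sep=sep, index_label="spot")
        return
    if fmt == "mtx":
        mmwrite(str(path), coo_matrix(m.counts))
        stem = path.with_suffix("")
        Path(f"{stem}.genes.txt").write_text("\n".join(m.gene_ids) + "\n")
        coord_df = pd.DataFrame(
            {"x": m.coords[:, 0], "y": m.coords[:, 1]}, index=m.spot_ids
        )
        coord_df.to_csv(f"{stem}.coords.tsv", sep="\t", index_label="spot")
        return
    raise ValueError(f"unknown format {fmt!r}")


def normalize_counts(m: SpatialExpressionMatrix) -> SpatialExpressionMatrix:
    """Depth-normalize counts, cell-ranger style.

    Each spot's counts are scaled by ``median(per-spot totals) / (that
    spot's total)`` so every spot ends up at the median library size.
    Spots with zero total are left at zero. Idempotent: an
    already-normalized matrix passes through with a warning.
    """
    if m.normalized:
        warnings.warn("matrix already normalized; returning unchanged", stacklevel=2)
        return m
    totals = m.counts.sum(axis=1)
    median = np.median(totals)
    scale = np.ones_like(totals)
    nz = totals > 0
    scale[nz] = median / totals[nz]
    return replace(m, counts=m.counts * scale[:, None], normalized=True)


def log_transform(m: SpatialExpressionMatrix, pseudocount: float = 1.0) -> SpatialExpressionMatrix:
    """Entrywise ``log2(x + pseudocount)``."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if np.any(m.counts < 0):
        raise ValueError("negative entries cannot be log-transformed")
    return replace(
        m, counts=np.log2(m.counts + pseudocount), log_transformed=True
    )


def filter_genes(m: SpatialExpressionMatrix, min_spots: int = 10) -> SpatialExpressionMatrix:
    """Keep genes expressed (nonzero) in at least ``min_spots`` spots.

    The default of 10 mirrors the downstream treatment of segments: regions
    supported by fewer than ten nodes are already handled as noise, so genes
    detectable in fewer spots cannot be called spatially variable anyway.
    """
    if min_spots < 0:
        raise ValueError("min_spots must be >= 0")
    keep = (m.counts > 0).sum(axis=0) >= min_spots
    if not np.any(keep):
        raise ValueError("gene filter removed every gene")
    return replace(
        m,
        counts=m.counts[:, keep],
        gene_ids=[g for g, k in zip(m.gene_ids, keep) if k],
    )


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write a per-gene result table as TSV.

    Expects columns gene, p_value, q_value, smooth_factor, n_segments
    (extra columns are preserved).
    """
    lead = ["gene", "p_value", "q_value", "smooth_factor", "n_segments"]
    cols = lead + [c for c in results.columns if c not in lead]
    results[cols].to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
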