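"""Synthetic benchmark data for spatially variable gene detection.

Emulates the standard simulation design for this problem: a tissue section
of a few hundred spots split into three contiguous regions (modeled after
the granular, outer plexiform and olfactory nerve layers of an olfactory
bulb section), SV genes whose log-expression is drawn per region from
N(0, sigma^2), N(1, sigma^2) and N(2, sigma^2), and null genes obtained by
randomly shuffling SV genes' values across spots — identical value
distribution, zero spatial structure. Optional perturbations add Gaussian
noise or randomly exchange values between spots, and an invertible depth
allocation turns the continuous values into sequencing-like counts.

A loader hook (:func:`make_benchmark` accepts explicit ``coords`` and
``regions``) substitutes a real spot layout when one is available; the
jittered-grid stand-in keeps the benchmark self-contained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import SpatialExpressionMatrix


@dataclass
class SimulatedDataset:
    matrix: SpatialExpressionMatrix
    truth: np.ndarray  # per-gene boolean SV flag
    regions: np.ndarray  # region id per spot
    sigma: float
    values: np.ndarray  # pre-count-transform expression values (n x g)
    params: dict = field(default_factory=dict)


def synthetic_layout(
    n: int = 262,
    region_fractions: tuple[float, float, float] = (0.4, 0.3, 0.3),
    seed: int = 0,
    jitter: float = 0.15,
) -> tuple[np.ndarray, np.ndarray]:
    """Jittered grid of ``n`` spots split into 3 contiguous horizontal bands.

    Fractions must sum to 1; band sizes are exact up to rounding (+-1 spot).
    Jitter keeps points in general position for the triangulation while
    preserving the banded structure, so each region is connected in the
    Delaunay graph.
    """
    if n < 30:
        raise ValueError("need at least 30 spots")
    fr = np.asarray(region_fractions, dtype=float)
    if abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("region fractions must sum to 1")
    rng = np.random.default_rng(seed)
    ncols = int(np.ceil(np.sqrt(n)))
    nrows = int(np.ceil(n / ncols))
    xs, ys = np.meshgrid(np.arange(ncols), np.arange(nrows))
    coords = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)[:n]
    coords += rng.uniform(-jitter, jitter, size=coords.shape)
    # spots are in row-major order, so prefix slices are horizontal bands
    cuts = np.round(np.cumsum(fr) * n).astype(int)
    regions = np.zeros(n, dtype=int)
    regions[cuts[0]:cuts[1]] = 1
    regions[cuts[1]:] = 2
    return coords, regions


def simulate_sv_gene(
    regions: np.ndarray,
    sigma: float,
    region_means: tuple[float, float, float] = (0.0, 1.0, 2.0),
    seed: int = 0,
) -> np.ndarray:
    """One SV gene: values ~ N(mean of the spot's region, sigma^2)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    means = np.asarray(region_means, dtype=float)[np.asarray(regions, dtype=int)]
    return rng.normal(means, sigma)


def shuffle_gene(values: np.ndarray, seed: int = 0) -> np.ndarray:
    """Uniformly random permutation of a gene's values across spots."""
    rng = np.random.default_rng(seed)
    return rng.permutation(np.asarray(values))


def perturb(values: np.ndarray, mode: str, amount: float, seed: int = 0) -> np.ndarray:
    """Perturb a gene's values.

    ``gaussian_noise`` adds i.i.d. N(0, amount^2). ``exchange`` picks
    ``floor(amount * n)`` spots and permutes their values among themselves
    (derangement-style: no selected spot keeps its own value when
    avoidable); other spots are untouched.
    """
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    if mode == "gaussian_noise":
        if amount < 0:
            raise ValueError("noise sd must be >= 0")
        if amount == 0:
            return values.copy()
        return values + rng.normal(0.0, amount, size=values.shape)
    if mode == "exchange":
        if not 0 <= amount <= 1:
            raise ValueError("exchange fraction must be in [0, 1]")
        m = int(np.floor(amount * len(values)))
        out = values.copy()
        if m < 2:
            return out
        chosen = rng.choice(len(values), size=m, replace=False)
        out[chosen] = values[chosen][_derangement(m, rng)]
        return out
    raise ValueError(f"unknown perturbation mode {mode!r}")


def _derangement(m: int, rng: np.random.Generator) -> np.ndarray:
    """Random fixed-point-free permutation of range(m); cyclic fallback."""
    for _ in range(100):
        perm = rng.permutation(m)
        if not np.any(perm == np.arange(m)):
            return perm
    return np.roll(np.arange(m), 1)


def to_counts(
    values: np.ndarray,
    depth_profile: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Turn continuous (log2-scale) expression values into counts.

    Inverts the depth normalization + log transform of the analysis path:
    per spot, values are exponentiated base 2, rescaled to proportions and
    allocated the spot's sequencing depth, with stochastic rounding so
    expected counts are unbiased. Running normalization and log2 on the
    output recovers the inputs up to rounding noise.
    """
    values = np.asarray(values, dtype=float)
    depth = np.asarray(depth_profile, dtype=float)
    if np.any(depth <= 0):
        raise ValueError("depths must be positive")
    rng = np.random.default_rng(seed)
    w = np.exp2(values)
    props = w / w.sum(axis=1, keepdims=True)
    expected = props * depth[:, None]
    floor = np.floor(expected)
    counts = floor + (rng.random(expected.shape) < (expected - floor))
    return counts.astype(float)


def lognormal_depths(n: int, mean_depth: float = 1e4, cv_log: float = 0.25, seed: int = 0) -> np.ndarray:
    """Synthetic per-spot library sizes: log-normal around ``mean_depth``."""
    rng = np.random.default_rng(seed)
    return mean_depth * rng.lognormal(mean=0.0, sigma=cv_log, size=n)


def make_benchmark(
    n_sv: int = 100,
    n_null: int = 900,
    sigma: float = 0.3,
    n_spots: int = 262,
    region_fractions: tuple[float, float, float] = (0.4, 0.3, 0.3),
    noise_sd: float = 0.0,
    exchange_fraction: float = 0.0,
    as_counts: bool = True,
    mean_depth: float = 1e4,
    coords: np.ndarray | None = None,
    regions: np.ndarray | None = None,
    seed: int = 0,
) -> SimulatedDataset:
    """Compose a full benchmark dataset.

    ``n_sv`` region-structured genes at the given sigma plus ``n_null``
    spatially random genes obtained by shuffling the (optionally perturbed)
    SV genes, cycling through them when n_null > n_sv. With ``as_counts``
    the values are converted to sequencing-like counts against a log-normal
    depth profile; the analysis pipeline then normalizes and log-transforms
    them back. Fully deterministic given ``seed``.
    """
    root = np.random.SeedSequence(seed)
    seeds = root.generate_state(4 + n_sv + n_null + 2 * (n_sv + n_null)).astype(np.int64)
    si = iter(seeds.tolist())
    if coords is None or regions is None:
        coords, regions = synthetic_layout(
            n_spots, region_fractions, seed=next(si)
        )
    else:
        next(si)
        coords = np.asarray(coords, dtype=float)
        regions = np.asarray(regions, dtype=int)
    n = coords.shape[0]
    sv = np.empty((n, n_sv))
    for j in range(n_sv):
        vals = simulate_sv_gene(regions, sigma, seed=next(si))
        if noise_sd > 0:
            vals = perturb(vals, "gaussian_noise", noise_sd, seed=next(si))
        if exchange_fraction > 0:
            vals = perturb(vals, "exchange", exchange_fraction, seed=next(si))
        sv[:, j] = vals
    nulls = np.empty((n, n_null))
    for j in range(n_null):
        nulls[:, j] = shuffle_gene(sv[:, j % n_sv], seed=next(si))
    values = np.hstack([sv, nulls])
    truth = np.r_[np.ones(n_sv, bool), np.zeros(n_null, bool)]
    gene_ids = [f"sv_{j}" for j in range(n_sv)] + [f"null_{j}" for j in range(n_null)]
    spot_ids = [f"spot_{i}" for i in range(n)]
    if as_counts:
        depths = lognormal_depths(n, mean_depth, seed=next(si))
        counts = to_counts(values, depths, seed=next(si))
        normalized = False
    else:
        # already on the analysis (log2) scale; flag it so the pipeline
        # skips normalization and the log transform
        counts = values - values.min() if values.min() < 0 else values.copy()
        normalized = True
    matrix = SpatialExpressionMatrix(
        coords=coords,
        counts=counts,
        gene_ids=gene_ids,
        spot_ids=spot_ids,
        normalized=normalized,
        log_transformed=normalized,
    )
    return SimulatedDataset(
        matrix=matrix,
        truth=truth,
        regions=regions,
        sigma=sigma,
        values=values,
        params={
            "seed": seed,
            "n_sv": n_sv,
            "n_null": n_null,
            "sigma": sigma,
            "n_spots": n,
            "region_fractions": tuple(region_fractions),
            "noise_sd": noise_sd,
            "exchange_fraction": exchange_fraction,
            "as_counts": as_counts,
            "mean_depth": mean_depth,
        },
    )
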