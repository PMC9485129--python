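"""Per-gene Gaussian mixture modeling of expression states.

A gene's log2 expression values across spots are modeled as a univariate
Gaussian mixture; each component is one discrete *expression state* (off,
low, high, ...). Components are relabeled so means ascend, hence state
indices are ordered by expression level — states further apart in index are
further apart in expression, which is what the ordinal interaction penalty
downstream relies on. The number of components is chosen by BIC over a
range of candidate K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from sklearn.mixture import GaussianMixture


@dataclass(frozen=True)
class GeneGMM:
    """A fitted univariate mixture with mean-ascending components."""

    K: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    bic: float

    def __post_init__(self) -> None:
        assert np.all(np.diff(self.means) >= 0), "components must ascend by mean"
        assert abs(self.weights.sum() - 1.0) < 1e-8


def fit_gmm(values: np.ndarray, K: int, seed: int = 0) -> GeneGMM:
    """Fit a K-component univariate Gaussian mixture by EM.

    EM runs to a 1e-4 log-likelihood tolerance (at most 200 iterations)
    from a k-means initialization seeded by ``seed``. BIC is
    ``-2 loglik + (3K - 1) ln n``: K means, K variances, K - 1 free
    weights. Collapsing components are kept proper by a variance floor of
    ``1e-6 * var(values)``.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if K < 1:
        raise ValueError("K must be >= 1")
    if n <= K:
        raise ValueError(f"need more observations ({n}) than components ({K})")
    if K == 1:
        mu = float(values.mean())
        var = float(values.var())
        floor = max(1e-6 * var, 1e-12)
        var = max(var, floor)
        loglik = norm.logpdf(values, mu, np.sqrt(var)).sum()
        bic = -2.0 * loglik + 2 * np.log(n)
        return GeneGMM(
            K=1,
            weights=np.array([1.0]),
            means=np.array([mu]),
            variances=np.array([var]),
            bic=float(bic),
        )
    var_all = values.var()
    reg = max(1e-6 * var_all, 1e-12)
    gm = GaussianMixture(
        n_components=K,
        covariance_type="full",
        tol=1e-4,
        max_iter=200,
        n_init=1,
        init_params="kmeans",
        reg_covar=reg,
        random_state=int(seed) % (2**31),
    )
    x = values.reshape(-1, 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gm.fit(x)
    order = np.argsort(gm.means_.ravel())
    weights = gm.weights_[order]
    means = gm.means_.ravel()[order]
    variances = gm.covariances_.reshape(-1)[order]
    # sklearn's univariate full-covariance BIC uses the same 3K-1 count
    bic = float(gm.bic(x))
    return GeneGMM(K=K, weights=weights, means=means, variances=variances, bic=bic)


def select_gmm(
    values: np.ndarray, k_min: int = 2, k_max: int = 10, seed: int = 0
) -> GeneGMM:
    """Fit mixtures for K in [k_min, k_max] and return the best-BIC model.

    ``k_max`` is capped at the number of distinct values (and at n - 1).
    Genes with fewer than 3 distinct values cannot support a mixture and
    fall back to a degenerate single-state model, which downstream analysis
    reports as not spatially variable.
    """
    values = np.asarray(values, dtype=float)
    n_distinct = len(np.unique(values))
    if n_distinct < 3:
        if n_distinct > 1:
            warnings.warn(
                "fewer than 3 distinct values; using single-state model",
                stacklevel=2,
            )
        return fit_gmm(values, 1, seed)
    k_max = min(k_max, n_distinct, values.shape[0] - 1)
    k_min = min(k_min, k_max)
    best: GeneGMM | None = None
    for K in range(k_min, k_max + 1):
        model = fit_gmm(values, K, seed)
        if best is None or model.bic < best.bic:
            best = model
    assert best is not None
    return best


def posterior_responsibilities(gmm: GeneGMM, values: np.ndarray) -> np.ndarray:
    """(n, K) posterior probability of each state at each value."""
    values = np.asarray(values, dtype=float)
    log_p = norm.logpdf(
        values[:, None], gmm.means[None, :], np.sqrt(gmm.variances)[None, :]
    ) + np.log(gmm.weights)[None, :]
    log_p -= log_p.max(axis=1, keepdims=True)
    p = np.exp(log_p)
    return p / p.sum(axis=1, keepdims=True)


def initial_labels(gmm: GeneGMM, values: np.ndarray) -> np.ndarray:
    """Assign each spot its most probable expression state.

    The argmax of the posterior responsibility; exact ties break toward the
    lower (lower-expression) state, which keeps runs order-stable.
    """
    if gmm.K == 1:
        return np.zeros(len(values), dtype=int)
    resp = posterior_responsibilities(gmm, values)
    # np.argmax returns the first (lowest) index on ties
    return np.argmax(resp, axis=1)


def data_penalties(values: np.ndarray, gmm: GeneGMM) -> np.ndarray:
    """(n, K) data penalty matrix: absolute distance to each state mean.

    The cost of assigning state k to spot p is ``|e_p - mu_k|``; the row
    minimum is attained at the state whose mean is nearest the observed
    value.
    """
    values = np.asarray(values, dtype=float)
    return np.abs(values[:, None] - gmm.means[None, :])
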