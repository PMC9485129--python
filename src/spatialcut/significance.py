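"""Complete-spatial-randomness tests for graph segments.

Under the null, spots carrying a given expression state are scattered over
the tissue by a homogeneous spatial Poisson process, so the number of
matching spots falling inside a candidate region of V nodes is
Poisson(V * rho), with rho the graph-wide density of that state. A segment
produced by the graph cuts is evidence of spatial structure when the
observed count k in the segment is improbably high under that null. The
gene-level p-value is the best (smallest) segment p-value; genome-wide
multiplicity is handled with Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import poisson
from statsmodels.stats.multitest import multipletests

#: noise-segment rule, shared with the smooth-factor search
NOISE_MAX_SIZE = 9
NOISE_MIN_P = 0.1


@dataclass(frozen=True)
class SegmentTest:
    """CSR test of one segment.

    V: nodes in the segment; k: nodes whose observed state equals the
    segment's hidden label; rho: graph-wide density of that observed state;
    lam = V * rho; p: tail probability of seeing >= k matches.
    """

    V: int
    k: int
    rho: float
    lam: float
    p: float
    label: int

    @property
    def is_noise(self) -> bool:
        return self.V <= NOISE_MAX_SIZE and self.p >= NOISE_MIN_P


def poisson_tail(k: int, lam: float) -> float:
    """Upper-tail probability P(X >= k) for X ~ Poisson(lam).

    Computed via the survival function (regularized gamma), stable for
    small tails. k = 0 covers the whole support and returns 1.
    """
    if lam < 0:
        raise ValueError("lam must be non-negative")
    if k < 0:
        raise ValueError("k must be non-negative")
    if k == 0:
        return 1.0
    return float(poisson.sf(k - 1, lam))


def poisson_point(k: int, lam: float) -> float:
    """Point probability P(X = k); the literal quadrat-count statement."""
    if lam < 0:
        raise ValueError("lam must be non-negative")
    return float(poisson.pmf(k, lam))


def segment_pvalue(
    nodes: np.ndarray,
    hidden_label: int,
    observed_labels: np.ndarray,
    tail: bool = True,
) -> SegmentTest:
    """CSR test of a single segment against the observed expression states.

    With ``tail=True`` (default, the standard quadrat-count practice) the
    p-value is the enrichment tail P(X >= k); ``tail=False`` uses the point
    probability P(X = k) instead.
    """
    observed_labels = np.asarray(observed_labels)
    nodes = np.asarray(nodes, dtype=int)
    if len(nodes) == 0:
        raise ValueError("segment must be nonempty")
    n = len(observed_labels)
    V = len(nodes)
    rho = float(np.count_nonzero(observed_labels == hidden_label)) / n
    k = int(np.count_nonzero(observed_labels[nodes] == hidden_label))
    lam = V * rho
    p = poisson_tail(k, lam) if tail else poisson_point(k, lam)
    return SegmentTest(V=V, k=k, rho=rho, lam=lam, p=min(p, 1.0), label=int(hidden_label))


def gene_pvalue(
    segments: list[tuple[np.ndarray, int]],
    observed_labels: np.ndarray,
    exclude_noise: bool = True,
    tail: bool = True,
) -> tuple[float, list[SegmentTest]]:
    """Best (minimum) segment p-value of a gene's segmentation.

    Noise segments (<= 9 nodes with p >= 0.1) are excluded from the minimum
    by default; note the rule is conjunctive, so a small segment with a
    small p-value still counts. If no segment is eligible the gene gets
    p = 1.
    """
    tests = [
        segment_pvalue(nodes, label, observed_labels, tail=tail)
        for nodes, label in segments
    ]
    eligible = [t.p for t in tests if not (exclude_noise and t.is_noise)]
    best_p = min(eligible) if eligible else 1.0
    return best_p, tests


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, input order preserved."""
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(pvals) == 0:
        return pvals.copy()
    _, q, _, _ = multipletests(pvals, method="fdr_bh")
    return q
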