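# Methods

## Model

A spatial expression dataset is treated as a marked point pattern: spots (or
single cells) at planar coordinates, each carrying a discrete *expression
state* per gene. Detection of spatial variability is cast as a two-step
inference per gene:

1. **Segmentation.** A hidden Markov random field (HMRF) over the Delaunay
   graph of spot positions assigns each spot a hidden state; the field is
   the minimizer of the energy `E(X) = Σ_p U[p, x_p] + α Σ_(p,q) S[x_p, x_q]`
   over graph edges. Connected same-state components of the optimized field
   are the candidate regions.
2. **Testing.** Each candidate region is tested against complete spatial
   randomness (CSR): if spots of a given observed state were scattered by a
   homogeneous Poisson process, the count of matching spots inside a V-node
   region would be Poisson(Vρ), ρ being the state's graph-wide frequency.
   The segment p-value is the enrichment tail P(X ≥ k); the gene's p-value
   is the minimum over its (non-noise) segments, and genes are ranked
   genome-wide by Benjamini–Hochberg adjusted q-values.

Assumptions worth keeping in mind: coordinates are Cartesian and duplicate
positions are rejected (the triangulation needs general position); the CSR
null ignores spot-density gradients (no inhomogeneous baseline); segment
tests are one-sided for enrichment — depleted regions are detected via the
complementary enriched segments of other states.

## Expression states

Per gene, log2(normalized count + 1) values are fit with univariate Gaussian
mixtures for K = 2…10 by EM (tolerance 1e-4, ≤ 200 iterations, k-means
initialization, seeded); the K minimizing BIC (−2·loglik + (3K−1)·ln n) is
kept. Components are relabeled in ascending-mean order so the state index is
ordinal in expression, which justifies the interaction penalty
`S[i, j] = |i − j|·F`: neighbors differing by two states pay twice the
penalty of neighbors differing by one. Spots are labeled by maximum
posterior responsibility; exact ties break to the lower state. Genes with
fewer than three distinct values get a degenerate single-state model and
p = 1 (they cannot be spatially variable at this resolution). Near-constant
components are kept proper by a variance floor of 1e-6 × the gene variance.

Posterior-argmax labeling coincides with nearest-mean labeling whenever
components share weight and variance; with unequal variances the posterior
is the statistically coherent choice and is what the package uses.

## Graph cuts

The exact s–t min-cut runs on `scipy.sparse.csgraph.maximum_flow`. Float
capacities are converted to fixed-point integers: the scale is 1e7 when
capacities are small and is reduced adaptively so that the largest capacity
and the terminal-side flow bound stay below 2³⁰ (the solver's arithmetic is
32-bit). Expansion moves use the standard reparameterization of each regular
pairwise term into terminal capacities plus one directed edge of capacity
`B + C − A − D ≥ 0`; regularity holds for every binary subproblem because
`S` is a metric. A proposed move is accepted only if the exact float energy
strictly decreases, so fixed-point rounding can at worst miss a marginal
move, never corrupt the energy trajectory. Sweeps visit labels in ascending
order and stop when a full sweep makes no move (≤ 20 sweeps). For two labels
a single expansion is the global optimum; for K ≥ 3 the result is a strong
local minimum (global minimization is NP-hard), verified in tests to be
bounded by every uniform labeling and the initialization.

## Relative scale of data and smoothing terms

The data penalty is kept exactly `U[p, k] = |e_p − μ_k|` on the log2 scale,
where state means are typically ~1 apart, and the smooth-factor search runs
over α = 10, 20, …, 100 (start 10, step 10, capped at 100 to bound
runtime; a flag selects step 5). These two conventions are only compatible
if the interaction magnitude F bridges the scales: with F = 1 the smallest
searched α already pays ≥ 10 per discordant edge against data penalties of
order 1, and every gene collapses to a single segment. The pipeline default
is therefore **F = 0.1**, making the effective smoothing weights α·F =
1…10 — one discordant edge costs about one unit of expression distance at
the low end. This is the operating point at which region-scale segments
survive the cut on the σ = 0.3 benchmark (sensitivity 1.0 at desk scale)
while shuffled genes still collapse to a single uninformative segment.
`interaction_matrix` itself keeps F = 1.0 as its neutral default; F is
configurable everywhere.

## Smooth-factor search and score

Per gene, each candidate α is scored by
`−log10(P) − |noise segments| · 200/n`, where P is the minimum segment
p-value of the current segmentation and noise segments have ≤ 9 nodes *and*
p ≥ 0.1 (conjunctive: a small but significant segment is signal, not
noise). The search stops at the first α scoring strictly worse than its
predecessor and returns the best-scoring state seen (not merely the
pre-worsening α — on non-monotone traces the maximum is kept). Observed
state labels are fixed once per gene from the GMM; only the hidden field is
re-optimized per α. Noise segments are excluded from the gene-level minimum
p-value by default (flag to disable).

## Statistics

`poisson_tail` uses the Poisson survival function (regularized incomplete
gamma), agreeing with the summed-PMF oracle to 1e-10 over the tested grid.
The tail P(X ≥ k) is the default segment p-value; a strict point-probability
mode P(X = k) exists behind a flag for the literal quadrat-count statement.
No within-gene correction is applied across segments before taking the
minimum; BH across genes is the only multiplicity control. BH itself is
`statsmodels` `fdr_bh`, tested against a hand-written step-up oracle.

## Synthetic benchmark

The generator emulates the standard simulation design for this task: a
262-spot layout split into three contiguous bands (fractions 0.4/0.3/0.3 by
default, standing in for the granular, outer plexiform and olfactory nerve
layers of an olfactory bulb section), SV genes drawn per region from
N(0, σ²)/N(1, σ²)/N(2, σ²) with σ ∈ [0.1, 0.6], and null genes that are
random permutations of SV genes across spots (identical value multiset, no
spatial structure). Shuffling happens after any noise/exchange perturbation.
The layout is a jittered grid rather than real tissue coordinates so that no
download is needed; `make_benchmark` accepts explicit `coords`/`regions` to
substitute a real slide. Values are converted to counts by allocating a
log-normal per-spot depth (default mean 1e4) proportionally to 2^value with
stochastic rounding — the explicit inverse of the pipeline's
median-depth normalization + log2, verified by a round-trip correlation
> 0.95.

What the simulation does *not* emulate: empty spots/dropout beyond what the
count allocation produces, spot-density gradients, technology-specific noise
(MERFISH/seqFISH), or more than three regions. Passing the benchmark shows
the machinery is correct and calibrated under the stated generative model;
it does not by itself certify performance on a specific real platform.

Default problem sizes in the test suite and the acceptance script — 100 SV
+ 900 null genes at σ = 0.3, 870 all-null genes, 50 + 200 at σ = 0.1 and
0.6 — are a 1:9 SV:null mixture at the benchmark's spot count, sized so a
full reproduction runs in minutes on one CPU.

## Evaluation

Confusion metrics follow the standard definitions (accuracy, sensitivity,
FPR, F1) with zero denominators reported as 0 plus a degenerate flag.
Pattern-vs-reference distances operate on per-spot bit vectors: normalized
Hamming `|XOR|/(|AND| + a)` with a = 10, Jaccard, and symmetric Hausdorff on
the coordinates of set bits (empty side → dataset-diameter sentinel plus a
flag, not infinity). Segments map to layers by maximum overlap, ties to the
lower index. Tissue reconstruction clusters spots by k-means on the SV-gene
expression matrix, then smooths the clustering with one graph-cuts pass; the
interaction is Potts (`F` for any differing pair) because cluster labels are
nominal, with the ordinal form behind a flag. Accuracy against ground truth
uses maximum-overlap matching (several clusters may map to one true layer),
not optimal bipartite assignment.

## Pipeline engineering

Gene filtering (nonzero in ≥ 10 spots by default — segments below ten nodes
are noise-ruled anyway) runs on raw counts, then normalization, then log2.
Per-gene seeds derive from `SeedSequence(global_seed, spawn_key=(gene_index,))`,
so results are identical for any worker count; parallelism is joblib-based
and opt-in. A failing gene is logged and reported with p = 1 instead of
aborting a genome-scale run. The FDR threshold (default 0.05) only filters
reporting; the full table is always written.

## Known limitations

- The smooth-factor search is sequential and can stop at a local optimum of
  the score; a non-monotone score beyond the first dip is never explored.
- The CSR null assumes homogeneous spot density; strongly non-uniform
  layouts (e.g. dissociated cells with density gradients) can inflate
  enrichment in dense areas.
- Min-cut capacities are fixed-point; at extreme α (≥ ~1e3 with large K)
  the adaptive scale coarsens and marginal moves may be skipped (energies
  remain exact).
- 2-D only; no 3-D triangulation.
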