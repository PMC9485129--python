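# spatialcut

Identify **spatially variable (SV) genes** in spatial transcriptomics data —
genes whose expression distribution depends significantly on the position of
the measured spots or cells — fast enough to run genome-scale analyses on a
desktop.

## Method

Spot positions are triangulated (Delaunay) into a sparse neighbor graph
`G = (V, E)`. Each gene's log2 expression is discretized into *expression
states* by a univariate Gaussian mixture `p(x) = Σ_k π_k N(x | μ_k, σ_k²)`
with the number of components chosen by BIC (K = 2…10); states are ordered
by their means. A hidden Markov random field over the graph is then solved
by minimizing

```
E(X) = Σ_p U[p, x_p]  +  α Σ_{(p,q) ∈ E} S[x_p, x_q]
```

where `U[p, k] = |e_p − μ_k|` is the data penalty, `S[i, j] = |i − j|·F` the
ordinal interaction penalty, and α the smooth factor. Two-label problems are
solved exactly by s–t min-cut; multi-label problems by alpha-expansion
(exact binary cuts, guaranteed non-increasing energy). The smooth factor is
tuned per gene by a sequential search (α = 10, 20, … 100) maximizing a
signal-to-noise score

```
Score = −log10(P) − |noise segments| · 200/n
```

where noise segments have ≤ 9 nodes and p ≥ 0.1. The connected same-label
segments of the optimized field are candidate regions, each tested against
complete spatial randomness: under a homogeneous Poisson null the number of
spots in a V-node segment whose observed state matches the segment's hidden
label is Poisson(Vρ), with ρ the graph-wide density of that state; the
segment p-value is the enrichment tail P(X ≥ k). A gene's p-value is its
best segment p-value and genome-wide significance is controlled with
Benjamini–Hochberg.

The package also ships the standard simulation benchmark (3-region layout,
region means 0/1/2, shuffled nulls, noise/exchange perturbations, count
transform) and evaluation utilities (confusion metrics, normalized
Hamming/Jaccard/Hausdorff distances to reference structures, k-means +
graph-cuts tissue reconstruction), so the whole system is testable without
any downloads.

## Worked example

```python
from spatialcut import make_benchmark, run_pipeline, PipelineConfig
from spatialcut.evaluation import confusion_metrics

ds = make_benchmark(n_sv=20, n_null=80, sigma=0.3, seed=1)   # 262 spots
res = run_pipeline(ds.matrix, PipelineConfig(seed=1))
print(res.table.head(3).to_string(index=False))
called = (res.table.q_value < 0.05).to_numpy()
rep = confusion_metrics(ds.truth, called)
print(f"sensitivity={rep.sensitivity:.2f} FPR={rep.fpr:.3f}")
```

prints

```
gene      p_value      q_value  smooth_factor  n_segments
sv_0 8.196112e-17 8.196112e-15           10.0           3
sv_1 5.981348e-15 1.495337e-13           10.0           2
sv_2 1.708272e-12 1.552975e-11           10.0           2
sensitivity=1.00 FPR=0.025
```

Each row is one gene: `p_value` is the best segment's tail probability
under spatial randomness, `q_value` its BH-adjusted value, `smooth_factor`
the α selected by the score search, and `n_segments` the number of
connected regions in the chosen segmentation. All 20 simulated SV genes are
recovered and 2 of 80 shuffled genes are false positives at FDR < 0.05 at
this small scale.

The same pipeline is available from the shell:

```sh
spatialcut simulate --out-prefix bench --n-sv 100 --n-null 900 --seed 1
spatialcut run bench.tsv --out results.tsv --seed 1
spatialcut evaluate results.tsv bench.truth.tsv
spatialcut plot bench.tsv sv_0 --out sv_0.png
```

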