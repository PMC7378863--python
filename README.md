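# agavenet

Directed, signed microbial interaction networks from genus-level abundance
tables — with everything around them: abundance processing, alpha diversity,
balanced two-way ANOVA, functional-guild comparisons, network analytics with
keystone-hub identification, and random-network significance testing.  A
generalized Lotka–Volterra (gLV) community simulator with known ground truth
makes the whole chain testable end to end without any external data.

The package is aimed at microbial-ecology studies that compare compartments
(e.g. rhizosphere vs. bulk soil) across seasons with 16S-style count tables,
and at anyone who wants a reproducible, fully seeded re-implementation of
that analysis chain.

## The methods in brief

**Community model.**  Abundances follow a discrete Ricker-form gLV map

    x_i(t+1) = x_i(t) · exp( r_i + Σ_j a_ij x_j(t) + ε_i(t) ),

where `r_i` is taxon *i*'s intrinsic growth rate, `a_ij` the per-unit effect
of taxon *j* on taxon *i* (`a_ii < 0`: self-limitation), and `ε` log-scale
Gaussian process noise.  Sequencing libraries are multinomial samples of the
relative abundances at a drawn depth.

**Network inference.**  The map linearises on log-ratios:
`y_i(t) = ln x_i(t+1) − ln x_i(t) = r_i + Σ_j a_ij x_j(t)`.  For each target
taxon a sparse coefficient set is chosen by forward stepwise regression
under BIC (with a backward pruning pass).  Because survey samples are not a
true time series, the fit is repeated over B sample orderings (canonical
season/site/replicate order plus random within-season shuffles that keep
dry before rainy); an edge `j → i` enters the *consensus network* only if
selected with a consistent sign in at least a fraction *f* of orderings.
Edge weight is the support fraction, the coefficient the median fitted
`a_ij`.

**Analytics.**  Order, size, density `m/(n(n−1))`, directed mean degree
`m/n`, clustering, diameter/radius, components, cycles, a deterministic
maximal independent set, minimum vertex/edge cuts, greedy-modularity
communities, hubs by maximal total/in/out degree, a discrete power-law fit
of the degree distribution (MLE with `xmin = 1`), and a 13-class triad motif
census against a degree-preserving edge-switch null.  Global significance
uses one hundred Erdős–Rényi `G(n, m)` networks matched on order and size,
with empirical two-sided add-one p-values.

**Group statistics.**  Balanced 2×2 two-way ANOVA both from raw values and
from printed cell means/SDs (with equal cell n the summaries determine the
F statistics exactly), and functional-guild abundances obtained by summing
the relative abundances of member genera, compared across factors with
Benjamini–Hochberg control.

## Worked example

```python
from agavenet import CellSummary, anova2_from_summaries

calcium = [
    CellSummary("dry", "rhizosphere", 1037.11, 78.90, 12),
    CellSummary("dry", "bulk", 1004.68, 34.21, 12),
    CellSummary("rainy", "rhizosphere", 1987.62, 148.62, 12),
    CellSummary("rainy", "bulk", 1917.81, 120.85, 12),
]
res = anova2_from_summaries(calcium)
print(f"F_season = {res.F_a:.1f}")      # F_season = 945.3
```

Soil calcium differs overwhelmingly between seasons (F₁,₄₄ ≈ 945, the
seasonal contrast dwarfs the pooled within-cell variance) and barely between
soil types (F ≈ 2.8) — reconstructed purely from the four cell means and
standard deviations at n = 12.

The full chain on synthetic data (`python examples/06_full_pipeline.py`):

```
samples: 48; networks: 8
condition                nodes edges  density      Q  sig
both_dry                    46    65    0.031  0.411    4
both_rainy                  46    44    0.021  0.582    0
both_both                   46    36    0.017  0.581    0
rhizosphere_dry             46    56    0.027  0.535    0
...
```

Each row is one condition subset's consensus network: ~46 genera survive the
bootstrap (≥ 0.80) and abundance (≥ 1% in some sample) filters, networks are
sparse (density ~0.02–0.03, mean degree near one edge per genus), modularity
sits near 0.4–0.6, and few properties stand out against the matched random
ensemble.  `examples/` contains one short script per capability
(simulation, processing, ANOVA + guilds, inference, analytics + null model,
full pipeline); the CLI mirrors them (`agavenet simulate|process|guilds|
anova|infer|analyze|null|run`).

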