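# Methods

This note records the models, defaults, numerical choices and known
limitations behind each stage of the package, in the order the pipeline runs
them.

## Synthetic community generator

**Model.**  Communities follow a discrete generalized Lotka–Volterra map in
Ricker (exponential) form with step Δt = 1:

    x_i(t+1) = x_i(t) · exp( r_i + Σ_j A[i,j] x_j(t) + ε_i(t) ),
    ε_i(t) ~ Normal(0, noise_sd²).

The exponential update guarantees positivity, and noise enters on the log
scale (multiplicative), which matches compositional count data better than
additive noise.  The update is deterministic when `noise_sd = 0`, and a
single isolated taxon with r > 0, a < 0 converges to the closed-form
equilibrium x* = −r/a (used as a test oracle).

**Parameter draws.**  `sample_glv_parameters` uses r ~ U(0.3, 0.8) per step,
self-limitation diag(A) ~ −U(0.5, 1.5) (equilibria of order one), and
exactly `round(connectance · n(n−1))` nonzero off-diagonal entries with
magnitude `interaction_scale · U(0.5, 1.5)` (default scale 0.15 — moderate
interactions, roughly 10–30 % of self-limitation) and fair-coin signs.

**Study design.**  The default design is 2 soil types × 2 seasons × 4 sites
× 3 replicates = 48 samples.  Library depths are drawn uniformly from
50,000–150,000 reads, bracketing typical 16S library sizes (mean ≈ 140 k)
and the usual rarefaction depths (~60 k).  Reads are multinomial given the
relative abundances — no PCR/chimera artefacts, no read-level error.

**Condition effects.**  Each soil × season condition derives its parameters
from one shared base draw: in the rhizosphere the growth rates of genera
carrying nitrogen-fixation, exopolysaccharide-production or
nutrient-storage traits rise by `effect_size` (default 0.5, i.e. +50 %),
in bulk soil the stress-tolerance guilds rise instead, and the rainy season
strengthens a random third of the interactions and adds a mild global
growth boost.  This couples the trait table to the dynamics, so guild-level
contrasts and between-condition network differences are real, not painted
on.

**Sample ordering.**  Under the default `sampling="trajectory"`, the
site/replicate samples of one condition are successive noisy states of a
single community trajectory (burn-in 5 steps, spacing 3), so the canonical
sample order carries dynamical information — the situation the
pseudo-time-series inference assumes.  `sampling="equilibrium"` draws each
sample from an independent run instead, emulating the view that field
replicates share no temporal structure.  Both interpretations of how
non-time-series surveys map onto a time-series method can therefore be
generated.

**What the generator does not emulate.**  Real 16S data add compositional
coupling at fixed depth, taxonomic misassignment, sequencing error,
zero-inflation beyond multinomial sampling, and environmental covariates.
Passing tests on this generator show the chain is correct *given* gLV
dynamics; they do not certify recovery of interactions from real surveys,
where the model is at best an approximation.

## Abundance processing

Rarefaction subsamples each library without replacement (multivariate
hypergeometric) to a common depth, by default the smallest library.  The
taxonomy filter keeps taxa classified at the target rank with bootstrap
confidence ≥ 0.80 (inclusive).  The relative-abundance filter keeps genera
reaching ≥ 1 % (inclusive) in at least one sample by default; a `scope=
"mean"` alternative is exposed because "greater than 1 %" criteria are
stated ambiguously across the literature.  Filtered tables are **not**
renormalised: downstream regression receives proportions of the original
community, since renormalisation would distort the gLV design matrix.

Alpha diversity delegates to scikit-bio: observed richness, bias-corrected
Chao1 (`S_obs + F1(F1−1)/(2(F2+1))`, defined even when F2 = 0 — important
after rarefaction), Shannon in natural log (nats; values near 6–7 for soil
communities with hundreds of genera are consistent with nats), and
Gini–Simpson `1 − Σ p².`

## Two-way ANOVA

Only balanced complete 2×2 designs are supported.  With equal cell size n
the error mean square is the pooled within-cell variance — the mean of the
four cell variances — so printed cell means and SDs determine the F
statistics exactly; `anova2_from_summaries` exploits this, while
`anova2_raw` does the classical decomposition from observations.  Both are
cross-checked against each other (≤ 1e−9) and against statsmodels'
`anova_lm` in the tests.  Published "±" values are treated as cell standard
deviations with n = 12 per cell; under this reading the printed calcium and
ammonium season F statistics reconstruct to within rounding.  No data
transformation is applied by default; a log-transform flag exists because
field studies often transform non-normal analytes without saying which.
Guild-level ANOVAs are corrected per effect across categories with
Benjamini–Hochberg; a concrete multiplicity rule had to be chosen since
published figures typically report only significance stars.

## Interaction-network inference

**Design.**  `y_i(t) = ln x_i(t+1) − ln x_i(t)` regressed on the abundances
`x_j(t)` plus an intercept (the growth rate).  Zeros are replaced by a
pseudocount — half the smallest nonzero proportion — before the log; the
predictors keep their observed values.

**Selection.**  Forward stepwise search under BIC (AIC available), ties
broken by lowest column index, with two refinements that experience with
exact (noiseless) data forced:

* the residual sum of squares is floored at `1e−24 · ‖y‖²` inside the
  criterion, so once a fit is numerically exact, models compare by
  parameter count instead of by machine-noise residuals;
* the forward path continues past "no single column improves the
  criterion" (extending by the best RSS reducer, up to twice
  `max_parents`), because a weak interaction can look useless until its
  partners are in the model; the reported model is the criterion-minimizing
  prefix, a backward pass prunes columns made redundant by later additions,
  and the `max_parents` cap (default 5) binds on the final model.

Without both refinements, greedy selection stalls in local optima and
noiseless sign recovery plateaus near F1 ≈ 0.8; with them it is exact on
the test systems.

**Consensus.**  B orderings (default 10; the first canonical
season/site/replicate, the rest random within-season shuffles preserving
dry → rainy), one fit per target taxon per ordering; an edge j → i needs a
consistent sign in ≥ f·B orderings.  Self-terms `a_ii` are kept separately
and never appear as graph edges.  The consensus fraction default is
f = 0.3: the rule's published descriptions do not fix it, and on default
synthetic surveys f = 0.3 yields consensus networks at the scale reported
for real soil communities (mean degree ≈ 1 on ~50 genera, density
0.017–0.03), while f ≥ 0.4 empties the edge set — random re-orderings are a
harsh filter.  Raising f never adds edges (tested).

**Power.**  Sign recovery depends on data volume.  Noiseless: three
replicate 30-step trajectories of a 10-taxon community suffice for exact
recovery.  With process noise SD 0.05 the per-observation interaction
signal (~0.015 on the log-ratio scale) is below the noise floor, and BIC
needs roughly ten replicate trajectories (~290 observations) to recover
most signs (mean F1 ≈ 0.8); the noisy-recovery test is sized accordingly.

## Network analytics

Distance-type properties (clustering, diameter, radius, cuts, independent
set, communities) are computed on the undirected projection, collapsing
antiparallel edge pairs; diameter, radius and minimum cuts use the largest
connected component, with the component count reported separately.
"Mean degree" is reported in the directed convention m/n — which makes a
61-node network with printed mean degree 1.017 a 62-edge graph, consistent
with its printed density — alongside the total-degree mean 2m/n, because
published tables are not always internally consistent under one convention.

Cycles are summarised through strongly connected components of size ≥ 2
(exhaustive simple-cycle enumeration is exponential).  The maximal
independent set is greedy by ascending degree with lexicographic
tie-breaks — deterministic, maximal, not maximum.  Communities use greedy
(CNM) modularity maximisation rather than Louvain, for determinism; the
reported modularity is always re-derivable from the returned partition by
the Newman formula (tested to 1e−12).  Hubs are the maximizers of total,
in- and out-degree with all ties reported.

The degree-distribution exponent is a discrete maximum-likelihood fit with
`xmin = 1` (likelihood via the Hurwitz zeta function, bounded search on
α ∈ (1, 20]); an all-equal degree sequence has no interior optimum and is
flagged degenerate.  The triad census counts the 13 connected 3-node
directed isomorphism classes; its null preserves both degree sequences via
directed edge switches (10 × edge-count swap attempts per replicate;
z = (obs − mean)/SD, undefined when the null count never varies).  With 100
null replicates the |z| > 2 rate on matched Erdős–Rényi graphs sits at the
nominal ~5 %; far fewer replicates inflate it through noisy SD estimates.

## Null model

Global properties are scored against N = 100 uniform simple directed
G(n, m) graphs matched on order and size — the minimal null holding exactly
the matched quantities fixed (degree-preserving nulls are reserved for the
motif census).  Each property gets an empirical two-sided p with the
add-one correction, `p = min(1, 2·min(p_low, p_high))` where
`p_tail = (1 + #{null at least as extreme})/(N + 1)`, so the smallest
attainable p at N = 100 is 2/101 and matched properties can never be
flagged.  Calibration (observed graph drawn from the null itself) keeps the
false-flag rate below the nominal α = 0.05 — the add-one correction and
discreteness make the test conservative.

## Pipeline

All randomness descends from one master seed through named SeedSequence
substreams (simulation, rarefaction, per-network inference, per-network
null), so a rerun is byte-identical.  The run emits eight condition
networks — both soils, rhizosphere and bulk crossed with dry, rainy and
both seasons (bulk × both is not a standard column) — each with an edge
list, GraphML, a property report, hubs and a null summary, plus alpha
diversity with its two-way ANOVAs, the guild ANOVA table and one
consolidated JSON report keyed by a config hash.

## Problem sizes in tests and the acceptance script

Exhaustive brute-force metric verification covers all 64 three-node
digraphs and a systematic slice of the 4,096 four-node digraphs, with dense
random sampling of 4–5-node graphs for the expensive cut-set checks (true
exhaustion at five nodes — 2²⁰ graphs — adds nothing but time).  The
null-calibration check uses 500 null-drawn observed graphs scored against a
disjoint 100-graph ensemble slice from the same pool; sharing the ensemble
across repetitions leaves the expected false-flag rate unchanged while
keeping the computation to ~600 property reports.  The acceptance script's
pipeline run uses the default 48-sample study, 10 orderings and a
100-network null per condition.

## Known limitations

* gLV on relative abundances is an approximation: proportions rescale the
  interaction coefficients and introduce compositional coupling the model
  ignores (SparCC/SPIEC-EASI-style corrections are out of scope).
* Consensus-over-orderings controls false positives but costs recall;
  edge sets are sensitive to f and B, which is why both are explicit
  configuration.
* Only balanced 2×2 ANOVA is implemented; unbalanced or multi-level
  designs need a different tool.
* The minimum-cut, independent-set and community algorithms return one
  deterministic answer among possibly many optima.
* Hub identification is degree-based; betweenness/eigenvector centrality
  rankings are deliberately out of scope.
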