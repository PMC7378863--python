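"""Simulate a 48-sample two-soil x two-season survey with known interactions.

The generator runs a Ricker-form generalized Lotka-Volterra community per
condition and samples sequencing libraries multinomially, so the count table
comes with its ground-truth interaction matrices.
"""

from agavenet import make_study

bundle = make_study(seed=7)

print(f"count table: {bundle.counts.shape[0]} taxa x {bundle.counts.shape[1]} samples")
print(bundle.metadata.groupby(["soil_type", "season"]).size().rename("samples"), "\n")
sizes = bundle.counts.sum(axis=0)
print(f"library sizes: min {sizes.min()}, mean {sizes.mean():.0f}, max {sizes.max()}")
A = bundle.truth_A["rhizosphere_dry"].to_numpy()
off = (A != 0).sum() - A.shape[0]
print(f"ground-truth links (rhizosphere, dry): {off} off-diagonal interactions")
# Every condition has its own interaction matrix; the counts alone go to the
# pipeline, the matrices stay available to score what inference recovers.
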