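"""Normalize and filter a count table: rarefaction, bootstrap and abundance
filters, genus aggregation, and alpha diversity."""

from agavenet import (
    CountMatrix,
    aggregate_to_rank,
    alpha_diversity,
    filter_by_bootstrap,
    filter_min_relabund,
    make_study,
    rarefy,
    relative_abundance,
)

bundle = make_study(seed=7)
cm = CountMatrix(bundle.counts, bundle.metadata)

rarefied = rarefy(cm, seed=0)  # subsample every library to the smallest one
print(f"rarefied to {int(rarefied.library_sizes.iloc[0])} reads per sample")

filtered, report = filter_by_bootstrap(rarefied, bundle.taxonomy, min_conf=0.80)
print(f"bootstrap filter dropped {report['n_discarded']} taxa "
      f"({report['discarded_fraction']:.1%} of reads)")

genus = aggregate_to_rank(filtered, bundle.taxonomy, rank="genus")
relab = relative_abundance(genus)
kept = filter_min_relabund(relab, 0.01)  # >= 1% in at least one sample
print(f"{genus.counts.shape[0]} genera, {kept.shape[0]} reach 1% somewhere")

div = alpha_diversity(rarefied)
print("\nalpha diversity (mean over samples):")
print(div.mean().round(3).to_string())
# Shannon is in nats; chao1 >= observed richness by construction.
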