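"""End-to-end pipeline: simulate -> process -> guild stats -> infer -> analyze -> null.

One :class:`RunConfig` drives every stage; all randomness descends from a
single master seed through per-stage substreams, so a rerun with the same
config is byte-identical.  The run emits, per condition column of the
standard eight-network scheme (both soils / rhizosphere / bulk crossed with
dry / rainy / both seasons, omitting the redundant bulk-both column is NOT
done — the scheme is both{dry,rainy,both}, rhizosphere{dry,rainy,both},
bulk{dry,rainy}), an inferred network, its property report, its hub table
and its random-ensemble null summary, plus alpha-diversity and guild ANOVA
tables, consolidated into one JSON report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abundance as ab
from . import simulate as sim
from .errors import ParameterError, PipelineError
from .inference import InferenceConfig, infer_consensus_network, write_network
from .network import global_metrics, identify_hubs
from .nullmodel import null_summary
from .stats import anova2_raw, compare_guilds, guild_abundance

__all__ = ["RunConfig", "run_pipeline", "NETWORK_SCHEME"]

log = logging.getLogger("agavenet")

#: the eight condition columns of the standard report
NETWORK_SCHEME = (
    ("both", "dry"), ("both", "rainy"), ("both", "both"),
    ("rhizosphere", "dry"), ("rhizosphere", "rainy"), ("rhizosphere", "both"),
    ("bulk", "dry"), ("bulk", "rainy"),
)


@dataclass
class RunConfig:
    """Flat, serialisable configuration of a full pipeline run."""

    outdir: str = "agavenet_run"
    seed: int = 0
    # simulation (used when counts_path is None)
    counts_path: str | None = None
    metadata_path: str | None = None
    taxonomy_path: str | None = None
    traits_path: str | None = None
    n_taxa: int = 80
    n_genera: int = 60
    connectance: float = 0.06
    interaction_scale: float = 0.15
    noise_sd: float = 0.05
    effect_size: float = 0.5
    sampling: str = "trajectory"
    # processing
    rarefy_depth: int | str = "auto"
    min_bootstrap: float = 0.80
    min_relabund: float = 0.01
    relabund_scope: str = "any_sample"
    # inference
    n_orderings: int = 10
    consensus_threshold: float = 0.3
    max_parents: int = 5
    pseudocount: float | None = None
    # null model
    null_n: int = 100
    alpha: float = 0.05

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if math.isnan(f) else f
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _stage(name):
    def deco(fn):
        def wrapped(*a, **k):
            log.info("stage %s: start", name)
            try:
                return fn(*a, **k)
            except PipelineError:
                raise
            except Exception as e:  # noqa: BLE001 — stage boundary
                raise PipelineError(name, str(e)) from e
        return wrapped
    return deco


@_stage("simulate")
def _get_inputs(cfg: RunConfig, rng_seed) -> sim.StudyBundle:
    if cfg.counts_path:
        cm = ab.read_count_table(cfg.counts_path, metadata=cfg.metadata_path)
        taxonomy = ab.read_taxonomy(cfg.taxonomy_path) if cfg.taxonomy_path else None
        traits = (
            pd.read_csv(cfg.traits_path, sep="\t") if cfg.traits_path else pd.DataFrame()
        )
        return sim.StudyBundle(
            counts=cm.counts, metadata=cm.metadata, taxonomy=taxonomy,
            traits=traits, truth_A={},
        )
    return sim.make_study(
        n_taxa=cfg.n_taxa, n_genera=cfg.n_genera, connectance=cfg.connectance,
        interaction_scale=cfg.interaction_scale, noise_sd=cfg.noise_sd,
        effect_size=cfg.effect_size, sampling=cfg.sampling, seed=rng_seed,
    )


@_stage("process")
def _process(cfg: RunConfig, bundle: sim.StudyBundle, seed):
    cm = ab.CountMatrix(bundle.counts, bundle.metadata)
    depth = None if cfg.rarefy_depth in ("auto", None) else int(cfg.rarefy_depth)
    rarefied = ab.rarefy(cm, depth=depth, seed=seed)
    report = {"rarefy_depth": int(rarefied.library_sizes.iloc[0])}
    if bundle.taxonomy is not None:
        filtered, fr = ab.filter_by_bootstrap(
            rarefied, bundle.taxonomy, rank="genus", min_conf=cfg.min_bootstrap
        )
        report["bootstrap_filter"] = fr
        genus = ab.aggregate_to_rank(filtered, bundle.taxonomy, rank="genus")
    else:
        genus = rarefied
    relab = ab.relative_abundance(genus)
    kept = ab.filter_min_relabund(relab, cfg.min_relabund, scope=cfg.relabund_scope)
    report["n_genera_before_relabund_filter"] = int(relab.shape[0])
    report["n_genera_after_relabund_filter"] = int(kept.shape[0])
    alpha_div = ab.alpha_diversity(rarefied)
    return genus, relab, kept, alpha_div, report


@_stage("group_stats")
def _group_stats(cfg: RunConfig, kept_relab, traits, metadata, alpha_div):
    out = {}
    if traits is not None and not traits.empty:
        guilds, gr = guild_abundance(kept_relab, traits)
        gtable = compare_guilds(guilds, metadata, alpha=cfg.alpha)
        out["guilds"] = guilds
        out["guild_anova"] = gtable
        out["guild_report"] = gr
    rows = {}
    for idx in alpha_div.columns:
        res = anova2_raw(
            alpha_div[idx].to_numpy(),
            metadata.loc[alpha_div.index, "soil_type"].to_numpy(),
            metadata.loc[alpha_div.index, "season"].to_numpy(),
        )
        rows[idx] = {"F_soil_type": res.F_a, "F_season": res.F_b,
                     "F_interaction": res.F_ab, **res.p_values()}
    out["alpha_anova"] = rows
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the consolidated report (also written to disk)."""
    outdir = Path(config.outdir)
    for sub in ("counts", "processed", "networks", "reports", "null"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(config.seed)
    ss_sim, ss_rarefy, ss_infer, ss_null = master.spawn(4)
    log.info("run: seed=%s config_hash=%s", config.seed, config.config_hash())

    bundle = _get_inputs(config, ss_sim)
    if bundle.truth_A:
        sim.write_bundle(bundle, outdir / "counts")
    genus, relab, kept, alpha_div, proc_report = _process(config, bundle, ss_rarefy)
    ab.write_count_table(ab.CountMatrix(genus.counts), outdir / "processed" / "genus_counts.tsv")
    kept.to_csv(outdir / "processed" / "genus_relabund.tsv", sep="\t")
    alpha_div.to_csv(outdir / "processed" / "alpha_diversity.tsv", sep="\t")

    stats_out = _group_stats(config, kept, bundle.traits, bundle.metadata, alpha_div)
    if "guild_anova" in stats_out:
        stats_out["guild_anova"].to_csv(outdir / "reports" / "guild_anova.tsv", sep="\t")

    inf_cfg = InferenceConfig(
        pseudocount=config.pseudocount, n_orderings=config.n_orderings,
        consensus_threshold=config.consensus_threshold, max_parents=config.max_parents,
    )
    networks, features, hubs, nulls = {}, {}, {}, {}
    infer_seeds = ss_infer.spawn(len(NETWORK_SCHEME))
    null_seeds = ss_null.spawn(len(NETWORK_SCHEME))
    for k, (soil, season) in enumerate(NETWORK_SCHEME):
        label = f"{soil}_{season}"
        subset = {}
        if soil != "both":
            subset["soil_type"] = soil
        if season != "both":
            subset["season"] = season
        log.info("stage infer[%s]: start", label)
        try:
            net = infer_consensus_network(
                kept, bundle.metadata, subset=subset or None,
                config=inf_cfg, seed=infer_seeds[k],
            )
            rep = global_metrics(net)
            hub = identify_hubs(net)
            nulls[label] = null_summary(
                net, n=config.null_n, alpha=config.alpha, seed=null_seeds[k]
            )
        except Exception as e:  # noqa: BLE001 — stage boundary
            raise PipelineError(f"infer[{label}]", str(e)) from e
        networks[label] = net
        features[label] = rep
        hubs[label] = hub
        write_network(net, outdir / "networks" / f"net_{label}.tsv")
        write_network(net, outdir / "networks" / f"net_{label}.graphml", graphml=True)
        nulls[label].to_csv(outdir / "null" / f"null_{label}.tsv", sep="\t")

    report = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_samples": int(bundle.counts.shape[1]),
        "processing": proc_report,
        "alpha_anova": stats_out["alpha_anova"],
        "guild_anova": (
            stats_out["guild_anova"].reset_index().to_dict(orient="records")
            if "guild_anova" in stats_out else None
        ),
        "networks": {
            label: {
                "features": features[label].numeric_properties(),
                "hubs": dataclasses.asdict(hubs[label]),
                "n_significant_vs_null": int(nulls[label]["significant"].sum()),
            }
            for label in features
        },
    }
    report = _jsonify(report)
    with open(outdir / "reports" / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    config.to_yaml(outdir / "reports" / "effective_config.yaml")
    log.info("run: done (%d networks)", len(features))
    return report
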