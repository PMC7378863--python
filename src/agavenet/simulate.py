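"""Synthetic community generator.

Ground-truth communities follow a discrete generalized Lotka-Volterra (gLV)
model in Ricker form,

    x_i(t+1) = x_i(t) * exp(r_i + sum_j A[i, j] x_j(t) + eps_i(t)),

with intrinsic growth rates ``r``, a signed interaction matrix ``A`` (entry
``A[i, j]`` is the per-unit effect of taxon *j* on taxon *i*), and log-scale
Gaussian process noise ``eps``.  Sequencing is emulated as multinomial
sampling of reads at a drawn library depth, so every downstream stage of the
pipeline — filtering, diversity, network inference, network analytics — can
be exercised against a known interaction structure.

The default study design mirrors a two-soil (rhizosphere vs. bulk), two-season
(dry vs. rainy), four-site, three-replicate survey: 48 samples in total.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DivergenceError, ParameterError

__all__ = [
    "GLVParams",
    "Trajectory",
    "StudyDesign",
    "StudyBundle",
    "sample_glv_parameters",
    "simulate_glv",
    "sample_reads",
    "make_study",
    "write_bundle",
    "TRAIT_CATEGORIES",
]


@dataclass(frozen=True)
class GLVParams:
    """Ground-truth gLV parameters for one community."""

    n_taxa: int
    r: np.ndarray          # (n_taxa,) intrinsic growth rates, 1/step
    A: np.ndarray          # (n_taxa, n_taxa) interaction matrix
    noise_sd: float = 0.0  # SD of multiplicative log-normal process noise
    connectance: float = 0.0

    def __post_init__(self):
        r = np.asarray(self.r, dtype=float)
        A = np.asarray(self.A, dtype=float)
        if A.shape != (self.n_taxa, self.n_taxa) or r.shape != (self.n_taxa,):
            raise ParameterError("r/A shapes inconsistent with n_taxa")
        if np.any(np.diag(A) >= 0):
            raise ParameterError("diagonal of A must be negative (self-limitation)")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "A", A)

    @property
    def n_links(self) -> int:
        off = self.A.copy()
        np.fill_diagonal(off, 0.0)
        return int(np.count_nonzero(off))


@dataclass(frozen=True)
class Trajectory:
    """Simulated abundance time course: taxa x (T+1) matrix plus step labels."""

    abundances: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        if np.any(self.abundances < 0):
            raise ParameterError("abundances must be non-negative")


@dataclass(frozen=True)
class StudyDesign:
    """Factorial survey layout; the default reproduces a 48-sample study."""

    soil_types: tuple = ("rhizosphere", "bulk")
    seasons: tuple = ("dry", "rainy")
    n_sites: int = 4
    n_replicates: int = 3
    depth_range: tuple = (50_000, 150_000)

    def __post_init__(self):
        lo, hi = self.depth_range
        if lo > hi or lo < 1:
            raise ParameterError("depth_range must satisfy 1 <= min <= max")
        if self.n_sites < 1 or self.n_replicates < 1:
            raise ParameterError("n_sites and n_replicates must be >= 1")

    @property
    def n_samples(self) -> int:
        return len(self.soil_types) * len(self.seasons) * self.n_sites * self.n_replicates


@dataclass
class StudyBundle:
    """Everything a simulated study produces, ground truth included."""

    counts: pd.DataFrame       # taxa x samples, integer reads
    metadata: pd.DataFrame     # per-sample soil_type/season/site/replicate
    taxonomy: pd.DataFrame     # per-taxon lineage + bootstrap confidences
    traits: pd.DataFrame       # genus / category / class
    truth_A: dict              # condition label -> interaction DataFrame
    params: dict = field(default_factory=dict)


def sample_glv_parameters(
    n_taxa: int,
    connectance: float,
    interaction_scale: float = 0.15,
    seed: int | np.random.SeedSequence = 0,
    noise_sd: float = 0.0,
) -> GLVParams:
    """Draw random gLV parameters with the requested connectance.

    Growth rates are uniform on [0.3, 0.8); self-limitation terms are uniform
    on [-1.5, -0.5), giving single-taxon equilibria of order one.  Exactly
    ``round(connectance * n_taxa * (n_taxa - 1))`` off-diagonal entries are
    nonzero, placed uniformly at random, with magnitude
    ``interaction_scale * U(0.5, 1.5)`` and a fair-coin sign.
    """
    if not 0 <= connectance <= 1:
        raise ParameterError("connectance must lie in [0, 1]")
    if n_taxa < 1:
        raise ParameterError("n_taxa must be >= 1")
    if interaction_scale < 0:
        raise ParameterError("interaction_scale must be non-negative")
    rng = np.random.default_rng(seed)
    r = rng.uniform(0.3, 0.8, size=n_taxa)
    A = np.zeros((n_taxa, n_taxa))
    np.fill_diagonal(A, -rng.uniform(0.5, 1.5, size=n_taxa))
    n_pairs = n_taxa * (n_taxa - 1)
    n_links = int(round(connectance * n_pairs))
    if n_links:
        pairs = [(i, j) for i in range(n_taxa) for j in range(n_taxa) if i != j]
        chosen = rng.choice(len(pairs), size=n_links, replace=False)
        for k in chosen:
            i, j = pairs[k]
            A[i, j] = rng.choice([-1.0, 1.0]) * interaction_scale * rng.uniform(0.5, 1.5)
    return GLVParams(n_taxa=n_taxa, r=r, A=A, noise_sd=noise_sd, connectance=connectance)


def simulate_glv(
    params: GLVParams,
    x0: np.ndarray,
    T: int,
    seed: int | np.random.SeedSequence | None = None,
) -> Trajectory:
    """Integrate the Ricker-form gLV map for ``T`` steps.

    The exponential update keeps abundances strictly non-negative; noise is
    multiplicative (log-scale Gaussian with SD ``params.noise_sd``).  The run
    is deterministic when ``noise_sd == 0``.
    """
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 < 0):
        raise ParameterError("x0 must be non-negative")
    if T < 1:
        raise ParameterError("T must be >= 1")
    rng = np.random.default_rng(seed)
    n = params.n_taxa
    out = np.empty((n, T + 1))
    out[:, 0] = x0
    x = x0.copy()
    for t in range(T):
        eps = rng.normal(0.0, params.noise_sd, size=n) if params.noise_sd > 0 else 0.0
        x = x * np.exp(params.r + params.A @ x + eps)
        if not np.all(np.isfinite(x)):
            bad = int(np.flatnonzero(~np.isfinite(x))[0])
            raise DivergenceError(step=t + 1, taxon=bad)
        out[:, t + 1] = x
    return Trajectory(abundances=out, times=np.arange(T + 1))


def sample_reads(
    abundances: np.ndarray,
    depth: int,
    seed: int | np.random.SeedSequence | None = None,
) -> np.ndarray:
    """Multinomially sample one sequencing library from an abundance vector."""
    x = np.asarray(abundances, dtype=float)
    if np.any(x < 0):
        raise ParameterError("abundances must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ParameterError("need at least one positive abundance")
    if depth < 1:
        raise ParameterError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.multinomial(int(depth), x / total)


# Functional-guild vocabulary used by the trait-table generator.  Guilds follow
# the usual soil-microbiology grouping: nutrient-cycling capabilities,
# stress-tolerance traits, and environmental-adaptation traits.
TRAIT_CATEGORIES = {
    "N_fixation": "nutrient_cycling",
    "denitrification": "nutrient_cycling",
    "P_solubilization": "nutrient_cycling",
    "nitrification": "nutrient_cycling",
    "salt_tolerance": "stress_tolerance",
    "desiccation_tolerance": "stress_tolerance",
    "thermotolerance": "stress_tolerance",
    "spore_formation": "stress_tolerance",
    "EPS_production": "environmental_adaptation",
    "antibiotic_production": "environmental_adaptation",
    "filamentous_growth": "environmental_adaptation",
    "nutrient_storage": "environmental_adaptation",
}

_PHYLA = ("Actinobacteria", "Proteobacteria", "Acidobacteria", "Chloroflexi", "Firmicutes")


def _make_taxonomy(n_taxa: int, n_genera: int, rng: np.random.Generator) -> pd.DataFrame:
    taxa = [f"OTU_{k:04d}" for k in range(1, n_taxa + 1)]
    genera = [f"Genus{k:03d}" for k in range(1, n_genera + 1)]
    # every genus appears at least once; surplus OTUs fold into existing genera
    assign = list(range(n_genera)) + list(rng.integers(0, n_genera, size=n_taxa - n_genera))
    rng.shuffle(assign)
    phylum_of_genus = rng.choice(len(_PHYLA), size=n_genera)
    low_conf = rng.random(n_taxa) < 0.08  # a small tail of poorly classified taxa
    genus_conf = np.where(low_conf, rng.uniform(0.40, 0.79, n_taxa), rng.uniform(0.82, 1.0, n_taxa))
    return pd.DataFrame(
        {
            "phylum": [_PHYLA[phylum_of_genus[g]] for g in assign],
            "genus": [genera[g] for g in assign],
            "phylum_conf": np.round(rng.uniform(0.90, 1.0, n_taxa), 3),
            "genus_conf": np.round(genus_conf, 3),
        },
        index=pd.Index(taxa, name="taxon_id"),
    )


def _make_traits(genera: list[str], rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    cats = list(TRAIT_CATEGORIES)
    for g in genera:
        mask = rng.random(len(cats)) < 0.15
        for c, m in zip(cats, mask):
            if m:
                rows.append((g, c, TRAIT_CATEGORIES[c]))
    if not any(r[1] == "N_fixation" for r in rows):  # keep the focal guild populated
        rows.append((genera[0], "N_fixation", "nutrient_cycling"))
    df = pd.DataFrame(rows, columns=["genus", "category", "class"])
    return df.sort_values(["genus", "category"]).reset_index(drop=True)


def make_study(
    design: StudyDesign | None = None,
    n_taxa: int = 80,
    n_genera: int = 60,
    connectance: float = 0.06,
    interaction_scale: float = 0.15,
    noise_sd: float = 0.05,
    effect_size: float = 0.5,
    sampling: str = "trajectory",
    spacing: int = 3,
    burn_in: int = 5,
    seed: int = 0,
) -> StudyBundle:
    """Simulate a full factorial study with known interaction structure.

    Each soil-type x season condition gets its own gLV parameter set derived
    from a shared base draw: in the rhizosphere the growth rates of
    nitrogen-fixing and exopolysaccharide-producing genera are raised by
    ``effect_size`` (relative), while stress-tolerant genera are favoured in
    bulk soil; in the rainy season a random subset of interactions is
    strengthened.  Under ``sampling="trajectory"`` the site/replicate samples
    of a condition are successive (noisy) states of one community trajectory,
    so sample order carries dynamical information; ``sampling="equilibrium"``
    draws each sample from an independent run instead.
    """
    if sampling not in ("trajectory", "equilibrium"):
        raise ParameterError("sampling must be 'trajectory' or 'equilibrium'")
    design = design or StudyDesign()
    master = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss_params, ss_tax, ss_traits, ss_cond = master.spawn(4)
    rng_tax = np.random.default_rng(ss_tax)
    rng_traits = np.random.default_rng(ss_traits)

    taxonomy = _make_taxonomy(n_taxa, min(n_genera, n_taxa), rng_tax)
    genera = sorted(taxonomy["genus"].unique())
    traits = _make_traits(genera, rng_traits)
    base = sample_glv_parameters(
        n_taxa, connectance, interaction_scale, seed=ss_params, noise_sd=noise_sd
    )

    boosted_guilds = {"N_fixation", "EPS_production", "nutrient_storage"}
    stress_guilds = {"salt_tolerance", "desiccation_tolerance", "spore_formation"}
    genus_cats = traits.groupby("genus")["category"].apply(set).to_dict()
    taxon_genus = taxonomy["genus"].to_numpy()
    boosted = np.array([bool(genus_cats.get(g, set()) & boosted_guilds) for g in taxon_genus])
    stressed = np.array([bool(genus_cats.get(g, set()) & stress_guilds) for g in taxon_genus])

    rng_cond = np.random.default_rng(ss_cond)
    cond_params: dict[tuple, GLVParams] = {}
    off = np.flatnonzero((base.A != 0) & ~np.eye(n_taxa, dtype=bool))
    rainy_links = rng_cond.choice(off, size=max(1, len(off) // 3), replace=False) if len(off) else []
    for soil in design.soil_types:
        for season in design.seasons:
            r = base.r.copy()
            A = base.A.copy()
            if soil == "rhizosphere":
                r[boosted] *= 1.0 + effect_size
            else:
                r[stressed] *= 1.0 + effect_size
            if season == "rainy":
                A.flat[rainy_links] *= 1.0 + effect_size
                r *= 1.05  # mild moisture boost
            cond_params[(soil, season)] = GLVParams(
                n_taxa=n_taxa, r=r, A=A, noise_sd=noise_sd, connectance=connectance
            )

    n_points = design.n_sites * design.n_replicates
    columns, meta_rows = {}, []
    for ci, ((soil, season), p) in enumerate(sorted(cond_params.items())):
        ss_traj, ss_reads, ss_depth, ss_x0 = master.spawn(1)[0].spawn(4)
        # per-condition substreams keyed by condition order for reproducibility
        rng_depth = np.random.default_rng(ss_depth)
        rng_x0 = np.random.default_rng(ss_x0)
        if sampling == "trajectory":
            x0 = rng_x0.uniform(0.2, 1.2, size=n_taxa)
            T = burn_in + spacing * n_points
            traj = simulate_glv(p, x0, T, seed=ss_traj)
            states = [traj.abundances[:, burn_in + spacing * (k + 1)] for k in range(n_points)]
        else:
            states = []
            for k, child in enumerate(ss_traj.spawn(n_points)):
                x0 = rng_x0.uniform(0.2, 1.2, size=n_taxa)
                states.append(simulate_glv(p, x0, burn_in + spacing, seed=child).abundances[:, -1])
        read_streams = ss_reads.spawn(n_points)
        k = 0
        for site in range(1, design.n_sites + 1):
            for rep in range(1, design.n_replicates + 1):
                depth = int(rng_depth.integers(design.depth_range[0], design.depth_range[1] + 1))
                sample_id = f"{soil[0].upper()}_{season[0].upper()}_s{site}_r{rep}"
                columns[sample_id] = sample_reads(states[k], depth, seed=read_streams[k])
                meta_rows.append((sample_id, soil, season, f"site{site}", rep))
                k += 1

    counts = pd.DataFrame(columns, index=taxonomy.index, dtype=int)
    metadata = pd.DataFrame(
        meta_rows, columns=["sample_id", "soil_type", "season", "site", "replicate"]
    ).set_index("sample_id")
    truth = {
        f"{soil}_{season}": pd.DataFrame(p.A, index=taxonomy.index, columns=taxonomy.index)
        for (soil, season), p in sorted(cond_params.items())
    }
    return StudyBundle(
        counts=counts, metadata=metadata, taxonomy=taxonomy, traits=traits,
        truth_A=truth, params={f"{s}_{n}": p for (s, n), p in sorted(cond_params.items())},
    )


def write_bundle(bundle: StudyBundle, outdir: str | Path) -> dict[str, Path]:
    """Write every bundle table as tab-separated UTF-8 text; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in [
        ("counts", bundle.counts), ("metadata", bundle.metadata),
        ("taxonomy", bundle.taxonomy),
    ]:
        paths[name] = outdir / f"{name}.tsv"
        df.to_csv(paths[name], sep="\t")
    paths["traits"] = outdir / "traits.tsv"
    bundle.traits.to_csv(paths["traits"], sep="\t", index=False)
    for cond, A in bundle.truth_A.items():
        p = outdir / f"truth_A_{cond}.tsv"
        A.to_csv(p, sep="\t", float_format="%.10g")
        paths[f"truth_A_{cond}"] = p
    return paths
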