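"""Consensus gLV interaction-network inference from abundance profiles.

The discrete (Ricker-form) generalized Lotka-Volterra model

    x_i(t+1) = x_i(t) * exp(r_i + sum_j a_ij x_j(t))

linearises on log-ratios: y_i(t) = ln x_i(t+1) - ln x_i(t) is linear in the
abundances x_j(t) with intercept r_i.  For each target taxon i a sparse
coefficient vector is selected by forward stepwise regression under an
information criterion (BIC by default), which keeps the fitted networks far
sparser than the taxon count.

Field surveys are rarely true time series.  Following the pseudo-time-series
idea, samples are arranged into an ordering (by season, then site, then
replicate), the fit is repeated over B random within-season shufflings that
preserve the dry -> rainy direction, and only edges selected with a
consistent sign in at least a fraction f of the orderings enter the
*consensus network*.  Edge j -> i means taxon j affects taxon i; its weight
is the support fraction and its coefficient the median fitted a_ij.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError

__all__ = [
    "InferenceConfig",
    "InteractionNetwork",
    "build_design",
    "fit_taxon",
    "infer_consensus_network",
    "write_network",
    "read_network",
]

_SEASON_ORDER = {"dry": 0, "rainy": 1}


@dataclass(frozen=True)
class InferenceConfig:
    """Knobs of the consensus inference.

    pseudocount
        value substituted for zero proportions before taking logs; ``None``
        uses half the smallest nonzero value in the table.
    n_orderings
        number B of sample orderings (the first is the canonical
        season/site/replicate order, the rest random within-season shuffles).
    consensus_threshold
        minimum fraction f of orderings that must select an edge with the
        same sign.
    max_parents
        cap on selected predictors per target taxon.
    selection_criterion
        "bic" or "aic" for the forward search.
    """

    pseudocount: float | None = None
    n_orderings: int = 20
    consensus_threshold: float = 0.3
    max_parents: int = 5
    selection_criterion: str = "bic"

    def __post_init__(self):
        if not 0 < self.consensus_threshold <= 1:
            raise ParameterError("consensus_threshold must lie in (0, 1]")
        if self.n_orderings < 1:
            raise ParameterError("n_orderings must be >= 1")
        if self.pseudocount is not None and self.pseudocount <= 0:
            raise ParameterError("pseudocount must be positive")
        if self.selection_criterion not in ("bic", "aic"):
            raise ParameterError("selection_criterion must be 'bic' or 'aic'")


@dataclass
class InteractionNetwork:
    """Directed signed interaction graph plus per-taxon self terms.

    Edges carry ``sign`` (+1/-1), ``weight`` (consensus support in (0, 1])
    and ``coefficient`` (median fitted a_ij).  Self-interactions a_ii are not
    edges; they live in ``self_terms``.
    """

    graph: nx.DiGraph
    self_terms: dict = field(default_factory=dict)
    growth_rates: dict = field(default_factory=dict)

    def __post_init__(self):
        for u, v, d in self.graph.edges(data=True):
            if u == v:
                raise ParameterError("self-loops must go to self_terms, not edges")
            if d.get("sign") not in (1, -1):
                raise ParameterError(f"edge {u}->{v} missing a +-1 sign")
            if not 0 < d.get("weight", 1) <= 1:
                raise ParameterError(f"edge {u}->{v} weight outside (0, 1]")

    @property
    def order(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def size(self) -> int:
        return self.graph.number_of_edges()

    def to_edgelist(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "sign": d["sign"],
             "weight": d["weight"], "coefficient": d["coefficient"]}
            for u, v, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["source", "target", "sign", "weight", "coefficient"])


def build_design(
    series: pd.DataFrame, pseudocount: float | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Turn an ordered taxa x samples table into regression targets and design.

    Returns ``(Y, X)`` where row i of ``Y`` holds y_i(t) = ln x_i(t+1) -
    ln x_i(t) for t = 0..T-1 and ``X`` (T x n_taxa) holds the abundances
    x_j(t); the intercept column is added by the fitting step.  Zeros are
    replaced by ``pseudocount`` before the log (default: half the smallest
    nonzero entry).
    """
    if series.shape[1] < 3:
        raise ParameterError("need at least 3 ordered samples")
    vals = series.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ParameterError("abundances must be non-negative")
    if pseudocount is None:
        nz = vals[vals > 0]
        if nz.size == 0:
            raise ParameterError("all-zero table")
        pseudocount = nz.min() / 2.0
    filled = np.where(vals > 0, vals, pseudocount)
    y = np.log(filled[:, 1:]) - np.log(filled[:, :-1])
    X = vals[:, :-1].T  # predictors are the observed (unfilled) abundances
    Y = pd.DataFrame(y, index=series.index)
    return Y, X


def _criterion(rss: float, n: int, k: int, kind: str, floor: float = 0.0) -> float:
    # Gaussian log-likelihood information criterion; k counts all coefficients.
    # rss is floored at the numerical-precision level of the response so that
    # exact fits compare by parameter count alone, not by machine noise.
    rss = max(rss, floor, 1e-300)
    ll = n * np.log(rss / n)
    return ll + (np.log(n) if kind == "bic" else 2.0) * k


def fit_taxon(
    y: np.ndarray, X: np.ndarray, config: InferenceConfig = InferenceConfig()
) -> tuple[dict, float]:
    """Forward stepwise sparse regression of one taxon's log-ratio response.

    Builds the forward path greedily from the intercept-only model: at each
    step the candidate column minimizing the selection criterion is appended
    (ties broken by the lowest column index); when no single column improves
    the criterion the path is still extended by the best RSS-reducing column,
    because an interaction can look weak until its partners are in the model.
    The reported model is the criterion-minimizing prefix of the path, after
    a backward pass that drops any column whose removal improves the
    criterion.  Coefficients come from OLS on the final selected set.

    Returns ``(coefs, intercept)`` with ``coefs`` mapping column index ->
    fitted a_ij.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    usable = []
    for j in range(X.shape[1]):
        if np.ptp(X[:, j]) == 0:
            warnings.warn(f"constant design column {j} skipped", stacklevel=2)
        else:
            usable.append(j)
    ones = np.ones((n, 1))
    # relative RSS floor: residuals below ~1e-12 of the response scale are
    # numerically zero, so exact fits are compared by parameter count only
    floor = float(y @ y) * 1e-24

    def rss_of(cols: list[int]) -> float:
        M = np.column_stack([ones] + [X[:, c] for c in cols])
        resid = y - M @ np.linalg.lstsq(M, y, rcond=None)[0]
        return float(resid @ resid)

    def crit_of(cols: list[int], rss: float | None = None) -> float:
        if rss is None:
            rss = rss_of(cols)
        return _criterion(rss, n, len(cols) + 1, config.selection_criterion, floor)

    path: list[int] = []
    best_prefix: list[int] = []
    best_crit = crit_of([])
    # explore past the cap: a column picked early may only become redundant
    # (and prunable) once the model is complete; the cap binds after pruning
    budget = min(len(usable), config.max_parents * 2)
    while len(path) < budget:
        cand = [(crit_of(path + [j], r), r, j)
                for j in usable if j not in path
                for r in (rss_of(path + [j]),)]
        crit, _, j = min(cand, key=lambda t: (t[0], t[2]))
        improving = crit < best_crit - 1e-12
        if not improving:
            # extend by best RSS instead; the prefix choice below ignores
            # these steps unless a later exact fit vindicates them
            _, _, j = min(cand, key=lambda t: (t[1], t[2]))
            crit = crit_of(path + [j])
        path.append(j)
        if crit < best_crit - 1e-12:
            best_prefix = list(path)
            best_crit = crit
    selected = list(best_prefix)
    # backward pruning, dropping the most dispensable column first
    improved = True
    while improved and selected:
        improved = False
        best_drop, best_drop_crit = None, best_crit
        for j in selected:
            crit = crit_of([c for c in selected if c != j])
            if crit < best_drop_crit - 1e-12:
                best_drop, best_drop_crit = j, crit
        if best_drop is not None:
            selected.remove(best_drop)
            best_crit = best_drop_crit
            improved = True
    while len(selected) > config.max_parents:  # enforce the parent cap
        drop = min(selected, key=lambda j: (crit_of([c for c in selected if c != j]), j))
        selected.remove(drop)
    selected.sort()
    M = np.column_stack([ones] + [X[:, c] for c in selected])
    beta = np.linalg.lstsq(M, y, rcond=None)[0]
    coefs = {j: float(beta[k + 1]) for k, j in enumerate(selected)}
    return coefs, float(beta[0])


def _canonical_order(samples: pd.Index, metadata: pd.DataFrame | None) -> list:
    if metadata is None:
        return list(samples)
    meta = metadata.loc[samples]
    key = sorted(
        samples,
        key=lambda s: (
            _SEASON_ORDER.get(str(meta.loc[s].get("season", "")), 0),
            str(meta.loc[s].get("site", "")),
            str(meta.loc[s].get("replicate", "")),
            str(s),
        ),
    )
    return key


def _random_order(samples: list, metadata: pd.DataFrame | None, rng: np.random.Generator) -> list:
    """Shuffle within season, keeping every dry sample before every rainy one."""
    if metadata is None or "season" not in metadata.columns:
        out = list(samples)
        rng.shuffle(out)
        return out
    seasons = metadata.loc[samples, "season"].astype(str)
    out = []
    for season in sorted(seasons.unique(), key=lambda s: _SEASON_ORDER.get(s, 99)):
        block = [s for s in samples if seasons[s] == season]
        rng.shuffle(block)
        out.extend(block)
    return out


def infer_consensus_network(
    relab: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    subset: dict | None = None,
    config: InferenceConfig = InferenceConfig(),
    seed=None,
) -> InteractionNetwork:
    """Infer the consensus signed interaction network for one condition.

    ``relab`` is a taxa x samples table (proportions or abundances);
    ``subset`` restricts samples by metadata equality, e.g.
    ``{"soil_type": "rhizosphere", "season": "dry"}``.  For b = 1..B an
    ordering is drawn (b=1 canonical, the rest random within-season
    shuffles), the gLV regression is fitted for every target taxon, and the
    per-ordering selections are merged: edge j -> i survives iff it is
    selected with a consistent sign in at least ``config.consensus_threshold``
    of the orderings.
    """
    samples = relab.columns
    if subset:
        if metadata is None:
            raise ParameterError("subset selection requires metadata")
        mask = pd.Series(True, index=metadata.index)
        for k, v in subset.items():
            mask &= metadata[k].astype(str) == str(v)
        samples = relab.columns.intersection(metadata.index[mask])
    if len(samples) < 4:
        raise ParameterError(f"need >= 4 samples in the subset, got {len(samples)}")
    sub = relab[list(samples)]
    keep = sub.sum(axis=1) > 0
    if not keep.any():
        raise ParameterError("no taxa with nonzero abundance in subset")
    sub = sub.loc[keep]
    taxa = list(sub.index)
    meta = metadata.loc[list(samples)] if metadata is not None else None

    rng = np.random.default_rng(seed)
    B = config.n_orderings
    canonical = _canonical_order(sub.columns, meta)
    pos = {(j, i): [] for j in range(len(taxa)) for i in range(len(taxa))}
    neg = {k: [] for k in pos}
    intercepts = np.zeros(len(taxa))
    selfs = {t: [] for t in taxa}
    for b in range(B):
        order = canonical if b == 0 else _random_order(canonical, meta, rng)
        Y, X = build_design(sub[order], config.pseudocount)
        for i, taxon in enumerate(taxa):
            coefs, r_hat = fit_taxon(Y.iloc[i].to_numpy(), X, config)
            intercepts[i] += r_hat / B
            for j, a in coefs.items():
                if j == i:
                    selfs[taxon].append(a)
                elif a > 0:
                    pos[(j, i)].append(a)
                elif a < 0:
                    neg[(j, i)].append(a)

    G = nx.DiGraph()
    G.add_nodes_from(taxa)
    need = config.consensus_threshold * B
    for (j, i) in sorted(pos):
        np_, nn = len(pos[(j, i)]), len(neg[(j, i)])
        if np_ < need and nn < need:
            continue
        if np_ == nn:  # ambiguous sign at equal support: no consensus
            continue
        vals = pos[(j, i)] if np_ > nn else neg[(j, i)]
        G.add_edge(
            taxa[j], taxa[i],
            sign=1 if np_ > nn else -1,
            weight=len(vals) / B,
            coefficient=float(np.median(vals)),
        )
    return InteractionNetwork(
        graph=G,
        self_terms={t: float(np.median(v)) for t, v in selfs.items() if v},
        growth_rates={t: float(intercepts[i]) for i, t in enumerate(taxa)},
    )


def write_network(net: InteractionNetwork, path: str | Path, graphml: bool = False) -> None:
    """Write the edge list as TSV (or GraphML when ``graphml=True``)."""
    path = Path(path)
    if graphml or path.suffix == ".graphml":
        G = net.graph.copy()
        G.graph["self_terms"] = ",".join(f"{k}:{v:.6g}" for k, v in sorted(net.self_terms.items()))
        nx.write_graphml(G, path)
    else:
        with open(path, "w") as fh:
            fh.write("# nodes: " + "\t".join(map(str, net.graph.nodes)) + "\n")
            net.to_edgelist().to_csv(fh, sep="\t", index=False)


def read_network(path: str | Path) -> InteractionNetwork:
    path = Path(path)
    if path.suffix == ".graphml":
        G = nx.read_graphml(path)
        G = nx.DiGraph(G)
        G.graph.pop("self_terms", None)
        for _, _, d in G.edges(data=True):
            d["sign"] = int(d["sign"])
        return InteractionNetwork(graph=G)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# nodes:"):
            raise FormatError(f"{path}: missing node header line")
        nodes = first.split(":", 1)[1].strip().split("\t") if first.split(":", 1)[1].strip() else []
        df = pd.read_csv(fh, sep="\t")
    G = nx.DiGraph()
    G.add_nodes_from(nodes)
    for row in df.itertuples(index=False):
        G.add_edge(row.source, row.target, sign=int(row.sign),
                   weight=float(row.weight), coefficient=float(row.coefficient))
    return InteractionNetwork(graph=G)
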