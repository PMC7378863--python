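"""Network analytics: global properties, hubs, communities, degree law, motifs.

Computes the classic descriptive vector for a directed interaction graph —
order, size, density, mean degree, clustering, diameter/radius, components,
cycles, a deterministic maximal independent set, minimum vertex/edge cuts,
modularity and communities, and a discrete power-law fit of the degree
distribution.  Distance- and cut-type properties are taken on the undirected
projection (antiparallel edge pairs collapse to one edge), and on the
largest connected component when the graph is disconnected.

Hubs are the degree maximizers: keystone candidates with maximal total,
in- (most affected by the community) and out-degree (affecting the most
other taxa).  The motif census counts the 13 connected 3-node directed
subgraph classes and scores them against a degree-preserving edge-switch
null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import greedy_modularity_communities, modularity
from scipy.optimize import minimize_scalar
from scipy.special import zeta

from .errors import ParameterError
from .inference import InteractionNetwork

__all__ = [
    "NetworkFeatureReport",
    "HubReport",
    "PowerlawFit",
    "global_metrics",
    "identify_hubs",
    "detect_communities",
    "maximal_independent_set",
    "powerlaw_fit",
    "motif_census",
    "TRIAD_CLASSES",
]

#: the 13 connected 3-node directed subgraph (triad) isomorphism classes
TRIAD_CLASSES = (
    "021D", "021U", "021C", "111D", "111U", "030T", "030C",
    "201", "120D", "120U", "120C", "210", "300",
)


def _as_digraph(net) -> nx.DiGraph:
    G = net.graph if isinstance(net, InteractionNetwork) else net
    if G.number_of_nodes() == 0:
        raise ParameterError("empty graph")
    return G


@dataclass(frozen=True)
class PowerlawFit:
    alpha: float
    ks: float
    degenerate: bool = False


@dataclass
class NetworkFeatureReport:
    """The full property vector of one directed network."""

    order: int
    size: int
    density: float
    mean_degree: float            # directed convention: size / order
    mean_total_degree: float      # 2 * size / order
    clustering: float
    diameter: int | None
    radius: int | None
    n_components: int
    has_cycles: bool
    n_cyclic_nodes: int
    independent_set: tuple = ()
    independent_set_size: int = 0
    vertex_cut: tuple = ()
    edge_cut: tuple = ()
    modularity: float = 0.0
    n_modules: int = 0
    communities: dict = field(default_factory=dict)
    powerlaw_alpha: float | None = None
    powerlaw_ks: float | None = None

    def numeric_properties(self) -> dict:
        """Scalar properties, for null-model comparison and JSON reports."""
        return {
            "order": float(self.order),
            "size": float(self.size),
            "density": self.density,
            "mean_degree": self.mean_degree,
            "mean_total_degree": self.mean_total_degree,
            "clustering": self.clustering,
            "diameter": None if self.diameter is None else float(self.diameter),
            "radius": None if self.radius is None else float(self.radius),
            "n_components": float(self.n_components),
            "n_cyclic_nodes": float(self.n_cyclic_nodes),
            "independent_set_size": float(self.independent_set_size),
            "vertex_cut_size": float(len(self.vertex_cut)),
            "edge_cut_size": float(len(self.edge_cut)),
            "modularity": self.modularity,
            "n_modules": float(self.n_modules),
            "powerlaw_alpha": self.powerlaw_alpha,
            "powerlaw_ks": self.powerlaw_ks,
        }


@dataclass(frozen=True)
class HubReport:
    hubs_total: tuple
    hubs_in: tuple
    hubs_out: tuple
    max_total: int
    max_in: int
    max_out: int


def maximal_independent_set(U: nx.Graph) -> list:
    """Deterministic maximal independent set: greedy by ascending degree,
    ties broken lexicographically by node label."""
    chosen, blocked = [], set()
    for v in sorted(U.nodes, key=lambda v: (U.degree(v), str(v))):
        if v not in blocked:
            chosen.append(v)
            blocked.add(v)
            blocked.update(U.neighbors(v))
    return sorted(chosen, key=str)


def detect_communities(net) -> tuple[dict, float]:
    """Greedy (CNM) modularity communities on the undirected projection.

    Returns a node -> module-id map (modules numbered by decreasing size,
    ties by smallest member label) and the Newman modularity of that
    partition.  An edgeless graph yields singleton modules with modularity 0
    by convention.
    """
    G = _as_digraph(net)
    U = nx.Graph(G.to_undirected())
    if U.number_of_edges() == 0:
        return {v: i for i, v in enumerate(sorted(U.nodes, key=str))}, 0.0
    comms = [set(c) for c in greedy_modularity_communities(U)]
    comms.sort(key=lambda c: (-len(c), str(min(c, key=str))))
    part = {v: i for i, c in enumerate(comms) for v in c}
    return part, float(modularity(U, comms))


def global_metrics(
    net,
    include_cuts: bool = True,
    include_powerlaw: bool = True,
) -> NetworkFeatureReport:
    """Compute the full property vector of a directed network.

    ``include_cuts=False`` skips the (max-flow based) minimum vertex/edge
    cuts, the most expensive entries, for large ensemble sweeps.
    """
    G = _as_digraph(net)
    n = G.number_of_nodes()
    m = G.number_of_edges()
    U = nx.Graph(G.to_undirected())
    density = m / (n * (n - 1)) if n > 1 else 0.0
    clustering = nx.average_clustering(U) if n > 0 else 0.0

    comps = sorted(nx.connected_components(U), key=lambda c: (-len(c), str(min(c, key=str))))
    big = U.subgraph(comps[0])
    if big.number_of_nodes() > 1:
        ecc = nx.eccentricity(big)
        diameter, radius = max(ecc.values()), min(ecc.values())
    else:
        diameter = radius = 0

    scc_big = [c for c in nx.strongly_connected_components(G) if len(c) >= 2]
    n_cyclic = sum(len(c) for c in scc_big)

    mis = maximal_independent_set(U)
    vertex_cut: tuple = ()
    edge_cut: tuple = ()
    if include_cuts and big.number_of_nodes() > 1:
        bg = nx.Graph(big)
        if bg.number_of_nodes() > 2 and not _is_complete(bg):
            vertex_cut = tuple(sorted(nx.minimum_node_cut(bg), key=str))
        edge_cut = tuple(sorted((tuple(sorted(e, key=str)) for e in nx.minimum_edge_cut(bg)), key=str))

    part, Q = detect_communities(G)
    alpha = ks = None
    if include_powerlaw:
        deg = [d for _, d in G.degree() if d > 0]
        if len(deg) >= 5:
            fit = powerlaw_fit(deg)
            alpha, ks = fit.alpha, fit.ks

    return NetworkFeatureReport(
        order=n, size=m, density=density,
        mean_degree=m / n, mean_total_degree=2 * m / n,
        clustering=float(clustering),
        diameter=diameter, radius=radius,
        n_components=nx.number_connected_components(U),
        has_cycles=n_cyclic > 0, n_cyclic_nodes=n_cyclic,
        independent_set=tuple(mis), independent_set_size=len(mis),
        vertex_cut=vertex_cut, edge_cut=edge_cut,
        modularity=Q, n_modules=len(set(part.values())), communities=part,
        powerlaw_alpha=alpha, powerlaw_ks=ks,
    )


def _is_complete(U: nx.Graph) -> bool:
    n = U.number_of_nodes()
    return U.number_of_edges() == n * (n - 1) // 2


def identify_hubs(net) -> HubReport:
    """Degree-maximizing nodes (self-loops excluded); ties all reported."""
    G = _as_digraph(net)
    loops = set(nx.selfloop_edges(G))
    din = dict(G.in_degree())
    dout = dict(G.out_degree())
    for u, v in loops:
        din[v] -= 1
        dout[u] -= 1
    dtot = {v: din[v] + dout[v] for v in G}

    def top(d):
        mx = max(d.values())
        return tuple(sorted((v for v, k in d.items() if k == mx), key=str)), mx

    hubs_total, max_total = top(dtot)
    hubs_in, max_in = top(din)
    hubs_out, max_out = top(dout)
    return HubReport(hubs_total, hubs_in, hubs_out, max_total, max_in, max_out)


def powerlaw_fit(degrees) -> PowerlawFit:
    """Discrete power-law MLE with xmin = 1 plus a KS goodness distance.

    Maximizes  L(alpha) = -n log zeta(alpha) - alpha * sum(log k)  over
    alpha in (1, 20]; the KS statistic compares the empirical CDF of the
    degrees with the fitted zeta CDF.  An all-equal degree sequence is
    degenerate (the likelihood has no interior optimum for all-ones) and is
    flagged as such.
    """
    deg = np.asarray([d for d in degrees if d > 0], dtype=float)
    if deg.size == 0:
        raise ParameterError("no nonzero degrees to fit")
    if deg.size < 5:
        raise ParameterError("need at least 5 nonzero degrees")
    slog = float(np.log(deg).sum())
    n = deg.size

    def nll(a):
        return n * np.log(zeta(a, 1)) + a * slog

    degenerate = len(set(deg.tolist())) == 1
    res = minimize_scalar(nll, bounds=(1.0001, 20.0), method="bounded")
    alpha = float(res.x)
    kmax = int(deg.max())
    ks_grid = np.arange(1, kmax + 1)
    pmf = ks_grid ** (-alpha) / zeta(alpha, 1)
    cdf_fit = np.cumsum(pmf)
    cdf_emp = np.searchsorted(np.sort(deg), ks_grid, side="right") / n
    ks = float(np.max(np.abs(cdf_emp - cdf_fit)))
    return PowerlawFit(alpha=alpha, ks=ks, degenerate=degenerate)


def _census13(G: nx.DiGraph) -> dict:
    c = nx.triadic_census(G)
    return {k: c[k] for k in TRIAD_CLASSES}


def motif_census(net, n_random: int = 100, seed=None) -> pd.DataFrame:
    """Triad census with z-scores against a degree-preserving null.

    Null replicates are degree-sequence-preserving randomizations obtained by
    directed edge switches (10x the edge count of attempted swaps per
    replicate).  z = (obs - mean_null) / sd_null; classes whose null count
    never varies get z = NaN.
    """
    G = _as_digraph(net)
    if G.number_of_nodes() < 3:
        raise ParameterError("motif census needs >= 3 nodes")
    obs = _census13(G)
    m = G.number_of_edges()
    rng = np.random.default_rng(seed)
    null_counts = {k: [] for k in TRIAD_CLASSES}
    for _ in range(n_random):
        H = G.copy()
        if m >= 3 and G.number_of_nodes() >= 4:
            try:
                nx.directed_edge_swap(
                    H, nswap=10 * m, max_tries=1000 * m,
                    seed=int(rng.integers(2**31 - 1)),
                )
            except nx.NetworkXException:
                pass  # too few switchable triples; null replicate stays as-is
        for k, v in _census13(H).items():
            null_counts[k].append(v)
    rows = []
    for k in TRIAD_CLASSES:
        arr = np.asarray(null_counts[k], dtype=float)
        mu, sd = float(arr.mean()), float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        z = (obs[k] - mu) / sd if sd > 0 else np.nan
        rows.append({"triad": k, "observed": obs[k], "null_mean": mu, "null_sd": sd, "z": z})
    return pd.DataFrame(rows).set_index("triad")
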