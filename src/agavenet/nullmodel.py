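"""Random-network null model for network-property significance.

An observed interaction network is compared against an ensemble (default one
hundred) of simple directed Erdos-Renyi G(n, m) graphs matched on order
(node count) and size (edge count) — the minimal null holding exactly the
matched quantities fixed.  Each property is summarised by its null mean and
SD, and an empirical two-sided p-value with the add-one correction

    p_tail = (1 + #{null at least as extreme}) / (N + 1),
    p = min(1, 2 * min(p_low, p_high)),

so the smallest attainable p at N = 100 is 2/101.  Matched constraints
(order, size, hence density) are identical in every replicate and can never
be flagged.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ParameterError
from .network import NetworkFeatureReport, global_metrics

__all__ = ["random_ensemble", "ensemble_reports", "compare_to_null", "null_summary"]

#: properties identical across the matched ensemble by construction
MATCHED = ("order", "size", "density")


def random_ensemble(order: int, size: int, n: int = 100, seed=None) -> list[nx.DiGraph]:
    """Draw ``n`` uniform simple directed graphs with the given order and size."""
    if order < 1:
        raise ParameterError("order must be >= 1")
    max_edges = order * (order - 1)
    if not 0 <= size <= max_edges:
        raise ParameterError(f"size must lie in [0, {max_edges}] for order {order}")
    rng = np.random.default_rng(seed)
    return [
        nx.gnm_random_graph(order, size, directed=True, seed=int(rng.integers(2**31 - 1)))
        for _ in range(n)
    ]


def ensemble_reports(
    graphs: list[nx.DiGraph], include_cuts: bool = True
) -> list[NetworkFeatureReport]:
    return [global_metrics(g, include_cuts=include_cuts) for g in graphs]


def compare_to_null(
    observed: NetworkFeatureReport,
    ensemble: list[NetworkFeatureReport],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-property null mean/SD, empirical two-sided p and significance flag.

    Properties undefined on some null replicates (e.g. the power-law exponent
    of a graph with too few connected nodes) are summarised over the
    replicates where they exist; a property absent from *every* replicate is
    an error.
    """
    if not ensemble:
        raise ParameterError("ensemble is empty")
    obs = observed.numeric_properties()
    rows = []
    for prop, value in obs.items():
        null_vals = [r.numeric_properties().get(prop) for r in ensemble]
        if all(v is None for v in null_vals):
            if value is None:  # undefined everywhere (e.g. degree-law on a tiny graph)
                rows.append({"property": prop, "observed": np.nan, "null_mean": np.nan,
                             "null_sd": np.nan, "n_null": 0, "p": np.nan, "significant": False})
                continue
            raise ParameterError(f"property {prop!r} missing from every ensemble report")
        arr = np.asarray([v for v in null_vals if v is not None], dtype=float)
        if value is None:
            rows.append({"property": prop, "observed": np.nan, "null_mean": float(arr.mean()),
                         "null_sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
                         "n_null": len(arr), "p": np.nan, "significant": False})
            continue
        N = len(arr)
        p_low = (1 + int((arr <= value).sum())) / (N + 1)
        p_high = (1 + int((arr >= value).sum())) / (N + 1)
        p = min(1.0, 2.0 * min(p_low, p_high))
        rows.append(
            {
                "property": prop,
                "observed": value,
                "null_mean": float(arr.mean()),
                "null_sd": float(arr.std(ddof=1)) if N > 1 else 0.0,
                "n_null": N,
                "p": p,
                "significant": bool(p <= alpha) and prop not in MATCHED,
            }
        )
    return pd.DataFrame(rows).set_index("property")


def null_summary(
    net,
    n: int = 100,
    alpha: float = 0.05,
    seed=None,
    include_cuts: bool = True,
) -> pd.DataFrame:
    """Convenience wrapper: observed report + matched ensemble + comparison."""
    observed = global_metrics(net, include_cuts=include_cuts)
    graphs = random_ensemble(observed.order, observed.size, n=n, seed=seed)
    reports = ensemble_reports(graphs, include_cuts=include_cuts)
    return compare_to_null(observed, reports, alpha=alpha)
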