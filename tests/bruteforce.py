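"""Independent brute-force reference implementations used as test oracles.

Everything here works from raw edge lists with explicit loops and
exhaustive enumeration — deliberately naive, O(n^3) or worse — so the
package's networkx-backed analytics can be checked against definitions
rather than against another library call.
"""

from __future__ import annotations

import itertools

import numpy as np


def und_edges(edges):
    """Undirected projection of a directed edge list (no self-loops)."""
    return {frozenset((u, v)) for u, v in edges if u != v}


def density(n, edges):
    return len(set(edges)) / (n * (n - 1)) if n > 1 else 0.0


def clustering(nodes, edges):
    """Average local clustering on the undirected projection."""
    ue = und_edges(edges)
    adj = {v: set() for v in nodes}
    for e in ue:
        u, v = tuple(e)
        adj[u].add(v)
        adj[v].add(u)
    total = 0.0
    for v in nodes:
        nb = sorted(adj[v])
        d = len(nb)
        if d < 2:
            continue
        links = sum(
            1 for a, b in itertools.combinations(nb, 2) if frozenset((a, b)) in ue
        )
        total += 2 * links / (d * (d - 1))
    return total / len(nodes)


def components(nodes, edges):
    """Connected components of the undirected projection (list of sets)."""
    adj = {v: set() for v in nodes}
    for e in und_edges(edges):
        u, v = tuple(e)
        adj[u].add(v)
        adj[v].add(u)
    seen, comps = set(), []
    for v in nodes:
        if v in seen:
            continue
        stack, comp = [v], set()
        while stack:
            w = stack.pop()
            if w in comp:
                continue
            comp.add(w)
            stack.extend(adj[w] - comp)
        seen |= comp
        comps.append(comp)
    return comps


def _bfs_dists(src, adj):
    dist = {src: 0}
    frontier = [src]
    while frontier:
        nxt = []
        for v in frontier:
            for w in adj[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    nxt.append(w)
        frontier = nxt
    return dist


def diameter_radius(nodes, edges):
    """(diameter, radius) of the largest undirected component."""
    comps = sorted(components(nodes, edges), key=lambda c: (-len(c), sorted(map(str, c))))
    big = comps[0]
    if len(big) == 1:
        return 0, 0
    adj = {v: set() for v in big}
    for e in und_edges(edges):
        u, v = tuple(e)
        if u in big:
            adj[u].add(v)
            adj[v].add(u)
    eccs = []
    for v in big:
        dist = _bfs_dists(v, adj)
        eccs.append(max(dist.values()))
    return max(eccs), min(eccs)


def cyclic_nodes(nodes, edges):
    """Nodes lying on a directed cycle (length >= 2): reachable from themselves."""
    adj = {v: set() for v in nodes}
    for u, v in edges:
        if u != v:
            adj[u].add(v)
    out = set()
    for v in nodes:
        # BFS from successors of v back to v
        stack, seen = list(adj[v]), set()
        while stack:
            w = stack.pop()
            if w == v:
                out.add(v)
                break
            if w in seen:
                continue
            seen.add(w)
            stack.extend(adj[w])
    return out


def degrees(nodes, edges):
    """(in, out, total) degree dicts, self-loops excluded."""
    din = {v: 0 for v in nodes}
    dout = {v: 0 for v in nodes}
    for u, v in edges:
        if u != v:
            dout[u] += 1
            din[v] += 1
    dtot = {v: din[v] + dout[v] for v in nodes}
    return din, dout, dtot


def modularity(nodes, edges, partition):
    """Newman modularity of a node->module map on the undirected projection."""
    ue = und_edges(edges)
    m = len(ue)
    if m == 0:
        return 0.0
    deg = {v: 0 for v in nodes}
    for e in ue:
        u, v = tuple(e)
        deg[u] += 1
        deg[v] += 1
    q = 0.0
    modules = set(partition.values())
    for c in modules:
        members = {v for v in nodes if partition[v] == c}
        lc = sum(1 for e in ue if set(e) <= members)
        dc = sum(deg[v] for v in members)
        q += lc / m - (dc / (2 * m)) ** 2
    return q


def is_maximal_independent(nodes, edges, mis):
    ue = und_edges(edges)
    mis = set(mis)
    for a, b in itertools.combinations(sorted(mis, key=str), 2):
        if frozenset((a, b)) in ue:
            return False
    adj = {v: set() for v in nodes}
    for e in ue:
        u, v = tuple(e)
        adj[u].add(v)
        adj[v].add(u)
    return all(v in mis or adj[v] & mis for v in nodes)


def min_vertex_cut_size(nodes, edges):
    """Smallest vertex set whose removal disconnects the (connected) projection.

    Returns None for complete graphs (no cut exists).
    """
    nodes = sorted(nodes, key=str)
    ue = und_edges(edges)
    if len(nodes) < 3:
        return None
    for k in range(0, len(nodes) - 1):
        for cut in itertools.combinations(nodes, k):
            rest = [v for v in nodes if v not in cut]
            if len(rest) < 2:
                continue
            sub = {e for e in ue if not (set(e) & set(cut))}
            if len(components(rest, [tuple(e) for e in sub])) > 1:
                return k
    return None


def min_edge_cut_size(nodes, edges):
    """Smallest undirected edge set whose removal disconnects the projection."""
    ue = sorted(und_edges(edges), key=lambda e: sorted(map(str, e)))
    if not ue:
        return 0
    for k in range(0, len(ue) + 1):
        for cut in itertools.combinations(range(len(ue)), k):
            rest = [tuple(ue[i]) for i in range(len(ue)) if i not in cut]
            if len(components(list(nodes), rest)) > 1:
                return k
    return len(ue)


# --- triad census ---------------------------------------------------------

def _code(edges3, perm):
    """6-bit adjacency code of a 3-node digraph under a node permutation."""
    a, b, c = perm
    pairs = [(a, b), (b, a), (a, c), (c, a), (b, c), (c, b)]
    return tuple(int(p in edges3) for p in pairs)


def _canon(edges3, trio):
    return min(_code(edges3, p) for p in itertools.permutations(trio))


def triad_class_codes():
    """Canonical code -> triad name for all 16 classes, built from scratch."""
    reps = {
        "003": [],
        "012": [(0, 1)],
        "102": [(0, 1), (1, 0)],
        "021D": [(1, 0), (1, 2)],
        "021U": [(0, 1), (2, 1)],
        "021C": [(0, 1), (1, 2)],
        "111D": [(0, 1), (1, 0), (2, 1)],
        "111U": [(0, 1), (1, 0), (1, 2)],
        "030T": [(0, 1), (2, 1), (0, 2)],
        "030C": [(0, 1), (1, 2), (2, 0)],
        "201": [(0, 1), (1, 0), (0, 2), (2, 0)],
        "120D": [(1, 0), (1, 2), (0, 2), (2, 0)],
        "120U": [(0, 1), (2, 1), (0, 2), (2, 0)],
        "120C": [(0, 1), (1, 2), (0, 2), (2, 0)],
        "210": [(0, 1), (1, 0), (1, 2), (0, 2), (2, 0)],
        "300": [(0, 1), (1, 0), (1, 2), (2, 1), (0, 2), (2, 0)],
    }
    return {_canon(set(e), (0, 1, 2)): name for name, e in reps.items()}


_CODES = triad_class_codes()


def triad_census(nodes, edges):
    """Counts of all 16 triad classes by exhaustive triple enumeration."""
    eset = {(u, v) for u, v in edges if u != v}
    counts = {name: 0 for name in _CODES.values()}
    for trio in itertools.combinations(sorted(nodes, key=str), 3):
        sub = {(u, v) for u, v in eset if u in trio and v in trio}
        counts[_CODES[_canon(sub, trio)]] += 1
    return counts


# --- diversity / anova ----------------------------------------------------

def shannon(counts):
    p = np.asarray(counts, float)
    p = p[p > 0] / p.sum()
    return float(-(p * np.log(p)).sum())


def chao1(counts):
    v = np.asarray(counts)
    s = int((v > 0).sum())
    f1 = int((v == 1).sum())
    f2 = int((v == 2).sum())
    return s + f1 * (f1 - 1) / (2 * (f2 + 1))


def simpson(counts):
    p = np.asarray(counts, float)
    p = p / p.sum()
    return float(1 - (p ** 2).sum())
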