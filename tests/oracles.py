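"""Independent reference implementations used to cross-check the package.

These are deliberately written in a different style from the library —
plain dictionaries and explicit loops instead of vectorised linear algebra —
so that agreement is evidence of correctness rather than shared code.
"""

from __future__ import annotations

import itertools

import networkx as nx


def walk_curves(edges, roles, source, t_max=100, mass_tol=1e-6):
    """Absorbing random walk by explicit per-node bookkeeping.

    edges: iterable of (u, v, weight); roles: node -> role string.
    Returns (curves, t_stop) with curves[node] the cumulative arrival list
    indexed by time step 0..t_stop.
    """
    nodes = sorted(roles)
    nbrs = {u: {} for u in nodes}
    for u, v, w in edges:
        nbrs[u][v] = w
        nbrs[v][u] = w
    out = {u: sum(nbrs[u].values()) for u in nodes}
    movable = {u: roles[u] != "tf" and out[u] > 0 for u in nodes}
    curves = {u: [0.0] for u in nodes}
    if not movable[source]:
        return curves, 0
    mass = {u: 0.0 for u in nodes}
    mass[source] = 1.0
    t_stop = 0
    for t in range(1, t_max + 1):
        new = {u: 0.0 for u in nodes}
        for u in nodes:
            if movable[u] and mass[u] > 0.0:
                for v, w in nbrs[u].items():
                    new[v] += mass[u] * w / out[u]
        for v in nodes:
            curves[v].append(curves[v][-1] + new[v])
            mass[v] = new[v] if movable[v] else mass[v] + new[v]
        t_stop = t
        if sum(mass[v] for v in nodes if movable[v]) < mass_tol:
            break
    return curves, t_stop


def t50_of_curve(curve, t_max=100):
    """First step reaching half of the final cumulative arrival."""
    total = curve[-1]
    if total <= 0.0:
        return t_max + 1
    for t in range(1, len(curve)):
        if curve[t] >= 0.5 * total - 1e-12:
            return t
    return t_max + 1


def walk_t50(edges, roles, source, t_max=100, mass_tol=1e-6):
    """node -> t50 for one source, via the plain-dict walk."""
    curves, _ = walk_curves(edges, roles, source, t_max, mass_tol)
    return {g: t50_of_curve(c, t_max) for g, c in curves.items()}


def auc_exhaustive(positive, negative):
    """AUC by counting every ordered (positive, negative) pair; ties half."""
    hits = 0.0
    for x in positive:
        for y in negative:
            if x < y:
                hits += 1.0
            elif x == y:
                hits += 0.5
    return hits / (len(positive) * len(negative))


def min_node_weight_path(graph: nx.Graph, weights, source, target):
    """Cheapest source->target path under node-sum cost (non-source nodes),
    by exhaustive simple-path enumeration; lexicographic tie-break."""
    best = None
    for path in nx.all_simple_paths(graph, source, target):
        cost = sum(weights[n] for n in path[1:])
        key = (cost, tuple(path))
        if best is None or key < best:
            best = key
    return best  # (cost, path) or None


def wilcoxon_exact_two_sided(x, y):
    """Two-sided rank-sum p by full enumeration of group assignments
    (tie-free inputs only)."""
    pooled = sorted(x) + sorted(y)
    assert len(set(pooled)) == len(pooled), "tie-free inputs required"
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    observed = sum(ranks[v] for v in x)
    n = len(x)
    all_ranks = [ranks[v] for v in pooled]
    sums = [sum(c) for c in itertools.combinations(all_ranks, n)]
    mean = sum(sums) / len(sums)
    extreme = sum(1 for s in sums if abs(s - mean) >= abs(observed - mean) - 1e-9)
    return extreme / len(sums)
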