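"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: plain set algebra, hand-rolled BFS
and explicit shortest-path enumeration, element-by-element TOPSIS loops.
None of it shares code with the package under test.
"""

from __future__ import annotations

import math
from collections import deque


# --------------------------------------------------------------------------
# Association coefficients from raw node/edge sets
# --------------------------------------------------------------------------

def assoc_counts_oracle(nodes_a, edges_a, nodes_b, edges_b, inter_edges=frozenset()):
    """NAA tallies by direct set intersection, with derived-edge lookup."""
    union_nodes = set(nodes_a) | set(nodes_b)
    union_edges = set(edges_a) | set(edges_b)
    derived = {
        e for e in inter_edges
        if e[0] in union_nodes and e[1] in union_nodes and e not in union_edges
    }
    return {
        "n_ab": len(union_nodes),
        "e_ab": len(union_edges) + len(derived),
        "n_r": len(set(nodes_a) & set(nodes_b)),
        "e_r": len(set(edges_a) & set(edges_b)),
        "e_d": len(derived),
    }


def assoc_coeff_oracle(counts):
    """C_N, C_E, C straight from the defining ratios."""
    c_n = counts["n_r"] / counts["n_ab"]
    if counts["e_ab"] == 0:
        return {"c_n": c_n, "c_e": None, "c": c_n}
    c_e = (counts["e_r"] + counts["e_d"]) / counts["e_ab"]
    return {"c_n": c_n, "c_e": c_e, "c": math.sqrt((c_n ** 2 + c_e ** 2) / 2)}


# --------------------------------------------------------------------------
# Shortest-path centralities by explicit path enumeration
# --------------------------------------------------------------------------

def _bfs_dist(adj, source):
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def _enumerate_shortest_paths(adj, dist, s, t):
    """All shortest s-t paths, walked backward along the BFS distance field."""
    if t not in dist:
        return []
    paths = []

    def back(node, tail):
        if node == s:
            paths.append((s, *reversed(tail)))
            return
        for u in adj[node]:
            if u in dist and dist[u] == dist[node] - 1:
                back(u, tail + [node])

    back(t, [])
    return paths


def centralities_oracle(nodes, edges):
    """Normalized betweenness, WF closeness, and edge betweenness.

    ``edges`` must be canonical sorted pairs.  Requires n >= 3 for the
    betweenness normalizations to be meaningful.
    """
    nodes = sorted(nodes)
    n = len(nodes)
    adj = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)

    node_btw = {v: 0.0 for v in nodes}
    edge_btw = {e: 0.0 for e in edges}
    closeness = {}

    dists = {s: _bfs_dist(adj, s) for s in nodes}
    for v in nodes:
        reach = {u for u in dists[v] if u != v}
        if not reach:
            closeness[v] = 0.0
        else:
            total = sum(dists[v][u] for u in reach)
            closeness[v] = (len(reach) / (n - 1)) * (len(reach) / total)

    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            paths = _enumerate_shortest_paths(adj, dists[s], s, t)
            if not paths:
                continue
            sigma = len(paths)
            for p in paths:
                for inner in p[1:-1]:
                    node_btw[inner] += 1.0 / sigma
                for a, b in zip(p, p[1:]):
                    e = (a, b) if a <= b else (b, a)
                    edge_btw[e] += 1.0 / sigma

    node_scale = (n - 1) * (n - 2) / 2.0
    edge_scale = n * (n - 1) / 2.0
    for v in nodes:
        node_btw[v] = node_btw[v] / node_scale if node_scale > 0 else 0.0
    for e in edges:
        edge_btw[e] /= edge_scale
    return node_btw, closeness, edge_btw


# --------------------------------------------------------------------------
# Entropy + TOPSIS, element by element
# --------------------------------------------------------------------------

def entropy_topsis_oracle(rows, labels=None):
    """Final TOPSIS indices from a list-of-lists matrix, recomputed stepwise."""
    n = len(rows)
    k = len(rows[0])
    # entropy weights
    entropy = []
    for j in range(k):
        col = [r[j] for r in rows]
        if all(x == col[0] for x in col):
            entropy.append(1.0)
            continue
        s = sum(col)
        e = 0.0
        for x in col:
            p = x / s
            if p > 0:
                e -= p * math.log(p)
        entropy.append(e / math.log(n))
    disp = [1.0 - e for e in entropy]
    total = sum(disp)
    weights = [d / total for d in disp] if total > 0 else [1.0 / k] * k

    # vector normalization and weighting
    v = [[0.0] * k for _ in range(n)]
    for j in range(k):
        norm = math.sqrt(sum(r[j] ** 2 for r in rows))
        for i in range(n):
            z = rows[i][j] / norm if norm > 0 else 0.0
            v[i][j] = weights[j] * z
    z_plus = [max(v[i][j] for i in range(n)) for j in range(k)]
    z_minus = [min(v[i][j] for i in range(n)) for j in range(k)]
    scores = []
    for i in range(n):
        d_plus = math.sqrt(sum((v[i][j] - z_plus[j]) ** 2 for j in range(k)))
        d_minus = math.sqrt(sum((v[i][j] - z_minus[j]) ** 2 for j in range(k)))
        scores.append(d_minus / (d_plus + d_minus) if d_plus + d_minus > 0 else 0.5)
    if labels is None:
        return weights, scores
    return weights, dict(zip(labels, scores))


# --------------------------------------------------------------------------
# Protected k-core with an explicit (randomizable) removal order
# --------------------------------------------------------------------------

def protected_kcore_oracle(nodes, edges, protected, k, rng=None):
    """One-at-a-time removal simulation; order chosen by ``rng`` if given."""
    nodes = set(nodes)
    adj = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    protected = set(protected)
    while True:
        removable = sorted(
            v for v in nodes if v not in protected and len(adj[v]) < k
        )
        if not removable:
            break
        victim = removable[rng.integers(len(removable))] if rng is not None else removable[0]
        nodes.discard(victim)
        for nb in adj.pop(victim):
            adj[nb].discard(victim)
    kept_edges = set()
    for u in nodes:
        for v in adj[u]:
            kept_edges.add((u, v) if u <= v else (v, u))
    return nodes, kept_edges
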