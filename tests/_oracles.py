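"""Independent brute-force oracles used by the test suite.

Deliberately written as plain loops over the mathematical definitions,
sharing no code with the library implementations they check.
"""

from itertools import combinations

import numpy as np


def ssgsea_brute(expr, gene_ids, gene_set, alpha):
    """Explicit weighted-ECDF walk down the per-cell ranking."""
    inset = {g.upper() for g in gene_set}
    pairs = sorted(zip(expr, gene_ids), key=lambda t: (-t[0], str(t[1])))
    G = len(pairs)
    n_in = sum(1 for _, g in pairs if str(g).upper() in inset)
    if n_in == 0 or n_in == G:
        raise ValueError("degenerate gene set")
    total_w = 0.0
    for pos, (_, g) in enumerate(pairs):
        if str(g).upper() in inset:
            total_w += (G - pos) ** alpha
    score = 0.0
    cum_in = 0.0
    cum_out = 0
    for pos, (_, g) in enumerate(pairs):
        if str(g).upper() in inset:
            cum_in += (G - pos) ** alpha
        else:
            cum_out += 1
        score += cum_in / total_w - cum_out / (G - n_in)
    return score


def _all_shortest_paths(adj, s, t):
    """All shortest s-t paths in an undirected graph by breadth-first layering."""
    from collections import deque

    dist = {s: 0}
    preds = {s: []}
    q = deque([s])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                preds[v] = [u]
                q.append(v)
            elif dist[v] == dist[u] + 1:
                preds[v].append(u)
    if t not in dist:
        return []
    paths = []

    def back(node, acc):
        if node == s:
            paths.append([s] + acc[::-1])
            return
        for p in preds[node]:
            back(p, acc + [node])

    back(t, [])
    return paths


def betweenness_brute(adj):
    """Normalized betweenness by exhaustive shortest-path enumeration."""
    nodes = sorted(adj)
    n = len(nodes)
    bc = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        paths = _all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += through / len(paths)
    scale = 2.0 / ((n - 1) * (n - 2)) if n > 2 else 0.0
    return {v: bc[v] * scale for v in nodes}


def closeness_brute(adj):
    """Classical closeness (n-1)/sum(dist) on a connected undirected graph."""
    from collections import deque

    nodes = sorted(adj)
    n = len(nodes)
    out = {}
    for s in nodes:
        dist = {s: 0}
        q = deque([s])
        while q:
            u = q.popleft()
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    q.append(v)
        out[s] = (n - 1) / sum(dist[v] for v in nodes if v != s)
    return out


def q_monte_carlo(rank_ratios, n_draws, seed):
    """Monte-Carlo estimate of the joint dominance probability
    P(U_(i) <= r_(i) for all i) with its standard error."""
    rng = np.random.default_rng(seed)
    r = np.sort(np.asarray(rank_ratios, dtype=float))
    draws = np.sort(rng.uniform(size=(n_draws, r.size)), axis=1)
    hit = np.all(draws <= r[None, :], axis=1)
    p = hit.mean()
    se = np.sqrt(max(p * (1 - p), 1e-12) / n_draws)
    return p, se
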