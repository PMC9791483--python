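"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: betweenness is
counted from shortest-path enumeration via adjacency-matrix powers, and
clustering from explicit neighbour-pair triangle checks.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np


def brute_betweenness(G: nx.Graph) -> dict:
    """Raw betweenness (endpoints excluded, fractional over shortest paths)."""
    nodes = list(G.nodes)
    n = len(nodes)
    A = nx.to_numpy_array(G, nodelist=nodes, weight=None)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0)
    sigma = np.zeros((n, n))
    np.fill_diagonal(sigma, 1)
    P = np.eye(n)
    for k in range(1, n):
        P = P @ A
        new = (dist == np.inf) & (P > 0)
        dist[new] = k
        sigma[new] = P[new]
    bet = dict.fromkeys(nodes, 0.0)
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(dist[s, t]):
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if dist[s, v] + dist[v, t] == dist[s, t]:
                    bet[nodes[v]] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return bet


def brute_clustering(G: nx.Graph) -> dict:
    """Local clustering: realized neighbour pairs over possible pairs."""
    out = {}
    for v in G.nodes:
        nbrs = [u for u in G.neighbors(v) if u != v]
        k = len(nbrs)
        if k < 2:
            out[v] = 0.0
            continue
        links = sum(1 for a, b in combinations(nbrs, 2) if G.has_edge(a, b))
        out[v] = 2 * links / (k * (k - 1))
    return out
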