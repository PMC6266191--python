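"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the library code paths (and networkx's centrality
routines): shortest paths come from a hand-rolled BFS, betweenness from the
pair-dependency formula sigma(s,v)*sigma(v,t)/sigma(s,t) summed over pairs,
and derived networks from direct per-dyad rule evaluation.
"""

from __future__ import annotations

from collections import deque


def bfs_distances_and_counts(adj: dict, source):
    """Unweighted shortest-path distances and path counts from one source."""
    dist = {source: 0}
    sigma = {source: 1}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                sigma[v] = 0
                queue.append(v)
            if dist[v] == dist[u] + 1:
                sigma[v] += sigma[u]
    return dist, sigma


def brute_betweenness(nodes: list, edges: list) -> dict:
    """Normalized betweenness on an undirected simple graph.

    For every node v and unordered pair {s, t} (v not in {s, t}) with t
    reachable from s, v's share of shortest s-t paths is
    sigma(s,v)*sigma(v,t)/sigma(s,t) when d(s,v)+d(v,t)=d(s,t).
    Normalization: divide by (n-1)(n-2)/2.
    """
    adj = {u: set() for u in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    dist = {}
    sigma = {}
    for s in nodes:
        dist[s], sigma[s] = bfs_distances_and_counts(adj, s)
    bc = {v: 0.0 for v in nodes}
    nodelist = list(nodes)
    for i, s in enumerate(nodelist):
        for t in nodelist[i + 1 :]:
            if t not in dist[s]:
                continue
            d_st = dist[s][t]
            for v in nodes:
                if v == s or v == t or v not in dist[s] or v not in dist[t]:
                    continue
                if dist[s][v] + dist[t][v] == d_st:
                    bc[v] += sigma[s][v] * sigma[t][v] / sigma[s][t]
    n = len(nodes)
    if n > 2:
        norm = (n - 1) * (n - 2) / 2
        bc = {v: val / norm for v, val in bc.items()}
    return bc


def brute_closeness(nodes: list, edges: list) -> dict:
    """Closeness with the reachable-fraction scaling; isolates score 0.

    closeness(v) = ((r-1)/(n-1)) * (r-1)/sum_of_distances, where r is the
    number of nodes reachable from v (including v).
    """
    adj = {u: set() for u in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    n = len(nodes)
    out = {}
    for v in nodes:
        dist, _ = bfs_distances_and_counts(adj, v)
        r = len(dist)
        total = sum(dist.values())
        if r <= 1 or total == 0 or n <= 1:
            out[v] = 0.0
        else:
            out[v] = ((r - 1) / (n - 1)) * ((r - 1) / total)
    return out


def brute_derive_edges(rule, node_ids: list, weight_of) -> set:
    """All unordered pairs satisfying a tie rule, by direct evaluation.

    ``weight_of(a, b)`` returns the directed weight or None. Uses
    ``evaluate_tie`` on every pair — the enumeration, not the graph builder,
    is the point.
    """
    from rosterlens.definitions import evaluate_tie

    edges = set()
    for i, a in enumerate(node_ids):
        for b in node_ids[i + 1 :]:
            verdict, _ = evaluate_tie(rule, weight_of(a, b), weight_of(b, a))
            if verdict:
                edges.add(frozenset((a, b)))
    return edges
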