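"""Independent brute-force oracles for graph metrics and motif counts.

Deliberately naive: Floyd-Warshall distances, DFS path enumeration for
betweenness, vertex-subset enumeration for maximal cliques, explicit
union-find for neighborhood components. These share no code path with the
package implementations they check.
"""
from __future__ import annotations

import math
from itertools import combinations, permutations


def floyd_warshall(nodes: list, edges: set[tuple]) -> dict:
    """All-pairs shortest path lengths by Floyd-Warshall over directed edges."""
    inf = math.inf
    d = {(u, v): (0 if u == v else inf) for u in nodes for v in nodes}
    for u, v in edges:
        d[(u, v)] = 1
    for k in nodes:
        for i in nodes:
            for j in nodes:
                if d[(i, k)] + d[(k, j)] < d[(i, j)]:
                    d[(i, j)] = d[(i, k)] + d[(k, j)]
    return d


def _count_shortest_paths(nodes, edges, s, t):
    """(min length, total count, count through each node) via DFS over simple paths."""
    succ = {u: [v for (a, v) in edges if a == u] for u in nodes}
    best = {"len": math.inf}
    paths = []

    def dfs(path):
        u = path[-1]
        if len(path) - 1 > best["len"]:
            return
        if u == t:
            if len(path) - 1 < best["len"]:
                best["len"] = len(path) - 1
                paths.clear()
            if len(path) - 1 == best["len"]:
                paths.append(list(path))
            return
        for v in succ[u]:
            if v not in path:
                path.append(v)
                dfs(path)
                path.pop()

    dfs([s])
    through = {v: 0 for v in nodes}
    for p in paths:
        for v in p[1:-1]:
            through[v] += 1
    return best["len"], len(paths), through


def betweenness_oracle(nodes: list, edges: set[tuple]) -> dict:
    """Unnormalized directed betweenness: sum over ordered pairs s != t of
    sigma_st(v)/sigma_st."""
    bc = {v: 0.0 for v in nodes}
    for s in nodes:
        for t in nodes:
            if s == t:
                continue
            length, total, through = _count_shortest_paths(nodes, edges, s, t)
            if total == 0:
                continue
            for v in nodes:
                if v not in (s, t) and through[v]:
                    bc[v] += through[v] / total
    return bc


def directed_metrics_oracle(nodes: list, edges: set[tuple]) -> dict:
    """degree / outdegree / harmonic closeness / average shortest path
    length / neighborhood connectivity per node, from first principles."""
    d = floyd_warshall(nodes, edges)
    out = {}
    for v in nodes:
        outdeg = sum(1 for (a, b) in edges if a == v)
        indeg = sum(1 for (a, b) in edges if b == v)
        dists = [d[(v, u)] for u in nodes if u != v and math.isfinite(d[(v, u)])]
        closeness = sum(1.0 / x for x in dists)
        aspl = sum(dists) / len(dists) if dists else None
        neigh = {b for (a, b) in edges if a == v} | {a for (a, b) in edges if b == v}
        degs = [
            sum(1 for (a, b) in edges if a == u) + sum(1 for (a, b) in edges if b == u)
            for u in neigh
        ]
        nc = sum(degs) / len(degs) if degs else 0.0
        out[v] = {
            "degree": indeg + outdeg,
            "outdegree": outdeg,
            "closeness": closeness,
            "average_shortest_path_length": aspl,
            "neighborhood_connectivity": nc,
        }
    return out


def mcc_oracle(nodes: list, uedges: set[frozenset]) -> dict:
    """MCC by enumerating every vertex subset and testing clique maximality."""
    adj = {v: set() for v in nodes}
    for e in uedges:
        a, b = tuple(e)
        adj[a].add(b)
        adj[b].add(a)
    mcc = {v: 0 for v in nodes}
    for r in range(2, len(nodes) + 1):
        for sub in combinations(nodes, r):
            if not all(b in adj[a] for a, b in combinations(sub, 2)):
                continue
            if any(all(u in adj[w] for u in sub) for w in nodes if w not in sub):
                continue  # extendable, not maximal
            for v in sub:
                mcc[v] += math.factorial(r - 1)
    return mcc


def mnc_oracle(nodes: list, uedges: set[frozenset]) -> dict:
    """MNC via union-find over each open neighborhood."""
    adj = {v: set() for v in nodes}
    for e in uedges:
        a, b = tuple(e)
        adj[a].add(b)
        adj[b].add(a)
    out = {}
    for v in nodes:
        neigh = list(adj[v])
        if not neigh:
            out[v] = 0
            continue
        parent = {u: u for u in neigh}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in combinations(neigh, 2):
            if b in adj[a]:
                parent[find(a)] = find(b)
        sizes: dict = {}
        for u in neigh:
            r = find(u)
            sizes[r] = sizes.get(r, 0) + 1
        out[v] = max(sizes.values())
    return out


def motif_oracle(kinds: dict, edges: set[tuple], both_gene_edges: bool = True) -> set[tuple]:
    """All (mirna, tf, gene, kind) motif instances by scanning every
    kind-consistent ordered triple."""
    found = set()
    for m in [v for v, k in kinds.items() if k == "miRNA"]:
        for t in [v for v, k in kinds.items() if k == "TF"]:
            for g in [v for v, k in kinds.items() if k == "gene"]:
                mt, tm = (m, t) in edges, (t, m) in edges
                mg, tg = (m, g) in edges, (t, g) in edges
                if both_gene_edges:
                    comp = mt and tm and mg and tg
                else:
                    comp = mt and tm and (mg or tg)
                if comp:
                    found.add((m, t, g, "composite"))
                elif mt and mg and tg:
                    found.add((m, t, g, "miRNA-FFL"))
                elif tm and mg and tg:
                    found.add((m, t, g, "TF-FFL"))
    return found


def hypergeom_tail_oracle(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by enumerating every n-subset of an N-element universe."""
    universe = list(range(N))
    hits = set(range(K))
    total = 0
    ge = 0
    for draw in combinations(universe, n):
        total += 1
        if len(hits.intersection(draw)) >= k:
            ge += 1
    return ge / total
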