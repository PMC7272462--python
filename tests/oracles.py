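"""Independent brute-force oracles for the weighted graph measures.

Everything here is deliberately naive — explicit loops, exhaustive
enumeration — and shares no code with the package's implementations.
Intended for graphs of at most ~8 nodes.
"""

from __future__ import annotations

import math

RTOL = 1e-9


def lengths_from_weights(w):
    n = len(w)
    return [
        [
            0.0 if i == j else (1.0 / w[i][j] if w[i][j] > 0 else math.inf)
            for j in range(n)
        ]
        for i in range(n)
    ]


def floyd_warshall(w):
    """All-pairs shortest paths by the triple loop, lengths 1/w."""
    d = lengths_from_weights(w)
    n = len(w)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return d


def strength(w):
    return [sum(row) for row in w]


def global_efficiency(w):
    n = len(w)
    d = floyd_warshall(w)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and math.isfinite(d[i][j]) and d[i][j] > 0:
                total += 1.0 / d[i][j]
    return total / (n * (n - 1))


def nodal_efficiency(w):
    n = len(w)
    d = floyd_warshall(w)
    out = []
    for i in range(n):
        acc = 0.0
        for j in range(n):
            if i != j and math.isfinite(d[i][j]) and d[i][j] > 0:
                acc += 1.0 / d[i][j]
        out.append(acc / (n - 1))
    return out


def characteristic_path_length(w):
    n = len(w)
    d = floyd_warshall(w)
    finite = [d[i][j] for i in range(n) for j in range(n) if i != j and math.isfinite(d[i][j])]
    if not finite:
        raise ValueError("no reachable pair")
    return sum(finite) / len(finite)


def clustering(w):
    """Onnela clustering by explicit triple enumeration on max-scaled weights."""
    n = len(w)
    wmax = max(max(row) for row in w)
    if wmax <= 0:
        return [0.0] * n
    out = []
    for i in range(n):
        k = sum(1 for j in range(n) if j != i and w[i][j] > 0)
        if k < 2:
            out.append(0.0)
            continue
        acc = 0.0
        for j in range(n):
            for h in range(n):
                if j == i or h == i:
                    continue
                acc += ((w[i][j] / wmax) * (w[i][h] / wmax) * (w[j][h] / wmax)) ** (1.0 / 3.0)
        out.append(acc / (k * (k - 1)))
    return out


def local_efficiency(w):
    """Global efficiency of each node's explicitly constructed neighbor subgraph."""
    n = len(w)
    out = []
    for i in range(n):
        nbrs = [j for j in range(n) if j != i and w[i][j] > 0]
        if len(nbrs) < 2:
            out.append(0.0)
            continue
        sub = [[w[a][b] for b in nbrs] for a in nbrs]
        out.append(global_efficiency(sub))
    return out


def betweenness(w):
    """Betweenness by exhaustive enumeration of all shortest paths per pair.

    DFS over simple paths, pruned by the Floyd-Warshall distance bound so
    only shortest paths are enumerated; interior nodes of each shortest path
    are credited 1/(number of shortest paths for that pair). Each unordered
    pair counts once.
    """
    n = len(w)
    lengths = lengths_from_weights(w)
    d = floyd_warshall(w)
    bc = [0.0] * n

    def shortest_path_list(s, t):
        target = d[s][t]
        paths = []

        def dfs(u, length, visited, path):
            if length > target * (1 + RTOL) + 1e-15:
                return
            if u == t:
                if abs(length - target) <= RTOL * max(1.0, target):
                    paths.append(list(path))
                return
            for v in range(n):
                if v in visited or not math.isfinite(lengths[u][v]) or u == v:
                    continue
                # prune: going through v cannot still reach t within the bound
                if length + lengths[u][v] + d[v][t] > target * (1 + RTOL) + 1e-15:
                    continue
                visited.add(v)
                path.append(v)
                dfs(v, length + lengths[u][v], visited, path)
                path.pop()
                visited.remove(v)

        dfs(s, 0.0, {s}, [s])
        return paths

    for s in range(n):
        for t in range(s + 1, n):
            if not math.isfinite(d[s][t]):
                continue
            paths = shortest_path_list(s, t)
            if not paths:
                continue
            share = 1.0 / len(paths)
            for path in paths:
                for node in path[1:-1]:
                    bc[node] += share
    return bc
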