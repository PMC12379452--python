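"""Independent brute-force oracles used by the test suite.

These are deliberately naive (loops over pairs, BFS by hand, exhaustive
partition enumeration) and share no code with the package paths they
check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def ccf_brute(x, y, lag_max):
    """rho(tau) for tau in [-lag_max, lag_max], straight from the formula:
    full-series means/sds with 1/T normalization, truncated lag sums."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    T = len(x)
    mx, my = x.mean(), y.mean()
    sx = np.sqrt(np.mean((x - mx) ** 2))
    sy = np.sqrt(np.mean((y - my) ** 2))
    out = []
    for tau in range(-lag_max, lag_max + 1):
        acc = 0.0
        for t in range(T):
            if 0 <= t + tau < T:
                acc += (x[t + tau] - mx) * (y[t] - my)
        out.append((acc / T) / (sx * sy))
    return np.array(out)


def degrees_brute(n_nodes, edges):
    deg = [0] * n_nodes
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1
    return deg


def clustering_brute(n_nodes, edges, count_low_as_zero=False):
    """Average local clustering; nodes with k<2 excluded by default."""
    adj = [set() for _ in range(n_nodes)]
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    vals = []
    for i in range(n_nodes):
        k = len(adj[i])
        if k < 2:
            if count_low_as_zero:
                vals.append(0.0)
            continue
        e_i = sum(
            1 for a, b in combinations(sorted(adj[i]), 2) if b in adj[a]
        )
        vals.append(2.0 * e_i / (k * (k - 1)))
    return float(np.mean(vals)) if vals else 0.0


def efficiency_brute(n_nodes, edges):
    """Mean 1/d over ordered pairs, BFS hop counts, 0 for unreachable."""
    adj = [[] for _ in range(n_nodes)]
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    total = 0.0
    for s in range(n_nodes):
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for w in adj[u]:
                    if w not in dist:
                        dist[w] = dist[u] + 1
                        nxt.append(w)
            frontier = nxt
        for t, d in dist.items():
            if t != s:
                total += 1.0 / d
    return total / (n_nodes * (n_nodes - 1))


def modularity_brute(n_nodes, edges, membership):
    """Q = sum_c (e_c/m - (d_c/2m)^2)."""
    m = len(edges)
    if m == 0:
        return 0.0
    deg = degrees_brute(n_nodes, edges)
    comms = set(membership)
    q = 0.0
    for c in comms:
        nodes = {i for i in range(n_nodes) if membership[i] == c}
        e_c = sum(1 for u, v in edges if u in nodes and v in nodes)
        d_c = sum(deg[i] for i in nodes)
        q += e_c / m - (d_c / (2.0 * m)) ** 2
    return q


def set_partitions(items):
    """All partitions of a list (Bell-number many; use for <= 8 items)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def best_modularity_partition(n_nodes, edges):
    """Exhaustively maximize Q over all partitions (tiny graphs only)."""
    best_q, best_part = -np.inf, None
    for part in set_partitions(range(n_nodes)):
        memb = [0] * n_nodes
        for c, block in enumerate(part):
            for i in block:
                memb[i] = c
        q = modularity_brute(n_nodes, edges, memb)
        if q > best_q:
            best_q, best_part = q, memb
    return best_q, best_part
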