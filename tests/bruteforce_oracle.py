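"""Independent brute-force graph/statistics oracles for small problems.

Pure-python reference implementations (BFS, exhaustive path enumeration,
itertools sign enumeration) kept deliberately separate from the library
code paths they validate.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def bfs_distances(adj: np.ndarray, source: int) -> list[float]:
    n = len(adj)
    dist = [float("inf")] * n
    dist[source] = 0
    q = deque([source])
    while q:
        u = q.popleft()
        for v in range(n):
            if adj[u][v] and dist[v] == float("inf"):
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def all_pairs_distances(adj: np.ndarray) -> list[list[float]]:
    return [bfs_distances(adj, s) for s in range(len(adj))]


def clustering_coefficients(adj: np.ndarray) -> list[float]:
    n = len(adj)
    out = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i][j]]
        k = len(nbrs)
        if k < 2:
            out.append(0.0)
            continue
        links = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if adj[a][b]
        )
        out.append(2.0 * links / (k * (k - 1)))
    return out


def harmonic_path_length(adj: np.ndarray) -> float:
    n = len(adj)
    total = 0.0
    for i in range(n):
        d = bfs_distances(adj, i)
        for j in range(n):
            if i != j and d[j] != float("inf"):
                total += 1.0 / d[j]
    if total == 0:
        return float("inf")
    return n * (n - 1) / total


def global_efficiency(adj: np.ndarray) -> float:
    n = len(adj)
    total = 0.0
    for i in range(n):
        d = bfs_distances(adj, i)
        for j in range(n):
            if i != j and d[j] != float("inf"):
                total += 1.0 / d[j]
    return total / (n * (n - 1))


def local_efficiency(adj: np.ndarray) -> list[float]:
    n = len(adj)
    out = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i][j]]
        if len(nbrs) < 2:
            out.append(0.0)
            continue
        sub = [[adj[a][b] for b in nbrs] for a in nbrs]
        m = len(nbrs)
        total = 0.0
        for a in range(m):
            d = bfs_distances(np.array(sub), a)
            for b in range(m):
                if a != b and d[b] != float("inf"):
                    total += 1.0 / d[b]
        out.append(total / (m * (m - 1)))
    return out


def _count_shortest_paths(adj: np.ndarray, s: int, t: int) -> tuple[int, dict[int, int]]:
    """Number of shortest s-t paths and, per intermediate node, the number
    passing through it, by explicit enumeration of all shortest paths."""
    n = len(adj)
    dist = bfs_distances(adj, s)
    if dist[t] == float("inf"):
        return 0, {}
    paths = []
    stack = [[s]]
    while stack:
        path = stack.pop()
        u = path[-1]
        if u == t:
            paths.append(path)
            continue
        for v in range(n):
            if adj[u][v] and dist[v] == dist[u] + 1 and dist[v] <= dist[t]:
                stack.append(path + [v])
    through: dict[int, int] = {}
    for path in paths:
        for v in path[1:-1]:
            through[v] = through.get(v, 0) + 1
    return len(paths), through


def betweenness_normalized(adj: np.ndarray) -> list[float]:
    n = len(adj)
    raw = [0.0] * n
    for s, t in itertools.combinations(range(n), 2):
        total, through = _count_shortest_paths(adj, s, t)
        if total == 0:
            continue
        for v, cnt in through.items():
            raw[v] += cnt / total
    norm = (n - 1) * (n - 2) / 2.0
    return [r / norm for r in raw]


def participation(adj: np.ndarray, partition) -> list[float]:
    n = len(adj)
    out = []
    for i in range(n):
        k = sum(adj[i])
        if k == 0:
            out.append(0.0)
            continue
        acc = 0.0
        for m in set(partition):
            km = sum(adj[i][j] for j in range(n) if partition[j] == m)
            acc += (km / k) ** 2
        out.append(1.0 - acc)
    return out


def within_module_z(adj: np.ndarray, partition) -> list[float]:
    n = len(adj)
    out = [0.0] * n
    for m in set(partition):
        members = [i for i in range(n) if partition[i] == m]
        if len(members) < 2:
            continue
        kin = [
            sum(adj[i][j] for j in members) for i in members
        ]
        mean = sum(kin) / len(kin)
        sd = (sum((k - mean) ** 2 for k in kin) / len(kin)) ** 0.5
        if sd > 0:
            for i, k in zip(members, kin):
                out[i] = (k - mean) / sd
    return out


def exhaustive_sign_p(diffs) -> float:
    """Directional sign-flip p by explicit enumeration of all assignments."""
    diffs = list(diffs)
    n = len(diffs)
    observed = sum(diffs) / n
    if observed == 0:
        return 1.0
    count = 0
    for signs in itertools.product((1, -1), repeat=n):
        mean = sum(s * d for s, d in zip(signs, diffs)) / n
        if observed > 0 and mean >= observed - 1e-12:
            count += 1
        elif observed < 0 and mean <= observed + 1e-12:
            count += 1
    return count / 2 ** n


def bh_stepup(pvals, alpha=0.05) -> set[int]:
    """Hand-rolled Benjamini-Hochberg step-up selection."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    kmax = 0
    for rank, idx in enumerate(order, start=1):
        if pvals[idx] <= rank * alpha / m:
            kmax = rank
    return set(order[:kmax])
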