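"""Independent brute-force graph-metric oracle.

Deliberately naive: queue-based BFS per source and literal transcription of
the metric definitions, sharing no code with the package's engine.
"""

from collections import deque

import numpy as np


def bfs_distances(adj) -> np.ndarray:
    a = np.asarray(adj, dtype=bool)
    n = a.shape[0]
    dist = np.full((n, n), np.inf)
    for s in range(n):
        dist[s, s] = 0
        q = deque([s])
        while q:
            u = q.popleft()
            for v in range(n):
                if a[u, v] and not np.isfinite(dist[s, v]):
                    dist[s, v] = dist[s, u] + 1
                    q.append(v)
    return dist


def global_efficiency(adj) -> float:
    a = np.asarray(adj, dtype=bool)
    n = a.shape[0]
    d = bfs_distances(a)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def nodal_efficiency(adj) -> np.ndarray:
    a = np.asarray(adj, dtype=bool)
    n = a.shape[0]
    d = bfs_distances(a)
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                out[i] += 1.0 / d[i, j]
        out[i] /= n - 1
    return out


def local_efficiency(adj) -> float:
    a = np.asarray(adj, dtype=bool)
    n = a.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        if len(nbrs) < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        total += global_efficiency(sub)
    return total / n


def clustering(adj) -> float:
    a = np.asarray(adj, dtype=bool)
    n = a.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(1 for x in range(k) for y in range(x + 1, k)
                    if a[nbrs[x], nbrs[y]])
        total += 2.0 * links / (k * (k - 1))
    return total / n


def path_length(adj) -> float:
    a = np.asarray(adj, dtype=bool)
    n = a.shape[0]
    d = bfs_distances(a)
    vals = [d[i, j] for i in range(n) for j in range(n)
            if i != j and np.isfinite(d[i, j])]
    if not vals:
        raise ValueError("no connected pair")
    return float(np.mean(vals))
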