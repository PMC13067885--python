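"""Binary brain-network topology over a sparsity sweep.

From a Fisher-z functional-connectivity matrix, binary undirected graphs are
built by proportional thresholding (keep the K strongest edges, K =
round(sparsity * n_pairs)) across a sparsity grid. At each threshold the
following are computed:

* global efficiency ``Eg = mean over ordered pairs of 1/d_ij`` (1/inf = 0),
* local efficiency ``Eloc = mean over nodes of Eg(neighbour subgraph)``,
* nodal efficiency ``Ne_i = mean over j != i of 1/d_ij``,
* small-worldness ``sigma = (C/<C_rand>) / (L/<L_rand>)`` normalized against
  an ensemble of degree-preserving rewired null networks.

Each metric is aggregated over the sweep as an area under the curve,
``AUC = step * sum of per-threshold values`` — the threshold-free summary
used for all group statistics.

Graphs are plain boolean adjacency matrices; every metric here is defined
for small dense networks (10 ROI nodes) and implemented directly so it can
be checked against an independent brute-force oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .roi_connectivity import FcMatrix, ROI_ORDER

__all__ = [
    "SparsityGrid",
    "AucMetricSet",
    "n_edges_at_sparsity",
    "threshold_proportional",
    "shortest_path_lengths",
    "is_connected",
    "global_efficiency",
    "local_efficiency",
    "nodal_efficiency",
    "clustering_and_pathlength",
    "rewire_degree_preserving",
    "small_worldness",
    "metric_auc",
    "network_metrics",
    "min_connected_sparsity",
    "ring_lattice",
]


@dataclass(frozen=True)
class SparsityGrid:
    """Thresholds ``s_min + k*step`` while they stay within ``s_max``.

    The defaults (0.2667 to 0.50, step 0.01) yield 24 thresholds,
    0.2667 ... 0.4967.
    """

    s_min: float = 0.2667
    s_max: float = 0.50
    step: float = 0.01

    def __post_init__(self):
        if not (0 < self.s_min <= self.s_max <= 1 and self.step > 0):
            raise ValueError("invalid sparsity grid")

    @property
    def thresholds(self) -> np.ndarray:
        k = np.arange(int(np.floor((self.s_max - self.s_min) / self.step + 1e-9)) + 1)
        return self.s_min + k * self.step

    @property
    def width(self) -> float:
        return self.step * self.thresholds.size


def _as_adjacency(g) -> np.ndarray:
    a = np.asarray(g, dtype=bool)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not (a == a.T).all() or a.diagonal().any():
        raise ValueError("adjacency must be symmetric with empty diagonal")
    return a


def n_edges_at_sparsity(sparsity: float, n_nodes: int = 10) -> int:
    """Nearest-integer (half-up) edge count at a proportional threshold."""
    if not 0 < sparsity <= 1:
        raise ValueError("sparsity must lie in (0, 1]")
    n_pairs = n_nodes * (n_nodes - 1) // 2
    return int(np.floor(sparsity * n_pairs + 0.5))


def _ranked_edges(z: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle edges sorted by weight desc, ties by (i, j) lex asc."""
    iu, ju = np.triu_indices(z.shape[0], k=1)
    w = z[iu, ju]
    order = np.lexsort((ju, iu, -w))
    return iu[order], ju[order], w[order]


def threshold_proportional(fc: FcMatrix, sparsity: float) -> np.ndarray:
    """Binary adjacency keeping the K strongest-z edges.

    Ties at the cutoff are broken by lexicographic (i, j) order, which makes
    the edge sets nested across increasing sparsity.
    """
    z = fc.z
    n = z.shape[0]
    k = n_edges_at_sparsity(sparsity, n)
    ii, jj, ww = _ranked_edges(z)
    if int((ww > 0).sum()) < k:
        raise ValueError(
            f"only {int((ww > 0).sum())} positive edges available, need {k}")
    adj = np.zeros((n, n), dtype=bool)
    adj[ii[:k], jj[:k]] = True
    return adj | adj.T


def shortest_path_lengths(g) -> np.ndarray:
    """All-pairs unweighted shortest-path lengths; inf where unreachable.

    Breadth-first search expressed as boolean frontier propagation — exact
    hop counts for the small dense graphs used here.
    """
    a = _as_adjacency(g)
    n = a.shape[0]
    ai = a.astype(np.int64)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    reach = np.eye(n, dtype=bool)
    frontier = np.eye(n, dtype=bool)
    d = 0
    while frontier.any():
        d += 1
        new = ((frontier.astype(np.int64) @ ai) > 0) & ~reach
        dist[new] = d
        reach |= new
        frontier = new
    return dist


def is_connected(g) -> bool:
    a = _as_adjacency(g)
    return bool(np.isfinite(shortest_path_lengths(a)).all())


def _inv_dist(dist: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return inv


def global_efficiency(g) -> float:
    """Mean over ordered node pairs of 1/d_ij (unreachable pairs give 0)."""
    a = _as_adjacency(g)
    n = a.shape[0]
    if n < 2:
        return 0.0
    inv = _inv_dist(shortest_path_lengths(a))
    return float(inv.sum() / (n * (n - 1)))


def nodal_efficiency(g, node: int | None = None):
    """Ne_i = mean over j != i of 1/d_ij; vector if ``node`` is None."""
    a = _as_adjacency(g)
    n = a.shape[0]
    inv = _inv_dist(shortest_path_lengths(a))
    ne = inv.sum(axis=1) / (n - 1)
    return ne if node is None else float(ne[node])


def local_efficiency(g) -> float:
    """Mean over nodes of the global efficiency of the neighbour subgraph.

    Nodes with fewer than two neighbours contribute 0.
    """
    a = _as_adjacency(g)
    n = a.shape[0]
    total = 0.0
    for i in range(n):
        nb = np.flatnonzero(a[i])
        if nb.size < 2:
            continue
        total += global_efficiency(a[np.ix_(nb, nb)])
    return total / n


def clustering_and_pathlength(g) -> tuple[float, float]:
    """(C, L): mean binary clustering coefficient and characteristic path.

    C_i = triangles through i / (k_i choose 2), 0 for degree < 2. L is the
    mean shortest-path length over connected ordered pairs; raises if no
    pair is connected.
    """
    a = _as_adjacency(g)
    dist = shortest_path_lengths(a)
    off = ~np.eye(a.shape[0], dtype=bool)
    finite = np.isfinite(dist) & off
    if not finite.any():
        raise ValueError("graph has no connected node pair")
    return _clustering_mean(a), float(dist[finite].mean())


def _clustering_mean(a: np.ndarray) -> float:
    ai = a.astype(np.int64)
    deg = ai.sum(axis=1)
    tri2 = np.diag(ai @ ai @ ai)  # = 2 * triangles through each node
    denom = deg * (deg - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c_i = np.where(denom > 0, tri2 / denom, 0.0)
    return float(c_i.mean())


def ring_lattice(n_nodes: int, degree: int) -> np.ndarray:
    """Ring lattice: each node linked to its ``degree/2`` nearest neighbours
    on each side."""
    if degree % 2 != 0 or not 0 < degree < n_nodes:
        raise ValueError("degree must be even and < n_nodes")
    a = np.zeros((n_nodes, n_nodes), dtype=bool)
    for off in range(1, degree // 2 + 1):
        idx = np.arange(n_nodes)
        a[idx, (idx + off) % n_nodes] = True
        a[(idx + off) % n_nodes, idx] = True
    return a


def _edge_list(a: np.ndarray) -> np.ndarray:
    iu, ju = np.triu_indices(a.shape[0], k=1)
    keep = a[iu, ju]
    return np.column_stack([iu[keep], ju[keep]])


def _double_edge_swaps(a: np.ndarray, n_swaps: int, rng: np.random.Generator
                       ) -> np.ndarray:
    """Perform up to ``n_swaps`` successful double-edge swaps (degree
    preserving), rejecting self-loops and multi-edges."""
    edges = _edge_list(a).tolist()
    m = len(edges)
    if m < 2 or n_swaps < 1:
        return a.copy()
    n = a.shape[0]
    # flat boolean membership table + python-level edge list: the loop is
    # hot (thousands of nulls per sweep) and numpy scalar indexing is slow
    flat = a.ravel().tolist()
    successes = 0
    attempts = 0
    max_attempts = 50 * n_swaps
    block = max(256, 4 * n_swaps)
    picks = rng.integers(0, m, size=(block, 2)).tolist()
    flips = (rng.random(block) < 0.5).tolist()
    cursor = 0
    while successes < n_swaps and attempts < max_attempts:
        if cursor >= block:
            picks = rng.integers(0, m, size=(block, 2)).tolist()
            flips = (rng.random(block) < 0.5).tolist()
            cursor = 0
        e1, e2 = picks[cursor]
        flip = flips[cursor]
        cursor += 1
        attempts += 1
        if e1 == e2:
            continue
        u, v = edges[e1]
        x, y = edges[e2]
        if flip:
            x, y = y, x
        # proposed: (u, x), (v, y)
        if u == x or u == y or v == x or v == y:
            continue
        if flat[u * n + x] or flat[v * n + y]:
            continue
        flat[u * n + v] = flat[v * n + u] = False
        flat[x * n + y] = flat[y * n + x] = False
        flat[u * n + x] = flat[x * n + u] = True
        flat[v * n + y] = flat[y * n + v] = True
        edges[e1] = (u, x) if u < x else (x, u)
        edges[e2] = (v, y) if v < y else (y, v)
        successes += 1
    return np.array(flat, dtype=bool).reshape(n, n)


def rewire_degree_preserving(g, n_swaps: int | None = None,
                             seed=None, require_connected: bool = True,
                             max_retries: int = 100) -> np.ndarray:
    """Degree-preserving randomization by repeated double-edge swaps.

    ``n_swaps`` defaults to 10x the edge count. If ``require_connected`` and
    the rewired graph is disconnected, it is redrawn from the same stream up
    to ``max_retries`` times.
    """
    a = _as_adjacency(g)
    m = int(a.sum()) // 2
    if n_swaps is None:
        n_swaps = 10 * m
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _ in range(max_retries):
        out = _double_edge_swaps(a, n_swaps, rng)
        if not require_connected or is_connected(out):
            return out
    raise RuntimeError(
        f"could not draw a connected degree-preserving null in {max_retries} tries")


try:  # the null-ensemble loop is the hot path of the sparsity sweep
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dep in practice
    _HAVE_NUMBA = False


if _HAVE_NUMBA:

    @_njit(cache=False)
    def _ensemble_c_l(adj, n_swaps, n_rand, seed, max_retries):  # pragma: no cover - jitted
        """Mean clustering and path length over a degree-preserving null
        ensemble; returns (c_mean, l_mean, ok)."""
        np.random.seed(seed)
        n = adj.shape[0]
        m = 0
        for i in range(n):
            for j in range(i + 1, n):
                if adj[i, j]:
                    m += 1
        eu0 = np.empty(m, np.int64)
        ev0 = np.empty(m, np.int64)
        k = 0
        for i in range(n):
            for j in range(i + 1, n):
                if adj[i, j]:
                    eu0[k] = i
                    ev0[k] = j
                    k += 1
        a = np.empty((n, n), np.uint8)
        eu = np.empty(m, np.int64)
        ev = np.empty(m, np.int64)
        dist = np.empty(n, np.int64)
        queue = np.empty(n, np.int64)
        c_sum = 0.0
        l_sum = 0.0
        for _ in range(n_rand):
            connected = False
            l_graph = 0.0
            for _retry in range(max_retries):
                for i in range(n):
                    for j in range(n):
                        a[i, j] = 1 if adj[i, j] else 0
                for e in range(m):
                    eu[e] = eu0[e]
                    ev[e] = ev0[e]
                if m >= 2 and n_swaps >= 1:
                    successes = 0
                    attempts = 0
                    max_attempts = 50 * n_swaps
                    while successes < n_swaps and attempts < max_attempts:
                        attempts += 1
                        e1 = np.random.randint(0, m)
                        e2 = np.random.randint(0, m)
                        if e1 == e2:
                            continue
                        u = eu[e1]
                        v = ev[e1]
                        x = eu[e2]
                        y = ev[e2]
                        if np.random.random() < 0.5:
                            t = x
                            x = y
                            y = t
                        if u == x or u == y or v == x or v == y:
                            continue
                        if a[u, x] == 1 or a[v, y] == 1:
                            continue
                        a[u, v] = 0
                        a[v, u] = 0
                        a[x, y] = 0
                        a[y, x] = 0
                        a[u, x] = 1
                        a[x, u] = 1
                        a[v, y] = 1
                        a[y, v] = 1
                        if u < x:
                            eu[e1] = u
                            ev[e1] = x
                        else:
                            eu[e1] = x
                            ev[e1] = u
                        if v < y:
                            eu[e2] = v
                            ev[e2] = y
                        else:
                            eu[e2] = y
                            ev[e2] = v
                        successes += 1
                # all-pairs BFS: connectivity + path-length sum in one pass
                connected = True
                total = 0.0
                for s in range(n):
                    for i in range(n):
                        dist[i] = -1
                    dist[s] = 0
                    queue[0] = s
                    head = 0
                    tail = 1
                    while head < tail:
                        u = queue[head]
                        head += 1
                        for w in range(n):
                            if a[u, w] == 1 and dist[w] < 0:
                                dist[w] = dist[u] + 1
                                queue[tail] = w
                                tail += 1
                    if tail < n:
                        connected = False
                        break
                    for i in range(n):
                        total += dist[i]
                if connected:
                    l_graph = total / (n * (n - 1))
                    break
            if not connected:
                return 0.0, 0.0, False
            # mean binary clustering coefficient
            c_graph = 0.0
            for i in range(n):
                deg = 0
                for j in range(n):
                    deg += a[i, j]
                if deg < 2:
                    continue
                tri = 0
                for j in range(n):
                    if a[i, j] == 1:
                        for kk in range(j + 1, n):
                            if a[i, kk] == 1 and a[j, kk] == 1:
                                tri += 1
                c_graph += 2.0 * tri / (deg * (deg - 1))
            c_sum += c_graph / n
            l_sum += l_graph
        return c_sum / n_rand, l_sum / n_rand, True


def _null_ensemble_means(a: np.ndarray, n_rand: int, n_swaps: int,
                         rng: np.random.Generator) -> tuple[float, float]:
    """(mean C, mean L) over connected degree-preserving nulls."""
    if _HAVE_NUMBA:
        kernel_seed = int(rng.integers(0, 2**31 - 1))
        c_rand, l_rand, ok = _ensemble_c_l(
            np.ascontiguousarray(a, dtype=np.bool_), n_swaps, n_rand,
            kernel_seed, 100)
        if not ok:
            raise RuntimeError(
                "could not draw a connected null in 100 tries")
        return c_rand, l_rand
    c_sum = 0.0
    l_sum = 0.0
    off = ~np.eye(a.shape[0], dtype=bool)
    for _ in range(n_rand):
        for _retry in range(100):
            null = _double_edge_swaps(a, n_swaps, rng)
            dist = shortest_path_lengths(null)
            if np.isfinite(dist).all():
                break
        else:
            raise RuntimeError("could not draw a connected null in 100 tries")
        c_sum += _clustering_mean(null)
        l_sum += float(dist[off].mean())
    return c_sum / n_rand, l_sum / n_rand


def small_worldness(g, n_rand: int = 1000, seed=None) -> float:
    """sigma = (C/<C_rand>) / (L/<L_rand>) over ``n_rand`` rewired nulls.

    The input graph must be connected. Nulls preserve the degree sequence
    exactly (10x-edge-count double-edge swaps); disconnected nulls are
    redrawn so L stays finite. For graphs admitting no swap (e.g. complete
    graphs) every null equals the input and sigma is exactly 1.
    """
    a = _as_adjacency(g)
    if not is_connected(a):
        raise ValueError("small-worldness requires a connected graph")
    c, l = clustering_and_pathlength(a)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = int(a.sum()) // 2
    c_rand, l_rand = _null_ensemble_means(a, n_rand, 10 * m, rng)
    if c_rand == 0:
        raise ValueError("degenerate null ensemble: mean clustering is 0")
    return (c / c_rand) / (l / l_rand)


def metric_auc(values, step: float = 0.01) -> float:
    """AUC over the sparsity sweep: ``step * sum(values)``."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty metric curve")
    return float(step * v.sum())


@dataclass(frozen=True)
class AucMetricSet:
    """Per-participant AUC summaries over the sparsity grid."""

    sigma_auc: float
    eg_auc: float
    eloc_auc: float
    ne_auc: np.ndarray  # one value per ROI, ROI_ORDER order
    curves: pd.DataFrame | None = field(default=None, compare=False)

    def as_dict(self) -> dict:
        d = {"sigma": self.sigma_auc, "Eg": self.eg_auc, "Eloc": self.eloc_auc}
        for roi, v in zip(ROI_ORDER, self.ne_auc):
            d[f"Ne_{roi}"] = float(v)
        return d


def network_metrics(fc: FcMatrix, grid: SparsityGrid = SparsityGrid(),
                    n_rand: int = 1000, seed=None,
                    return_curves: bool = False) -> AucMetricSet:
    """Sweep the grid, compute Eg/Eloc/sigma/Ne per threshold, AUC each."""
    thresholds = grid.thresholds
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    child_seeds = ss.spawn(len(thresholds))
    n = fc.z.shape[0]
    eg_c = np.empty(thresholds.size)
    eloc_c = np.empty(thresholds.size)
    sig_c = np.empty(thresholds.size)
    ne_c = np.empty((thresholds.size, n))
    for t, s in enumerate(thresholds):
        adj = threshold_proportional(fc, s)
        if not is_connected(adj):
            raise ValueError(
                f"graph disconnected at sparsity {s:.4f}; choose the grid "
                "minimum with min_connected_sparsity")
        eg_c[t] = global_efficiency(adj)
        eloc_c[t] = local_efficiency(adj)
        ne_c[t] = nodal_efficiency(adj)
        sig_c[t] = small_worldness(adj, n_rand=n_rand,
                                   seed=np.random.default_rng(child_seeds[t]))
    curves = None
    if return_curves:
        curves = pd.DataFrame({"sparsity": thresholds, "Eg": eg_c,
                               "Eloc": eloc_c, "sigma": sig_c})
        for i, roi in enumerate(ROI_ORDER[:n]):
            curves[f"Ne_{roi}"] = ne_c[:, i]
    return AucMetricSet(
        sigma_auc=metric_auc(sig_c, grid.step),
        eg_auc=metric_auc(eg_c, grid.step),
        eloc_auc=metric_auc(eloc_c, grid.step),
        ne_auc=np.array([metric_auc(ne_c[:, i], grid.step) for i in range(n)]),
        curves=curves,
    )


def min_connected_sparsity(matrices, labels=None) -> float:
    """Smallest common sparsity keeping every matrix's top-K graph connected.

    For each matrix, find the minimal K such that its K strongest edges span
    a connected graph; return ``max(K) / n_pairs`` over matrices.
    """
    matrices = list(matrices)
    if not matrices:
        raise ValueError("need at least one connectivity matrix")
    if labels is None:
        labels = [str(i) for i in range(len(matrices))]
    k_max = 0
    n_pairs = None
    for label, fc in zip(labels, matrices):
        z = fc.z
        n = z.shape[0]
        n_pairs = n * (n - 1) // 2
        ii, jj, ww = _ranked_edges(z)
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        n_comp = n
        k_needed = None
        for k, (i, j, w) in enumerate(zip(ii, jj, ww), start=1):
            if w <= 0:
                break
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
                n_comp -= 1
            if n_comp == 1:
                k_needed = k
                break
        if k_needed is None:
            raise ValueError(
                f"matrix {label!r}: too few positive edges to connect all nodes")
        k_max = max(k_max, k_needed)
    return k_max / n_pairs
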