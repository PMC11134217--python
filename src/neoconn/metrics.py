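"""Weighted graph metrics over proportionally thresholded networks.

Networks are built from a connectivity matrix by proportional thresholding:
the strongest edges are retained until a target density (fraction of
possible edges) is reached, over a grid of densities from 0.10 to 0.35 in
steps of 0.01.  On each network seven measures are computed:

* segregation — clustering coefficient (Onnela geometric-mean form),
  transitivity, local efficiency, modularity (Louvain with deterministic
  refinement); triangle-based metrics normalise weights internally by the
  network maximum, so they are invariant to uniform rescaling;
* integration — characteristic path length and global efficiency, both on
  shortest paths with edge length = 1 / weight on the raw weights (so
  path lengths keep the natural scale of the connectivity values);
* small-worldness — clustering over path length, each normalised by its
  mean across random null networks with the same size and edge-weight
  distribution (the normalisation makes sigma scale-free).

Each metric's density profile is summarised by the trapezoidal mean over
the density range (its AUC).
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .core import ConnectivityMatrix, MetricCurve, WeightedNetwork

__all__ = [
    "default_density_grid",
    "proportional_threshold",
    "clustering_coefficient",
    "transitivity",
    "shortest_path_matrix",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "modularity",
    "modularity_value",
    "null_network",
    "draw_null_networks",
    "small_worldness",
    "metric_auc",
    "metric_curves",
    "GLOBAL_METRICS",
]

GLOBAL_METRICS = (
    "characteristic_path_length",
    "global_efficiency",
    "clustering_coefficient",
    "transitivity",
    "local_efficiency",
    "modularity",
    "small_worldness",
)

NODAL_METRICS = ("clustering_coefficient", "local_efficiency")


def default_density_grid(
    d_min: float = 0.10, d_max: float = 0.35, step: float = 0.01
) -> np.ndarray:
    """Density grid 0.10, 0.11, ..., 0.35 (26 points by default)."""
    n = int(round((d_max - d_min) / step)) + 1
    grid = np.round(d_min + step * np.arange(n), 10)
    if np.any(grid <= 0) or np.any(grid > 1):
        raise ValueError("densities must lie in (0, 1]")
    return grid


def _ranked_edges(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle edges sorted by descending weight, ties by (i, j)."""
    n = values.shape[0]
    iu, ju = np.triu_indices(n, 1)
    w = values[iu, ju]
    order = np.lexsort((ju, iu, -w))
    return np.stack([iu[order], ju[order]], axis=1), w[order]


def proportional_threshold(
    matrix: ConnectivityMatrix | WeightedNetwork, density: float
) -> WeightedNetwork:
    """Retain the strongest edges up to the requested density.

    Keeps the top ``floor(density * n(n-1)/2)`` edges by weight (ties
    broken by ascending node-pair order so results are deterministic and
    edge sets are nested across densities); all other entries are zeroed.
    Zero-weight pairs are never counted as connections.
    """
    if not 0 < density <= 1:
        raise ValueError(f"density must lie in (0, 1], got {density}")
    values = matrix.values if isinstance(matrix, ConnectivityMatrix) else matrix.weights
    labels = list(matrix.labels)
    n = values.shape[0]
    m_keep = int(np.floor(density * n * (n - 1) / 2))
    pairs, w = _ranked_edges(values)
    keep = pairs[:m_keep][w[:m_keep] > 0]
    out = np.zeros_like(values)
    out[keep[:, 0], keep[:, 1]] = values[keep[:, 0], keep[:, 1]]
    out = out + out.T
    return WeightedNetwork(labels=labels, weights=out)


def _normalized(net: WeightedNetwork) -> np.ndarray:
    w = net.weights
    wmax = w.max()
    return w / wmax if wmax > 0 else w.copy()


def clustering_coefficient(net: WeightedNetwork) -> tuple[np.ndarray, float]:
    """Weighted clustering per node (geometric mean of triangle weights).

    ``C_i = sum_{j,k} (w_ij w_ik w_jk)^(1/3) / (k_i (k_i - 1))`` on
    max-normalised weights; nodes of degree < 2 get 0.  Returns the
    per-node vector and the network mean.
    """
    w = _normalized(net)
    cw = np.cbrt(w)
    cyc3 = np.diag(cw @ cw @ cw)
    k = (w > 0).sum(axis=1)
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, cyc3 / np.where(denom > 0, denom, 1), 0.0)
    return c, float(c.mean())


def transitivity(net: WeightedNetwork) -> float:
    """Collectively normalised clustering: total triangle weight over
    total connected-triple count; 0 for graphs without connected triples."""
    w = _normalized(net)
    cw = np.cbrt(w)
    cyc3 = np.diag(cw @ cw @ cw)
    k = (w > 0).sum(axis=1)
    denom = float((k * (k - 1)).sum())
    return float(cyc3.sum() / denom) if denom > 0 else 0.0


def shortest_path_matrix(net: WeightedNetwork) -> np.ndarray:
    """All-pairs shortest path lengths with edge length = 1 / weight.

    Lengths are taken on the raw weights (the conventional mapping from
    connection strength to travel cost); unreachable pairs are ``inf``.
    """
    w = net.weights
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / w, 0.0)
    return shortest_path(csr_matrix(lengths), method="D", directed=False)


def characteristic_path_length(
    net: WeightedNetwork, return_infinite: bool = False
) -> float | tuple[float, int]:
    """Mean shortest path length over reachable (finite) node pairs.

    Disconnected pairs are excluded from the mean; their count is
    available via ``return_infinite``.
    """
    if net.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    d = shortest_path_matrix(net)
    off = ~np.eye(net.n_nodes, dtype=bool)
    finite = np.isfinite(d) & off
    n_inf = int((off & ~finite).sum())
    if not finite.any():
        raise ValueError("no finite path between any pair of nodes")
    value = float(d[finite].mean())
    return (value, n_inf) if return_infinite else value


def global_efficiency(net: WeightedNetwork) -> float:
    """Mean inverse shortest path length (1/inf = 0) over node pairs."""
    if net.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    d = shortest_path_matrix(net)
    off = ~np.eye(net.n_nodes, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    return float(inv[off].mean())


def local_efficiency(net: WeightedNetwork) -> tuple[np.ndarray, float]:
    """Efficiency of each node's neighbourhood with the node removed.

    For node ``u`` with neighbours ``V``, shortest paths are computed on
    the subgraph induced by ``V`` (edge length = 1 / weight) and
    ``E_u = sum_{j != h in V} (w_uj w_uh / d_jh)^(1/3) / (k_u (k_u - 1))``
    on max-normalised weights.  Degree < 2 yields 0.
    """
    w = _normalized(net)
    n = net.n_nodes
    e = np.zeros(n)
    for u in range(n):
        (neigh,) = np.nonzero(w[u])
        k = neigh.size
        if k < 2:
            continue
        sub = w[np.ix_(neigh, neigh)]
        with np.errstate(divide="ignore"):
            lengths = np.where(sub > 0, 1.0 / sub, 0.0)
        d = shortest_path(csr_matrix(lengths), method="D", directed=False)
        with np.errstate(divide="ignore"):
            einv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
        cw = np.cbrt(w[u, neigh])
        ce = np.cbrt(einv)
        e[u] = float(cw @ ce @ cw) / (k * (k - 1))
    return e, float(e.mean())


def modularity_value(weights: np.ndarray, labels: np.ndarray) -> float:
    """Weighted Newman modularity Q of a given node partition."""
    m2 = weights.sum()
    if m2 == 0:
        raise ValueError("modularity undefined for an edgeless graph")
    deg = weights.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        idx = labels == c
        q += weights[np.ix_(idx, idx)].sum() / m2 - (deg[idx].sum() / m2) ** 2
    return float(q)


def _refine_partition(
    weights: np.ndarray, labels: np.ndarray, max_passes: int = 50
) -> np.ndarray:
    """Greedy single-node-move hill climb on Q until no move improves it.

    Each pass sweeps the nodes once, moving a node to the community (or a
    fresh singleton) with the largest positive Q gain; community weight
    and degree totals are updated incrementally.
    """
    m2 = weights.sum()
    deg = weights.sum(axis=1)
    n = len(labels)
    for _ in range(max_passes):
        _, labels = np.unique(labels, return_inverse=True)
        n_comm = int(labels.max()) + 1
        onehot = np.zeros((n, n_comm + 1))
        onehot[np.arange(n), labels] = 1.0
        w_comm = weights @ onehot  # w_comm[v, c] = weight from v into c
        d_comm = deg @ onehot  # total degree per community (+ empty slot)
        improved = False
        for u in range(n):
            cur = labels[u]
            w_to = w_comm[u]
            d_other = d_comm.copy()
            d_other[cur] -= deg[u]  # u's own community without u
            gains = (
                2.0 * (w_to - w_to[cur]) / m2
                - 2.0 * deg[u] * (d_other - d_other[cur]) / m2**2
            )
            gains[cur] = 0.0
            best = int(np.argmax(gains))
            if gains[best] > 1e-12:
                labels[u] = best
                w_comm[:, cur] -= weights[:, u]
                w_comm[:, best] += weights[:, u]
                d_comm[cur] -= deg[u]
                d_comm[best] += deg[u]
                improved = True
        if not improved:
            break
    return labels


def _swap_pass(weights: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, bool]:
    """One pass of cross-community pair swaps; applies the best positive swap.

    Escapes local optima of the single-move climb where exchanging two
    nodes between communities raises Q but each individual move lowers it.
    """
    m2 = weights.sum()
    deg = weights.sum(axis=1)
    n = len(labels)
    _, labels = np.unique(labels, return_inverse=True)
    n_comm = int(labels.max()) + 1
    if n_comm < 2:
        return labels, False
    onehot = np.zeros((n, n_comm))
    onehot[np.arange(n), labels] = 1.0
    w_comm = weights @ onehot
    d_comm = deg @ onehot
    best_gain, best_pair = 1e-12, None
    for u in range(n):
        a = labels[u]
        for v in range(u + 1, n):
            b = labels[v]
            if a == b:
                continue
            w_uv = weights[u, v]
            # u -> b, then v -> a (without u)
            d1 = (
                2.0 * (w_comm[u, b] - w_comm[u, a]) / m2
                - 2.0 * deg[u] * (d_comm[b] - (d_comm[a] - deg[u])) / m2**2
            )
            w_v_a = w_comm[v, a] - w_uv
            w_v_b = w_comm[v, b] + w_uv
            d2 = (
                2.0 * (w_v_a - w_v_b) / m2
                - 2.0
                * deg[v]
                * ((d_comm[a] - deg[u]) - (d_comm[b] + deg[u] - deg[v]))
                / m2**2
            )
            if d1 + d2 > best_gain:
                best_gain, best_pair = d1 + d2, (u, v)
    if best_pair is None:
        return labels, False
    u, v = best_pair
    labels[u], labels[v] = labels[v], labels[u]
    return labels, True


def _merge_communities(weights: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Greedily merge community pairs while any merge increases Q."""
    labels = labels.copy()
    m2 = weights.sum()
    deg = weights.sum(axis=1)
    while True:
        comms = np.unique(labels)
        if comms.size < 2:
            return labels
        masks = {c: labels == c for c in comms}
        w_cc = {c: weights[:, masks[c]].sum(axis=1) for c in comms}
        d_c = {c: deg[masks[c]].sum() for c in comms}
        best_gain, best_pair = 1e-12, None
        for i, a in enumerate(comms):
            for b in comms[i + 1 :]:
                gain = 2 * w_cc[b][masks[a]].sum() / m2 - 2 * d_c[a] * d_c[b] / m2**2
                if gain > best_gain:
                    best_gain, best_pair = gain, (a, b)
        if best_pair is None:
            return labels
        labels[masks[best_pair[1]]] = best_pair[0]


#: Below this node count the modularity search enumerates all partitions
#: (Bell(10) ~ 1.16e5) instead of relying on the stochastic search, whose
#: local optima are not guaranteed to be global.
EXACT_MODULARITY_MAX_NODES = 10


def _exact_modularity_small(w: np.ndarray) -> tuple[float, np.ndarray]:
    """Globally optimal Q by iterating restricted growth strings."""
    n = len(w)
    m2 = w.sum()
    deg = w.sum(axis=1)
    a = np.zeros(n, dtype=int)
    best_q, best = -np.inf, a.copy()
    while True:
        intra = float(w[a[:, None] == a[None, :]].sum())
        d_c = np.bincount(a, weights=deg)
        q = intra / m2 - float(((d_c / m2) ** 2).sum())
        if q > best_q + 1e-15:
            best_q, best = q, a.copy()
        i = n - 1
        while i > 0 and a[i] > max(a[:i]):
            a[i] = 0
            i -= 1
        if i == 0:
            break
        a[i] += 1
        a[i + 1 :] = 0
    return best_q, best


def modularity(
    net: WeightedNetwork, n_restarts: int = 10, seed: int = 0
) -> tuple[float, np.ndarray]:
    """Best-found weighted modularity Q and its node partition.

    For graphs of at most ``EXACT_MODULARITY_MAX_NODES`` nodes the optimal
    partition is found exactly by enumeration.  Larger graphs use seeded
    Louvain ``n_restarts`` times, each result polished by alternating a
    single-node-move hill climb, greedy community merges, and
    cross-community pair swaps until none improves Q; the best partition
    over restarts is returned.  Deterministic for a given seed.
    """
    if net.n_edges == 0:
        raise ValueError("modularity undefined for an edgeless graph")
    w = net.weights
    if net.n_nodes <= EXACT_MODULARITY_MAX_NODES:
        return _exact_modularity_small(w)
    g = nx.from_numpy_array(w)
    rng = np.random.default_rng(seed)
    best_q, best_labels = -np.inf, None
    for restart in range(n_restarts):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        if restart % 2 == 0:
            comms = nx.community.louvain_communities(g, weight="weight", seed=sub_seed)
            labels = np.empty(net.n_nodes, dtype=int)
            for ci, members in enumerate(comms):
                labels[list(members)] = ci
        else:
            # random restart: escape Louvain-shaped local optima
            k = int(np.random.default_rng(sub_seed).integers(2, max(3, net.n_nodes)))
            labels = np.random.default_rng(sub_seed).integers(0, k, net.n_nodes)
        q_prev = -np.inf
        for _ in range(40):
            labels = _refine_partition(w, labels)
            labels = _merge_communities(w, labels)
            labels, swapped = _swap_pass(w, labels)
            q = modularity_value(w, labels)
            if not swapped and q <= q_prev + 1e-13:
                break
            q_prev = q
        labels = _refine_partition(w, labels)
        q = modularity_value(w, labels)
        if q > best_q + 1e-13:
            best_q, best_labels = q, labels
    return best_q, best_labels


def null_network(
    net: WeightedNetwork, seed: int = 0, preserve_degree: bool = False
) -> WeightedNetwork:
    """Random network with the same size and edge-weight distribution.

    Default: topology drawn uniformly among simple graphs with the same
    node and edge count, with the empirical weights randomly assigned to
    the new edges.  ``preserve_degree`` instead rewires the original
    topology by degree-preserving double edge swaps before reassigning the
    permuted weights.
    """
    rng = np.random.default_rng(seed)
    n = net.n_nodes
    iu, ju = np.triu_indices(n, 1)
    (edge_idx,) = np.nonzero(net.weights[iu, ju])
    weights_list = net.weights[iu[edge_idx], ju[edge_idx]]
    m = weights_list.size
    if m == 0:
        return WeightedNetwork(labels=list(net.labels), weights=np.zeros_like(net.weights))
    if preserve_degree:
        g = nx.from_numpy_array((net.weights > 0).astype(int))
        nx.double_edge_swap(
            g, nswap=10 * m, max_tries=1000 * m, seed=int(rng.integers(2**31 - 1))
        )
        pairs = np.array(sorted(tuple(sorted(e)) for e in g.edges()))
    else:
        chosen = rng.choice(iu.size, size=m, replace=False)
        pairs = np.stack([iu[chosen], ju[chosen]], axis=1)
    permuted = rng.permutation(weights_list)
    out = np.zeros_like(net.weights)
    out[pairs[:, 0], pairs[:, 1]] = permuted
    out = out + out.T
    return WeightedNetwork(labels=list(net.labels), weights=out)


def draw_null_networks(
    net: WeightedNetwork,
    n_null: int = 100,
    seed: int = 0,
    preserve_degree: bool = False,
) -> list[WeightedNetwork]:
    """The seeded null-network sample used by :func:`small_worldness`."""
    rng = np.random.default_rng(seed)
    return [
        null_network(
            net, seed=int(rng.integers(2**31 - 1)), preserve_degree=preserve_degree
        )
        for _ in range(n_null)
    ]


def small_worldness(
    net: WeightedNetwork,
    n_null: int = 100,
    seed: int = 0,
    preserve_degree: bool = False,
    null_nets: list[WeightedNetwork] | None = None,
) -> float:
    """Small-world coefficient sigma = (C/C_null) / (L/L_null).

    ``C`` is the mean clustering coefficient and ``L`` the characteristic
    path length; the normalisers are means over ``n_null`` random networks
    with the same size and edge-weight distribution.  About 1 for random
    graphs, > 1 for small-world graphs.  An explicit null sample may be
    supplied via ``null_nets`` (e.g. for cross-validation against other
    metric implementations on a fixed null set).
    """
    _, c = clustering_coefficient(net)
    l, n_inf = characteristic_path_length(net, return_infinite=True)
    if n_inf > 0:
        warnings.warn(
            f"network is disconnected ({n_inf} unreachable pairs); "
            "path length uses finite pairs only"
        )
    if null_nets is None:
        null_nets = draw_null_networks(net, n_null, seed, preserve_degree)
    c_nulls, l_nulls = [], []
    for null in null_nets:
        _, cn = clustering_coefficient(null)
        c_nulls.append(cn)
        l_nulls.append(characteristic_path_length(null))
    c_bar = float(np.mean(c_nulls))
    l_bar = float(np.mean(l_nulls))
    if c_bar <= 0:
        raise ValueError("null networks have zero clustering; sigma undefined")
    return (c / c_bar) / (l / l_bar)


def metric_auc(curve: MetricCurve | tuple[np.ndarray, np.ndarray]) -> float | np.ndarray:
    """Trapezoidal mean of a metric over its density range.

    ``sum_i (Y_i + Y_{i+1})/2 * (d_{i+1} - d_i) / (d_N - d_1)`` — the
    average metric value across densities, insensitive to any single
    threshold choice.  For per-node (2-D) curves, one AUC per node.
    """
    if isinstance(curve, MetricCurve):
        d, y = curve.densities, curve.values
    else:
        d, y = np.asarray(curve[0], float), np.asarray(curve[1], float)
    if d.size < 2:
        raise ValueError("AUC needs at least 2 densities")
    if np.any(np.diff(d) <= 0):
        raise ValueError("densities must be strictly increasing")
    area = np.trapezoid(y, d, axis=0)
    result = area / (d[-1] - d[0])
    return float(result) if np.ndim(result) == 0 else result


def metric_curves(
    matrix: ConnectivityMatrix,
    densities: np.ndarray | None = None,
    metrics: tuple[str, ...] = GLOBAL_METRICS,
    nodal_metrics: tuple[str, ...] = (),
    n_null: int = 100,
    n_restarts: int = 10,
    seed: int = 0,
    null_model: str = "weight_permute",
) -> tuple[dict[str, MetricCurve], dict[str, MetricCurve]]:
    """Evaluate metrics for one subject across the density grid.

    Returns ``(global_curves, nodal_curves)``; nodal curves hold a
    ``(n_densities, n_nodes)`` value matrix.  Stochastic metrics
    (modularity search, small-worldness nulls) are seeded per density.
    """
    if densities is None:
        densities = default_density_grid()
    unknown = set(metrics) - set(GLOBAL_METRICS)
    if unknown:
        raise ValueError(f"unknown metrics: {sorted(unknown)}")
    bad_nodal = set(nodal_metrics) - set(NODAL_METRICS)
    if bad_nodal:
        raise ValueError(f"no nodal form for: {sorted(bad_nodal)}")
    if null_model not in ("weight_permute", "rewire"):
        raise ValueError(f"unknown null model {null_model!r}")
    rng = np.random.default_rng(seed)
    glob: dict[str, list[float]] = {m: [] for m in metrics}
    nodal: dict[str, list[np.ndarray]] = {m: [] for m in nodal_metrics}
    for d in densities:
        net = proportional_threshold(matrix, float(d))
        d_seed = int(rng.integers(2**31 - 1))
        need_clust = "clustering_coefficient" in metrics or (
            "clustering_coefficient" in nodal_metrics
        )
        if need_clust:
            c_nodes, c_mean = clustering_coefficient(net)
            if "clustering_coefficient" in metrics:
                glob["clustering_coefficient"].append(c_mean)
            if "clustering_coefficient" in nodal_metrics:
                nodal["clustering_coefficient"].append(c_nodes)
        if "transitivity" in metrics:
            glob["transitivity"].append(transitivity(net))
        need_le = "local_efficiency" in metrics or "local_efficiency" in nodal_metrics
        if need_le:
            le_nodes, le_mean = local_efficiency(net)
            if "local_efficiency" in metrics:
                glob["local_efficiency"].append(le_mean)
            if "local_efficiency" in nodal_metrics:
                nodal["local_efficiency"].append(le_nodes)
        if "characteristic_path_length" in metrics:
            glob["characteristic_path_length"].append(
                characteristic_path_length(net)
            )
        if "global_efficiency" in metrics:
            glob["global_efficiency"].append(global_efficiency(net))
        if "modularity" in metrics:
            q, _ = modularity(net, n_restarts=n_restarts, seed=d_seed)
            glob["modularity"].append(q)
        if "small_worldness" in metrics:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                glob["small_worldness"].append(
                    small_worldness(
                        net,
                        n_null=n_null,
                        seed=d_seed,
                        preserve_degree=(null_model == "rewire"),
                    )
                )
    global_curves = {
        m: MetricCurve(metric=m, densities=densities, values=np.array(v))
        for m, v in glob.items()
    }
    nodal_curves = {
        m: MetricCurve(metric=m, densities=densities, values=np.array(v))
        for m, v in nodal.items()
    }
    return global_curves, nodal_curves
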