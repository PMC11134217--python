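"""Brute-force reference implementations for validation.

Deliberately slow, literal renderings of every graph metric, used to
cross-check the optimised implementations in :mod:`neoconn.metrics` on
small graphs: explicit triple enumeration for clustering and transitivity,
Floyd–Warshall over all node triples for shortest paths, per-neighbourhood
enumeration for local efficiency, and exhaustive set-partition search for
modularity.  They share only the package's conventions (max-weight
normalisation, edge length = 1 / weight), never its code paths.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np

from .core import WeightedNetwork

__all__ = [
    "clustering_brute",
    "transitivity_brute",
    "floyd_warshall",
    "characteristic_path_length_brute",
    "global_efficiency_brute",
    "local_efficiency_brute",
    "modularity_exhaustive",
    "set_partitions",
    "exact_permutation_p",
]


def _norm(net: WeightedNetwork) -> np.ndarray:
    w = np.array(net.weights, dtype=float)
    return w / w.max() if w.max() > 0 else w


def clustering_brute(net: WeightedNetwork) -> tuple[np.ndarray, float]:
    """Per-node clustering by explicit enumeration of all (j, k) pairs."""
    w = _norm(net)
    n = len(w)
    c = np.zeros(n)
    for i in range(n):
        k = int((w[i] > 0).sum())
        if k < 2:
            continue
        total = 0.0
        for j in range(n):
            for h in range(n):
                if j == i or h == i or j == h:
                    continue
                total += (w[i, j] * w[i, h] * w[j, h]) ** (1.0 / 3.0)
        c[i] = total / (k * (k - 1))
    return c, float(c.mean())


def transitivity_brute(net: WeightedNetwork) -> float:
    w = _norm(net)
    n = len(w)
    num = 0.0
    den = 0.0
    for i in range(n):
        k = int((w[i] > 0).sum())
        den += k * (k - 1)
        for j in range(n):
            for h in range(n):
                if j == i or h == i or j == h:
                    continue
                num += (w[i, j] * w[i, h] * w[j, h]) ** (1.0 / 3.0)
    return num / den if den > 0 else 0.0


def floyd_warshall(lengths: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths by the classic triple loop."""
    n = len(lengths)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and lengths[i, j] > 0:
                d[i, j] = lengths[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def _distances(net: WeightedNetwork) -> np.ndarray:
    w = np.array(net.weights, dtype=float)  # raw weights: length = 1/w
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / w, 0.0)
    return floyd_warshall(lengths)


def characteristic_path_length_brute(net: WeightedNetwork) -> float:
    d = _distances(net)
    n = len(d)
    vals = [d[i, j] for i in range(n) for j in range(n) if i != j and np.isfinite(d[i, j])]
    if not vals:
        raise ValueError("no finite pairs")
    return float(np.mean(vals))


def global_efficiency_brute(net: WeightedNetwork) -> float:
    d = _distances(net)
    n = len(d)
    vals = [
        1.0 / d[i, j] if np.isfinite(d[i, j]) else 0.0
        for i in range(n)
        for j in range(n)
        if i != j
    ]
    return float(np.mean(vals))


def local_efficiency_brute(net: WeightedNetwork) -> tuple[np.ndarray, float]:
    """Local efficiency with per-neighbourhood Floyd–Warshall."""
    w = _norm(net)
    n = len(w)
    e = np.zeros(n)
    for u in range(n):
        neigh = [v for v in range(n) if w[u, v] > 0]
        k = len(neigh)
        if k < 2:
            continue
        sub = w[np.ix_(neigh, neigh)]
        with np.errstate(divide="ignore"):
            lengths = np.where(sub > 0, 1.0 / sub, 0.0)
        d = floyd_warshall(lengths)
        total = 0.0
        for a, j in enumerate(neigh):
            for b, h in enumerate(neigh):
                if a == b:
                    continue
                if np.isfinite(d[a, b]) and d[a, b] > 0:
                    total += (w[u, j] * w[u, h] / d[a, b]) ** (1.0 / 3.0)
        e[u] = total / (k * (k - 1))
    return e, float(e.mean())


def set_partitions(items: list[int]):
    """Yield all set partitions of ``items`` (Bell-number many)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [partition[i] + [first]] + partition[i + 1 :]
        yield [[first]] + partition


def modularity_exhaustive(net: WeightedNetwork) -> tuple[float, list[list[int]]]:
    """Globally optimal weighted modularity by enumerating all partitions.

    Feasible only for small graphs (Bell(10) ~ 1.2e5).
    """
    w = np.array(net.weights, dtype=float)
    n = len(w)
    if n > 10:
        raise ValueError("exhaustive search limited to <= 10 nodes")
    m2 = w.sum()
    if m2 == 0:
        raise ValueError("edgeless graph")
    deg = w.sum(axis=1)
    best_q, best_part = -np.inf, None
    for partition in set_partitions(list(range(n))):
        q = 0.0
        for block in partition:
            idx = np.array(block)
            q += w[np.ix_(idx, idx)].sum() / m2 - (deg[idx].sum() / m2) ** 2
        if q > best_q:
            best_q, best_part = q, partition
    return float(best_q), best_part


def exact_permutation_p(y: np.ndarray, design, stat_fn) -> float:
    """Exact two-sided Freedman–Lane p by full permutation enumeration.

    ``stat_fn(y, design)`` must return the observed group t statistic for
    an outcome vector.  Usable only for tiny n (n! permutations).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    Z = design.nuisance
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    fitted = Z @ beta
    resid = y - fitted
    t_obs = abs(stat_fn(y, design))
    count = 0
    total = 0
    for perm in permutations(range(n)):
        y_star = fitted + resid[list(perm)]
        t_star = abs(stat_fn(y_star, design))
        if t_star >= t_obs - 1e-12:
            count += 1
        total += 1
    return (1 + count) / (1 + total)
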