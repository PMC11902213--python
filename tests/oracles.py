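"""Brute-force reference implementations used only as test oracles.

Each oracle is coded independently of the production path: explicit loops,
direct textbook formulas, no shared helpers with the package.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


# ---------------------------------------------------------------------------
# graph topology
# ---------------------------------------------------------------------------

def clustering_oracle(adj: dict) -> float:
    """Mean local clustering by explicit neighbour-pair counting."""
    vals = []
    for node, nbrs in adj.items():
        k = len(nbrs)
        if k < 2:
            vals.append(0.0)
            continue
        links = 0
        nbrs = list(nbrs)
        for i in range(k):
            for j in range(i + 1, k):
                if nbrs[j] in adj[nbrs[i]]:
                    links += 1
        vals.append(2.0 * links / (k * (k - 1)))
    return sum(vals) / len(vals)


def _bfs_counts(adj: dict, source):
    """Distances and shortest-path counts from one source (BFS)."""
    dist = {source: 0}
    sigma = {source: 1}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                sigma[w] = 0
                queue.append(w)
            if dist[w] == dist[u] + 1:
                sigma[w] += sigma[u]
    return dist, sigma


def betweenness_oracle(adj: dict) -> dict:
    """Normalized betweenness via pairwise shortest-path counting.

    b(v) = Σ_{s<t, s≠v≠t} σ_st(v)/σ_st, normalized by (n−1)(n−2)/2.
    """
    nodes = list(adj)
    n = len(nodes)
    dist = {}
    sigma = {}
    for s in nodes:
        dist[s], sigma[s] = _bfs_counts(adj, s)
    b = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            if t not in dist[s]:
                continue
            d_st = dist[s][t]
            total = sigma[s][t]
            for v in nodes:
                if v in (s, t) or v not in dist[s] or v not in dist[t]:
                    continue
                if dist[s][v] + dist[t][v] == d_st:
                    b[v] += sigma[s][v] * sigma[t][v] / total
    if n > 2:
        scale = 2.0 / ((n - 1) * (n - 2))
        b = {v: x * scale for v, x in b.items()}
    return b


def topology_oracle(adj: dict, edge_signs: dict) -> dict:
    """All Table-style topology metrics by brute force."""
    n = len(adj)
    m = sum(len(v) for v in adj.values()) // 2
    degrees = [len(adj[v]) for v in adj]
    dmax = max(degrees)
    deg_cent = (
        sum(dmax - d for d in degrees) / ((n - 1) * (n - 2)) if n > 2 else None
    )
    b = betweenness_oracle(adj)
    bmax = max(b.values())
    betw_cent = (
        sum(bmax - x for x in b.values()) / (n - 1) if n > 2 else None
    )
    neg = sum(1 for s in edge_signs.values() if s < 0)
    return {
        "nodes": n,
        "edges": m,
        "average_degree": 2.0 * m / n,
        "clustering_coefficient": clustering_oracle(adj),
        "degree_centralization": deg_cent,
        "betweenness_centralization": betw_cent,
        "negative_edge_pct": 100.0 * neg / m if m else 0.0,
    }


# ---------------------------------------------------------------------------
# rank correlation
# ---------------------------------------------------------------------------

def average_ranks(x) -> list:
    """Average ranks with midranks for ties, by sorting positions."""
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y) -> float:
    """Spearman rho as the Pearson correlation of average ranks."""
    rx, ry = average_ranks(list(x)), average_ranks(list(y))
    mx = sum(rx) / len(rx)
    my = sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den


# ---------------------------------------------------------------------------
# factor-analysis weights
# ---------------------------------------------------------------------------

def _jacobi_varimax(load: np.ndarray, max_sweeps: int = 100) -> np.ndarray:
    """Classic pairwise-rotation (Kaiser) varimax, independent of SVD route."""
    lam = load.copy()
    p, k = lam.shape
    if k < 2:
        return lam
    for _ in range(max_sweeps):
        changed = False
        for a in range(k - 1):
            for b in range(a + 1, k):
                x, y = lam[:, a], lam[:, b]
                u = x**2 - y**2
                v = 2.0 * x * y
                num = 2.0 * (p * np.sum(u * v) - np.sum(u) * np.sum(v))
                den = p * np.sum(u**2 - v**2) - (
                    np.sum(u) ** 2 - np.sum(v) ** 2
                )
                phi = 0.25 * math.atan2(num, den)
                if abs(phi) < 1e-12:
                    continue
                c, s = math.cos(phi), math.sin(phi)
                lam[:, a], lam[:, b] = c * x + s * y, -s * x + c * y
                changed = True
        if not changed:
            break
    return lam


def factor_weights_oracle(values: np.ndarray) -> np.ndarray:
    """Communality-share weights from an explicit eigendecomposition.

    Standardize columns, form the correlation matrix directly, eigendecompose
    with np.linalg.eigh, retain eigenvalues > 1 (at least one), varimax-rotate
    via pairwise Jacobi rotations, and return communality shares.
    """
    x = np.asarray(values, dtype=float)
    n, p = x.shape
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    corr = z.T @ z / (n - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    k = max(1, int(np.sum(evals > 1.0)))
    load = evecs[:, :k] * np.sqrt(evals[:k])
    load = _jacobi_varimax(load)
    h2 = np.sum(load**2, axis=1)
    return h2 / h2.sum()


# ---------------------------------------------------------------------------
# sampling adequacy
# ---------------------------------------------------------------------------

def kmo_oracle(corr: np.ndarray) -> float:
    """KMO by direct formula evaluation (explicit loops)."""
    r = np.asarray(corr, dtype=float)
    p = r.shape[0]
    inv = np.linalg.inv(r)
    r2 = 0.0
    q2 = 0.0
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            r2 += r[i, j] ** 2
            q = -inv[i, j] / math.sqrt(inv[i, i] * inv[j, j])
            q2 += q**2
    return r2 / (r2 + q2)
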