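"""Distance-based community-environment association tests.

Bray-Curtis dissimilarity of community counts, Euclidean distance of
(z-scored) environmental indicator profiles, the Mantel permutation test
between two distance matrices, classical principal-coordinate analysis
(PCoA), and the symmetric Procrustes superposition test (PROTEST).

Permutation p-values are one-sided (positive association) with the
add-one convention p = (1 + #{r_perm ≥ r_obs}) / (n_perm + 1), so the
smallest attainable p with 999 permutations is 0.001. All randomness is
driven by an explicit seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .errors import AlignmentError, DegenerateDataError, DomainError
from .io import CountTable, DistanceMatrix, IndicatorTable

__all__ = [
    "bray_curtis",
    "env_distance",
    "mantel",
    "MantelResult",
    "pcoa",
    "procrustes_test",
    "ProcrustesResult",
]


def bray_curtis(table: CountTable | pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between sample rows.

    d(i,j) = Σ|x_i − x_j| / Σ(x_i + x_j) over taxa; lies in [0, 1].
    """
    df = table.data if isinstance(table, CountTable) else table
    x = df.to_numpy(dtype=float)
    if np.any(x < 0):
        raise DomainError("Bray-Curtis requires non-negative abundances")
    if np.any(x.sum(axis=1) == 0):
        raise DomainError("Bray-Curtis undefined for zero-sum samples")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(list(df.index.astype(str)), d)


def env_distance(
    table: IndicatorTable | pd.DataFrame, standardize: bool = True
) -> DistanceMatrix:
    """Euclidean distance between samples' indicator profiles.

    With ``standardize`` each indicator is z-scored first (the default, so
    indicators on different scales contribute comparably).
    """
    vals = table.values() if isinstance(table, IndicatorTable) else table.astype(float)
    x = vals.to_numpy(dtype=float)
    if standardize:
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = vals.columns[np.flatnonzero(sd == 0)[0]]
            raise DegenerateDataError(
                f"zero-variance indicator {bad!r} cannot be standardized"
            )
        x = (x - x.mean(axis=0)) / sd
    d = squareform(pdist(x, metric="euclidean"))
    return DistanceMatrix(list(vals.index.astype(str)), d)


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    method: str
    seed: int | None


def _rank_matrix(d: np.ndarray) -> np.ndarray:
    """Rank-transform the off-diagonal entries of a symmetric matrix.

    The lower triangle of a jointly row/column-permuted matrix is always a
    re-pairing of the same multiset of off-diagonal values, so ranking once
    up front turns a Spearman Mantel test into a Pearson one.
    """
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(d[iu])
    out = np.zeros_like(d)
    out[iu] = ranks
    out.T[iu] = ranks
    return out


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    method: str = "pearson",
    n_perm: int = 999,
    seed: int | None = None,
) -> MantelResult:
    """Mantel permutation test of association between two distance matrices.

    r is the (Pearson or Spearman) correlation of the unraveled lower
    triangles; significance comes from jointly permuting the rows and
    columns of ``d2``, one-sided for positive association.
    """
    if d1.labels != d2.labels:
        raise AlignmentError("distance matrices have different sample labels")
    n = len(d1.labels)
    if n < 4:
        raise DomainError(f"Mantel test needs >= 4 samples, got {n}")
    if method not in ("pearson", "spearman"):
        raise DomainError(f"unknown method {method!r}")
    a = d1.values
    b = d2.values
    if method == "spearman":
        a = _rank_matrix(a)
        b = _rank_matrix(b)
    iu = np.triu_indices(n, k=1)
    va = a[iu]
    va = (va - va.mean()) / va.std()

    def corr_with(bm: np.ndarray) -> float:
        vb = bm[iu]
        sd = vb.std()
        if sd == 0 or va.std() == 0:
            raise DegenerateDataError("constant distance matrix in Mantel test")
        vb = (vb - vb.mean()) / sd
        return float(va @ vb / len(va))

    r_obs = corr_with(b)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr_with(b[np.ix_(perm, perm)]) >= r_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return MantelResult(r=r_obs, p=p, n_perm=n_perm, method=method, seed=seed)


def pcoa(d: DistanceMatrix, k: int = 2) -> pd.DataFrame:
    """Classical principal-coordinate embedding of a distance matrix.

    Double-centers −½ D² and takes the top-k eigenvectors scaled by the
    square roots of their (positive) eigenvalues. Negative eigenvalues
    (possible for semimetric inputs such as Bray-Curtis) are dropped with a
    warning. Columns are ordered by decreasing eigenvalue.
    """
    n = len(d.labels)
    if not 1 <= k < n:
        raise DomainError(f"k must satisfy 1 <= k < n = {n}")
    d2 = d.values**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-12, 1e-10 * abs(evals[0]))
    if np.any(~pos[:k]):
        warnings.warn(
            "requested axes extend into non-positive eigenvalues; "
            "they were dropped",
            stacklevel=2,
        )
    keep = min(k, int(pos.sum()))
    coords = evecs[:, :keep] * np.sqrt(evals[:keep])
    coords -= coords.mean(axis=0, keepdims=True)  # numerically exact centering
    return pd.DataFrame(
        coords,
        index=pd.Index(d.labels, name="sample_id"),
        columns=[f"PCo{i + 1}" for i in range(keep)],
    )


@dataclass
class ProcrustesResult:
    m2: float
    r: float
    p: float
    n_perm: int
    seed: int | None


def _standardize_config(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=0, keepdims=True)
    norm = np.linalg.norm(x)
    if norm == 0:
        raise DegenerateDataError("degenerate (all-identical) configuration")
    return x / norm


def procrustes_test(
    x,
    y,
    n_perm: int = 999,
    seed: int | None = None,
) -> ProcrustesResult:
    """Symmetric Procrustes superposition with a permutation test (PROTEST).

    Both coordinate matrices are centered and scaled to unit Frobenius norm;
    the optimal rotation/reflection and scaling leave the residual
    m² = 1 − (Σ singular values of XᵀY)², with Procrustes correlation
    r = √(1 − m²). Significance permutes the row order of ``y``, one-sided
    on r. The narrower matrix is padded with zero columns.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 2 or y.ndim != 2:
        raise DomainError("coordinate matrices must be 2-D")
    if x.shape[0] != y.shape[0]:
        raise AlignmentError(
            f"row counts differ: {x.shape[0]} vs {y.shape[0]}"
        )
    n = x.shape[0]
    if n < 3:
        raise DegenerateDataError("Procrustes needs >= 3 samples")
    k = max(x.shape[1], y.shape[1])
    if x.shape[1] < k:
        x = np.hstack([x, np.zeros((n, k - x.shape[1]))])
    if y.shape[1] < k:
        y = np.hstack([y, np.zeros((n, k - y.shape[1]))])
    xs = _standardize_config(x)
    ys = _standardize_config(y)

    def trace_corr(yp: np.ndarray) -> float:
        return float(np.linalg.svd(xs.T @ yp, compute_uv=False).sum())

    r_obs = trace_corr(ys)
    m2 = max(0.0, 1.0 - r_obs**2)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        # row permutation preserves both the centering and the norm of ys
        if trace_corr(ys[perm]) >= r_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return ProcrustesResult(
        m2=m2, r=min(1.0, r_obs), p=p, n_perm=n_perm, seed=seed
    )
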