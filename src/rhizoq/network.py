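"""Thresholded microbial co-occurrence networks and their topology.

Pipeline: filter taxa by mean relative abundance, correlate taxon
abundance profiles across samples (Spearman by default), keep edges that
are simultaneously strong (|r| above a cutoff, strict) and significant
(p below a cutoff, strict), then summarize the resulting signed graph with
Table-style topology metrics: node/edge counts, average degree, mean local
clustering, Freeman degree and betweenness centralization, and the share of
negative edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, DomainError
from .io import CountTable, Network, TaxonomyMap

__all__ = [
    "abundance_filter",
    "correlation_matrix",
    "build_network",
    "topology",
    "NetworkTopology",
    "hub_report",
]


def abundance_filter(
    table: CountTable, min_mean_rel_abundance: float
) -> CountTable:
    """Keep taxa whose mean relative abundance exceeds the threshold.

    The comparison is strict (> threshold); column order is preserved.
    """
    if not 0.0 <= min_mean_rel_abundance < 1.0:
        raise DomainError("abundance threshold must lie in [0, 1)")
    rel = table.relative_abundance()
    keep = rel.mean(axis=0) > min_mean_rel_abundance
    if not keep.any():
        warnings.warn(
            "abundance filter removed every taxon", stacklevel=2
        )
    return CountTable(table.data.loc[:, keep.to_numpy()].copy())


def correlation_matrix(
    table: CountTable | pd.DataFrame,
    method: str = "spearman",
    use_relative: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs taxon correlations and two-sided p-values.

    Rows are samples, columns taxa. Spearman uses average ranks for ties;
    Pearson p-values come from the t-distribution. Constant taxa yield
    undefined correlations, recorded as NaN with a warning.
    """
    df = table.relative_abundance() if (
        isinstance(table, CountTable) and use_relative
    ) else (table.data if isinstance(table, CountTable) else table)
    x = df.to_numpy(dtype=float)
    n, p = x.shape
    if n < 4:
        raise DomainError(f"need >= 4 samples for correlation p-values, got {n}")
    if p < 2:
        raise DomainError("need >= 2 taxa")
    constant = np.ptp(x, axis=0) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant taxa: correlations undefined "
            "and recorded as missing",
            stacklevel=2,
        )
    if method == "spearman":
        xx = stats.rankdata(x, axis=0)  # average ranks on ties
    elif method == "pearson":
        xx = x
    else:
        raise DomainError(f"unknown correlation method {method!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.corrcoef(xx, rowvar=False)
        r = np.clip(r, -1.0, 1.0)
        # two-sided p from the t-distribution (the standard approximation
        # for both Pearson and Spearman at these sample sizes)
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    pv = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    pv[np.isclose(np.abs(r), 1.0)] = 0.0
    np.fill_diagonal(pv, 0.0)
    # mark constant-taxon pairs as missing
    if constant.any():
        r[constant, :] = np.nan
        r[:, constant] = np.nan
        pv[constant, :] = np.nan
        pv[:, constant] = np.nan
    np.fill_diagonal(r, 1.0)
    cols = df.columns
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(pv, index=cols, columns=cols),
    )


def build_network(
    r: pd.DataFrame,
    p: pd.DataFrame,
    taxonomy: TaxonomyMap | None = None,
    r_min: float = 0.6,
    p_max: float = 0.01,
    mean_abundance: pd.Series | None = None,
    keep_isolates: bool = False,
    fdr: bool = False,
) -> Network:
    """Signed correlation graph with edges where |r| > r_min and p < p_max.

    Both inequalities are strict. Isolated nodes are dropped unless
    ``keep_isolates``. ``fdr=True`` applies Benjamini-Hochberg to the
    pairwise p-values before thresholding. Node annotations (phylum, mean
    relative abundance) come from ``taxonomy`` / ``mean_abundance``.
    """
    if not r.index.equals(p.index) or not r.columns.equals(p.columns):
        raise AlignmentError("r and p matrices are not aligned")
    taxa = list(r.index)
    rv = r.to_numpy(dtype=float)
    pv = p.to_numpy(dtype=float).copy()
    iu = np.triu_indices(len(taxa), k=1)
    if fdr:
        raw = pv[iu]
        ok = ~np.isnan(raw)
        adj = np.full_like(raw, np.nan)
        if ok.any():
            adj[ok] = _bh_adjust(raw[ok])
        pv[iu] = adj
        pv.T[iu] = adj

    g = nx.Graph()
    if keep_isolates:
        g.add_nodes_from(taxa)
    mask = (
        (np.abs(rv[iu]) > r_min)
        & (pv[iu] < p_max)
        & ~np.isnan(rv[iu])
        & ~np.isnan(pv[iu])
    )
    for i, j in zip(iu[0][mask], iu[1][mask]):
        rij = float(rv[i, j])
        g.add_edge(
            taxa[i],
            taxa[j],
            r=rij,
            p=float(pv[i, j]),
            sign="+" if rij >= 0 else "-",
        )
    for node in g.nodes:
        g.nodes[node]["phylum"] = (
            taxonomy.phylum(node) if taxonomy is not None else "Unknown"
        )
        g.nodes[node]["mean_relative_abundance"] = float(
            mean_abundance.get(node, 0.0)
        ) if mean_abundance is not None else 0.0
    return Network(g)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


@dataclass
class NetworkTopology:
    """Graph-level summary metrics of a co-occurrence network."""

    nodes: int
    edges: int
    average_degree: float
    clustering_coefficient: float
    betweenness_centralization: float | None
    degree_centralization: float | None
    negative_edge_pct: float

    def as_dict(self) -> dict:
        return {
            "nodes": self.nodes,
            "edges": self.edges,
            "average_degree": self.average_degree,
            "clustering_coefficient": self.clustering_coefficient,
            "betweenness_centralization": self.betweenness_centralization,
            "degree_centralization": self.degree_centralization,
            "negative_edge_pct": self.negative_edge_pct,
        }


def topology(net: Network) -> NetworkTopology:
    """Topology metrics of a signed network.

    Clustering is the mean local clustering coefficient with degree-<2
    nodes contributing 0. Centralizations follow Freeman:
    degree: Σ(d_max − d_i) / ((n−1)(n−2)) on raw degrees;
    betweenness: Σ(b_max − b_i) / (n−1) on normalized betweenness.
    Both are undefined (None, with a warning) for n < 3.
    """
    g = net.graph
    n = g.number_of_nodes()
    if n < 1:
        raise DomainError("topology requires at least one node")
    m = g.number_of_edges()
    degrees = np.array([d for _, d in g.degree()], dtype=float)
    avg_degree = 2.0 * m / n
    clustering = float(np.mean(list(nx.clustering(g).values())))
    if n < 3:
        warnings.warn(
            "centralization undefined for networks with < 3 nodes",
            stacklevel=2,
        )
        deg_cent = betw_cent = None
    else:
        deg_cent = float(np.sum(degrees.max() - degrees) / ((n - 1) * (n - 2)))
        b = np.array(
            list(nx.betweenness_centrality(g, normalized=True).values())
        )
        betw_cent = float(np.sum(b.max() - b) / (n - 1))
    neg = sum(1 for _, _, d in g.edges(data=True) if d["r"] < 0)
    neg_pct = 100.0 * neg / m if m else 0.0
    return NetworkTopology(
        nodes=n,
        edges=m,
        average_degree=avg_degree,
        clustering_coefficient=clustering,
        betweenness_centralization=betw_cent,
        degree_centralization=deg_cent,
        negative_edge_pct=neg_pct,
    )


def hub_report(net: Network, top_k: int | None = None) -> pd.DataFrame:
    """Nodes ranked by degree (ties broken by label).

    Columns: taxon, degree, positive_neighbors, negative_neighbors, phylum.
    """
    rows = []
    for node in net.graph.nodes:
        pos = sum(
            1 for _, _, d in net.graph.edges(node, data=True) if d["r"] >= 0
        )
        neg = sum(
            1 for _, _, d in net.graph.edges(node, data=True) if d["r"] < 0
        )
        rows.append(
            {
                "taxon": node,
                "degree": net.graph.degree(node),
                "positive_neighbors": pos,
                "negative_neighbors": neg,
                "phylum": net.graph.nodes[node].get("phylum", "Unknown"),
            }
        )
    df = pd.DataFrame(
        rows, columns=["taxon", "degree", "positive_neighbors",
                       "negative_neighbors", "phylum"]
    )
    df = df.sort_values(
        ["degree", "taxon"], ascending=[False, True]
    ).reset_index(drop=True)
    if top_k is not None:
        df = df.head(top_k)
    return df
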