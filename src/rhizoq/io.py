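"""Tabular and graph I/O plus the core data containers.

The containers are thin, validated wrappers around pandas/networkx objects:

* :class:`IndicatorTable` — replicate-level soil indicator measurements with
  treatment metadata (plant species, amendment dose, replicate).
* :class:`CountTable` — sample × taxon non-negative integer counts.
* :class:`TaxonomyMap` — taxon → (genus, phylum) annotation.
* :class:`Network` — signed thresholded correlation graph.
* :class:`DistanceMatrix` — symmetric distances with labels.

Formats are plain text only: TSV/CSV tables, GraphML or edge-list TSV for
networks, JSON reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    ParseError,
    SchemaError,
    ValidationError,
)

META_COLUMNS = ("sample_id", "species", "dose_pct", "replicate")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class IndicatorTable:
    """Replicate-level soil indicator measurements.

    ``data`` is indexed by sample_id and holds the metadata columns
    ``species`` (str), ``dose_pct`` (float, % w/w), ``replicate`` (int ≥ 1)
    followed by one numeric column per indicator, order preserved.
    """

    data: pd.DataFrame
    indicators: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.indicators:
            self.indicators = [
                c for c in self.data.columns if c not in META_COLUMNS
            ]
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique()
            raise ValidationError(
                f"duplicate sample_id(s): {', '.join(map(str, dupes))}"
            )
        for col in ("species", "dose_pct", "replicate"):
            if col not in self.data.columns:
                raise SchemaError(f"missing required column: {col}")
        if (self.data["replicate"] < 1).any():
            raise ValidationError("replicate must be >= 1")
        vals = self.data[self.indicators]
        bad = ~np.isfinite(vals.to_numpy(dtype=float, na_value=np.nan))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ParseError(
                f"non-finite indicator value at sample "
                f"{vals.index[r]!r}, column {self.indicators[c]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def values(self) -> pd.DataFrame:
        """Indicator columns only, as floats."""
        return self.data[self.indicators].astype(float)

    def subset(self, mask) -> "IndicatorTable":
        return IndicatorTable(self.data.loc[mask].copy(), list(self.indicators))


@dataclass
class CountTable:
    """Sample × taxon non-negative integer count matrix."""

    data: pd.DataFrame  # index sample_id, columns taxon_id

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate sample_id in count table")
        if self.data.columns.has_duplicates:
            raise ValidationError("duplicate taxon_id in count table")
        arr = self.data.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("count table contains non-numeric cells")
        if np.any(arr < 0):
            raise ValidationError("negative counts are not allowed")
        if np.any(arr != np.floor(arr)):
            raise ValidationError(
                "fractional counts are not allowed; relative abundances must "
                "be converted explicitly downstream"
            )
        if arr.shape[1] > 0:  # an all-taxa-filtered table may be empty
            zero = arr.sum(axis=1) == 0
            if zero.any():
                bad = self.data.index[zero][0]
                raise ValidationError(f"all-zero sample row: {bad!r}")
        self.data = self.data.astype(np.int64)
        self.data.index.name = "sample_id"
        self.data.columns.name = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    def relative_abundance(self) -> pd.DataFrame:
        arr = self.data.to_numpy(dtype=float)
        return pd.DataFrame(
            arr / arr.sum(axis=1, keepdims=True),
            index=self.data.index,
            columns=self.data.columns,
        )


@dataclass
class TaxonomyMap:
    """taxon_id → (genus, phylum)."""

    mapping: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        for tid, (genus, phylum) in self.mapping.items():
            if not genus or not phylum:
                raise ValidationError(
                    f"taxon {tid!r} has empty genus or phylum"
                )

    def genus(self, taxon_id: str) -> str:
        return self.mapping[taxon_id][0]

    def phylum(self, taxon_id: str, default: str = "Unknown") -> str:
        if taxon_id in self.mapping:
            return self.mapping[taxon_id][1]
        return default


@dataclass
class Network:
    """Undirected signed correlation graph.

    Nodes carry ``phylum`` and ``mean_relative_abundance``; edges carry the
    correlation ``r``, its p-value ``p`` and ``sign`` ('+' or '-').
    """

    graph: nx.Graph

    def __post_init__(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise ValidationError("self-loops are not allowed")
        for u, v, d in self.graph.edges(data=True):
            r = d.get("r")
            if r is None or not -1.0 <= r <= 1.0:
                raise ValidationError(f"edge ({u},{v}) has invalid r={r}")
            expected = "+" if r >= 0 else "-"
            if d.get("sign") != expected:
                raise ValidationError(
                    f"edge ({u},{v}) sign {d.get('sign')!r} does not match "
                    f"sign(r={r})"
                )

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if d.shape != (n, n):
            raise AlignmentError(
                f"distance matrix shape {d.shape} does not match "
                f"{n} labels"
            )
        if not np.all(np.isfinite(d)):
            raise ValidationError("distance matrix has non-finite entries")
        if np.any(d < 0):
            raise ValidationError("distances must be non-negative")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal is not zero")
        # store exactly symmetric copy
        self.values = (d + d.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    def condensed(self) -> np.ndarray:
        """Lower-triangle vector (scipy condensed order)."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _sep(dialect: str) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    raise ValidationError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'")


def read_indicator_table(path, dialect: str = "tsv") -> IndicatorTable:
    """Read a replicate-level indicator table.

    Expected header: sample_id, species, dose_pct, replicate, then one
    column per indicator. Indicator cells must parse as finite numbers.
    """
    df = pd.read_csv(path, sep=_sep(dialect), dtype=str)
    for col in META_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col}")
    indicators = [c for c in df.columns if c not in META_COLUMNS]
    if not indicators:
        raise SchemaError("no indicator columns found after metadata")
    out = df[["species"]].copy()
    out.index = pd.Index(df["sample_id"], name="sample_id")
    try:
        out["dose_pct"] = pd.to_numeric(df["dose_pct"]).to_numpy()
        out["replicate"] = pd.to_numeric(df["replicate"]).astype(int).to_numpy()
    except (ValueError, TypeError) as exc:
        raise ParseError(f"bad metadata value: {exc}") from exc
    out = out[["species", "dose_pct", "replicate"]]
    for col in indicators:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() | ~np.isfinite(parsed)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ParseError(
                f"cannot parse value {df[col].iloc[row]!r} at row {row + 1}, "
                f"column {col!r}"
            )
        out[col] = parsed.to_numpy(dtype=float)
    return IndicatorTable(out, indicators)


def write_indicator_table(table: IndicatorTable, path, dialect: str = "tsv") -> None:
    table.data.to_csv(path, sep=_sep(dialect), index=True, index_label="sample_id")


def read_count_table(path, orientation: str = "samples_by_taxa") -> CountTable:
    """Read a sample × taxon count TSV.

    ``orientation='taxa_by_samples'`` transposes on load so the in-memory
    layout is always samples × taxa.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "taxa_by_samples":
        df = df.T
    elif orientation != "samples_by_taxa":
        raise ValidationError(f"unknown orientation {orientation!r}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number) or np.any(arr != np.floor(arr)):
        raise ValidationError("count table must contain integers only")
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    df.columns = df.columns.astype(str)
    return CountTable(df)


def write_count_table(table: CountTable, path) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample_id")


def read_taxonomy(path) -> TaxonomyMap:
    """Read a taxonomy TSV with columns taxon_id, genus, phylum."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("taxon_id", "genus", "phylum"):
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col}")
    return TaxonomyMap(
        {r.taxon_id: (r.genus, r.phylum) for r in df.itertuples()}
    )


def write_taxonomy(tax: TaxonomyMap, path) -> None:
    rows = [
        {"taxon_id": t, "genus": g, "phylum": p}
        for t, (g, p) in tax.mapping.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# network I/O
# ---------------------------------------------------------------------------

def write_network(net: Network, path, format: str = "graphml") -> None:
    """Write a network as GraphML or edge-list TSV (columns u,v,r,p,sign)."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(net.graph, path)
    elif format == "edge-tsv":
        rows = [
            {"u": u, "v": v, "r": d["r"], "p": d["p"], "sign": d["sign"]}
            for u, v, d in sorted(net.graph.edges(data=True))
        ]
        pd.DataFrame(rows, columns=["u", "v", "r", "p", "sign"]).to_csv(
            path, sep="\t", index=False, float_format="%.6g"
        )
    else:
        raise ValidationError(f"unknown network format {format!r}")


def read_network_edges(path) -> Network:
    """Read an edge-list TSV written by :func:`write_network`."""
    df = pd.read_csv(path, sep="\t", dtype={"u": str, "v": str, "sign": str})
    g = nx.Graph()
    for row in df.itertuples():
        g.add_edge(row.u, row.v, r=float(row.r), p=float(row.p), sign=row.sign)
    return Network(g)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def write_report(results: Mapping[str, object], path) -> None:
    """Write an aggregated JSON report.

    ``results`` maps stage names to JSON-serializable blocks (or None for
    stages that did not run). Output is deterministic: sorted keys, fixed
    separators, so identical inputs + seed give byte-identical files.
    """
    if not any(v is not None for v in results.values()):
        raise ValidationError("report requires at least one stage output")

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    text = json.dumps(dict(results), indent=2, sort_keys=True, default=default)
    Path(path).write_text(text + "\n")
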