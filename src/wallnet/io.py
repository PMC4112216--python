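"""Readers and writers for the pipeline's text formats.

Matrices travel as TSV/CSV with a header row and row-ID first column
(delimiter inferred from the extension); networks as GraphML plus an
edge-list TSV mirror.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

__all__ = [
    "read_matrix",
    "read_trait_table",
    "write_matrix",
    "read_id_list",
    "write_network",
    "read_edgelist",
]


def _sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a numeric matrix with row-ID first column and header row."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique()
        lines = [i + 2 for i, rid in enumerate(df.index) if rid in set(dup)]
        raise ValueError(f"duplicate row IDs {list(dup[:5])} (lines {lines[:10]}) in {path}")
    if pd.Index(df.columns).has_duplicates:
        raise ValueError(f"duplicate column IDs in {path}")
    bad = df.columns[~df.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
    if len(bad):
        col = bad[0]
        nonnum = pd.to_numeric(df[col], errors="coerce").isna()
        line = int(nonnum.to_numpy().argmax()) + 2
        raise ValueError(f"non-numeric value in column {col!r} near line {line} of {path}")
    return df.astype(float)


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Read a samples x traits table, honoring an optional units header row.

    If the second data row is entirely non-numeric it is interpreted as unit
    strings and stored in ``table.attrs['units']``.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=_sep(path), index_col=0, dtype=str)
    units = None
    if len(raw) and pd.to_numeric(raw.iloc[0], errors="coerce").isna().all():
        units = raw.iloc[0].to_dict()
        raw = raw.iloc[1:]
    df = raw.apply(pd.to_numeric)
    if units:
        df.attrs["units"] = units
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_sep(path))
    return path


def read_id_list(path: str | Path) -> list[str]:
    """One identifier per line; blank lines ignored."""
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_network(graph: nx.Graph, path: str | Path, format: str = "graphml") -> Path:
    """Write a network as GraphML or an edge-list TSV.

    Edge attributes (weight, sign, rescued) and node attributes (kind, clade)
    are preserved; the edge list carries columns source, target and every edge
    attribute present.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "graphml":
        nx.write_graphml(graph, path)
    elif format == "edgelist":
        keys: list[str] = sorted({k for _, _, d in graph.edges(data=True) for k in d})
        rows = [
            {"source": u, "target": v, **{k: d.get(k, "") for k in keys}}
            for u, v, d in graph.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["source", "target", *keys]).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format {format!r}")
    return path


def read_edgelist(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
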