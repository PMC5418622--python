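"""Readers and writers for the plain-text formats used by the pipeline.

All tables are delimited text (CSV by default).  A Ct table has one row per
cell with a ``day`` column, an optional ``qc`` column and one column per
assay; undetected wells may be encoded as blank, ``NA`` or an instrument
sentinel such as ``999``.  Networks are serialized to GraphML (lossless
round trip) or Graphviz DOT (for rendering: weak edges dashed, strong edges
solid).
"""
from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import CtMatrix, ExpressionMatrix, MarkerPanel

#: On-disk encodings accepted for an undetected well.
DEFAULT_SENTINELS = ("", "NA", "999")

DEFAULT_CONTROLS = ("GAPDH", "ACTB")


# ---------------------------------------------------------------------------
# Ct matrices
# ---------------------------------------------------------------------------

def read_ct_matrix(
    path: str | Path,
    day_column: str = "day",
    qc_column: str | None = "qc",
    sentinels: Sequence[str] = DEFAULT_SENTINELS,
    controls: Sequence[str] = DEFAULT_CONTROLS,
    sep: str = ",",
) -> CtMatrix:
    """Read a cell x assay Ct table.

    The first column is taken as the cell identifier.  ``sentinels`` are the
    string encodings mapped to the internal undetected marker.  ``controls``
    names the control assays; entries absent from the table are ignored.

    Raises
    ------
    ValueError
        If ``day_column`` is missing, or a detected well holds a non-numeric
        value (the error names the offending cell and assay).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, index_col=0, sep=sep)
    if day_column not in df.columns:
        raise ValueError(
            f"day column {day_column!r} not found in {path}; "
            f"columns present: {list(df.columns)}"
        )
    day = df[day_column].astype(int).to_numpy()
    if qc_column is not None and qc_column in df.columns:
        qc = [v if v else "ok" for v in df[qc_column]]
    else:
        qc = None
    skip = {day_column, qc_column}
    assay_cols = [c for c in df.columns if c not in skip]
    sentinel_set = {s.strip() for s in sentinels}
    values = np.empty((len(df), len(assay_cols)), dtype=float)
    for j, col in enumerate(assay_cols):
        for i, raw in enumerate(df[col]):
            token = raw.strip()
            if token in sentinel_set:
                values[i, j] = np.nan
            else:
                try:
                    values[i, j] = float(token)
                except ValueError:
                    raise ValueError(
                        f"non-numeric Ct {raw!r} for cell {df.index[i]!r}, "
                        f"assay {col!r}"
                    ) from None
    return CtMatrix(
        values=values,
        cell_ids=list(df.index),
        day=day,
        assay_ids=assay_cols,
        control_assays=[c for c in controls if c in assay_cols],
        qc_flags=qc,
    )


def write_ct_matrix(
    ct: CtMatrix, path: str | Path, sentinel: str = "", sep: str = ","
) -> None:
    """Write a Ct matrix; undetected wells are encoded as ``sentinel``."""
    df = ct.to_frame()
    df.to_csv(path, na_rep=sentinel, sep=sep, float_format="%.17g")


# ---------------------------------------------------------------------------
# Expression matrices, panels, bulk tables
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path, sep: str = ",") -> ExpressionMatrix:
    df = pd.read_csv(path, index_col=0, sep=sep, float_precision="round_trip")
    if "day" not in df.columns:
        raise ValueError(f"expression table {path} lacks a 'day' column")
    day = df["day"].astype(int).to_numpy()
    genes = [c for c in df.columns if c != "day"]
    return ExpressionMatrix(
        values=df[genes].to_numpy(float),
        cell_ids=list(df.index.astype(str)),
        day=day,
        gene_ids=genes,
    )


def write_expression_matrix(
    expr: ExpressionMatrix, path: str | Path, sep: str = ","
) -> None:
    expr.to_frame().to_csv(path, sep=sep, float_format="%.17g")


def read_marker_panel(path: str | Path, sep: str = ",") -> MarkerPanel:
    """Read a two-column ``gene,category`` table."""
    df = pd.read_csv(path, sep=sep)
    cols = [c.lower() for c in df.columns]
    if "gene" in cols and "category" in cols:
        gene_col = df.columns[cols.index("gene")]
        cat_col = df.columns[cols.index("category")]
    else:  # headerless two-column file
        df = pd.read_csv(path, sep=sep, header=None, names=["gene", "category"])
        gene_col, cat_col = "gene", "category"
    return MarkerPanel(dict(zip(df[gene_col].astype(str), df[cat_col].astype(str))))


def write_marker_panel(panel: MarkerPanel, path: str | Path, sep: str = ",") -> None:
    panel.to_frame().to_csv(path, index=False, sep=sep)


def read_bulk_matrix(path: str | Path, sep: str = ",") -> pd.DataFrame:
    """Read a gene x timepoint bulk table; columns become integer day labels."""
    df = pd.read_csv(path, index_col=0, sep=sep, float_precision="round_trip")
    df.columns = [int(c) for c in df.columns]
    df.index.name = "gene"
    return df.astype(float)


def write_bulk_matrix(bulk: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    bulk.to_csv(path, sep=sep, float_format="%.17g")


# ---------------------------------------------------------------------------
# Cell graphs
# ---------------------------------------------------------------------------

def _dot_quote(s: str) -> str:
    return '"' + s.replace('"', r"\"") + '"'


def write_graph(graph: nx.Graph, path: str | Path, fmt: str = "graphml") -> None:
    """Serialize a cell graph to GraphML or DOT.

    GraphML preserves all node/edge attributes and round-trips through
    :func:`read_graph`.  DOT output styles weak edges ``dashed`` and strong
    edges ``solid`` and embeds layout coordinates as ``pos`` when present.
    """
    if graph.number_of_nodes() < 1:
        raise ValueError("cannot serialize an empty graph")
    fmt = fmt.lower()
    if fmt == "graphml":
        nx.write_graphml(graph, str(path))
    elif fmt == "dot":
        lines = ["graph cells {"]
        for node, attrs in graph.nodes(data=True):
            parts = []
            if "day" in attrs:
                parts.append(f"day={attrs['day']}")
            if "x" in attrs and "y" in attrs:
                parts.append(f'pos="{attrs["x"]:.4f},{attrs["y"]:.4f}"')
            if "size" in attrs:
                parts.append(f"width={attrs['size']:.4f}")
            attr_str = f" [{', '.join(parts)}]" if parts else ""
            lines.append(f"    {_dot_quote(str(node))}{attr_str};")
        for u, v, attrs in graph.edges(data=True):
            style = "solid" if attrs.get("kind") == "strong" else "dashed"
            weight = attrs.get("similarity", math.nan)
            lines.append(
                f"    {_dot_quote(str(u))} -- {_dot_quote(str(v))} "
                f'[style={style}, weight="{weight:.6f}"];'
            )
        lines.append("}")
        Path(path).write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown graph format {fmt!r}; use 'graphml' or 'dot'")


def read_graph(path: str | Path) -> nx.Graph:
    """Read a GraphML cell graph written by :func:`write_graph`."""
    return nx.read_graphml(str(path))


def write_edge_list(graph: nx.Graph, path: str | Path, sep: str = ",") -> None:
    rows = [
        {
            "cell_i": u,
            "cell_j": v,
            "similarity": attrs.get("similarity", math.nan),
            "kind": attrs.get("kind", ""),
        }
        for u, v, attrs in graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["cell_i", "cell_j", "similarity", "kind"]).to_csv(
        path, index=False, sep=sep
    )
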