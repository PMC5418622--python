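"""Relational cell-cell networks from an SVD embedding.

Cells are embedded in their top singular components (PCA scores of the
gene-centered expression matrix).  Pairwise Euclidean distances on the
retained components are normalized by the largest distance in the dataset,
giving a bounded similarity ``s = 1 - d/d_max``.  Edges at or above a weak
similarity threshold are candidates; each node keeps only its best-scoring
candidates (per-node cap), the union over nodes forms the undirected edge
set, and edges at or above the strong threshold are classed ``strong``
(rendered solid) versus ``weak`` (dashed).  A force-directed layout places
the cells for plotting, and per-gene overlays size each node as
``2**(relative expression)``.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .config import PipelineConfig
from .datatypes import ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass
class Embedding:
    """Per-cell coordinates in the retained singular components."""

    coordinates: np.ndarray  # cell x component PC scores
    explained_variance_share: np.ndarray
    gene_loadings: np.ndarray  # gene x component
    cell_ids: list[str]
    gene_ids: list[str]
    day: np.ndarray

    @property
    def n_components(self) -> int:
        return self.coordinates.shape[1]


def _pca(X: np.ndarray, n_pcs: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Gene-centered SVD; returns (scores, variance shares, loadings, rank).

    Component signs are fixed so the largest-magnitude gene loading of each
    component is positive.  Variance shares are relative to the total
    variance of the centered matrix.  Warns when the rank falls short of
    the requested number of components.
    """
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = (s[0] if s.size else 0.0) * max(Xc.shape) * np.finfo(float).eps
    rank = int(np.sum(s > tol))
    if rank == 0:
        # all cells identical: a single degenerate component of zeros
        k = 1
        return (
            np.zeros((X.shape[0], 1)),
            np.zeros(1),
            np.zeros((X.shape[1], 1)),
            0,
        )
    k = min(n_pcs, rank)
    if rank < n_pcs:
        warnings.warn(
            f"matrix rank {rank} < requested {n_pcs} components; "
            f"returning {rank}",
            stacklevel=3,
        )
    for j in range(k):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    total = float((s**2).sum())
    scores = U[:, :k] * s[:k]
    shares = s[:k] ** 2 / total
    return scores, shares, Vt[:k].T, rank


def svd_embed(expr: ExpressionMatrix, config: PipelineConfig | None = None) -> Embedding:
    """Embed cells in the first ``config.n_pcs`` singular components.

    Columns (genes) are mean-centered; cell coordinates are the left
    singular vectors scaled by the singular values, i.e. conventional PCA
    scores.  If the matrix rank is below ``n_pcs`` only the available
    components are returned, with a warning.
    """
    if config is None:
        config = PipelineConfig()
    if expr.n_cells < 2:
        raise ValueError("svd_embed requires at least 2 cells")
    if expr.n_genes < 2:
        raise ValueError("svd_embed requires at least 2 genes")
    if not np.any(expr.values):
        raise ValueError("expression matrix is all-zero")
    scores, shares, loadings, rank = _pca(expr.values, config.n_pcs)
    return Embedding(
        coordinates=scores,
        explained_variance_share=shares,
        gene_loadings=loadings,
        cell_ids=list(expr.cell_ids),
        gene_ids=list(expr.gene_ids),
        day=expr.day.copy(),
    )


def normalized_similarity(embedding: Embedding) -> np.ndarray:
    """Cell x cell similarity ``1 - d/d_max`` on the retained components.

    The matrix is symmetric with unit diagonal and values in [0, 1]; the
    most distant cell pair has similarity exactly 0.  If all cells coincide
    (``d_max = 0``) similarity is all-ones, with a warning.
    """
    n = embedding.coordinates.shape[0]
    if n < 2:
        raise ValueError("similarity requires at least 2 cells")
    d = squareform(pdist(embedding.coordinates))
    dmax = d.max()
    if dmax == 0.0:
        warnings.warn("all cells identical in the embedding; similarity set to 1",
                      stacklevel=2)
        return np.ones((n, n))
    s = 1.0 - d / dmax
    np.fill_diagonal(s, 1.0)
    return s


def per_node_selection(
    similarity: np.ndarray, config: PipelineConfig
) -> list[list[int]]:
    """For each node, the indices of its selected best-scoring neighbours.

    Candidates are neighbours at or above the weak threshold, ranked by
    similarity descending with ties broken by cell index ascending; at most
    ``max_edges_per_node`` are kept per node.
    """
    S = np.asarray(similarity, float)
    n = S.shape[0]
    out = []
    for i in range(n):
        cand = [j for j in range(n) if j != i and S[i, j] >= config.weak_threshold]
        cand.sort(key=lambda j: (-S[i, j], j))
        out.append(cand[: config.max_edges_per_node])
    return out


def build_network(
    similarity: np.ndarray,
    config: PipelineConfig | None = None,
    cell_ids: list[str] | None = None,
    day: np.ndarray | None = None,
) -> nx.Graph:
    """Thresholded k-best network from a similarity matrix.

    For each node, neighbours with similarity at or above the weak
    threshold are ranked (similarity descending, ties broken by cell index
    ascending) and the top ``max_edges_per_node`` retained.  The edge set is
    the union of these per-node selections; an edge is ``strong`` when its
    similarity is at or above the strong threshold, else ``weak``.
    """
    if config is None:
        config = PipelineConfig()
    S = np.asarray(similarity, float)
    n = S.shape[0]
    if S.shape != (n, n) or not np.allclose(S, S.T, atol=1e-9):
        raise ValueError("similarity must be a symmetric square matrix")
    if not np.allclose(np.diag(S), 1.0, atol=1e-9):
        raise ValueError("similarity must have unit diagonal")
    ids = cell_ids if cell_ids is not None else [f"cell{i}" for i in range(n)]
    G = nx.Graph()
    for i, cid in enumerate(ids):
        attrs = {"day": int(day[i])} if day is not None else {}
        G.add_node(cid, **attrs)
    selected: set[tuple[int, int]] = set()
    for i, chosen in enumerate(per_node_selection(S, config)):
        for j in chosen:
            selected.add((min(i, j), max(i, j)))
    for i, j in sorted(selected):
        s = float(S[i, j])
        kind = "strong" if s >= config.strong_threshold else "weak"
        G.add_edge(ids[i], ids[j], similarity=s, kind=kind)
    log.info("network: %d nodes, %d edges (%d strong)", n, G.number_of_edges(),
             sum(1 for *_, a in G.edges(data=True) if a["kind"] == "strong"))
    return G


def layout_network(graph: nx.Graph, seed: int | None = None) -> nx.Graph:
    """Attach 2-D force-directed layout coordinates to each node.

    Uses a spring (stress-minimizing, neato-style) layout weighted by edge
    similarity; deterministic for a given seed.  A single node is placed at
    the origin.  Returns a copy with ``x``/``y`` node attributes.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot lay out an empty graph")
    G = graph.copy()
    if G.number_of_nodes() == 1:
        pos = {next(iter(G.nodes)): (0.0, 0.0)}
    else:
        pos = nx.spring_layout(G, seed=seed if seed is not None else 0,
                               weight="similarity")
    for node, (x, y) in pos.items():
        G.nodes[node]["x"] = float(x)
        G.nodes[node]["y"] = float(y)
    return G


def overlay_expression(
    graph: nx.Graph, expr: ExpressionMatrix, gene: str
) -> nx.Graph:
    """Size each node as ``2**(relative expression of gene)``.

    An undetected gene (r = 0) yields size 1.  Returns a copy with ``size``
    and ``overlay_gene`` node attributes.
    """
    values = expr.gene(gene)  # raises KeyError listing genes if unknown
    lookup = dict(zip(expr.cell_ids, values))
    G = graph.copy()
    G.graph["overlay_gene"] = gene
    for node in G.nodes:
        r = float(lookup.get(str(node), 0.0))
        G.nodes[node]["size"] = float(2.0**r)
    return G
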