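import networkx as nx
import numpy as np
import pytest

import ctgraph as cg
from ctgraph.config import PipelineConfig


@pytest.fixture(scope="session")
def default_run():
    """The default scenario run once at the package's default seed:
    (raw CtMatrix, SyntheticTruth, filtered CtMatrix, ExpressionMatrix)."""
    ct, truth = cg.generate_ct_matrix(
        cg.default_emt_scenario(), seed=cg.DEFAULT_SEED
    )
    ct_f, _removed = cg.filter_cells(ct)
    expr = cg.ct_to_relative_expression(ct_f)
    return ct, truth, ct_f, expr


@pytest.fixture(scope="session")
def default_network(default_run):
    """Relational network of the default run plus its cell->day map."""
    _, _, _, expr = default_run
    emb = cg.svd_embed(expr)
    sim = cg.normalized_similarity(emb)
    G = cg.build_network(sim, cell_ids=expr.cell_ids, day=expr.day)
    days = {c: int(d) for c, d in zip(expr.cell_ids, expr.day)}
    return G, days


def random_ct_matrix(rng, n_cells=6, n_assays=4, undetected_frac=0.2):
    """Small random CtMatrix for round-trip and QC tests."""
    values = rng.uniform(8.0, 24.0, size=(n_cells, n_assays))
    mask = rng.random(values.shape) < undetected_frac
    values[mask] = np.nan
    assays = [f"G{j}" for j in range(n_assays - 1)] + ["GAPDH"]
    flags = list(rng.choice(["ok", "ok", "ok", "doublet", "empty"], size=n_cells))
    return cg.CtMatrix(
        values=values,
        cell_ids=[f"c{i}" for i in range(n_cells)],
        day=rng.integers(0, 4, size=n_cells),
        assay_ids=assays,
        control_assays=["GAPDH"],
        qc_flags=flags,
    )


def brute_force_network(S, config: PipelineConfig) -> nx.Graph:
    """Independent O(n^2) enumeration of the thresholded k-best network.

    Plain nested loops: every node lists its above-threshold neighbours,
    keeps its ``max_edges_per_node`` best (similarity desc, index asc), and
    an undirected edge exists when either endpoint kept it.
    """
    n = S.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(n))
    kept = []
    for i in range(n):
        scored = []
        for j in range(n):
            if j != i and S[i, j] >= config.weak_threshold:
                scored.append((-S[i, j], j))
        scored.sort()
        kept.append({j for _, j in scored[: config.max_edges_per_node]})
    for i in range(n):
        for j in range(i + 1, n):
            if j in kept[i] or i in kept[j]:
                kind = "strong" if S[i, j] >= config.strong_threshold else "weak"
                G.add_edge(i, j, similarity=float(S[i, j]), kind=kind)
    return G


def random_similarity(rng, n):
    """Random symmetric unit-diagonal similarity matrix in [0, 1] with mass
    near the thresholds so weak/strong/absent all occur."""
    A = rng.uniform(0.85, 1.0, size=(n, n))
    S = (A + A.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return S
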