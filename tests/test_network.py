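import networkx as nx
import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

import ctgraph as cg
from ctgraph.config import PipelineConfig
from ctgraph.network import per_node_selection
from conftest import brute_force_network, random_similarity


def make_expr(values, days=None):
    values = np.asarray(values, float)
    n, m = values.shape
    return cg.ExpressionMatrix(
        values=values,
        cell_ids=[f"c{i}" for i in range(n)],
        day=np.zeros(n, int) if days is None else np.asarray(days),
        gene_ids=[f"G{j}" for j in range(m)],
    )


class TestSvdEmbed:
    def test_rank_one_matrix_has_unit_first_share(self):
        base = np.array([1.0, 2.0, 3.0])
        values = np.outer([0.0, 1.0, 2.0, 3.0], base)
        with pytest.warns(UserWarning, match="rank"):
            emb = cg.svd_embed(make_expr(values))
        assert emb.n_components == 1
        assert emb.explained_variance_share[0] == pytest.approx(1.0)

    def test_duplicating_cells_preserves_component_directions(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 10, size=(12, 6))
        emb1 = cg.svd_embed(make_expr(X))
        emb2 = cg.svd_embed(make_expr(np.vstack([X, X])))
        # loadings (directions) are unchanged by duplicating every cell
        np.testing.assert_allclose(
            np.abs(emb1.gene_loadings), np.abs(emb2.gene_loadings), atol=1e-9
        )

    def test_scores_match_covariance_eigendecomposition(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            X = rng.uniform(0, 10, size=(20, 10))
            emb = cg.svd_embed(make_expr(X), PipelineConfig(n_pcs=3))
            Xc = X - X.mean(axis=0)
            evals, evecs = np.linalg.eigh(Xc.T @ Xc)
            order = np.argsort(evals)[::-1]
            evals, evecs = evals[order], evecs[:, order]
            for j in range(3):
                i = int(np.argmax(np.abs(evecs[:, j])))
                if evecs[i, j] < 0:
                    evecs[:, j] *= -1
            scores = Xc @ evecs[:, :3]
            shares = evals[:3] / evals.sum()
            np.testing.assert_allclose(emb.coordinates, scores, atol=1e-8)
            np.testing.assert_allclose(
                emb.explained_variance_share, shares, atol=1e-8
            )

    def test_variance_shares_nonincreasing_in_unit_interval(self, default_run):
        *_, expr = default_run
        emb = cg.svd_embed(expr)
        ev = emb.explained_variance_share
        assert np.all((ev >= 0) & (ev <= 1))
        assert np.all(np.diff(ev) <= 1e-12)

    def test_single_cell_is_error(self):
        with pytest.raises(ValueError, match="2 cells"):
            cg.svd_embed(make_expr([[1.0, 2.0]]))

    def test_all_zero_matrix_is_error(self):
        with pytest.raises(ValueError, match="all-zero"):
            cg.svd_embed(make_expr(np.zeros((4, 3))))


class TestNormalizedSimilarity:
    def test_identical_cells_have_similarity_one(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 9.0]])
        with pytest.warns(UserWarning, match="rank"):  # 3 collinear cells
            emb = cg.svd_embed(make_expr(X), PipelineConfig(n_pcs=2))
        S = cg.normalized_similarity(emb)
        assert S[0, 1] == pytest.approx(1.0)

    def test_farthest_pair_has_similarity_zero(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(0, 12, size=(9, 5))
        emb = cg.svd_embed(make_expr(X))
        S = cg.normalized_similarity(emb)
        assert S.min() == pytest.approx(0.0)
        np.testing.assert_allclose(np.diag(S), 1.0)
        np.testing.assert_allclose(S, S.T)

    def test_matches_brute_force_pairwise_computation(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 10, size=(5, 4))
        emb = cg.svd_embed(make_expr(X))
        S = cg.normalized_similarity(emb)
        C = emb.coordinates
        d = np.zeros((5, 5))
        for i in range(5):
            for j in range(5):
                d[i, j] = np.sqrt(((C[i] - C[j]) ** 2).sum())
        expected = 1.0 - d / d.max()
        np.testing.assert_allclose(S, expected, atol=1e-12)

    def test_degenerate_all_identical_warns_and_returns_ones(self):
        emb = cg.Embedding(
            coordinates=np.zeros((3, 2)),
            explained_variance_share=np.zeros(2),
            gene_loadings=np.zeros((4, 2)),
            cell_ids=["a", "b", "c"],
            gene_ids=list("wxyz"),
            day=np.zeros(3, int),
        )
        with pytest.warns(UserWarning, match="identical"):
            S = cg.normalized_similarity(emb)
        assert np.all(S == 1.0)

    def test_distance_contraction_onto_top_components(self, default_run):
        # distances in the 3-PC embedding never exceed full-space distances
        *_, expr = default_run
        sub = expr.subset_cells(np.arange(0, expr.n_cells, 7))
        emb = cg.svd_embed(sub)
        d_pc = pdist(emb.coordinates)
        Xc = sub.values - sub.values.mean(axis=0)
        d_full = pdist(Xc)
        assert np.all(d_pc <= d_full + 1e-9)


class TestBuildNetwork:
    def test_three_cell_weak_strong_absent(self):
        S = np.array([
            [1.0, 0.95, 0.995],
            [0.95, 1.0, 0.50],
            [0.995, 0.50, 1.0],
        ])
        G = cg.build_network(S)
        assert G.number_of_edges() == 2
        assert G.edges["cell0", "cell1"]["kind"] == "weak"
        assert G.edges["cell0", "cell2"]["kind"] == "strong"
        assert not G.has_edge("cell1", "cell2")

    def test_hub_selection_capped_at_max_edges(self):
        # hub node 0 with 60 above-threshold neighbours selects exactly 50
        n = 61
        S = np.full((n, n), 0.5)
        rng = np.random.default_rng(6)
        sims = rng.uniform(0.92, 0.98, size=60)
        S[0, 1:] = S[1:, 0] = sims
        np.fill_diagonal(S, 1.0)
        config = PipelineConfig()
        chosen = per_node_selection(S, config)
        assert len(chosen[0]) == 50
        best50 = set(np.argsort(-sims)[:50] + 1)
        assert set(chosen[0]) == best50

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(7)
        config = PipelineConfig(max_edges_per_node=4)
        for _ in range(30):
            n = int(rng.integers(3, 16))
            S = random_similarity(rng, n)
            G = cg.build_network(S, config)
            oracle = brute_force_network(S, config)
            ours = {
                (frozenset((u, v)), a["kind"])
                for u, v, a in G.edges(data=True)
            }
            theirs = {
                (frozenset((f"cell{u}", f"cell{v}")), a["kind"])
                for u, v, a in oracle.edges(data=True)
            }
            assert ours == theirs

    def test_raising_weak_threshold_never_adds_edges(self):
        rng = np.random.default_rng(8)
        S = random_similarity(rng, 20)
        edges = [
            set(map(frozenset, cg.build_network(
                S, PipelineConfig(weak_threshold=w, max_edges_per_node=6)
            ).edges))
            for w in (0.90, 0.94, 0.97)
        ]
        assert edges[2] <= edges[1] <= edges[0]

    def test_raising_edge_cap_never_removes_edges(self):
        rng = np.random.default_rng(9)
        S = random_similarity(rng, 20)
        edges = [
            set(map(frozenset, cg.build_network(
                S, PipelineConfig(max_edges_per_node=c)
            ).edges))
            for c in (2, 5, 50)
        ]
        assert edges[0] <= edges[1] <= edges[2]

    def test_no_self_edges_and_similarity_floor(self, default_network):
        G, _ = default_network
        for u, v, attrs in G.edges(data=True):
            assert u != v
            assert attrs["similarity"] >= 0.92
            expected = "strong" if attrs["similarity"] >= 0.99 else "weak"
            assert attrs["kind"] == expected

    def test_asymmetric_matrix_is_error(self):
        S = np.array([[1.0, 0.5], [0.9, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            cg.build_network(S)

    def test_invalid_thresholds_are_configuration_error(self):
        with pytest.raises(ValueError, match="thresholds"):
            PipelineConfig(weak_threshold=0.99, strong_threshold=0.92)


class TestLayoutAndOverlay:
    def test_single_node_placed_at_origin(self):
        G = nx.Graph()
        G.add_node("solo")
        out = cg.layout_network(G, seed=1)
        assert (out.nodes["solo"]["x"], out.nodes["solo"]["y"]) == (0.0, 0.0)

    def test_two_connected_nodes_get_distinct_coordinates(self):
        G = nx.Graph()
        G.add_edge("a", "b", similarity=0.99)
        out = cg.layout_network(G, seed=1)
        pa = (out.nodes["a"]["x"], out.nodes["a"]["y"])
        pb = (out.nodes["b"]["x"], out.nodes["b"]["y"])
        assert pa != pb

    def test_layout_deterministic_for_seed(self, default_network):
        G, _ = default_network
        a = cg.layout_network(G, seed=42)
        b = cg.layout_network(G, seed=42)
        for n in G.nodes:
            assert a.nodes[n]["x"] == b.nodes[n]["x"]
            assert a.nodes[n]["y"] == b.nodes[n]["y"]

    @pytest.mark.parametrize("r,size", [(0.0, 1.0), (12.0, 4096.0), (3.0, 8.0)])
    def test_node_size_is_two_to_the_expression(self, r, size):
        expr = make_expr([[r], [0.0]])
        G = nx.Graph()
        G.add_nodes_from(["c0", "c1"])
        out = cg.overlay_expression(G, expr, "G0")
        assert out.nodes["c0"]["size"] == size
        assert out.nodes["c1"]["size"] == 1.0

    def test_overlay_sizes_monotone_in_expression(self, default_run):
        *_, expr = default_run
        G = nx.Graph()
        G.add_nodes_from(expr.cell_ids)
        out = cg.overlay_expression(G, expr, "CDH1")
        sizes = np.array([out.nodes[c]["size"] for c in expr.cell_ids])
        order = np.argsort(expr.gene("CDH1"))
        assert np.all(np.diff(sizes[order]) >= 0)

    def test_unknown_overlay_gene_lists_available(self, default_run):
        *_, expr = default_run
        G = nx.Graph()
        G.add_nodes_from(expr.cell_ids)
        with pytest.raises(KeyError, match="SOX17"):
            cg.overlay_expression(G, expr, "NOT_A_GENE")
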