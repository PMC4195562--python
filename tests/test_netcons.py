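import networkx as nx
import numpy as np
import pandas as pd
import pytest

from coupletrans.core_io import PipelineConfig
from coupletrans.coupling import pearson_correlation
from coupletrans.netcons import (
    AdjacencyMatrix,
    bootstrap_ec_null,
    classify_ec,
    coexpression_adjacency,
    ec_score,
    ec_scores,
    empirical_p_lower,
    full_matrix_correlation,
    node_properties,
    run_netcons,
    threshold_graph,
)
from coupletrans.synthetic_data import SyntheticConfig, generate_paired_dataset


def _random_adjacency(rng, n=6, cols=5):
    X = rng.normal(size=(n, cols))
    return coexpression_adjacency(X, [f"g{i}" for i in range(n)])


class TestAdjacency:
    def test_identical_profiles_weight_one(self):
        X = np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0]])
        A = coexpression_adjacency(X, ["a", "b"])
        assert A.W[0, 1] == pytest.approx(1.0)

    def test_matches_pairwise_oracle(self, rng):
        X = rng.normal(size=(3, 5))
        A = coexpression_adjacency(X, ["a", "b", "c"])
        for i in range(3):
            for j in range(i + 1, 3):
                assert A.W[i, j] == pytest.approx(
                    pearson_correlation(X[i], X[j]), abs=1e-12)

    def test_constant_row_gives_undefined_entries(self, rng):
        X = rng.normal(size=(3, 4))
        X[1] = 7.0
        A = coexpression_adjacency(X, ["a", "b", "c"])
        assert np.isnan(A.W[0, 1]) and np.isnan(A.W[1, 2])
        assert A.W[1, 1] == 1.0

    def test_too_few_genes_or_columns(self, rng):
        with pytest.raises(ValueError, match="2 gene"):
            coexpression_adjacency(rng.normal(size=(1, 5)), ["a"])
        with pytest.raises(ValueError, match="3 cell-type"):
            coexpression_adjacency(rng.normal(size=(3, 2)), list("abc"))

    def test_asymmetric_rejected(self):
        W = np.eye(3)
        W[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            AdjacencyMatrix(list("abc"), W)


class TestECScore:
    def test_self_identity(self, rng):
        A = _random_adjacency(rng)
        for g in A.gene_ids:
            assert ec_score(A, A, g) == pytest.approx(1.0, abs=1e-12)

    def test_negated_rows_give_minus_one(self, rng):
        A = _random_adjacency(rng)
        W2 = -A.W.copy()
        np.fill_diagonal(W2, 1.0)
        B = AdjacencyMatrix(A.gene_ids, W2)
        for g in A.gene_ids:
            assert ec_score(A, B, g) == pytest.approx(-1.0, abs=1e-12)

    def test_four_gene_worked_example(self):
        # EC of gene a = PCC of its off-diagonal rows in the two networks
        row_tr = [0.9, 0.1, -0.2]
        row_tl = [0.8, 0.2, -0.1]
        W_tr = np.eye(4)
        W_tl = np.eye(4)
        W_tr[0, 1:] = row_tr
        W_tr[1:, 0] = row_tr
        W_tl[0, 1:] = row_tl
        W_tl[1:, 0] = row_tl
        A = AdjacencyMatrix(list("abcd"), W_tr)
        B = AdjacencyMatrix(list("abcd"), W_tl)
        assert ec_score(A, B, "a") == pytest.approx(
            pearson_correlation(row_tr, row_tl), abs=1e-12)

    def test_vectorized_matches_scalar(self, rng):
        A = _random_adjacency(rng)
        B = _random_adjacency(rng)
        expect = [ec_score(A, B, g) for g in A.gene_ids]
        np.testing.assert_allclose(ec_scores(A, B), expect, atol=1e-12)

    def test_absent_gene_is_error(self, rng):
        A = _random_adjacency(rng)
        with pytest.raises(KeyError):
            ec_score(A, A, "missing")

    def test_undefined_entries_pairwise_excluded(self, rng):
        # gene b constant -> its incident entries NaN; EC of gene a must
        # equal the PCC over the remaining entries
        X_tr = rng.normal(size=(5, 5))
        X_tl = rng.normal(size=(5, 5))
        X_tr[1] = 3.0
        A = coexpression_adjacency(X_tr, list("abcde"))
        B = coexpression_adjacency(X_tl, list("abcde"))
        mask = [2, 3, 4]  # entries of row a excluding diag and gene b
        expect = pearson_correlation(A.W[0, mask], B.W[0, mask])
        assert ec_score(A, B, "a") == pytest.approx(expect, abs=1e-12)


class TestFullMatrixCorrelation:
    def test_identity_and_negation(self, rng):
        A = _random_adjacency(rng)
        assert full_matrix_correlation(A, A) == pytest.approx(1.0, abs=1e-12)
        W2 = -A.W.copy()
        np.fill_diagonal(W2, 1.0)
        B = AdjacencyMatrix(A.gene_ids, W2)
        assert full_matrix_correlation(A, B) == pytest.approx(-1.0, abs=1e-12)

    def test_three_gene_toy_equals_triangle_vector_pcc(self, rng):
        A = _random_adjacency(rng, n=3)
        B = _random_adjacency(rng, n=3)
        va = [A.W[0, 1], A.W[0, 2], A.W[1, 2]]
        vb = [B.W[0, 1], B.W[0, 2], B.W[1, 2]]
        assert full_matrix_correlation(A, B) == pytest.approx(
            pearson_correlation(va, vb), abs=1e-12)

    def test_symmetric_in_arguments(self, rng):
        A = _random_adjacency(rng)
        B = _random_adjacency(rng)
        assert full_matrix_correlation(A, B) == pytest.approx(
            full_matrix_correlation(B, A), abs=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        A = _random_adjacency(rng, n=4)
        B = _random_adjacency(rng, n=5)
        with pytest.raises(ValueError):
            full_matrix_correlation(A, B)


class TestBootstrapECNull:
    def test_seed_determinism(self, small_dataset, fast_config):
        _, em_tr, em_tl, smap, _ = small_dataset
        genes = [f"G{i:05d}" for i in range(30)]
        a, fa = bootstrap_ec_null(em_tr, em_tl, smap, 4, fast_config,
                                  genes=genes)
        b, fb = bootstrap_ec_null(em_tr, em_tl, smap, 4, fast_config,
                                  genes=genes)
        pd.testing.assert_frame_equal(a, b)
        np.testing.assert_array_equal(fa, fb)

    def test_pool_equals_k_collapses_null(self, small_dataset):
        # adjacency matrices are invariant to profile column order, so when
        # every draw is the full pool the null reproduces the observed
        # networks exactly: per-gene EC null sd is 0 and the full-matrix
        # null is constant
        _, em_tr, em_tl, smap, _ = small_dataset
        k_tr = len(smap.promoters("transcriptome"))
        k_tl = len(smap.promoters("translatome"))
        assert k_tr == k_tl  # generator symmetry
        cfg = PipelineConfig(n_boot=10, seed=1)
        genes = [f"G{i:05d}" for i in range(20)]
        null, fullmat = bootstrap_ec_null(em_tr, em_tl, smap, k_tr, cfg,
                                          genes=genes)
        np.testing.assert_allclose(null["null_sd"], 0.0, atol=1e-12)
        np.testing.assert_allclose(fullmat, fullmat[0], atol=1e-12)


class TestClassifyEC:
    def test_class_conditions(self):
        ec = np.array([0.4, -0.1, 0.0, np.nan, -0.4])
        nm = np.zeros(5)
        sd = np.array([0.1, 0.1, 0.1, 0.1, 0.0])
        z, cls = classify_ec(ec, nm, sd, 1.96)
        assert list(cls) == ["conserved", "neutral", "neutral",
                             "degenerate", "degenerate"]

    def test_positive_z_with_negative_ec_not_conserved(self):
        # conserved requires both Z >= crit and EC > 0
        z, cls = classify_ec(np.array([-0.2]), np.array([-0.9]),
                             np.array([0.1]), 1.96)
        assert z[0] == pytest.approx(7.0)
        assert cls[0] == "neutral"


def test_empirical_p_lower_with_smoothing():
    null = np.array([0.1, 0.2, 0.3, 0.4])
    assert empirical_p_lower(0.05, null) == pytest.approx(1 / 5)
    assert empirical_p_lower(0.25, null) == pytest.approx(3 / 5)
    assert empirical_p_lower(0.9, null) == pytest.approx(1.0)


class TestRewiredCalibration:
    def test_all_null_rewired_rate_near_nominal(self):
        """On data without planted structure the one-sided rewired call rate
        should sit near the nominal 2.5%."""
        cfg = SyntheticConfig(n_genes=1000, frac_coupled=0.0,
                              frac_uncoupled=0.0, frac_null=1.0,
                              frac_motif_genes=0.0, seed=31)
        em_tr, em_tl, smap, _ = generate_paired_dataset(cfg)
        table, _ = run_netcons(em_tr, em_tl, smap, "common",
                               PipelineConfig(n_boot=200, seed=8))
        rate = (table["ec_class"] == "rewired").mean()
        assert 0.01 <= rate <= 0.045


class TestThresholdGraph:
    def _adj(self, w01, w02=0.0, w12=0.0):
        W = np.eye(3)
        W[0, 1] = W[1, 0] = w01
        W[0, 2] = W[2, 0] = w02
        W[1, 2] = W[2, 1] = w12
        return AdjacencyMatrix(list("abc"), W)

    def test_threshold_selects_edges(self):
        G = threshold_graph(self._adj(0.95, 0.85), 0.9)
        assert set(map(frozenset, G.edges)) == {frozenset({"a", "b"})}

    def test_above_max_gives_empty_graph(self):
        G = threshold_graph(self._adj(0.5, 0.6, 0.7), 0.9)
        assert G.number_of_edges() == 0 and G.number_of_nodes() == 3

    def test_low_threshold_gives_complete_graph(self):
        G = threshold_graph(self._adj(0.5, 0.6, 0.7), 0.1)
        assert G.number_of_edges() == 3

    def test_nan_entries_give_no_edge(self):
        W = np.eye(3)
        W[0, 1] = W[1, 0] = np.nan
        W[0, 2] = W[2, 0] = 0.95
        G = threshold_graph(AdjacencyMatrix(list("abc"), W), 0.9)
        assert set(map(frozenset, G.edges)) == {frozenset({"a", "c"})}

    @pytest.mark.parametrize("t", [0.0, -1.0, 1.5])
    def test_invalid_threshold_rejected(self, t):
        with pytest.raises(ValueError):
            threshold_graph(self._adj(0.5), t)


class TestNodeProperties:
    def test_triangle(self):
        G = nx.complete_graph(3)
        nodes, edges, transitivity = node_properties(G)
        assert (nodes["degree"] == 2).all()
        assert transitivity == pytest.approx(1.0)
        assert (nodes["clustering"] == 1.0).all()
        assert len(edges) == 3

    def test_path_has_zero_transitivity(self):
        G = nx.path_graph(3)
        _, _, transitivity = node_properties(G)
        assert transitivity == 0.0

    def test_single_isolated_node_all_zero(self):
        G = nx.Graph()
        G.add_node("solo")
        nodes, edges, transitivity = node_properties(G)
        row = nodes.loc["solo"]
        assert (row == 0).all()
        assert edges.empty and transitivity == 0.0

    def test_isolated_nodes_zero_in_mixed_graph(self):
        G = nx.complete_graph(3)
        G.add_node("iso")
        nodes, _, _ = node_properties(G)
        assert (nodes.loc["iso"] == 0).all()
        assert (nodes.drop(index="iso")["alpha_centrality"] > 0).all()

    def test_star_centre_dominates(self):
        G = nx.star_graph(4)
        nodes, _, _ = node_properties(G)
        assert nodes.loc[0, "eigenvector"] == pytest.approx(1.0)
        assert nodes.loc[0, "betweenness"] == nodes["betweenness"].max()
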