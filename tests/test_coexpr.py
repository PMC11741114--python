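"""Ensemble coexpression network: correlation contract, scale-free
thresholding against a grid oracle, consensus rules, infomap modules."""

import numpy as np
import networkx as nx
import pandas as pd
import pytest
from scipy.stats import linregress
from sklearn.metrics import adjusted_rand_score

import mixlink as ml


def _as_expr(X: np.ndarray, prefix: str = "g") -> ml.ExprMatrix:
    df = pd.DataFrame(X, index=[f"{prefix}{i}" for i in range(X.shape[0])])
    return ml.ExprMatrix(counts=df.astype(float), normalized=True)


class TestPerturbedBootstrapCorrelation:
    def test_full_data_no_noise_equals_textbook_pearson(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((5, 4))
        C = ml.perturbed_bootstrap_correlation(_as_expr(X), noise_sd=0.0,
                                               bootstrap=False).to_numpy()
        for i in range(5):
            for j in range(5):
                xi, xj = X[i] - X[i].mean(), X[j] - X[j].mean()
                r = float(xi @ xj / np.sqrt((xi @ xi) * (xj @ xj)))
                assert C[i, j] == pytest.approx(r, abs=1e-12)

    def test_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(2)
        C = ml.perturbed_bootstrap_correlation(_as_expr(rng.standard_normal((20, 10))),
                                               noise_sd=0.2, seed=3).to_numpy()
        np.testing.assert_allclose(C, C.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(C), 1.0)
        assert np.abs(C).max() <= 1.0

    def test_collinear_genes_have_unit_correlation(self):
        base = np.linspace(0, 1, 8)
        X = np.vstack([base, 2 * base + 3, -base])
        C = ml.perturbed_bootstrap_correlation(_as_expr(X), noise_sd=0.0,
                                               bootstrap=False).to_numpy()
        assert C[0, 1] == pytest.approx(1.0)
        assert C[0, 2] == pytest.approx(-1.0)

    def test_zero_variance_gene_gets_zero_correlations(self):
        X = np.vstack([np.linspace(0, 1, 6), np.full(6, 3.0)])
        C = ml.perturbed_bootstrap_correlation(_as_expr(X), noise_sd=0.0,
                                               bootstrap=False).to_numpy()
        assert C[0, 1] == 0.0 and C[1, 1] == 1.0

    def test_fewer_than_four_samples_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            ml.perturbed_bootstrap_correlation(_as_expr(np.zeros((5, 3))))


class TestScaleFreeThreshold:
    def test_preferential_attachment_surrogate_reaches_r2_target(self):
        A = nx.to_numpy_array(nx.barabasi_albert_graph(500, 2, seed=42))
        np.fill_diagonal(A, 1.0)
        t, diag = ml.select_scale_free_threshold(A, candidate_thresholds=(0.5,))
        assert t == 0.5
        assert diag["r2"].iloc[0] >= 0.8 and diag["slope"].iloc[0] < 0

    def test_complete_graph_has_no_negative_slope_fit(self):
        A = np.ones((30, 30))
        with pytest.raises(ValueError, match="negative-slope"):
            ml.select_scale_free_threshold(A, candidate_thresholds=(0.5,))

    def test_choice_matches_independent_grid_recomputation(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((300, 20))
        C = np.corrcoef(X)
        cands = (0.3, 0.4, 0.5, 0.6, 0.7)
        chosen, diag = ml.select_scale_free_threshold(C, cands, r2_target=0.999)
        # independent recomputation: same binning contract, scipy fit
        best_t, best_r2 = None, -np.inf
        for t in cands:
            A = (np.abs(C) >= t).astype(float)
            np.fill_diagonal(A, 0)
            k = A.sum(axis=1)
            k = k[k > 0]
            if k.size == 0 or k.max() == k.min():
                continue
            edges = np.logspace(np.log10(k.min()), np.log10(k.max()), 11)
            edges[-1] += 1e-9
            cnt, _ = np.histogram(k, bins=edges)
            centers = np.sqrt(edges[:-1] * edges[1:])
            m = cnt > 0
            if m.sum() < 3:
                continue
            fit = linregress(np.log10(centers[m]),
                             np.log10(cnt[m] / cnt.sum() / np.diff(edges)[m]))
            if fit.slope < 0 and fit.rvalue ** 2 > best_r2:
                best_t, best_r2 = t, fit.rvalue ** 2
        assert chosen == best_t

    def test_edge_sets_nested_across_thresholds(self):
        rng = np.random.default_rng(11)
        C = np.corrcoef(rng.standard_normal((50, 15)))
        low = {(i, j) for i in range(50) for j in range(i + 1, 50) if abs(C[i, j]) >= 0.3}
        high = {(i, j) for i in range(50) for j in range(i + 1, 50) if abs(C[i, j]) >= 0.6}
        assert high <= low


class TestConsensusNetwork:
    def test_single_run_full_consensus_equals_that_runs_edges(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal(20)
        X = np.vstack([z + 0.3 * rng.standard_normal(20) for _ in range(15)]
                      + [rng.standard_normal(20) for _ in range(45)])
        expr = _as_expr(X)
        cfg = ml.EnsembleConfig(n_runs=1, consensus_frac=1.0, noise_sd=0.1, seed=9)
        net = ml.build_consensus_network(expr, cfg)
        seed0 = int(np.random.SeedSequence(9).spawn(1)[0].generate_state(1)[0] % (2 ** 31))
        C = ml.perturbed_bootstrap_correlation(expr, noise_sd=0.1, seed=seed0).to_numpy()
        t, _ = ml.select_scale_free_threshold(C, cfg.candidate_thresholds, cfg.r2_target)
        np.fill_diagonal(C, 0)
        expected = int((np.abs(C) >= t).sum()) // 2
        assert net.n_edges == expected
        assert net.run_thresholds == [t]

    def test_same_config_gives_identical_networks(self, small_dataset):
        _, (_, expr, _) = small_dataset
        filtered, _ = ml.filter_genes(expr)
        norm = ml.normalize_expression(filtered)
        cfg = ml.EnsembleConfig(n_runs=5, seed=21)
        n1 = ml.build_consensus_network(norm, cfg)
        n2 = ml.build_consensus_network(norm, cfg)
        pd.testing.assert_frame_equal(n1.edges, n2.edges)
        assert n1.edge_support == n2.edge_support

    def test_planted_blocks_separate_cleanly(self):
        # two 25-gene blocks (within r ~ 0.9, between ~ 0, latents
        # orthogonalized) embedded among background noise genes
        rng = np.random.default_rng(13)
        n = 40
        za = rng.standard_normal(n)
        zb = rng.standard_normal(n)
        zb -= za * (za @ zb) / (za @ za)
        zb *= np.std(za) / np.std(zb)
        X = np.vstack([za + 0.3 * rng.standard_normal(n) for _ in range(25)]
                      + [zb + 0.3 * rng.standard_normal(n) for _ in range(25)]
                      + [rng.standard_normal(n) for _ in range(100)])
        net = ml.build_consensus_network(_as_expr(X), ml.EnsembleConfig(n_runs=10, seed=4))
        idx = {g: i for i, g in enumerate(net.nodes)}
        within = between = 0
        for a, b in zip(net.edges["gene_a"], net.edges["gene_b"]):
            ia, ib = idx[a], idx[b]
            if ia >= 50 or ib >= 50:
                continue
            if (ia < 25) == (ib < 25):
                within += 1
            else:
                between += 1
        assert between == 0
        assert within / (2 * 25 * 24 / 2) > 0.8


class TestDetectModules:
    @staticmethod
    def _clique_network(sizes):
        genes, edges = [], {"gene_a": [], "gene_b": [], "support": []}
        start = 0
        for s in sizes:
            members = [f"g{start + i}" for i in range(s)]
            genes.extend(members)
            for i in range(s):
                for j in range(i + 1, s):
                    edges["gene_a"].append(members[i])
                    edges["gene_b"].append(members[j])
                    edges["support"].append(1.0)
            start += s
        ed = pd.DataFrame(edges)
        support = {(a, b): 1.0 for a, b in zip(ed["gene_a"], ed["gene_b"])}
        return ml.ConsensusNetwork(nodes=pd.Index(genes), edges=ed, edge_support=support,
                                   run_thresholds=[0.5], n_runs=1, consensus_frac=1.0)

    def test_two_disconnected_cliques_give_two_modules(self):
        net = self._clique_network([20, 20])
        part = ml.detect_modules(net, min_module_size=10, seed=0)
        assert sorted(part.module_sizes.tolist()) == [20, 20]
        m_first = part.assignment["g0"]
        assert (part.assignment[[f"g{i}" for i in range(20)]] == m_first).all()

    def test_module_ids_ordered_by_descending_size(self):
        net = self._clique_network([12, 30, 18])
        part = ml.detect_modules(net, min_module_size=10, seed=0)
        sizes = part.module_sizes
        assert list(sizes.index) == [1, 2, 3]
        assert sizes.tolist() == sorted(sizes.tolist(), reverse=True)

    def test_small_communities_left_unassigned(self):
        net = self._clique_network([20, 4])
        part = ml.detect_modules(net, min_module_size=10, seed=0)
        assert part.module_sizes.tolist() == [20]
        assert (part.assignment[[f"g{20 + i}" for i in range(4)]] == 0).all()

    def test_planted_partition_graph_recovered(self):
        g = nx.planted_partition_graph(4, 50, 0.3, 0.01, seed=5)
        edges = pd.DataFrame(
            {"gene_a": [f"g{u}" for u, v in g.edges()],
             "gene_b": [f"g{v}" for u, v in g.edges()],
             "support": 1.0})
        net = ml.ConsensusNetwork(nodes=pd.Index([f"g{i}" for i in range(200)]),
                                  edges=edges, edge_support={}, run_thresholds=[],
                                  n_runs=1, consensus_frac=1.0)
        part = ml.detect_modules(net, min_module_size=10, seed=1)
        planted = [i // 50 for i in range(200)]
        ari = adjusted_rand_score(planted, part.assignment[[f"g{i}" for i in range(200)]])
        assert ari >= 0.9

    def test_empty_network_rejected(self):
        net = ml.ConsensusNetwork(nodes=pd.Index(["a", "b"]),
                                  edges=pd.DataFrame(columns=["gene_a", "gene_b", "support"]),
                                  edge_support={}, run_thresholds=[], n_runs=1,
                                  consensus_frac=1.0)
        with pytest.raises(ValueError, match="no edges"):
            ml.detect_modules(net)
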