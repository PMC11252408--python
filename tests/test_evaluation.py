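"""Marker ranking, fidelity metrics, transition confidence and pseudotime."""

import numpy as np
import pytest
import scipy.sparse as sp

import trajblend as tb
from trajblend.datamodel import AnnotatedExpressionMatrix, RunConfig, ValidationError
from trajblend.evaluation import (MarkerTable, graph_pseudotime,
                                  marker_correlation, marker_cosine,
                                  pseudotime_stats, rank_markers,
                                  transition_confidence)
from trajblend.overlap_nocd import NeighborGraph


def labelled_matrix(counts, labels, pseudotime=None):
    counts = np.asarray(counts)
    m = AnnotatedExpressionMatrix(
        counts=sp.csr_matrix(counts),
        gene_ids=[f"g{i}" for i in range(counts.shape[1])],
        cell_ids=[f"c{i}" for i in range(counts.shape[0])],
        cell_type=np.array(labels, dtype=object),
        pseudotime=pseudotime)
    return tb.normalize_log1p(m)


class TestRankMarkers:
    def test_planted_markers_dominate_top_list(self, bridge_ref_lognorm):
        table = rank_markers(bridge_ref_lognorm, top_n=10)
        markers = bridge_ref_lognorm.provenance["marker_sets"]
        for t, cols in markers.items():
            planted = {f"gene_{i}" for i in cols}
            hits = sum(g in planted for g in table.genes(t))
            assert hits >= 9, t

    def test_identical_groups_deterministic(self):
        counts = np.tile([[5, 3, 1, 2]], (20, 1))
        m = labelled_matrix(counts, ["A"] * 10 + ["B"] * 10)
        a = rank_markers(m, top_n=4)
        b = rank_markers(m, top_n=4)
        assert a.markers == b.markers

    def test_top_n_clipped_to_gene_count(self, bridge_ref_lognorm):
        table = rank_markers(bridge_ref_lognorm, top_n=10_000)
        assert all(len(v) == bridge_ref_lognorm.n_genes
                   for v in table.markers.values())

    def test_tiny_group_excluded_with_warning(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 20, (21, 10))
        m = labelled_matrix(counts, ["A"] * 10 + ["B"] * 10 + ["C"])
        with pytest.warns(UserWarning, match="excluded"):
            table = rank_markers(m, top_n=5)
        assert "C" not in table.markers


class TestMarkerCorrelation:
    def test_identity_is_one(self, bridge_ref_lognorm):
        table = rank_markers(bridge_ref_lognorm, top_n=50)
        corr = marker_correlation(bridge_ref_lognorm, bridge_ref_lognorm, table)
        assert all(abs(v - 1.0) < 1e-12 for v in corr.values())

    def test_reversed_pattern_is_anticorrelated(self):
        rng = np.random.default_rng(1)
        base = rng.integers(1, 50, (30, 20))
        base[:15, :10] += 200  # A's markers
        ref = labelled_matrix(base, ["A"] * 15 + ["B"] * 15)
        flipped = labelled_matrix(base[:, ::-1], ["A"] * 15 + ["B"] * 15)
        flipped.gene_ids = list(ref.gene_ids)  # same names, reversed values
        table = rank_markers(ref, top_n=20)
        corr = marker_correlation(ref, flipped, table)
        assert corr["A"] < 0

    def test_matches_direct_covariance_oracle(self):
        rng = np.random.default_rng(2)
        ref = labelled_matrix(rng.integers(1, 99, (40, 20)),
                              ["A"] * 20 + ["B"] * 20)
        gen = labelled_matrix(rng.integers(1, 99, (30, 20)),
                              ["A"] * 15 + ["B"] * 15)
        table = rank_markers(ref, top_n=20)
        corr = marker_correlation(ref, gen, table)
        X = ref.layers["lognorm"].toarray()
        G = gen.layers["lognorm"].toarray()
        gidx = {g: i for i, g in enumerate(ref.gene_ids)}
        for t in ("A", "B"):
            cols = [gidx[g] for g in table.genes(t)]
            a = X[ref.cell_type == t].mean(0)[cols]
            b = G[gen.cell_type == t].mean(0)[cols]
            ca, cb = a - a.mean(), b - b.mean()
            r = (ca @ cb) / np.sqrt((ca @ ca) * (cb @ cb))
            assert abs(corr[t] - r) < 1e-12

    def test_missing_type_reported_none(self, bridge_ref_lognorm):
        table = rank_markers(bridge_ref_lognorm, top_n=10)
        no_bridge = bridge_ref_lognorm.subset_cells(
            bridge_ref_lognorm.cell_type != "bridge")
        corr = marker_correlation(bridge_ref_lognorm, no_bridge, table)
        assert corr["bridge"] is None


class TestMarkerCosine:
    def _table(self, genes_by_type):
        return MarkerTable({t: [(g, 1.0) for g in gs]
                            for t, gs in genes_by_type.items()},
                           top_n=max(map(len, genes_by_type.values())))

    def test_identical_lists(self):
        t = self._table({"A": [f"g{i}" for i in range(200)]})
        assert marker_cosine(t, t)["A"] == 1.0

    def test_disjoint_lists(self):
        a = self._table({"A": ["g1", "g2"]})
        b = self._table({"A": ["g3", "g4"]})
        assert marker_cosine(a, b)["A"] == 0.0

    def test_half_shared(self):
        a = self._table({"A": [f"g{i}" for i in range(200)]})
        b = self._table({"A": [f"g{i}" for i in range(100, 300)]})
        assert abs(marker_cosine(a, b)["A"] - 0.5) < 1e-12

    def test_absent_type_reported_none(self):
        a = self._table({"A": ["g1"]})
        b = self._table({"B": ["g1"]})
        assert marker_cosine(a, b)["A"] is None


class TestTransitionConfidence:
    def _graph(self, A):
        return NeighborGraph(sp.csr_matrix(np.asarray(A)), k=1)

    def test_no_inter_edges_gives_zero(self):
        A = np.zeros((4, 4), dtype=int)
        A[0, 1] = A[1, 0] = 1
        A[2, 3] = A[3, 2] = 1
        directed, sym = transition_confidence(
            self._graph(A), ["a", "a", "b", "b"], [0, 0, 1, 1])
        assert sym.loc["a", "b"] == 0.0

    def test_bridged_clusters_positive_and_directed(self):
        n = 10
        A = np.zeros((2 * n, 2 * n), dtype=int)
        A[:n, :n] = 1
        A[n:, n:] = 1
        A[n - 1, n] = A[n, n - 1] = 1  # the bridge edge
        np.fill_diagonal(A, 0)
        labels = ["early"] * n + ["late"] * n
        pt = [0.1] * n + [0.9] * n
        directed, sym = transition_confidence(self._graph(A), labels, pt)
        assert sym.loc["early", "late"] > 0
        assert directed.loc["early", "late"] == sym.loc["early", "late"]
        assert directed.loc["late", "early"] == 0.0

    def test_symmetric_before_direction(self):
        rng = np.random.default_rng(0)
        A = np.triu(rng.random((30, 30)) < 0.2, 1)
        A = (A | A.T).astype(int)
        labels = rng.choice(["a", "b", "c"], 30)
        pt = rng.random(30)
        _, sym = transition_confidence(self._graph(A), labels, pt)
        assert np.allclose(sym.values, sym.values.T)
        assert ((sym.values >= 0) & (sym.values <= 1)).all()

    def test_single_cluster_empty_matrix(self):
        A = np.zeros((3, 3), dtype=int)
        directed, _ = transition_confidence(self._graph(A), ["a"] * 3, [0, 1, 2])
        assert directed.size <= 1


class TestGraphPseudotime:
    def test_path_graph_hand_values(self):
        A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        g = NeighborGraph(sp.csr_matrix(A), k=1)
        pt = graph_pseudotime(g, 0)
        assert np.allclose(pt, [0, 0.5, 1.0])

    def test_root_is_zero(self):
        A = np.array([[0, 1], [1, 0]])
        g = NeighborGraph(sp.csr_matrix(A), k=1)
        assert graph_pseudotime(g, 1)[1] == 0.0

    def test_relabelling_permutes_consistently(self):
        rng = np.random.default_rng(1)
        A = np.triu(rng.random((12, 12)) < 0.4, 1)
        A = (A | A.T).astype(int)
        A[0, 1] = A[1, 0] = 1  # ensure root connectivity
        g = NeighborGraph(sp.csr_matrix(A), k=1)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pt = graph_pseudotime(g, 0)
            perm = rng.permutation(12)
            gp = NeighborGraph(sp.csr_matrix(A[np.ix_(perm, perm)]), k=1)
            pt_p = graph_pseudotime(gp, int(np.where(perm == 0)[0][0]))
        assert np.allclose(pt_p, pt[perm])

    def test_disconnected_cells_get_one_with_warning(self):
        A = np.zeros((3, 3), dtype=int)
        A[0, 1] = A[1, 0] = 1
        g = NeighborGraph(sp.csr_matrix(A), k=1)
        with pytest.warns(UserWarning, match="disconnected"):
            pt = graph_pseudotime(g, 0)
        assert pt[2] == 1.0


class TestPseudotimeStats:
    def test_constant_pseudotime_zero_variance(self):
        m = labelled_matrix(np.ones((4, 3), dtype=int), ["T"] * 4,
                            pseudotime=np.full(4, 0.5))
        var, summary = pseudotime_stats(m, "T")
        assert var == 0.0 and summary["n"] == 4

    def test_two_point_population_variance(self):
        m = labelled_matrix(np.ones((2, 3), dtype=int), ["T", "T"],
                            pseudotime=np.array([0.0, 1.0]))
        var, _ = pseudotime_stats(m, "T")
        assert abs(var - 0.25) < 1e-12

    def test_missing_target_raises(self):
        m = labelled_matrix(np.ones((2, 3), dtype=int), ["A", "A"],
                            pseudotime=np.array([0.0, 1.0]))
        with pytest.raises(ValidationError):
            pseudotime_stats(m, "T")
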