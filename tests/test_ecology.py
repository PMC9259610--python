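"""Niche metrics, diversity, Bray-Curtis/PCoA/ANOSIM, co-occurrence networks."""

import warnings

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from plastisphere_n2o import ecology as eco


def table_from_rows(rows, taxa=None, samples=None):
    arr = np.asarray(rows, dtype=float)
    samples = samples or [f"s{i}" for i in range(arr.shape[0])]
    taxa = taxa or [f"t{i}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, index=samples, columns=taxa)


class TestNiche:
    def test_uniform_breadth_is_state_count(self):
        t = table_from_rows([[2.0]] * 5, taxa=["a"])
        assert eco.niche_breadth(t, "a") == pytest.approx(5.0)

    def test_concentrated_breadth_is_one(self):
        t = table_from_rows([[9.0], [0.0], [0.0]], taxa=["a"])
        assert eco.niche_breadth(t, "a") == pytest.approx(1.0)

    def test_hand_profile(self):
        t = table_from_rows([[0.5], [0.3], [0.2]], taxa=["a"])
        assert eco.niche_breadth(t, "a") == pytest.approx(1 / 0.38)

    def test_breadth_bounds_and_permutation_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.random((6, 1))
        t = table_from_rows(x, taxa=["a"])
        b = eco.niche_breadth(t, "a")
        assert 1.0 <= b <= 6.0
        shuffled = table_from_rows(x[rng.permutation(6)], taxa=["a"])
        assert eco.niche_breadth(shuffled, "a") == pytest.approx(b)

    def test_overlap_identical_profiles(self):
        t = table_from_rows([[1, 2], [2, 4], [3, 6]], taxa=["a", "b"])
        assert eco.niche_overlap(t, "a", "b") == pytest.approx(1.0)

    def test_overlap_disjoint(self):
        t = table_from_rows([[1, 0], [1, 0], [0, 1]], taxa=["a", "b"])
        assert eco.niche_overlap(t, "a", "b") == pytest.approx(0.0)

    def test_overlap_hand_value_and_asymmetry(self):
        t = table_from_rows([[0.5, 0.2], [0.5, 0.3], [0.0, 0.5]], taxa=["a", "b"])
        assert eco.niche_overlap(t, "a", "b") == pytest.approx(0.5)
        assert eco.niche_overlap(t, "a", "b") != pytest.approx(
            eco.niche_overlap(t, "b", "a")
        )

    def test_overlap_scale_invariance(self):
        t1 = table_from_rows([[1, 5], [2, 1], [3, 2]], taxa=["a", "b"])
        t2 = table_from_rows([[10, 5], [20, 1], [30, 2]], taxa=["a", "b"])
        assert eco.niche_overlap(t1, "a", "b") == pytest.approx(
            eco.niche_overlap(t2, "a", "b")
        )


class TestDiversity:
    def test_uniform_shannon(self):
        t = table_from_rows([[5] * 8], samples=["s"])
        d = eco.diversity_indices(t, "s")
        assert d["shannon"] == pytest.approx(np.log(8))

    def test_single_taxon(self):
        t = table_from_rows([[7, 0]], samples=["s"])
        d = eco.diversity_indices(t, "s")
        assert d["shannon"] == 0.0
        assert d["simpson"] == 0.0

    def test_chao1_hand_value(self):
        # 10 observed taxa, 4 singletons, 2 doubletons -> 10 + 16/4 = 14
        counts = [1, 1, 1, 1, 2, 2, 3, 4, 5, 6]
        t = table_from_rows([counts], samples=["s"])
        assert eco.diversity_indices(t, "s")["chao1"] == pytest.approx(14.0)

    def test_chao1_matches_skbio_when_f2_positive(self):
        from skbio.diversity.alpha import chao1 as skbio_chao1

        counts = np.array([1, 1, 1, 2, 2, 2, 5, 9, 14])
        t = table_from_rows([counts], samples=["s"])
        ours = eco.diversity_indices(t, "s")["chao1"]
        assert ours == pytest.approx(skbio_chao1(counts, bias_corrected=False))

    def test_non_integer_counts_rejected(self):
        t = table_from_rows([[0.5, 1.3]], samples=["s"])
        with pytest.raises(ValueError):
            eco.diversity_indices(t, "s")


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        t = table_from_rows([[1, 2, 0], [1, 2, 0], [0, 0, 5]])
        d = eco.bray_curtis(t)
        assert d.iloc[0, 1] == pytest.approx(0.0)
        assert d.iloc[0, 2] == pytest.approx(1.0)

    def test_hand_value(self):
        t = table_from_rows([[1, 2, 3], [3, 2, 1]])
        assert eco.bray_curtis(t).iloc[0, 1] == pytest.approx(1 / 3)

    def test_bounded_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(0)
        t = table_from_rows(rng.integers(0, 50, size=(5, 12)))
        d = eco.bray_curtis(t).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert (d >= 0).all() and (d <= 1).all()


class TestPCoA:
    def test_recovers_line(self):
        x = np.array([0.0, 1.0, 3.0, 7.0])
        d = pd.DataFrame(np.abs(x[:, None] - x[None, :]))
        res = eco.pcoa(d, k=1)
        c = res["coordinates"].iloc[:, 0].to_numpy()
        # first axis reproduces the 1-D configuration up to sign/shift
        got = np.abs(c - c[0])
        assert np.allclose(got, x, atol=1e-8) or np.allclose(got[::-1], x[::-1] - x[0], atol=1e-8)

    def test_zero_matrix(self):
        d = pd.DataFrame(np.zeros((3, 3)))
        res = eco.pcoa(d, k=2)
        assert np.allclose(res["coordinates"].to_numpy(), 0.0)

    def test_euclidean_exactness(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(6, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        res = eco.pcoa(pd.DataFrame(d), k=3)
        c = res["coordinates"].to_numpy()
        d2 = np.linalg.norm(c[:, None] - c[None, :], axis=-1)
        assert np.allclose(d2, d, atol=1e-8)

    def test_asymmetric_rejected(self):
        d = pd.DataFrame([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            eco.pcoa(d)


def _two_clouds(n_per=6, sep=10.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, size=(n_per, 8))
    b = rng.normal(sep, 1.0, size=(n_per, 8))
    t = table_from_rows(np.abs(np.vstack([a, b])))
    labels = np.array(["g1"] * n_per + ["g2"] * n_per)
    return t, labels


class TestAnosim:
    def test_separated_groups(self):
        t, labels = _two_clouds(n_per=8)
        res = eco.anosim(eco.bray_curtis(t), labels, n_perm=999, seed=1)
        assert res["R"] > 0.8
        assert res["p"] <= 0.001

    def test_null_behaviour(self):
        rng = np.random.default_rng(2)
        t = table_from_rows(rng.random((12, 8)))
        labels = np.array(["a", "b"] * 6)
        res = eco.anosim(eco.bray_curtis(t), labels, n_perm=499, seed=3)
        assert abs(res["R"]) < 0.4
        assert res["p"] > 0.01

    def test_seed_reproducibility(self):
        t, labels = _two_clouds(sep=2.0, seed=5)
        d = eco.bray_curtis(t)
        a = eco.anosim(d, labels, n_perm=199, seed=9)
        b = eco.anosim(d, labels, n_perm=199, seed=9)
        assert a == b

    def test_statistic_matches_skbio(self):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import anosim as skbio_anosim

        t, labels = _two_clouds(sep=1.5, seed=7)
        d = eco.bray_curtis(t)
        ours = eco.anosim(d, labels, n_perm=99, seed=0)["R"]
        ref = skbio_anosim(
            DistanceMatrix(d.to_numpy(), ids=[str(i) for i in d.index]),
            list(labels),
            permutations=99,
        )["test statistic"]
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_degenerate_grouping_rejected(self):
        t, _ = _two_clouds()
        with pytest.raises(ValueError):
            eco.anosim(eco.bray_curtis(t), np.array(["a"] * 12))


class TestNetwork:
    def test_proportional_taxa_linked(self):
        rng = np.random.default_rng(3)
        base = rng.random(8) * 10 + 1
        t = table_from_rows(
            np.column_stack([base, 2 * base, rng.random(8)]), taxa=["a", "b", "c"]
        )
        net = eco.build_network(t, n_perm=499, seed=1)
        assert net.graph.has_edge("a", "b")

    def test_impossible_threshold_empty(self):
        rng = np.random.default_rng(4)
        t = table_from_rows(rng.random((8, 5)))
        net = eco.build_network(t, r2_min=1.0 + 1e-9, n_perm=99, seed=1)
        assert net.graph.number_of_edges() == 0

    def test_constant_taxa_excluded(self):
        rng = np.random.default_rng(5)
        t = table_from_rows(
            np.column_stack([np.full(8, 3.0), rng.random(8), rng.random(8)]),
            taxa=["const", "a", "b"],
        )
        with pytest.warns(UserWarning):
            net = eco.build_network(t, n_perm=99, seed=1)
        assert "const" in net.excluded
        assert "const" not in net.graph

    def test_null_false_positive_rate(self):
        """Independent taxa: edges appear at about the nominal error rate."""
        rng = np.random.default_rng(6)
        t = table_from_rows(rng.random((10, 30)))
        net = eco.build_network(t, n_perm=199, seed=2)
        n_pairs = 30 * 29 / 2
        # needing both r^2>0.9 and p<0.05 keeps the false-edge count tiny
        assert net.graph.number_of_edges() <= 0.02 * n_pairs

    def test_edges_satisfy_thresholds(self):
        rng = np.random.default_rng(7)
        base = rng.random(10)
        cols = {f"x{i}": base + rng.normal(0, 0.02, 10) for i in range(4)}
        cols["noise"] = rng.random(10)
        t = pd.DataFrame(cols)
        net = eco.build_network(t, n_perm=499, seed=3)
        for _, _, attrs in net.graph.edges(data=True):
            assert attrs["correlation"] ** 2 > net.r2_min
            assert attrs["p"] < net.p_max


class TestKeystone:
    def _net_from_graph(self, g):
        return eco.CooccurrenceNetwork(g, 0.9, 0.05, "spearman")

    def test_star_hub_first(self):
        g = nx.star_graph(["hub", "a", "b", "c", "d"])
        nx.set_node_attributes(g, "bnirK", "marker")
        ks = eco.keystone_taxa(self._net_from_graph(g), top_k=3)
        assert ks.iloc[0]["taxon"] == "hub"

    def test_clique_size_ordering(self):
        g = nx.union(
            nx.relabel_nodes(nx.complete_graph(5), lambda i: f"big{i}"),
            nx.relabel_nodes(nx.complete_graph(3), lambda i: f"small{i}"),
        )
        ks = eco.keystone_taxa(self._net_from_graph(g), top_k=8)
        assert set(ks.head(5)["taxon"]) == {f"big{i}" for i in range(5)}

    def test_empty_network(self):
        ks = eco.keystone_taxa(self._net_from_graph(nx.Graph()), top_k=3)
        assert ks.empty


def test_niche_metrics_weighted_summary():
    t = table_from_rows([[4, 1], [4, 0], [4, 0], [4, 0]], taxa=["even", "spike"])
    m = eco.niche_metrics(t)
    assert m.loc["even", "breadth"] == pytest.approx(4.0)
    assert m.loc["spike", "breadth"] == pytest.approx(1.0)
    community = (m["breadth"] * m["weight"]).sum()
    assert 1.0 < community < 4.0
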