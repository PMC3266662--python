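"""BBH transfer, reporter metabolites, gene projection, and path search."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sppr_omics.network import (
    NetworkError,
    bbh_transfer,
    color_coding_best_path,
    empath,
    enumerate_simple_paths,
    gene_projection,
    merge_significant_paths,
    PathResult,
    reporter_metabolites,
)


def scores_frame(rows):
    return pd.DataFrame(rows, columns=["query", "subject", "bitscore"])


class TestBBH:
    def test_reciprocal_unique_best_hits_mapped(self):
        scores = scores_frame([("s1", "t1", 60.0), ("t1", "s1", 70.0)])
        res = bbh_transfer(scores, {"s1": ["R1"]})
        assert res.reactions == {"t1": ["R1"]}

    def test_non_reciprocal_not_mapped(self):
        scores = scores_frame(
            [("a", "b", 90.0), ("b", "c", 95.0), ("c", "b", 60.0)]
        )
        res = bbh_transfer(scores, {"a": ["R1"]})
        assert res.reactions == {}

    def test_cutoff_excludes_low_scores(self):
        scores = scores_frame([("s1", "t1", 49.0), ("t1", "s1", 48.0)])
        assert bbh_transfer(scores, {"s1": ["R1"]}).reactions == {}
        # one direction above 50 suffices by default ("either direction")
        scores2 = scores_frame([("s1", "t1", 51.0), ("t1", "s1", 48.0)])
        assert bbh_transfer(scores2, {"s1": ["R1"]}).reactions == {"t1": ["R1"]}
        # strict mode demands both directions
        assert (
            bbh_transfer(scores2, {"s1": ["R1"]}, require_both=True).reactions == {}
        )

    def test_tied_best_hit_skipped(self):
        scores = scores_frame(
            [("s1", "t1", 60.0), ("s1", "t2", 60.0), ("t1", "s1", 70.0)]
        )
        assert bbh_transfer(scores, {"s1": ["R1"]}).reactions == {}

    def test_mapping_is_injective(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(20):
            s, t = f"s{i}", f"t{i}"
            sc = float(rng.uniform(55, 200))
            rows += [(s, t, sc), (t, s, sc * 0.9)]
        res = bbh_transfer(scores_frame(rows), {f"s{i}": [f"R{i}"] for i in range(20)})
        assert res.mapping["target"].is_unique and res.mapping["source"].is_unique


class TestReporterMetabolites:
    def edges(self, mapping):
        return pd.DataFrame(
            [(g, m) for m, genes in mapping.items() for g in genes],
            columns=["gene_id", "metabolite_id"],
        )

    def test_z_raw_matches_closed_form(self):
        pvals = pd.Series(
            {"g1": 0.001, "g2": 0.02, "g3": 0.5, "g4": 0.9, "g5": 0.3}
        )
        edges = self.edges(
            {"m1": ["g1", "g2"], "m2": ["g3", "g4", "g5"], "m3": ["g1"]}
        )
        table = reporter_metabolites(edges, pvals, n_background=200, seed=0,
                                     filtered=False)
        t = table.set_index("metabolite_id")
        z = pd.Series(stats.norm.isf(pvals), index=pvals.index)
        assert t.loc["m1", "z_raw"] == pytest.approx(
            (z["g1"] + z["g2"]) / np.sqrt(2), abs=1e-12
        )
        assert t.loc["m2", "z_raw"] == pytest.approx(
            (z["g3"] + z["g4"] + z["g5"]) / np.sqrt(3), abs=1e-12
        )

    def test_k1_metabolite_filtered(self):
        pvals = pd.Series({"g1": 1e-6, "g2": 1e-6, "g3": 1e-6})
        edges = self.edges({"m1": ["g1"], "m2": ["g2", "g3"]})
        table = reporter_metabolites(edges, pvals, n_background=200, seed=0)
        assert "m1" not in set(table["metabolite_id"])

    def test_equal_pvalues_give_null_corrected_scores(self):
        pvals = pd.Series({f"g{i}": 0.3 for i in range(20)})
        edges = self.edges({f"m{j}": [f"g{j}", f"g{j+1}", f"g{j+2}"] for j in range(10)})
        table = reporter_metabolites(edges, pvals, n_background=500, seed=1,
                                     filtered=False)
        assert np.allclose(table["z_corrected"], 0.0, atol=1e-9)
        assert not table["significant"].any()

    def test_invariant_to_metabolite_relabeling(self):
        rng = np.random.default_rng(2)
        pvals = pd.Series(rng.uniform(0.01, 1, 30), index=[f"g{i}" for i in range(30)])
        edges = self.edges(
            {f"m{j}": [f"g{(3*j+k) % 30}" for k in range(3)] for j in range(10)}
        )
        relabeled = edges.assign(
            metabolite_id=edges["metabolite_id"].map(lambda m: f"X_{m}")
        )
        a = reporter_metabolites(edges, pvals, n_background=300, seed=3, filtered=False)
        b = reporter_metabolites(relabeled, pvals, n_background=300, seed=3,
                                 filtered=False)
        np.testing.assert_allclose(
            a.sort_values("metabolite_id")["z_corrected"].to_numpy(),
            b.sort_values("metabolite_id")["z_corrected"].to_numpy(),
        )

    def test_corrected_z_calibrated_per_k(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(300)]
        pvals = pd.Series(rng.uniform(size=300), index=genes)
        edges = self.edges(
            {
                f"m{j}": list(rng.choice(genes, size=4, replace=False))
                for j in range(150)
            }
        )
        table = reporter_metabolites(edges, pvals, n_background=2000, seed=5,
                                     filtered=False)
        zc = table["z_corrected"]
        assert abs(zc.mean()) < 0.2
        assert 0.8 < zc.std() < 1.25

    def test_invalid_pvalues_error(self):
        edges = self.edges({"m1": ["g1", "g2"]})
        with pytest.raises(NetworkError):
            reporter_metabolites(edges, pd.Series({"g1": 0.0, "g2": 0.5}))


class TestGeneProjection:
    def test_shared_metabolite_creates_edge(self):
        edges = pd.DataFrame(
            [("a", "m1"), ("b", "m1"), ("c", "m2")],
            columns=["gene_id", "metabolite_id"],
        )
        g = gene_projection(edges)
        assert g.has_edge("a", "b") and not g.has_edge("a", "c")

    def test_max_weight_is_one_after_rescale(self):
        edges = pd.DataFrame(
            [("a", "m1"), ("b", "m1"), ("b", "m2"), ("c", "m2")],
            columns=["gene_id", "metabolite_id"],
        )
        g = gene_projection(edges, {"a": 100.0, "b": 50.0, "c": 10.0})
        weights = [d["weight"] for _, _, d in g.edges(data=True)]
        assert max(weights) == pytest.approx(1.0)
        assert all(0 < w <= 1 for w in weights)

    def test_adjacency_matches_brute_force(self):
        rng = np.random.default_rng(5)
        rows = [
            (f"g{rng.integers(8)}", f"m{rng.integers(6)}") for _ in range(30)
        ]
        edges = pd.DataFrame(rows, columns=["gene_id", "metabolite_id"]).drop_duplicates()
        g = gene_projection(edges)
        by_gene = edges.groupby("gene_id")["metabolite_id"].apply(set)
        for u, v in itertools.combinations(sorted(by_gene.index), 2):
            assert g.has_edge(u, v) == bool(by_gene[u] & by_gene[v])


def random_graph(seed, n=10, p=0.35):
    rng = np.random.default_rng(seed)
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            return nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})


class TestPathSearch:
    def test_unique_path_on_path_graph(self):
        g = nx.path_graph(3)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        scores = {"n0": 1.0, "n1": 2.0, "n2": 3.0}
        res = color_coding_best_path(g, scores, k=3, n_colorings=200, seed=0)
        assert set(res.path) == {"n0", "n1", "n2"}
        assert res.score == pytest.approx(6.0)

    def test_color_coding_equals_exhaustive_optimum(self):
        g = random_graph(7)
        rng = np.random.default_rng(8)
        scores = {n: float(rng.normal()) for n in g.nodes}
        nodes = sorted(g.nodes)
        idx = {n: i for i, n in enumerate(nodes)}
        adj = [[] for _ in nodes]
        for u, v in g.edges:
            adj[idx[u]].append(idx[v])
            adj[idx[v]].append(idx[u])
        arr = np.array([scores[n] for n in nodes])
        for k in (3, 4, 5):
            paths = enumerate_simple_paths(adj, k)
            best = max(arr[list(p)].sum() for p in paths)
            res = color_coding_best_path(g, scores, k=k, n_colorings=300, seed=9)
            assert res.score == pytest.approx(best, abs=1e-9)
            assert len(set(res.path)) == k  # simple path

    def test_enumeration_counts_each_undirected_path_once(self):
        g = nx.cycle_graph(4)
        adj = [[1, 3], [0, 2], [1, 3], [0, 2]]
        paths = enumerate_simple_paths(adj, 3)
        assert len(paths) == 4  # 4 distinct 3-node paths in C4


class TestEmpath:
    def test_planted_low_p_path_significant(self):
        # background large enough that the shuffle null rarely reassembles
        # the four extreme weights into one path
        g = random_graph(11, n=30, p=0.12)
        rng = np.random.default_rng(12)
        pvals = {n: float(rng.uniform(0.2, 1.0)) for n in g.nodes}
        nodes = sorted(g.nodes)
        # plant a strong path along an existing 4-walk
        path = [nodes[0]]
        while len(path) < 4:
            nbrs = [x for x in g.neighbors(path[-1]) if x not in path]
            if not nbrs:
                break
            path.append(nbrs[0])
        for n in path:
            pvals[n] = 1e-5
        res = empath(g, pvals, k_min=3, k_max=4, n_shuffle=500, seed=13)
        assert res.merged and res.merged[0].p < 0.025
        assert set(path) <= set(res.merged[0].gene_ids)

    def test_k_min_validation(self):
        g = random_graph(14)
        with pytest.raises(NetworkError):
            empath(g, {n: 0.5 for n in g.nodes}, k_min=1)

    def test_merge_overlapping_paths(self):
        a = PathResult(("x", "y", "z"), 3, 5.0, 0.01)
        b = PathResult(("z", "w", "v"), 3, 4.0, 0.02)
        c = PathResult(("p", "q", "r"), 3, 3.0, 0.001)
        merged = merge_significant_paths([a, b, c])
        assert len(merged) == 2
        genes = {m.gene_ids for m in merged}
        assert ("v", "w", "x", "y", "z") in genes
        assert merged[0].p == pytest.approx(0.001)
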