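import networkx as nx
import numpy as np
import pandas as pd
import pytest
from networkx.algorithms.community import modularity as nx_modularity

from gba.coexnet import (
    CommunityPartition,
    build_network,
    candidate_report,
    fast_greedy_communities,
    hrr,
    modularity,
    pcc_matrix,
    profile_filter,
    rank_neighbors,
)

from .oracles import all_partitions, modularity_by_hand, naive_hrr


def expr_frame(rows: dict[str, list[float]]) -> pd.DataFrame:
    return pd.DataFrame(rows).T


class TestPccMatrix:
    def test_self_and_affine_relations(self):
        x = [1.0, 4.0, 2.0, 9.0]
        df = expr_frame({"x": x, "up": [2 + 3 * v for v in x], "down": [5 - 2 * v for v in x]})
        corr = pcc_matrix(df)
        assert corr.loc["x", "x"] == 1.0
        assert corr.loc["x", "up"] == pytest.approx(1.0)
        assert corr.loc["x", "down"] == pytest.approx(-1.0)

    def test_worked_example(self):
        corr = pcc_matrix(expr_frame({"x": [1, 2, 3, 4], "y": [1, 2, 3, 10]}))
        # direct evaluation: r = 14 / sqrt(5 * 50)
        assert corr.loc["x", "y"] == pytest.approx(14 / np.sqrt(250), abs=1e-12)

    def test_zero_variance_genes_excluded_with_warning(self):
        df = expr_frame({"flat": [2.0, 2.0, 2.0], "x": [1.0, 2.0, 3.0], "y": [3.0, 1.0, 2.0]})
        with pytest.warns(UserWarning, match="flat"):
            corr = pcc_matrix(df)
        assert "flat" not in corr.index

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            pcc_matrix(expr_frame({"x": [1.0, 2.0], "y": [2.0, 1.0]}))


class TestRanksAndHrr:
    def three_gene_corr(self):
        return pcc_matrix(
            expr_frame({"A": [1, 2, 3, 4], "B": [2, 4, 6, 8], "C": [4, 3, 2, 1]})
        )

    def test_two_genes_rank_each_other_first(self):
        corr = pcc_matrix(expr_frame({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.5, 2.0]}))
        ranks = rank_neighbors(corr)
        assert ranks.loc["a", "b"] == 1 and ranks.loc["b", "a"] == 1
        assert hrr(ranks).loc["a", "b"] == 1

    def test_tie_broken_by_ascending_id(self):
        ranks = rank_neighbors(self.three_gene_corr())
        assert ranks.loc["A", "B"] == 1 and ranks.loc["A", "C"] == 2
        # A and B tie at PCC -1 from C's side: A wins the tie by id
        assert ranks.loc["C", "A"] == 1 and ranks.loc["C", "B"] == 2
        H = hrr(ranks)
        assert H.loc["A", "C"] == 2

    def test_gene_order_invariance(self):
        corr = self.three_gene_corr()
        shuffled = corr.loc[["C", "A", "B"], ["C", "A", "B"]]
        r1 = rank_neighbors(corr)
        r2 = rank_neighbors(shuffled)
        for i in "ABC":
            for j in "ABC":
                if i != j:
                    assert r1.loc[i, j] == r2.loc[i, j]

    def test_hrr_is_symmetric_integer_and_at_least_one(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(30, 8)), index=[f"g{i:02d}" for i in range(30)])
        H = hrr(rank_neighbors(pcc_matrix(df)))
        v = H.to_numpy()
        assert (v == v.T).all()
        off = v[~np.eye(30, dtype=bool)]
        assert off.min() >= 1 and np.issubdtype(v.dtype, np.integer)

    def test_matches_naive_recomputation(self):
        rng = np.random.default_rng(42)
        ids = [f"g{i:03d}" for i in range(60)]
        expr = rng.normal(size=(60, 8))
        ours = hrr(rank_neighbors(pcc_matrix(pd.DataFrame(expr, index=ids)))).to_numpy()
        theirs = naive_hrr(expr, ids)
        np.fill_diagonal(theirs, 0)
        assert (ours == theirs).all()


class TestBuildNetwork:
    def hrr_df(self, values, ids):
        return pd.DataFrame(values, index=ids, columns=ids)

    def test_threshold_is_strict(self):
        ids = ["bait", "g99", "g100"]
        H = self.hrr_df([[0, 99, 100], [99, 0, 150], [100, 150, 0]], ids)
        G = build_network(H, ["bait"], tau=100)
        assert G.has_edge("bait", "g99") and not G.has_edge("bait", "g100")

    def test_edges_touch_baits_in_default_mode(self, default_network_inputs, default_baits):
        G = build_network(default_network_inputs["hrr"], default_baits, tau=100)
        baits = set(default_baits)
        assert all(u in baits or v in baits for u, v in G.edges)

    def test_lowering_tau_never_adds_edges(self, default_network_inputs, default_baits):
        H = default_network_inputs["hrr"]
        wide = set(build_network(H, default_baits, tau=100).edges)
        narrow = set(build_network(H, default_baits, tau=30).edges)
        assert narrow <= wide

    def test_no_captured_pair_warns_with_isolated_baits(self):
        ids = ["b", "x"]
        H = self.hrr_df([[0, 500], [500, 0]], ids)
        with pytest.warns(UserWarning, match="isolated"):
            G = build_network(H, ["b"], tau=100)
        assert G.number_of_nodes() == 1 and G.number_of_edges() == 0

    def test_missing_baits_rejected(self):
        H = self.hrr_df([[0, 1], [1, 0]], ["a", "b"])
        with pytest.raises(ValueError, match="no bait"):
            build_network(H, ["zz"], tau=100)


class TestModularity:
    def triangles(self):
        return nx.Graph(
            [("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"), ("e", "f"), ("d", "f")]
        )

    def test_single_community_is_zero(self):
        G = self.triangles()
        assert modularity(G, {n: 0 for n in G}) == pytest.approx(0.0)

    def test_two_components_give_half(self):
        G = self.triangles()
        part = {n: (0 if n in "abc" else 1) for n in G}
        assert modularity(G, part) == pytest.approx(0.5)

    def test_all_singletons_is_negative(self):
        G = self.triangles()
        part = {n: i for i, n in enumerate(sorted(G))}
        assert modularity(G, part) == pytest.approx(-sum((2 / 12) ** 2 for _ in range(6)))

    def test_agrees_with_networkx_and_hand_formula(self):
        rng = np.random.default_rng(8)
        G = nx.gnp_random_graph(12, 0.35, seed=4)
        G = nx.relabel_nodes(G, {i: f"n{i:02d}" for i in G})
        part = {n: rng.integers(0, 3) for n in sorted(G)}
        blocks = [[n for n in G if part[n] == c] for c in range(3)]
        blocks = [b for b in blocks if b]
        ours = modularity(G, part)
        assert ours == pytest.approx(nx_modularity(G, [set(b) for b in blocks]))
        assert ours == pytest.approx(modularity_by_hand(list(G.edges), blocks))

    def test_edgeless_network_rejected(self):
        G = nx.Graph()
        G.add_node("a")
        with pytest.raises(ValueError, match="edgeless"):
            modularity(G, {"a": 0})


class TestFastGreedy:
    def test_two_triangles_match_exhaustive_optimum(self):
        G = nx.Graph(
            [("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"), ("e", "f"), ("d", "f")]
        )
        part = fast_greedy_communities(G)
        assert part.modularity == pytest.approx(0.5)
        assert part.members() == {0: ["a", "b", "c"], 1: ["d", "e", "f"]}
        edges = list(G.edges)
        best = max(
            modularity_by_hand(edges, blocks) for blocks in all_partitions(sorted(G))
        )
        assert part.modularity == pytest.approx(best)

    def test_single_edge_merges_the_pair(self):
        part = fast_greedy_communities(nx.Graph([("a", "b")]))
        assert part.modularity == pytest.approx(0.0)
        assert part.members() == {0: ["a", "b"]}

    def test_never_beats_exhaustive_search_and_ties_on_cliques(self):
        rng = np.random.default_rng(99)
        for trial in range(20):
            n = int(rng.integers(4, 8))
            G = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(0, 10_000)))
            G = nx.relabel_nodes(G, {i: f"n{i}" for i in G})
            if G.number_of_edges() == 0:
                continue
            part = fast_greedy_communities(G)
            edges = list(G.edges)
            best = max(
                modularity_by_hand(edges, blocks) for blocks in all_partitions(sorted(G))
            )
            assert part.modularity <= best + 1e-12
        two_cliques = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(3))
        two_cliques = nx.relabel_nodes(two_cliques, {i: f"n{i}" for i in two_cliques})
        part = fast_greedy_communities(two_cliques)
        edges = list(two_cliques.edges)
        best = max(
            modularity_by_hand(edges, blocks)
            for blocks in all_partitions(sorted(two_cliques))
        )
        assert part.modularity == pytest.approx(best)
        assert len(part.members()) == 2

    def test_deterministic_across_runs(self):
        G = nx.gnp_random_graph(15, 0.3, seed=3)
        G = nx.relabel_nodes(G, {i: f"n{i:02d}" for i in G})
        p1 = fast_greedy_communities(G)
        p2 = fast_greedy_communities(G)
        assert p1.communities == p2.communities and p1.modularity == p2.modularity

    def test_edgeless_network_rejected(self):
        G = nx.Graph()
        G.add_nodes_from("ab")
        with pytest.raises(ValueError, match="edgeless"):
            fast_greedy_communities(G)


class TestCandidateReport:
    def test_single_edge_reports_single_candidate(self):
        G = nx.Graph()
        G.add_node("b", is_bait=True)
        G.add_node("g", is_bait=False)
        G.add_edge("b", "g", hrr=3, pcc=0.9)
        part = CommunityPartition({"b": 0, "g": 0}, 0.0)
        rep = candidate_report(G, part)
        assert len(rep.candidates) == 1
        row = rep.candidates.iloc[0]
        assert row["gene"] == "g" and row["hrr"] == 3 and row["shared_community"]

    def test_sort_chain_hrr_then_pcc_then_id(self):
        G = nx.Graph()
        G.add_node("b", is_bait=True)
        for g, h, r in [("x", 3, 0.8), ("y", 3, 0.9), ("z", 7, 0.99)]:
            G.add_node(g, is_bait=False)
            G.add_edge("b", g, hrr=h, pcc=r)
        part = CommunityPartition({n: 0 for n in G}, 0.0)
        rep = candidate_report(G, part)
        assert list(rep.candidates["gene"]) == ["y", "x", "z"]


class TestProfileFilter:
    def setup_data(self):
        meta = pd.DataFrame(
            {
                "sample_id": ["YL1", "YS1", "OL1", "AR1"],
                "tissue": ["YL", "YS", "OL", "AR"],
                "replicate": [1, 1, 1, 1],
            }
        )
        tpm = pd.DataFrame(
            {
                "YL1": [1300.0, 10.0, 50.0],
                "YS1": [1310.0, 20.0, 60.0],
                "OL1": [90.0, 15.0, 70.0],
                "AR1": [40.0, 400.0, 80.0],
            },
            index=["young", "root", "old"],
        )
        return tpm, meta

    def test_young_aerial_maximum_is_retained(self):
        tpm, meta = self.setup_data()
        assert profile_filter(["young"], tpm, meta) == ["young"]

    def test_root_maximum_is_removed(self):
        tpm, meta = self.setup_data()
        assert profile_filter(["root"], tpm, meta) == []

    def test_full_tissue_pattern_is_identity(self):
        tpm, meta = self.setup_data()
        genes = ["young", "root", "old"]
        assert profile_filter(genes, tpm, meta, ("YL", "YS", "OL", "AR")) == genes

    def test_unknown_tissue_rejected(self):
        tpm, meta = self.setup_data()
        with pytest.raises(ValueError, match="unknown"):
            profile_filter(["young"], tpm, meta, ("XX",))
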