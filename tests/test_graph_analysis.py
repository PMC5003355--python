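import networkx as nx
import numpy as np
import pytest

from oracles import mcode_weight_naive
from procoexp import (
    ExpressionMatrix,
    hub_nodes,
    mcode_complexes,
    mcode_vertex_weights,
    neighbourhood,
    simulate_dataset,
    threshold_network,
    ward_subclusters,
)
from procoexp.graph_analysis import SubclusterResult
from procoexp.module_detect import ModuleAssignment
from procoexp.netbuild import AdjacencyMatrix


def _adj(a):
    a = np.asarray(a, dtype=float)
    return AdjacencyMatrix(ids=[f"P{i}" for i in range(a.shape[0])], a=a, beta=10)


def _assign(module_of):
    return ModuleAssignment(
        ids=list(module_of),
        module_of=dict(module_of),
        min_module_size=2,
        merge_cut_height=0.25,
    )


class TestThresholdNetwork:
    def test_extreme_cutoffs(self):
        a = np.full((4, 4), 0.5)
        np.fill_diagonal(a, 1.0)
        g0 = threshold_network(_adj(a), 0.0)
        assert g0.number_of_edges() == 6  # complete minus diagonal
        g1 = threshold_network(_adj(a), 0.51)
        assert g1.number_of_edges() == 0
        assert g1.number_of_nodes() == 4  # isolated nodes retained

    def test_exact_edge_set_by_inspection(self):
        a = np.array(
            [
                [1.0, 0.25, 0.10, 0.05],
                [0.25, 1.0, 0.30, 0.15],
                [0.10, 0.30, 1.0, 0.20],
                [0.05, 0.15, 0.20, 1.0],
            ]
        )
        g = threshold_network(_adj(a), 0.2)
        assert {frozenset(e) for e in g.edges} == {
            frozenset({"P0", "P1"}),
            frozenset({"P1", "P2"}),
            frozenset({"P2", "P3"}),
        }

    def test_raising_cutoff_never_raises_degree(self):
        rng = np.random.default_rng(6)
        a = rng.uniform(0, 1, (12, 12))
        a = (a + a.T) / 2
        adj = _adj(a)
        prev = None
        for cutoff in (0.1, 0.3, 0.5, 0.7, 0.9):
            deg = dict(threshold_network(adj, cutoff).degree())
            if prev is not None:
                assert all(deg[v] <= prev[v] for v in deg)
            prev = deg


class TestMcodeVertexWeights:
    def test_clique_pendant_and_path_values(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c")])  # P3
        w = mcode_vertex_weights(g)
        assert w["b"] == pytest.approx(2 / 3)  # 1-core of N[b] has density 2/3
        k4 = nx.complete_graph(4)
        wk = mcode_vertex_weights(k4)
        assert all(v == pytest.approx(3.0) for v in wk.values())
        lonely = nx.Graph()
        lonely.add_node("x")
        assert mcode_vertex_weights(lonely)["x"] == 0.0

    def test_matches_peeling_oracle_on_random_graphs(self):
        for seed in range(5):
            g = nx.gnp_random_graph(9, 0.4, seed=seed)
            adj = {v: set(g.neighbors(v)) for v in g}
            w = mcode_vertex_weights(g)
            for v in g:
                assert w[v] == pytest.approx(mcode_weight_naive(adj, v), abs=1e-10)


class TestMcodeComplexes:
    def test_haircut_trims_pendant_from_clique(self):
        g = nx.complete_graph(4)
        g.add_edge(0, "pendant")
        res = mcode_complexes(g)
        assert len(res.complexes) == 1
        assert res.complexes[0] == frozenset({0, 1, 2, 3})

    def test_barbell_step_through(self):
        # two 4-cliques joined by one bridge: every clique vertex weighs 3
        # (the bridge endpoint's top core is still its own clique), so
        # breadth-first inclusion at the default cutoff crosses the bridge
        # and yields a single complex — stepping through the seeding rule
        g = nx.Graph()
        g.add_edges_from(
            [(a, b) for a in "abcd" for b in "abcd" if a < b]
            + [(a, b) for a in "efgh" for b in "efgh" if a < b]
            + [("d", "e")]
        )
        w = mcode_vertex_weights(g)
        assert all(w[v] == pytest.approx(3.0) for v in "abcdefgh")
        res = mcode_complexes(g)
        assert len(res.complexes) == 1
        assert res.complexes[0] == frozenset("abcdefgh")

    def test_low_scoring_connector_separates_complexes(self):
        # two 4-cliques joined through a degree-2 middleman whose weight is
        # far below the seeds' -> expansion stops, two complexes
        g = nx.Graph()
        g.add_edges_from(
            [(a, b) for a in "abcd" for b in "abcd" if a < b]
            + [(a, b) for a in "efgh" for b in "efgh" if a < b]
            + [("d", "m"), ("m", "e")]
        )
        w = mcode_vertex_weights(g)
        assert w["m"] < 0.8 * 3.0
        res = mcode_complexes(g)
        assert sorted(map(sorted, res.complexes)) == [list("abcd"), list("efgh")]

    def test_node_order_invariance(self):
        edges = [(0, 1), (1, 2), (0, 2), (2, 3), (3, 4), (4, 5), (3, 5)]
        g1 = nx.Graph(edges)
        g2 = nx.Graph()
        g2.add_nodes_from([5, 3, 1, 0, 4, 2])
        g2.add_edges_from(reversed(edges))
        r1, r2 = mcode_complexes(g1), mcode_complexes(g2)
        assert r1.complexes == r2.complexes

    def test_fluff_is_a_stub(self):
        with pytest.raises(NotImplementedError):
            mcode_complexes(nx.complete_graph(3), fluff=True)


class TestHubNodes:
    def test_regular_graph_has_no_hubs(self):
        g = nx.cycle_graph(range(6))
        m = _assign({v: "blue" for v in range(6)})
        hs = hub_nodes(g, m, "blue")
        assert hs.hubs == []
        assert all(z == 0.0 for z in hs.z.values())

    def test_star_centre_is_unique_hub(self):
        # star K1,9 plus a ring over the leaves: centre degree 9, leaves 3
        g = nx.star_graph(9)  # 0 is the centre
        g.add_edges_from([(i, i % 9 + 1) for i in range(1, 10)])
        m = _assign({v: "brown" for v in g.nodes})
        hs = hub_nodes(g, m, "brown")
        deg = np.array([d for _, d in g.degree()])
        z0 = (9 - deg.mean()) / deg.std()
        assert hs.hubs == [0]
        assert hs.z[0] == pytest.approx(z0, abs=1e-10)

    def test_z_scores_sum_to_zero(self, recovered_modules):
        from procoexp import threshold_network

        _, _, _, adj, assign = recovered_modules[0]
        g = threshold_network(adj, 0.2)
        for colour in assign.colours():
            hs = hub_nodes(g, assign, colour)
            assert sum(hs.z.values()) == pytest.approx(0.0, abs=1e-9)

    def test_small_or_grey_module_rejected(self):
        g = nx.complete_graph(["a", "b"])
        m = _assign({"a": "blue", "b": "blue"})
        with pytest.raises(ValueError):
            hub_nodes(g, m, "blue")
        with pytest.raises(ValueError):
            hub_nodes(g, _assign({"a": "grey", "b": "grey", "c": "grey"}), "grey")


class TestNeighbourhood:
    def test_isolated_and_star_and_unknown(self):
        g = nx.star_graph(4)
        g.add_node("isolated")
        nb = neighbourhood(g, 0)
        assert set(nb.nodes) == {0, 1, 2, 3, 4}
        assert neighbourhood(g, "isolated").number_of_nodes() == 1
        with pytest.raises(KeyError):
            neighbourhood(g, "missing")


class TestWardSubclusters:
    def _expr(self, vals, ids=None):
        ids = ids or [f"P{i}" for i in range(len(vals))]
        return ExpressionMatrix(
            ids, [f"s{j}" for j in range(len(vals[0]))],
            np.asarray(vals, dtype=float), transformed=True,
        )

    def test_k_one_is_single_cluster(self):
        x = self._expr(np.random.default_rng(0).standard_normal((5, 6)))
        res = ward_subclusters(x, x.protein_ids, k=1)
        assert set(res.cluster_of.values()) == {"a"}

    def test_two_separated_blocks_recovered_exactly(self):
        rng = np.random.default_rng(1)
        up = np.tile([1.0, 1, 1, -1, -1, -1], (6, 1)) + rng.normal(0, 0.05, (6, 6))
        down = np.tile([-1.0, -1, -1, 1, 1, 1], (4, 1)) + rng.normal(0, 0.05, (4, 6))
        x = self._expr(np.vstack([up, down]))
        res = ward_subclusters(x, x.protein_ids, k=2)
        labels = [res.cluster_of[p] for p in x.protein_ids]
        assert labels[:6] == ["a"] * 6  # larger block gets 'a'
        assert labels[6:] == ["b"] * 4

    def test_merge_heights_match_lance_williams_oracle(self):
        from scipy.cluster.hierarchy import linkage

        from oracles import ward_heights

        rng = np.random.default_rng(5)
        vals = rng.standard_normal((7, 5))
        z = linkage(vals, method="ward")
        np.testing.assert_allclose(
            np.sort(z[:, 2]), np.sort(ward_heights(vals)), atol=1e-10
        )

    def test_labels_by_decreasing_size(self):
        rng = np.random.default_rng(2)
        centers = np.array([[3.0] * 6, [-3.0] * 6, [0.0] * 6])
        rows = np.vstack(
            [centers[0] + rng.normal(0, 0.1, (5, 6)),
             centers[1] + rng.normal(0, 0.1, (3, 6)),
             centers[2] + rng.normal(0, 0.1, (2, 6))]
        )
        x = self._expr(rows)
        res = ward_subclusters(x, x.protein_ids, k=3)
        sizes = res.sizes()
        assert sizes["a"] >= sizes["b"] >= sizes["c"]

    def test_invalid_k_rejected(self):
        x = self._expr(np.random.default_rng(3).standard_normal((4, 5)))
        with pytest.raises(ValueError):
            ward_subclusters(x, x.protein_ids, k=0)
        with pytest.raises(ValueError):
            ward_subclusters(x, x.protein_ids, k=5)

class TestHubRecovery:
    def test_planted_hubs_top_connectivity_decile(self, recovered_modules):
        hits, total = 0, 0
        for expr, _, truth, adj, _ in recovered_modules:
            idx = {p: i for i, p in enumerate(expr.protein_ids)}
            a = adj.a.copy()
            np.fill_diagonal(a, 0.0)
            for mod in set(truth.module_of.values()) - {-1}:
                members = [p for p in expr.protein_ids if truth.module_of[p] == mod]
                rows = [idx[p] for p in members]
                k = a[np.ix_(rows, rows)].sum(axis=1)
                cut = np.quantile(k, 0.9)
                for hub in truth.hub_ids & set(members):
                    total += 1
                    hits += k[members.index(hub)] >= cut
        assert hits / total >= 0.8
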