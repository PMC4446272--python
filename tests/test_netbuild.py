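import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import trilayer as tl
from oracles import betweenness_brute


class TestSimilarity:
    def test_overlap_coefficient_example(self):
        overlap, coef = tl.similarity({"a", "b", "c"}, {"b", "c", "d", "e"})
        assert overlap == 2
        assert coef == pytest.approx(2 / 3)

    def test_identical_sets_are_unit_similarity(self):
        s = {"a", "b", "c"}
        for method in ("overlap", "jaccard", "combined"):
            overlap, coef = tl.similarity(s, s, method)
            assert (overlap, coef) == (3, pytest.approx(1.0))

    def test_disjoint_sets_are_zero(self):
        assert tl.similarity({"a"}, {"b"}) == (0, 0.0)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            tl.similarity(set(), {"a"})

    @given(
        st.sets(st.integers(0, 30), min_size=1, max_size=15),
        st.sets(st.integers(0, 30), min_size=1, max_size=15),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_jaccard_bounded_by_overlap_coefficient(self, a, b):
        _, jac = tl.similarity(a, b, "jaccard")
        _, ov = tl.similarity(a, b, "overlap")
        assert 0.0 <= jac <= ov <= 1.0
        assert tl.similarity(a, b) == tl.similarity(b, a)


def _node(name, layer, genes, score=1.5, direction="up"):
    if layer == "physiology":
        return tl.LayerNode(name, layer, frozenset(genes))
    return tl.LayerNode(
        name, layer, frozenset(genes), score=score, direction=direction, p_value=0.01
    )


class TestBuildNetwork:
    def test_general_cutoff_boundary_is_inclusive(self):
        # coefficient exactly 0.50 kept, 0.49 dropped (sets of 100, overlap 50/49)
        base = [f"g{i}" for i in range(150)]
        a = _node("A", "process", base[:100])
        b_in = _node("B", "process", base[50:150])   # overlap 50 -> 0.50
        b_out = _node("C", "process", base[51:151] + ["x"])  # overlap 49 -> 0.49
        net = tl.build_network([a, b_in, b_out], [], [])
        assert net.has_edge("A", "B")
        assert not net.has_edge("A", "C")

    def test_physiology_process_pair_uses_relaxed_cutoff(self):
        genes = [f"g{i}" for i in range(20)]
        proc = _node("proc", "process", genes)
        phys = _node("bm_gain", "physiology", genes[:7] + [f"p{i}" for i in range(13)])
        tf = _node("tf", "regulator", genes[:7] + [f"q{i}" for i in range(13)])
        net = tl.build_network([proc], [tf], [phys])
        # coefficient = 7/20 = 0.35: kept for physiology-process only
        assert net.has_edge("bm_gain", "proc")
        assert not net.has_edge("tf", "proc")

    def test_disallowed_relationships_absent(self):
        genes = [f"g{i}" for i in range(5)]
        tf1 = _node("tf1", "regulator", genes)
        tf2 = _node("tf2", "regulator", genes)
        ph1 = _node("p1", "physiology", genes)
        ph2 = _node("p2", "physiology", genes)
        net = tl.build_network([], [tf1, tf2], [ph1, ph2])
        rels = {d["relationship"] for _, _, d in net.edges(data=True)}
        assert "regulator-regulator" not in rels
        assert "physiology-physiology" not in rels
        assert net.has_edge("tf1", "p1")

    def _random_nodes(self, rng, n=30):
        layers = ["process", "regulator", "physiology"]
        nodes = {layer: [] for layer in layers}
        for i in range(n):
            layer = layers[int(rng.integers(3))]
            genes = frozenset(
                f"g{j}" for j in rng.choice(60, rng.integers(3, 20), replace=False)
            )
            nodes[layer].append(_node(f"{layer[:2]}{i}", layer, genes))
        return nodes

    def test_edges_match_bruteforce_all_pairs(self):
        rng = np.random.default_rng(19)
        cfg = tl.NetworkConfig()
        nodes = self._random_nodes(rng)
        net = tl.build_network(
            nodes["process"], nodes["regulator"], nodes["physiology"], cfg
        )
        everyone = nodes["process"] + nodes["regulator"] + nodes["physiology"]
        allowed = {
            frozenset({"process"}),
            frozenset({"regulator", "process"}),
            frozenset({"regulator", "physiology"}),
            frozenset({"physiology", "process"}),
        }
        expected = set()
        for a, b in itertools.combinations(everyone, 2):
            pair = (
                frozenset({a.layer, b.layer})
                if a.layer != b.layer
                else frozenset({a.layer})
            )
            if pair not in allowed:
                continue
            inter = len(a.genes & b.genes)
            if inter < 1:
                continue
            coef = inter / min(len(a.genes), len(b.genes))
            cut = (
                0.3 if {a.layer, b.layer} == {"physiology", "process"} else 0.5
            )
            if coef >= cut:
                expected.add(frozenset({a.id, b.id}))
        got = {frozenset({a, b}) for a, b in net.edges}
        assert got == expected

    def test_rebuild_is_byte_identical_graphml(self, tmp_path):
        rng = np.random.default_rng(20)
        nodes = self._random_nodes(rng)
        args = (nodes["process"], nodes["regulator"], nodes["physiology"])
        net1 = tl.build_network(*args)
        net2 = tl.build_network(*args)
        from trilayer.io import export_network

        export_network(net1, "graphml", tmp_path / "a.graphml")
        export_network(net2, "graphml", tmp_path / "b.graphml")
        assert (tmp_path / "a.graphml").read_bytes() == (
            tmp_path / "b.graphml"
        ).read_bytes()

    def test_duplicate_ids_rejected(self):
        genes = frozenset({"g1", "g2"})
        with pytest.raises(ValueError, match="duplicate"):
            tl.build_network(
                [_node("X", "process", genes)], [_node("X", "regulator", genes)], []
            )


class TestTopologyStats:
    def test_path_graph_betweenness(self):
        net = nx.Graph()
        net.add_nodes_from("abc", layer="process")
        net.add_edges_from([("a", "b"), ("b", "c")])
        df, summary = tl.topology_stats(net)
        bc = dict(zip(df["node"], df["betweenness"]))
        assert bc == {"b": 1.0, "a": 0.0, "c": 0.0}
        assert summary["density"] == pytest.approx(2 / 3)

    def test_complete_graph_zero_betweenness(self):
        net = nx.complete_graph(4)
        df, _ = tl.topology_stats(net)
        assert (df["betweenness"] == 0).all()
        assert (df["clustering"] == 1.0).all()

    def test_matches_bruteforce_on_random_graphs(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            n = int(rng.integers(5, 21))
            g = nx.gnp_random_graph(n, 0.3, seed=int(rng.integers(10000)))
            df, _ = tl.topology_stats(g)
            adjacency = {v: set(g.neighbors(v)) for v in g.nodes}
            ref = betweenness_brute(adjacency)
            for node, bc in zip(df["node"], df["betweenness"]):
                assert bc == pytest.approx(ref[node], abs=1e-9)

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            tl.topology_stats(nx.Graph())
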