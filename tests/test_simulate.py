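"""Dysregulation simulator: gene selection, signal injection, harness."""

import numpy as np
import pytest

from semgsa import (
    SimulationDesign,
    build_design,
    generate_base_data,
    generate_pathways,
    inject_signal,
    run_simulation,
    select_affected_betweenness,
    select_affected_community,
    select_affected_neighbourhood,
)

from conftest import make_pathway


def _path_graph():
    return make_pathway(
        "path", [("A", "B", 1), ("B", "C", 1), ("C", "D", 1), ("D", "E", 1)]
    )


def _star_graph():
    return make_pathway("star", [("H", leaf, 1) for leaf in "ABCDE"])


class TestBetweenness:
    def test_path_centre_has_highest_betweenness(self):
        # brute force on A->B->C->D->E: C lies on the most shortest paths
        assert select_affected_betweenness(_path_graph(), 1) == ["C"]

    def test_star_centre(self):
        g = make_pathway(
            "star2",
            [("A", "H", 1), ("B", "H", 1), ("H", "C", 1), ("H", "D", 1)],
        )
        assert select_affected_betweenness(g, 1) == ["H"]

    def test_s_equal_to_size_returns_all(self):
        g = _path_graph()
        assert set(select_affected_betweenness(g, 5)) == g.nodes

    def test_small_graph_warns_and_returns_all(self):
        g = _path_graph()
        with pytest.warns(UserWarning, match="taking all"):
            out = select_affected_betweenness(g, 10)
        assert set(out) == g.nodes


class TestCommunity:
    def _two_cliques(self):
        edges = []
        a = [f"a{i}" for i in range(10)]
        b = [f"b{i}" for i in range(10)]
        for grp in (a, b):
            for i in range(10):
                for j in range(i + 1, 10):
                    edges.append((grp[i], grp[j], 1))
        edges.append(("a0", "b0", 1))  # bridge
        return make_pathway("cliques", edges), a, b

    def test_sample_comes_from_one_clique(self):
        g, a, b = self._two_cliques()
        sel = select_affected_community(g, 3, seed=1)
        assert len(sel) == 3
        assert set(sel) <= set(a) or set(sel) <= set(b)

    def test_single_community_samples_all_nodes(self):
        g = make_pathway(
            "k4", [("a", "b", 1), ("a", "c", 1), ("a", "d", 1), ("b", "c", 1),
                   ("b", "d", 1), ("c", "d", 1)]
        )
        sel = select_affected_community(g, 2, seed=0)
        assert set(sel) <= g.nodes

    def test_same_seed_same_sample(self):
        g, _, _ = self._two_cliques()
        assert select_affected_community(g, 4, seed=9) == select_affected_community(
            g, 4, seed=9
        )


class TestNeighbourhood:
    def test_star_centre_covers_whole_graph(self):
        g = _star_graph()
        sel = select_affected_neighbourhood(g, 6, seed=0)
        assert set(sel) == g.nodes

    def test_path_unique_maximum_is_centre_neighbourhood(self):
        # order-2 neighbourhood of C covers all 5 nodes; no other does
        g = _path_graph()
        sel = select_affected_neighbourhood(g, 5, seed=0)
        assert set(sel) == g.nodes

    def test_same_seed_same_sample(self):
        g = _star_graph()
        assert select_affected_neighbourhood(
            g, 3, seed=4
        ) == select_affected_neighbourhood(g, 3, seed=4)


class TestBuildDesign:
    def test_disjoint_pathways_no_overlap(self):
        g1 = make_pathway("p1", [(f"x{i}", f"x{i+1}", 1) for i in range(5)])
        g2 = make_pathway("p2", [(f"y{i}", f"y{i+1}", 1) for i in range(5)])
        aff, q0 = build_design([g1, g2], ["p1", "p2"], "betweenness", s=3, seed=0)
        assert len(aff.unique_genes) == 6
        assert q0 == []

    def test_identical_pathways_full_overlap(self):
        edges = [(f"x{i}", f"x{i+1}", 1) for i in range(5)]
        g1 = make_pathway("p1", edges)
        g2 = make_pathway("p2", edges)
        aff, _ = build_design([g1, g2], ["p1", "p2"], "betweenness", s=3, seed=0)
        assert len(aff.unique_genes) == 3

    def test_q0_excludes_pathways_with_two_affected_genes(self):
        g1 = make_pathway("q1p", [(f"x{i}", f"x{i+1}", 1) for i in range(5)])
        # shares two genes with the affected set of q1p (betweenness top-3
        # of a 6-chain is x2, x3 plus x1/x4 tie-broken by label -> x1)
        contaminated = make_pathway("cont", [("x2", "x3", 1), ("zz", "x2", 1)])
        clean = make_pathway("clean", [("u1", "u2", 1), ("u2", "u3", 1)])
        one_hit = make_pathway("onehit", [("x3", "w1", 1), ("w1", "w2", 1)])
        aff, q0 = build_design(
            [g1, contaminated, clean, one_hit], ["q1p"], "betweenness", s=3, seed=0
        )
        assert set(aff.per_pathway["q1p"]) >= {"x2", "x3"}
        assert "cont" not in q0
        assert {"clean", "onehit"} <= set(q0)

    def test_sign_from_outgoing_weights(self):
        g = make_pathway(
            "sgn",
            [("neg", "a", -1), ("neg", "b", -1), ("pos", "a", 1), ("a", "b", 0)],
        )
        aff, _ = build_design([g], ["sgn"], "betweenness", s=4, seed=0)
        assert aff.signs["neg"] == -1
        assert aff.signs["pos"] == 1
        assert aff.signs["a"] == 1  # zero outgoing sum defaults to up
        assert aff.signs["b"] == 1  # sink defaults to up

    def test_unique_genes_bounded_by_s_times_q1(self):
        paths = generate_pathways(6, (12, 20), seed=3)
        names = [g.name for g in paths[:4]]
        for topology in ("betweenness", "community", "neighbourhood"):
            aff, q0 = build_design(paths, names, topology, s=5, seed=1)
            assert len(aff.unique_genes) <= 5 * 4
            for name in names:
                assert len(aff.per_pathway[name]) <= 5
            # q0 membership is deterministic given the affected set
            unique = set(aff.unique_genes)
            expected_q0 = [
                g.name
                for g in paths
                if g.name not in names and len(g.nodes & unique) <= 1
            ]
            assert q0 == expected_q0

    def test_unknown_inputs_rejected(self):
        g = make_pathway("p", [("a", "b", 1)])
        with pytest.raises(ValueError, match="not in the collection"):
            build_design([g], ["nope"], "betweenness")
        with pytest.raises(ValueError, match="topology"):
            build_design([g], ["p"], "degree")


class TestBaseData:
    def test_exact_standardisation(self):
        data = generate_base_data(["a", "b", "c"], 10, 8, seed=0)
        Y = data.matrix()
        for grp in (0, 1):
            block = Y[data.group == grp]
            assert np.allclose(block.mean(axis=0), 0.0, atol=1e-12)
            assert np.allclose(block.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_independent_genes_have_near_zero_correlation(self):
        data = generate_base_data(
            [f"g{i}" for i in range(10)], 300, 300, standardize=False, seed=1
        )
        corr = np.corrcoef(data.matrix().T)
        off = corr[~np.eye(10, dtype=bool)]
        assert np.abs(off).max() < 0.15

    def test_block_correlation_recovered(self):
        genes = [f"g{i}" for i in range(30)]
        blocks = [genes[:15], genes[15:]]
        data = generate_base_data(
            genes, 400, 400, block_corr=0.5, blocks=blocks, seed=2
        )
        corr = np.corrcoef(data.matrix().T)
        within = []
        for blk in blocks:
            idx = [genes.index(g) for g in blk]
            sub = corr[np.ix_(idx, idx)]
            within.extend(sub[~np.eye(len(idx), dtype=bool)])
        assert np.mean(within) == pytest.approx(0.5, abs=0.05)
        across = corr[np.ix_(range(15), range(15, 30))]
        assert abs(across.mean()) < 0.05


class TestInjection:
    def test_case_means_shifted_by_signed_signal(self):
        from semgsa.simulate import AffectedSet

        data = generate_base_data(["up", "down", "null"], 20, 20, seed=3)
        aff = AffectedSet(
            per_pathway={"p": ("up", "down")}, signs={"up": 1, "down": -1}
        )
        out = inject_signal(data, aff, 0.7)
        cases = out.group == 1
        assert out.values.loc[cases, "up"].mean() == pytest.approx(0.7, abs=1e-10)
        assert out.values.loc[cases, "down"].mean() == pytest.approx(-0.7, abs=1e-10)
        assert out.values.loc[cases, "null"].mean() == pytest.approx(0.0, abs=1e-10)
        assert out.values.loc[~cases].abs().to_numpy().max() < 10  # controls untouched
        assert np.allclose(
            out.values.loc[~cases].to_numpy(), data.values.loc[~cases].to_numpy()
        )

    def test_absent_gene_fatal(self):
        from semgsa.simulate import AffectedSet

        data = generate_base_data(["a"], 5, 5, seed=4)
        aff = AffectedSet(per_pathway={"p": ("zz",)}, signs={"zz": 1})
        with pytest.raises(ValueError, match="zz"):
            inject_signal(data, aff, 0.5)


@pytest.fixture(scope="module")
def tiny_run():
    paths = generate_pathways(6, (10, 14), seed=8)
    design = SimulationDesign(
        topology="betweenness",
        signal=0.7,
        q1_pathways=tuple(g.name for g in paths[:3]),
        s=4,
        n_replicates=4,
        n_cases=20,
        n_controls=20,
        n_permutations=120,
        seed=123,
    )
    return design, paths, run_simulation(design, paths)


class TestHarness:
    def test_metrics_in_unit_interval(self, tiny_run):
        _, _, m = tiny_run
        assert 0.0 <= m.power <= 1.0
        if m.q0_pathways:
            assert 0.0 <= m.type_i_error <= 1.0

    def test_deterministic_given_seed(self, tiny_run):
        design, paths, m1 = tiny_run
        m2 = run_simulation(design, paths)
        assert m1.type_i_error == m2.type_i_error
        assert m1.power == m2.power
        assert np.array_equal(m1.per_replicate_q1, m2.per_replicate_q1)

    def test_strong_signal_gives_high_power(self, tiny_run):
        _, _, m = tiny_run
        assert m.power >= 0.5

    def test_invalid_design_rejected(self):
        with pytest.raises(ValueError):
            SimulationDesign(topology="betweenness", signal=0.5, q1_pathways=())
        with pytest.raises(ValueError):
            SimulationDesign(topology="betweenness", signal=0.5,
                             q1_pathways=("p",), s=0)


class TestGenerator:
    def test_pathways_are_connected_dags(self):
        import networkx as nx

        for g in generate_pathways(5, (10, 30), seed=4):
            assert nx.is_directed_acyclic_graph(g.graph)
            assert nx.is_connected(g.graph.to_undirected())
            weights = {d["weight"] for _, _, d in g.graph.edges(data=True)}
            assert weights <= {-1, 0, 1}

    def test_sizes_within_range_and_deterministic(self):
        a = generate_pathways(4, (12, 18), seed=9)
        b = generate_pathways(4, (12, 18), seed=9)
        for g1, g2 in zip(a, b):
            assert g1.n_nodes == g2.n_nodes
            assert 12 <= g1.n_nodes <= 18
            assert g1.directed_edges() == g2.directed_edges()
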