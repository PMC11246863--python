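"""Tree-decomposition validation, the path-cover construction, and the
preprocessing normal form."""

import pytest

from msps.decomposition import (
    TreeDecomposition,
    bag_per_edge_decomposition,
    from_path_cover,
    postprocess_solution,
    preprocess,
    single_bag_decomposition,
    validate,
    width,
)
from msps.graph_core import GraphError, WeightedGraph, path_score
from msps.generate import (
    random_dag_from_paths,
    random_path_instance,
    random_tree_instance,
)


def diamond_dag():
    return WeightedGraph(True, {"1": 1, "2": 1, "3": 1, "4": 1},
                         [("1", "2"), ("2", "4"), ("1", "3"), ("3", "4")])


class TestValidateAndWidth:
    def test_single_bag_is_always_valid(self):
        g = diamond_dag()
        td = single_bag_decomposition(g)
        assert validate(td, g).ok and width(td) == 3

    def test_bag_per_edge_on_a_path(self):
        g = random_path_instance(5, seed=1)
        td = bag_per_edge_decomposition(g)
        assert validate(td, g).ok and width(td) == 1
        assert len(td.bags) == 4

    def test_missing_bag_breaks_condition_two(self):
        g = random_path_instance(4, seed=2)
        td = bag_per_edge_decomposition(g)
        bags = dict(td.bags)
        dropped = bags.pop(max(bags))
        edges = [tuple(e) for e in td.tree_edges if max(td.bags) not in e]
        report = validate(TreeDecomposition(bags, edges), g)
        assert any("condition 2" in e for e in report.errors)

    def test_disconnected_occurrences_break_condition_three(self):
        g = WeightedGraph(True, {"a": 0, "b": 0, "c": 0}, [("a", "b")])
        td = TreeDecomposition({1: {"a", "b"}, 2: {"c"}, 3: {"a"}}, [(1, 2), (2, 3)])
        report = validate(td, g)
        assert any("condition 3" in e for e in report.errors)

    @pytest.mark.parametrize("bags,expected", [
        ({1: {"a", "b"}, 2: {"b", "c"}}, 1),
        ({1: {"a", "b", "c", "d"}}, 3),
        ({1: {"a", "b"}, 2: {"a", "b", "c"}}, 2),
    ])
    def test_width_is_max_bag_size_minus_one(self, bags, expected):
        td = TreeDecomposition(bags, [(i, i + 1) for i in range(1, len(bags))])
        assert width(td) == expected

    def test_width_of_empty_decomposition_raises(self):
        with pytest.raises(GraphError):
            width(TreeDecomposition({}, []))


class TestFromPathCover:
    def test_diamond_worked_example(self):
        g = diamond_dag()
        td = from_path_cover(g, [("1", "2", "4"), ("1", "3", "4")])
        assert [td.bags[i] for i in (1, 2, 3, 4)] == [
            {"1"}, {"1", "2"}, {"1", "2", "3"}, {"2", "3", "4"}]
        assert width(td) == 2 and validate(td, g).ok

    def test_path_graph_covered_by_itself(self):
        g = random_path_instance(5, seed=3)
        order = g.sorted_vertices()
        td = from_path_cover(g, [tuple(order)])
        assert width(td) == 1 and validate(td, g).ok
        assert td.bags[1] == {order[0]}
        for i in range(2, 6):
            assert td.bags[i] == {order[i - 2], order[i - 1]}

    @pytest.mark.parametrize("seed", range(30))
    def test_width_bounded_by_cover_size(self, seed):
        k = 2 + seed % 3
        g, cover = random_dag_from_paths(4 + seed % 6, k, seed)
        td = from_path_cover(g, cover)
        assert validate(td, g).ok
        assert width(td) <= k

    def test_uncovered_edge_is_rejected(self):
        g = diamond_dag()
        with pytest.raises(GraphError, match="not covered"):
            from_path_cover(g, [("1", "2", "4"), ("3", "4")])

    def test_cycle_is_rejected(self):
        g = WeightedGraph(True, {"a": 0, "b": 0}, [("a", "b"), ("b", "a")])
        with pytest.raises(GraphError, match="cycle"):
            from_path_cover(g, [("a", "b"), ("b", "a")])


class TestPreprocess:
    def test_no_heavy_vertices_single_bag(self):
        g = WeightedGraph(True, {"a": -1, "b": -2}, [("a", "b")])
        pg, rd = preprocess(g, single_bag_decomposition(g), c=1)
        assert pg.weights == g.weights  # no auxiliary vertices
        assert rd.check().ok
        # the root keeps its two empty leaf children and owns the only edge
        assert rd.edge_assignment[rd.root] == (("a", "b"),)
        kids = rd.children[rd.root]
        assert len(kids) == 2 and all(not rd.bags[k] for k in kids)

    def test_heavy_vertex_gains_pendant(self):
        g = WeightedGraph(True, {"v": 5}, [])
        pg, rd = preprocess(g, single_bag_decomposition(g), c=2)
        assert pg.n == 2 and pg.m == 1
        (aux,) = rd.aux_map
        assert rd.aux_map[aux] == "v" and pg.weights[aux] == 0
        assert any(b == {"v", aux} for b in rd.bags.values())
        assert rd.check().ok

    def test_bag_with_three_children_is_duplicated(self):
        g = WeightedGraph(True, {x: -1 for x in "abcd"},
                          [("a", "b"), ("a", "c"), ("a", "d")])
        td = TreeDecomposition(
            {1: {"a", "b"}, 2: {"a", "c"}, 3: {"a", "d"}, 4: {"a"}},
            [(4, 1), (4, 2), (4, 3)])
        pg, rd = preprocess(g, td, c=0.5, root=4)
        assert rd.check().ok
        for i, b in rd.bags.items():
            assert len(rd.children[i]) == (2 if b else len(rd.children[i]))
        # duplicated copies of bag {a} exist
        assert sum(1 for b in rd.bags.values() if b == frozenset("a")) >= 2

    @pytest.mark.parametrize("seed", range(20))
    def test_preserves_validity_width_and_bag_count(self, seed):
        kind = seed % 3
        if kind == 0:
            g, cover = random_dag_from_paths(6, 2 + seed % 3, seed)
            td = from_path_cover(g, cover)
        elif kind == 1:
            g, td = random_tree_instance(6, seed, directed=seed % 2 == 0)
        else:
            g = random_path_instance(6, seed, directed=False)
            td = single_bag_decomposition(g)
        for c in (0, 1):
            pg, rd = preprocess(g, td, c)
            assert rd.check().ok
            out = rd.as_tree_decomposition()
            assert validate(out, pg).ok
            assert width(out) <= max(width(td), 1)
            n_aux = len(rd.aux_map)
            # linear in the input: duplicates plus at most two empty leaves
            # per (original or pendant) bag
            assert len(rd.bags) <= 3 * (len(td.bags) + n_aux) + 2
            assert rd.terminals[rd.root] == frozenset()

    def test_invalid_decomposition_is_rejected(self):
        g = diamond_dag()
        td = TreeDecomposition({1: {"1", "2"}}, [])
        with pytest.raises(GraphError, match="invalid tree decomposition"):
            preprocess(g, td, 1)


class TestPostprocess:
    def make(self, weights, edges, c):
        g = WeightedGraph(True, weights, edges)
        return g, *preprocess(g, single_bag_decomposition(g), c)

    def test_pendant_edge_becomes_singleton(self):
        g, pg, rd = self.make({"v": 5}, [], 2)
        (aux,) = rd.aux_map
        ps = postprocess_solution([("v", aux)], rd, g, 2)
        assert ps.paths == (("v",),) and ps.total_score == 3

    def test_without_pendants_identical_to_plain_decomposition(self):
        g, pg, rd = self.make({"a": -1, "b": -1, "c": -1},
                              [("a", "b"), ("b", "c")], 0)
        ps = postprocess_solution([("a", "b"), ("b", "c")], rd, g, 0)
        assert ps.paths == (("a", "b", "c"),)

    def test_cycle_plus_pendant(self):
        g, pg, rd = self.make({"a": 1, "b": 1, "c": 1, "d": 9},
                              [("a", "b"), ("b", "c"), ("c", "a")], 1)
        aux_d = next(a for a, v in rd.aux_map.items() if v == "d")
        sel = [("a", "b"), ("b", "c"), ("c", "a"), ("d", aux_d)]
        ps = postprocess_solution(sel, rd, g, 1)
        assert len(ps) == 2 and ("d",) in ps.paths
        assert ps.total_score == sum(path_score(p, g, 1) for p in ps.paths) == 10

    def test_pendant_with_extra_edge_is_rejected(self):
        g, pg, rd = self.make({"v": 5, "u": 5}, [("u", "v")], 2)
        aux_v = next(a for a, v in rd.aux_map.items() if v == "v")
        aux_u = next(a for a, v in rd.aux_map.items() if v == "u")
        with pytest.raises(GraphError, match="auxiliary"):
            postprocess_solution([("v", aux_v), ("v", aux_v)], rd, g, 2)
        # pendant consumed while v is still mid-path is fine (path ...->v)
        ps = postprocess_solution([("u", "v"), ("v", aux_v)], rd, g, 2)
        assert ps.paths == (("u", "v"),)
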