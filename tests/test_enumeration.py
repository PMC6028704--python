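"""Pathway table DP: partitions, merging, exhaustiveness, cycles, invariants."""

import pytest

from pathenum.enumeration import (
    MemoryGuardExceeded,
    PathwayTable,
    classify_cyclic,
    enumerate_pathways,
    generate_partitions,
    get_pathways,
    pathway_is_complete,
    populate_table,
    write_pathways_jsonl,
)
from pathenum.oracle import naive_derivations, pathways_by_size
from pathenum.scope import guided_bfs
from pathenum.toys import ToySpec, generate

from conftest import make_graph


def enumerate_graph(graph, seeds, beta, **kw):
    seeds = frozenset(seeds)
    return enumerate_pathways(graph, guided_bfs(graph, seeds), seeds, beta, **kw)


def table_cells(table, graph, beta):
    """All non-bottom cells at columns 1..beta as {(met, k): frozenset of sets}."""
    out = {}
    for m in graph.metabolites:
        for k in table.sizes(m):
            if 1 <= k <= beta:
                out[(m, k)] = frozenset(table.get(m, k))
    return out


class TestGeneratePartitions:
    def test_two_inputs_column_three_sum_two(self):
        # the canonical worked example at the minimum sum
        parts = [p for p in generate_partitions(2, 3, [[0, 1, 2], [0, 1, 2]]) if sum(p) == 2]
        assert sorted(parts) == [(0, 2), (1, 1), (2, 0)]

    def test_full_sum_range_up_to_n_times_k_minus_1(self):
        parts = set(generate_partitions(2, 3, [[0, 1, 2], [0, 1, 2]]))
        assert parts == {(0, 2), (1, 1), (2, 0), (1, 2), (2, 1), (2, 2)}

    def test_single_input_bounds(self):
        assert list(generate_partitions(1, 2, [[0, 1]])) == [(1,)]

    def test_feasibility_filter_and_empty_stream(self):
        # p_i restricted to non-bottom columns; an empty feasible set kills the stream
        assert set(generate_partitions(2, 3, [[1], [0, 2]])) == {(1, 2)}
        assert list(generate_partitions(2, 3, [[], [0, 1]])) == []

    def test_values_capped_at_k_minus_1(self):
        parts = set(generate_partitions(2, 2, [[0, 1, 5], [0, 1, 5]]))
        assert parts == {(0, 1), (1, 0), (1, 1)}

    def test_no_duplicates_and_lazy_stream(self):
        gen = generate_partitions(3, 4, [[0, 1, 2, 3]] * 3)
        first = next(gen)
        rest = list(gen)
        assert first not in rest
        assert len(rest) + 1 == len(set(rest) | {first})


class TestPopulateTable:
    def test_shared_subpathway_collapses_to_size_two(self, byproduct_graph):
        # both inputs made by the same reaction: {r', r} has size 2, not 3
        table = PathwayTable(beta=3, seeds={"s"})
        table.insert("m1", frozenset(["rp"]))
        table.insert("m2", frozenset(["rp"]))
        populate_table(table, "r", (1, 1), ("m1", "m2"), ("y",))
        assert table.get("y", 2) == {frozenset(["rp", "r"])}
        assert table.get("y", 3) is None

    def test_seed_input_partition_zero_gives_singleton(self):
        table = PathwayTable(beta=2, seeds={"s"})
        populate_table(table, "r1", (0,), ("s",), ("b",))
        assert table.get("b", 1) == {frozenset(["r1"])}

    def test_disjoint_subpathways_sum_up(self):
        table = PathwayTable(beta=5, seeds={"s"})
        table.insert("m1", frozenset(["a"]))
        table.insert("m2", frozenset(["b", "c"]))
        populate_table(table, "r", (1, 2), ("m1", "m2"), ("y",))
        assert table.get("y", 4) == {frozenset(["a", "b", "c", "r"])}

    def test_bottom_component_violates_precondition(self):
        table = PathwayTable(beta=3, seeds={"s"})
        with pytest.raises(ValueError, match="⊥"):
            populate_table(table, "r", (1,), ("m1",), ("y",))


class TestEnumerate:
    def test_seed_column_zero_initialisation(self, chain_graph):
        table = enumerate_graph(chain_graph, {"A"}, 2)
        assert table.get("A", 0) == {frozenset()}
        assert table.get("B", 0) is None  # non-seed stays bottom at column 0

    def test_linear_chain_single_derivation(self, chain_graph):
        table = enumerate_graph(chain_graph, {"A"}, 2)
        assert table.get("C", 2) == {frozenset(["r1", "r2"])}
        assert table.get("C", 1) is None

    def test_parallel_routes_all_found(self):
        g = make_graph([("r1", ["A"], ["B"]), ("r2", ["A"], ["B"])])
        table = enumerate_graph(g, {"A"}, 1)
        assert table.get("B", 1) == {frozenset(["r1"]), frozenset(["r2"])}

    def test_branched_join_needs_both_arms(self, branched_graph):
        table = enumerate_graph(branched_graph, {"A"}, 3)
        pathways = get_pathways(table, "D", graph=branched_graph)
        assert [set(p.reactions) for p in pathways] == [{"r1", "r2", "r3"}]

    def test_beta_below_one_rejected(self, chain_graph):
        with pytest.raises(ValueError, match="beta"):
            enumerate_graph(chain_graph, {"A"}, 0)

    def test_memory_guard_names_cell(self):
        g = make_graph([(f"r{i}", ["A"], ["B"]) for i in range(6)])
        with pytest.raises(MemoryGuardExceeded, match=r"\('B', 1\)"):
            enumerate_graph(g, {"A"}, 1, max_pathways=3)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_naive_derivation_closure(self, seed):
        net = generate(ToySpec("random", n_reactions=9, seed=seed,
                               reversible_fraction=0.2 if seed % 2 else 0.0))
        beta = 3 + seed % 3
        table = enumerate_graph(net.graph, net.seeds, beta)
        oracle = naive_derivations(net.graph, net.seeds, beta)
        for m in net.graph.metabolites:
            dp = {k: table.get(m, k) for k in table.sizes(m) if 1 <= k <= beta}
            assert {k: v for k, v in dp.items() if v} == pathways_by_size(oracle[m]), m

    @pytest.mark.parametrize("seed", range(12))
    def test_every_stored_pathway_has_exact_size_and_is_unique(self, seed):
        net = generate(ToySpec("random", n_reactions=9, seed=seed))
        table = enumerate_graph(net.graph, net.seeds, 4)
        for m in net.graph.metabolites:
            seen = set()
            for k in table.sizes(m):
                cell = table.get(m, k)
                for rset in cell:
                    assert len(rset) == k
                    assert rset not in seen
                    seen.add(rset)

    @pytest.mark.parametrize("seed", range(12))
    def test_pruning_is_output_neutral(self, seed):
        net = generate(ToySpec("random", n_reactions=9, seed=seed, reversible_fraction=0.15))
        a = enumerate_graph(net.graph, net.seeds, 4, prune=True)
        b = enumerate_graph(net.graph, net.seeds, 4, prune=False)
        assert table_cells(a, net.graph, 4) == table_cells(b, net.graph, 4)

    @pytest.mark.parametrize("seed", range(12))
    def test_monotone_in_beta(self, seed):
        net = generate(ToySpec("random", n_reactions=9, seed=seed, reversible_fraction=0.15))
        small = enumerate_graph(net.graph, net.seeds, 3)
        large = enumerate_graph(net.graph, net.seeds, 5)
        for (m, k), cell in table_cells(small, net.graph, 3).items():
            assert cell == frozenset(large.get(m, k))
        # and nothing extra at columns <= 3 beyond what beta=3 found
        small_cells = table_cells(small, net.graph, 3)
        for (m, k), cell in table_cells(large, net.graph, 3).items():
            assert small_cells.get((m, k), frozenset()) == cell

    def test_result_invariant_to_reaction_declaration_order(self):
        rows = [
            ("r1", ["A"], ["B"]),
            ("r2", ["A"], ["C"]),
            ("r3", ["B", "C"], ["D"]),
            ("r4", ["D"], ["B"]),
        ]
        tables = []
        for order in ([0, 1, 2, 3], [3, 2, 1, 0], [2, 0, 3, 1]):
            g = make_graph([rows[i] for i in order])
            tables.append(table_cells(enumerate_graph(g, {"A"}, 4), g, 4))
        assert tables[0] == tables[1] == tables[2]


class TestCyclic:
    def test_two_cycle_regenerating_seed_is_cyclic(self, two_cycle_graph):
        table = enumerate_graph(two_cycle_graph, {"A"}, 2)
        pathways = get_pathways(table, "A", graph=two_cycle_graph)
        assert [(set(p.reactions), p.is_cyclic) for p in pathways] == [({"r1", "r2"}, True)]

    def test_linear_chain_is_acyclic(self, chain_graph):
        assert not classify_cyclic(["r1", "r2"], chain_graph)

    def test_four_reaction_loop_reported_exactly_once(self):
        net = generate(ToySpec("cycle", n_reactions=4))
        table = enumerate_graph(net.graph, net.seeds, 4)
        pathways = get_pathways(table, "m0", graph=net.graph)
        assert len(pathways) == 1
        (p,) = pathways
        assert p.is_cyclic and set(p.reactions) == {"r1", "r2", "r3", "r4"}

    def test_reversible_pair_flagged(self):
        g = make_graph([("r1", ["A"], ["B"])], reversible=["r1"])
        table = enumerate_graph(g, {"A"}, 2)
        pathways = get_pathways(table, "A", graph=g)
        assert any(p.contains_reversible_pair for p in pathways)


class TestGetPathways:
    def test_seed_target_excludes_empty_pathway(self, chain_graph):
        table = enumerate_graph(chain_graph, {"A"}, 2)
        assert get_pathways(table, "A", graph=chain_graph) == []

    def test_unreachable_target_empty_with_warning(self, chain_graph):
        table = enumerate_graph(chain_graph, {"A"}, 2)
        with pytest.warns(UserWarning, match="ghost"):
            assert get_pathways(table, "ghost") == []

    def test_deterministic_ordering_by_size_then_ids(self):
        g = make_graph([
            ("a", ["A"], ["B"]), ("b", ["A"], ["B"]),
            ("c", ["B"], ["C"]), ("d", ["C"], ["B"]),
        ])
        table = enumerate_graph(g, {"A"}, 3)
        pathways = get_pathways(table, "B", graph=g)
        assert pathways == sorted(pathways)
        assert pathways[0].size <= pathways[-1].size

    def test_jsonl_round_trip(self, branched_graph, tmp_path):
        from pathenum.enumeration import read_pathways_jsonl

        table = enumerate_graph(branched_graph, {"A"}, 3)
        pathways = get_pathways(table, "D", graph=branched_graph)
        path = tmp_path / "p.jsonl"
        write_pathways_jsonl(pathways, path)
        assert read_pathways_jsonl(path) == pathways


class TestCompleteness:
    @pytest.mark.parametrize("seed", range(15))
    def test_emitted_pathways_pass_induced_subgraph_check(self, seed):
        net = generate(ToySpec("random", n_reactions=9, seed=seed, reversible_fraction=0.2))
        table = enumerate_graph(net.graph, net.seeds, 4)
        for m in net.graph.metabolites:
            for p in get_pathways(table, m, graph=net.graph):
                assert pathway_is_complete(net.graph, p.reactions, net.seeds)

    def test_incomplete_set_fails_check(self, branched_graph):
        # r3 without r2 lacks a producer for C
        assert not pathway_is_complete(branched_graph, ["r1", "r3"], {"A"})
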