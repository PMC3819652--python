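from fractions import Fraction

import networkx as nx
import pytest

from umcheck.fixtures import random_model
from umcheck.gapfind import check_model
from umcheck.graph import (
    build_graph,
    export_graph,
    find_ums,
    um_subgraph,
    um_table,
)
from umcheck.model import Metabolite, Model, Reaction


def _analyse(model):
    blocked, gaps = check_model(model)
    graph = build_graph(model, blocked, gaps)
    sub = um_subgraph(graph, gaps, blocked)
    return blocked, gaps, graph, sub


def test_graph_is_bipartite_with_one_arc_per_nonzero(fig1a):
    model, _ = fig1a
    graph = build_graph(model)
    assert graph.number_of_nodes() == model.n_metabolites + model.n_reactions
    nnz = sum(len(r.stoichiometry) for r in model.reactions)
    assert graph.number_of_edges() == nnz == 10
    for src, dst in graph.edges:
        assert graph.nodes[src]["kind"] != graph.nodes[dst]["kind"]


def test_arc_direction_follows_consumption():
    mets = [Metabolite("A"), Metabolite("B")]
    rxns = [Reaction("R", {"A": Fraction(-1), "B": Fraction(1)}, 0, 1000)]
    model = Model("m", mets, rxns, exchange_ids=set())
    graph = build_graph(model)
    assert list(graph.edges) == [("A", "R"), ("R", "B")]


def test_um_subgraph_membership(fig1a, fig2):
    model, _ = fig1a
    _, _, _, sub = _analyse(model)
    assert set(sub.nodes) == {"A", "B", "C", "R1", "R2", "R3"}
    assert sub.number_of_edges() == 5  # A-R1, R1-B, B-R2, R2-C, C-R3

    model2, _ = fig2
    _, _, _, sub2 = _analyse(model2)
    assert set(sub2.nodes) == {"A", "B", "C", "Cp", "EX_A", "v1", "v2", "v3",
                               "v4"}
    assert "D" not in sub2.nodes and "Dstar" not in sub2.nodes


def test_no_blocked_reactions_gives_empty_subgraph():
    mets = [Metabolite("A")]
    rxns = [
        Reaction("EX_A", {"A": Fraction(-1)}, -1000, 1000),
        Reaction("SK_A", {"A": Fraction(-1)}, -1000, 1000),
    ]
    model = Model("ok", mets, rxns, exchange_ids={"EX_A", "SK_A"})
    _, _, _, sub = _analyse(model)
    assert sub.number_of_nodes() == 0
    assert find_ums(sub) == []


def test_disjoint_union_gives_two_modules(fig1a, fig1b):
    from dataclasses import replace

    model_a, _ = fig1a
    model_b, _ = fig1b
    renamed = [replace(r, id=f"b_{r.id}") for r in model_b.reactions]
    union = Model(
        "union",
        metabolites=model_a.metabolites + model_b.metabolites,
        reactions=model_a.reactions + renamed,
        exchange_ids=model_a.exchange_ids
        | {f"b_{r}" for r in model_b.exchange_ids},
    )
    _, gaps, _, sub = _analyse(union)
    ums = find_ums(sub, union, gaps)
    assert len(ums) == 2
    assert all(um.n_reactions == 3 for um in ums)
    members = {um.members for um in ums}
    assert frozenset({"A", "B", "C", "R1", "R2", "R3"}) in members


def test_modules_partition_gap_blocked_sets(fig2):
    model, _ = fig2
    blocked, gaps, _, sub = _analyse(model)
    ums = find_ums(sub, model, gaps)
    all_members = [m for um in ums for m in um.members]
    assert len(all_members) == len(set(all_members))  # disjoint
    assert set(all_members) == set(gaps.gaps) | set(blocked.blocked)


def test_components_match_bfs_oracle():
    """find_ums component membership equals a hand-rolled BFS on the
    undirected view, over random planted models."""
    for seed in range(10):
        model, _ = random_model(n_backbone=2, n_modules=(seed % 4),
                                sizes=(1, 3), seed=seed)
        _, gaps, _, sub = _analyse(model)
        ums = find_ums(sub, model, gaps)
        undirected = sub.to_undirected()
        seen = set()
        bfs_components = []
        for node in sorted(undirected.nodes):
            if node in seen:
                continue
            queue, comp = [node], set()
            while queue:
                current = queue.pop()
                if current in comp:
                    continue
                comp.add(current)
                queue.extend(undirected.neighbors(current))
            seen |= comp
            bfs_components.append(frozenset(comp))
        assert {um.members for um in ums} == set(bfs_components)


def test_um_table_rows(fig1a, fig1b):
    for fixture, rnp, rnc in ((fig1a, "A", "-"), (fig1b, "-", "H")):
        model, _ = fixture
        _, gaps, _, sub = _analyse(model)
        table = um_table(find_ums(sub, model, gaps))
        assert len(table) == 1
        row = table.iloc[0]
        assert row["n_reactions"] == 3 and row["n_metabolites"] == 3
        assert row["rnp"] == rnp and row["rnc"] == rnc
    assert list(um_table([]).columns) == [
        "um", "subsystem", "n_reactions", "n_metabolites", "rnp", "rnc"]


def test_sorting_by_reaction_count():
    model, _ = random_model(n_backbone=1, n_modules=3,
                            module_kinds=("rnp_chain",), sizes=(1, 3), seed=3)
    _, gaps, _, sub = _analyse(model)
    ums = find_ums(sub, model, gaps)
    counts = [um.n_reactions for um in ums]
    assert counts == sorted(counts, reverse=True)
    assert [um.index for um in ums] == list(range(1, len(ums) + 1))


@pytest.mark.parametrize("fmt", ["graphml", "gml", "dot"])
def test_export_formats(fmt, fig1a, tmp_path):
    model, _ = fig1a
    _, gaps, _, sub = _analyse(model)
    path = tmp_path / f"um.{fmt}"
    export_graph(sub, path, fmt)
    assert path.exists() and path.stat().st_size > 0
    if fmt == "graphml":
        back = nx.read_graphml(path)
        assert set(back.nodes) == set(sub.nodes)
        assert {(u, v) for u, v in back.edges} == set(sub.edges)


def test_export_empty_graph_and_unknown_format(tmp_path):
    empty = nx.DiGraph()
    export_graph(empty, tmp_path / "e.gml", "gml")
    assert (tmp_path / "e.gml").exists()
    with pytest.raises(ValueError, match="graphml"):
        export_graph(empty, tmp_path / "e.xyz", "xyz")
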