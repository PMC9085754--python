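import networkx as nx
import numpy as np
import pandas as pd
import pytest

from regaxis import (
    build_coexpression_network,
    common_across_drugs,
    datasets,
    detect_communities,
    import_edge_list,
    intersect_hubs,
    node_degrees,
    select_hubs,
)
from regaxis.networks import HubSet
from conftest import partition_agreement


def test_coexpression_duplicated_rows_edge_weight_one(rng):
    data = rng.normal(size=(5, 10))
    data[1] = data[0]
    expr = pd.DataFrame(data, index=[f"g{i}" for i in range(5)])
    net = build_coexpression_network(expr, tau=0.999, method="pearson")
    assert net.has_edge("g0", "g1")
    assert net.edges["g0", "g1"]["weight"] == pytest.approx(1.0)


def test_coexpression_tau_one_mostly_edgeless(rng):
    expr = pd.DataFrame(rng.normal(size=(10, 20)))
    expr.index = [f"g{i}" for i in range(10)]
    net = build_coexpression_network(expr, tau=1.0, method="pearson")
    assert net.number_of_edges() == 0


def test_coexpression_planted_block_recovered():
    """Genes loading on a shared latent factor connect at tau=0.8 while
    background noise genes stay (almost surely) isolated."""
    g = np.random.default_rng(42)
    n_samples = 30
    factor = g.normal(size=n_samples)
    block = 2.0 * factor + g.normal(scale=0.5, size=(6, n_samples))
    background = g.normal(size=(10, n_samples))
    expr = pd.DataFrame(
        np.vstack([block, background]),
        index=[f"b{i}" for i in range(6)] + [f"n{i}" for i in range(10)],
    )
    net = build_coexpression_network(expr, tau=0.8, method="uncentered")
    block_nodes = {f"b{i}" for i in range(6)}
    comp = next(c for c in nx.connected_components(net) if "b0" in c)
    assert comp == block_nodes
    assert all(net.degree(f"n{i}") == 0 for i in range(10))


def test_coexpression_constant_rows_excluded_under_pearson(rng):
    data = rng.normal(size=(4, 8))
    data[2] = 1.0
    expr = pd.DataFrame(data, index=list("abcd"))
    with pytest.warns(UserWarning):
        net = build_coexpression_network(expr, tau=0.5, method="pearson")
    assert "c" not in net


def test_import_edge_list_confidence_strict(tmp_path):
    path = tmp_path / "edges.tsv"
    path.write_text("A\tB\t0.3\nA\tC\t0.4\nA\tD\t0.41\n")
    net = import_edge_list(str(path), min_confidence=0.400)
    assert set(net.edges) == {("A", "D")}


def test_import_edge_list_sif_dedup_and_errors(tmp_path):
    path = tmp_path / "edges.sif"
    path.write_text("A\tpp\tB\nB\tpp\tA\nC\tpp\tD\n")
    net = import_edge_list(str(path), min_confidence=None)
    assert net.number_of_edges() == 2

    dup = tmp_path / "dup.tsv"
    dup.write_text("A\tB\t0.5\nB\tA\t0.9\n")
    net = import_edge_list(str(dup), min_confidence=0.4)
    assert net.edges["A", "B"]["confidence"] == pytest.approx(0.9)

    empty = tmp_path / "empty.tsv"
    empty.write_text("")
    assert import_edge_list(str(empty)).number_of_edges() == 0

    bad = tmp_path / "bad.tsv"
    bad.write_text("A\tB\tC\tD\tE\n")
    with pytest.raises(ValueError, match="bad.tsv:1"):
        import_edge_list(str(bad))


def test_node_degrees_against_brute_force(rng):
    for _ in range(20):
        n = int(rng.integers(3, 30))
        g = nx.gnp_random_graph(n, 0.3, seed=int(rng.integers(2**31)))
        deg = node_degrees(g)
        for v in g.nodes:
            assert deg[v] == sum(1 for e in g.edges if v in e)
        assert sum(deg.values()) == 2 * g.number_of_edges()


def test_select_hubs_rules():
    g = nx.star_graph(5)  # center 0 degree 5, leaves degree 1
    byk = select_hubs(g, min_degree=2)
    assert byk.hubs == [0] and byk.lowest_degree == 5
    allnodes = select_hubs(g, min_degree=0)
    assert len(allnodes.hubs) == 6
    topf = select_hubs(g, top_fraction=0.5)
    # ties at degree 1 are all included
    assert set(topf.hubs) == set(g.nodes)
    with pytest.raises(ValueError):
        select_hubs(g, min_degree=1, top_fraction=0.5)
    with pytest.raises(ValueError):
        select_hubs(g, top_fraction=1.5)


def test_hub_degree_threshold_count_fixture(rng):
    """A network whose degree sequence has exactly 34 nodes at degree >=
    30 yields 34 hubs under the absolute rule, with lowest selected
    degree 30."""
    degrees = [30 + int(d) for d in rng.integers(0, 40, size=34)] + [
        int(d) for d in rng.integers(1, 30, size=118)
    ]
    if sum(degrees) % 2:
        degrees[-1] += 1
    g = nx.configuration_model(degrees, seed=3)
    g = nx.Graph(g)
    g.remove_edges_from(nx.selfloop_edges(g))
    # configuration model may shave a few degrees when simplified; use
    # the realized degrees to define the expected hub count
    realized = node_degrees(g)
    expected = sorted(v for v, d in realized.items() if d >= 30)
    hubs = select_hubs(g, min_degree=30)
    assert hubs.hubs == expected
    assert hubs.lowest_degree >= 30


def test_detect_communities_components_and_clique():
    two_triangles = nx.union(
        nx.relabel_nodes(nx.complete_graph(3), {i: f"a{i}" for i in range(3)}),
        nx.relabel_nodes(nx.complete_graph(3), {i: f"b{i}" for i in range(3)}),
    )
    part = detect_communities(two_triangles)
    assert len(part.communities) == 2
    assert {frozenset(c) for c in map(set, part.communities)} == {
        frozenset({"a0", "a1", "a2"}),
        frozenset({"b0", "b1", "b2"}),
    }
    assert part.modularity >= 0.0

    clique = nx.complete_graph(5)
    assert len(detect_communities(clique).communities) == 1
    with pytest.raises(ValueError):
        detect_communities(nx.Graph())


def test_detect_communities_planted_blocks():
    g = nx.planted_partition_graph(2, 20, 0.9, 0.05, seed=7)
    truth = {n: (0 if n < 20 else 1) for n in g.nodes}
    part = detect_communities(g)
    assert partition_agreement(part.membership, truth) >= 0.95


def test_detect_communities_permutation_invariant(rng):
    g = nx.planted_partition_graph(2, 10, 0.9, 0.05, seed=2)
    part1 = detect_communities(g)
    mapping = dict(zip(g.nodes, rng.permutation(list(g.nodes))))
    part2 = detect_communities(nx.relabel_nodes(g, mapping))
    sets1 = {frozenset(mapping[n] for n in c) for c in part1.communities}
    sets2 = {frozenset(c) for c in part2.communities}
    assert sets1 == sets2


def test_intersect_hubs_and_na():
    coexp = HubSet(hubs=["FN1", "CD44", "X"], rule="t", lowest_degree=1)
    clusters = {
        "c1": HubSet(hubs=["FN1", "CD44", "Y"], rule="t", lowest_degree=1),
        "c2": HubSet(hubs=["Z"], rule="t", lowest_degree=1),
        "c3": HubSet(hubs=["CD44"], rule="t", lowest_degree=1),
    }
    out = intersect_hubs(coexp, clusters)
    assert out["c1"] == ["CD44", "FN1"]
    assert out["c2"] is None
    assert out["c3"] == ["CD44"]  # subset of coexp passes through
    for cluster, common in out.items():
        if common is not None:
            assert set(common) <= set(coexp.hubs)
            assert set(common) <= set(clusters[cluster].hubs)


def test_common_across_drugs_published_lists():
    per_drug = {
        drug: set().union(*(set(v) for v in clusters.values()), set())
        for drug, clusters in datasets.common_hub_table().items()
    }
    out = common_across_drugs(per_drug)
    assert out.loc["FN1", "n_drugs"] == 4
    assert out.loc["CD44", "n_drugs"] == 4
    assert out.loc["TIMP1", "n_drugs"] == 3
    assert out.loc["SPARC", "n_drugs"] == 2
    assert out.loc["SNAI2", "n_drugs"] == 2
    assert set(out.loc["FN1", "drugs"].split(",")) == {
        "Ponatinib", "Foretinib", "Selumetinib", "Trametinib",
    }
    assert out.loc["TYR", "n_drugs"] == 1
    with pytest.raises(ValueError):
        common_across_drugs({"only": {"FN1"}})
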