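import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from regaxis import (
    SimulationConfig,
    annotate_interaction_region,
    betweenness_centrality,
    build_axis_report,
    centrality_table,
    classify_cis_trans,
    datasets,
    find_mutual_edges,
    merge_networks,
    out_degree,
    rank_regulators,
    simulate_regulatory_network,
    two_hop_indirect_targets,
)


def brute_force_betweenness(g):
    """Enumerate all shortest paths between all ordered pairs and count
    pass-through fractions; normalize by (n-1)(n-2)."""
    n = g.number_of_nodes()
    bc = {v: 0.0 for v in g.nodes}
    for s, t in itertools.permutations(g.nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in g.nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += through / len(paths)
    if n > 2:
        for v in bc:
            bc[v] /= (n - 1) * (n - 2)
    return bc


def test_betweenness_path_and_star():
    path = nx.DiGraph([("a", "b"), ("b", "c")])
    bc = betweenness_centrality(path)
    assert bc["b"] == pytest.approx(0.5)
    assert bc["a"] == bc["c"] == 0.0
    star = nx.DiGraph([("c", f"l{i}") for i in range(4)])
    assert betweenness_centrality(star)["c"] == 0.0


def test_betweenness_matches_brute_force_on_random_digraphs():
    g = np.random.default_rng(123)
    for _ in range(200):
        n = int(g.integers(3, 7))
        net = nx.gnp_random_graph(n, float(g.uniform(0.2, 0.8)),
                                  seed=int(g.integers(2**31)), directed=True)
        got = betweenness_centrality(net)
        want = brute_force_betweenness(net)
        for v in net.nodes:
            assert got[v] == pytest.approx(want[v], abs=1e-12)


def test_merge_networks_union_provenance_and_conflict():
    mk = lambda rows: pd.DataFrame(
        rows, columns=["source", "target", "source_class", "target_class"]
    )
    a = mk([("L1", "T1", "lncRNA", "TF"), ("T1", "G1", "TF", "coding")])
    b = mk([("L1", "T1", "lncRNA", "TF"), ("T1", "G2", "TF", "coding")])
    net = merge_networks([a.assign(provenance="curated"), b.assign(provenance="ChIP")])
    assert net.number_of_edges() == 3
    assert sorted(net.edges["L1", "T1"]["provenance"]) == ["ChIP", "curated"]
    disjoint = merge_networks([a])
    assert disjoint.number_of_edges() == 2
    with pytest.raises(ValueError, match="tagged both"):
        merge_networks([a, mk([("T1", "G1", "lncRNA", "coding")])])


def test_out_degree_worked_example(axis_network):
    od = out_degree(axis_network)
    assert od["MALAT1"] == 8
    assert od["EGR1"] == 4
    assert od["YBX1"] == 4
    assert od["FN1"] == 0  # coding genes are sinks
    assert sum(od.values()) == axis_network.number_of_edges()


def test_rank_regulators_places_malat1_first(axis_network):
    cent = centrality_table(axis_network)
    assert rank_regulators(cent, "lncRNA")[0] == "MALAT1"
    tf_ranking = rank_regulators(cent, "TF")
    assert set(tf_ranking[:3]) >= {"EGR1", "YBX1"}
    # tie-break: out-degree ties resolved by betweenness then name
    ties = pd.DataFrame(
        {
            "node_class": ["TF"] * 3,
            "out_degree": [1, 1, 1],
            "betweenness": [0.0, 0.0, 0.0],
        },
        index=["b", "a", "c"],
    )
    assert rank_regulators(ties, "TF") == ["a", "b", "c"]
    with pytest.raises(ValueError):
        rank_regulators(cent, "nosuchclass")


def test_two_hop_indirect_targets_worked_example(axis_network):
    pairs = two_hop_indirect_targets(axis_network, "MALAT1")
    assert pairs == [("CD44", "EGR1"), ("FN1", "EGR1"), ("TIMP1", "EGR1")]
    # every pair certified by its 2-edge path
    for gene, tf in pairs:
        assert axis_network.has_edge("MALAT1", tf)
        assert axis_network.has_edge(tf, gene)
    assert two_hop_indirect_targets(axis_network, "TFX1") == []


def test_two_hop_diamond_counts_distinct_mediators():
    edges = pd.DataFrame(
        [
            ("L", "T1", "lncRNA", "TF"),
            ("L", "T2", "lncRNA", "TF"),
            ("T1", "G", "TF", "coding"),
            ("T2", "G", "TF", "coding"),
        ],
        columns=["source", "target", "source_class", "target_class"],
    )
    net = merge_networks([edges])
    assert two_hop_indirect_targets(net, "L") == [("G", "T1"), ("G", "T2")]


def test_find_mutual_edges(axis_network):
    assert find_mutual_edges(axis_network) == [("EGR1", "MALAT1")]
    dag = nx.DiGraph([("a", "b"), ("b", "c")])
    assert find_mutual_edges(dag) == []
    cycle = nx.DiGraph([("a", "b"), ("b", "c"), ("c", "a")])
    assert find_mutual_edges(cycle) == []


def test_classify_cis_trans(driver_annot):
    assert classify_cis_trans("MALAT1", "CD44", driver_annot) == "cis"
    assert classify_cis_trans("MALAT1", "FN1", driver_annot) == "trans"
    assert classify_cis_trans("FN1", "FN1", driver_annot) == "cis"
    # symmetric in its arguments
    for target in datasets.DRIVER_GENES:
        assert classify_cis_trans("MALAT1", target, driver_annot) == classify_cis_trans(
            target, "MALAT1", driver_annot
        )
    with pytest.raises(KeyError):
        classify_cis_trans("MALAT1", "NOPE", driver_annot)


def test_annotate_interaction_region(driver_annot):
    row = driver_annot.loc["FN1"]  # 5'UTR 1-100, CDS 101-1100, 3'UTR 1101-1600
    assert annotate_interaction_region((10, 20), row)["region"] == "5'UTR"
    spanning = annotate_interaction_region((95, 110), row)
    assert spanning["region"] == "CDS"  # midpoint 102
    assert spanning["overlap"]["5'UTR"] == pytest.approx(6 / 16)
    whole_utr3 = annotate_interaction_region((1101, 1600), row)
    assert whole_utr3["region"] == "3'UTR"
    assert whole_utr3["overlap"]["3'UTR"] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        annotate_interaction_region((0, 10), row)
    with pytest.raises(ValueError):
        annotate_interaction_region((1500, 1700), row)


def test_axis_report_worked_example(axis_network, driver_annot):
    report = build_axis_report(
        axis_network,
        annot=driver_annot,
        interaction_sites=datasets.malat1_interaction_sites(),
    )
    assert report.regulator == "MALAT1"
    assert report.direct_targets["coding"] == ["SNAI2", "SPARC"]
    assert {d["target"] for d in report.indirect_targets} == {"FN1", "CD44", "TIMP1"}
    assert all(d["via"] == "EGR1" for d in report.indirect_targets)
    assert report.mutual_partners == ["EGR1"]
    assert [g for g, m in report.cis_trans.items() if m == "cis"] == ["CD44"]
    regions = {g: r["region"] for g, r in report.interaction_regions.items()}
    assert regions == {
        "FN1": "5'UTR",
        "TIMP1": "CDS",
        "SNAI2": "CDS",
        "CD44": "3'UTR",
        "SPARC": "3'UTR",
    }


def test_axis_report_empty_network():
    report = build_axis_report(nx.DiGraph())
    assert report.no_regulator and report.regulator is None


def test_planted_regulator_always_ranked_first():
    for seed in range(20):
        cfg = SimulationConfig(rng_seed=seed)
        net, planted = simulate_regulatory_network(cfg)
        cent = centrality_table(net)
        assert rank_regulators(cent, "lncRNA")[0] == planted
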