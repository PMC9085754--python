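"""Directed lncRNA-TF-coding-gene regulatory network analysis.

The regulatory graph carries typed nodes (lncRNA, TF, coding) and
directed source->target edges from curated/ChIP/text-mined/predicted
evidence.  Master-regulator candidates are ranked by out-degree, then
betweenness centrality (directed, normalized by (n-1)(n-2), unweighted
hop-count shortest paths).  The module also resolves 2-hop indirect
regulation (lncRNA -> TF -> coding gene), mutual-edge feedback pairs,
cis/trans mode by shared chromosome, and the transcript region (5'UTR /
CDS / 3'UTR) of lncRNA-mRNA interaction sites, assembling everything
into a serializable regulatory-axis report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "AxisReport",
    "merge_networks",
    "out_degree",
    "betweenness_centrality",
    "centrality_table",
    "rank_regulators",
    "two_hop_indirect_targets",
    "find_mutual_edges",
    "classify_cis_trans",
    "annotate_interaction_region",
    "build_axis_report",
]

NODE_CLASSES = ("lncRNA", "TF", "coding")


@dataclass
class AxisReport:
    """One regulatory axis: a nominated master regulator and its reach."""

    regulator: str | None
    regulator_class: str | None = None
    direct_targets: dict[str, list[str]] = field(default_factory=dict)
    indirect_targets: list[dict[str, str]] = field(default_factory=list)
    mutual_partners: list[str] = field(default_factory=list)
    cis_trans: dict[str, str] = field(default_factory=dict)
    interaction_regions: dict[str, dict] = field(default_factory=dict)
    no_regulator: bool = False

    def to_dict(self) -> dict:
        return {
            "regulator": self.regulator,
            "regulator_class": self.regulator_class,
            "direct_targets": self.direct_targets,
            "indirect_targets": self.indirect_targets,
            "mutual_partners": self.mutual_partners,
            "cis_trans": self.cis_trans,
            "interaction_regions": self.interaction_regions,
            "no_regulator": self.no_regulator,
        }


def merge_networks(edge_sets: Iterable[pd.DataFrame]) -> nx.DiGraph:
    """Union of directed typed edge tables into one master network.

    Each table needs columns source, target, source_class, target_class
    and optionally provenance.  Parallel edges collapse to one edge
    whose ``provenance`` attribute accumulates all tags.  A node id
    appearing with conflicting classes across tables is an error.
    """
    g = nx.DiGraph()
    classes: dict[str, str] = {}

    def set_class(node: str, cls: str) -> None:
        if cls not in NODE_CLASSES:
            raise ValueError(f"unknown node class {cls!r} for {node!r}")
        if node in classes and classes[node] != cls:
            raise ValueError(
                f"node {node!r} tagged both {classes[node]!r} and {cls!r}"
            )
        classes[node] = cls

    for table in edge_sets:
        required = {"source", "target", "source_class", "target_class"}
        if not required <= set(table.columns):
            raise ValueError(f"edge table missing columns {required - set(table.columns)}")
        for row in table.itertuples(index=False):
            src, tgt = str(row.source), str(row.target)
            if src == tgt:
                continue
            set_class(src, str(row.source_class))
            set_class(tgt, str(row.target_class))
            tag = str(getattr(row, "provenance", "curated") or "curated")
            if g.has_edge(src, tgt):
                tags = g.edges[src, tgt]["provenance"]
                if tag not in tags:
                    tags.append(tag)
            else:
                g.add_edge(src, tgt, provenance=[tag])

    for node, cls in classes.items():
        if node not in g:
            g.add_node(node)
        g.nodes[node]["node_class"] = cls
    return g


def out_degree(net: nx.DiGraph) -> dict[str, int]:
    """Out-edge count per node."""
    return dict(net.out_degree())


def betweenness_centrality(net: nx.DiGraph) -> dict[str, float]:
    """Directed shortest-path betweenness, normalized by (n-1)(n-2).

    Paths are unweighted (hop counts); unreachable pairs contribute
    nothing.  Values lie in [0, 1].
    """
    if net.number_of_nodes() < 3:
        return {n: 0.0 for n in net.nodes}
    return nx.betweenness_centrality(net, normalized=True)


def centrality_table(net: nx.DiGraph) -> pd.DataFrame:
    """Per-node out-degree and betweenness with class annotations."""
    od = out_degree(net)
    bc = betweenness_centrality(net)
    return pd.DataFrame(
        {
            "node_class": {n: net.nodes[n].get("node_class", "") for n in net.nodes},
            "out_degree": od,
            "betweenness": bc,
        }
    ).rename_axis("node")


def rank_regulators(
    centralities: pd.DataFrame, node_class: str | None = None
) -> list[str]:
    """Rank nodes by out-degree, then betweenness, then name.

    ``centralities`` is the output of :func:`centrality_table`; passing
    ``node_class`` restricts ranking to that class (e.g. the lncRNAs).
    The head of the list is the nominated master regulator.
    """
    table = centralities
    if node_class is not None:
        table = table[table["node_class"] == node_class]
        if table.empty:
            raise ValueError(f"no nodes of class {node_class!r}")
    order = table.sort_index().sort_values(
        ["out_degree", "betweenness"], ascending=False, kind="stable"
    )
    return list(order.index)


def two_hop_indirect_targets(
    net: nx.DiGraph, source: str
) -> list[tuple[str, str]]:
    """Coding genes reached from ``source`` through one mediating TF.

    Returns sorted, deduplicated (coding_target, mediating_TF) pairs,
    each certified by the edges source->TF and TF->coding_target.
    """
    if source not in net:
        raise ValueError(f"source node {source!r} not in network")
    pairs = set()
    for mid in net.successors(source):
        if net.nodes[mid].get("node_class") != "TF":
            continue
        for tgt in net.successors(mid):
            if net.nodes[tgt].get("node_class") == "coding":
                pairs.add((tgt, mid))
    return sorted(pairs)


def find_mutual_edges(net: nx.DiGraph) -> list[tuple[str, str]]:
    """Unordered node pairs connected by directed edges both ways."""
    out = set()
    for u, v in net.edges:
        if net.has_edge(v, u):
            out.add(tuple(sorted((u, v))))
    return sorted(out)


def classify_cis_trans(
    regulator: str, target: str, annot: pd.DataFrame
) -> str:
    """'cis' when regulator and target share a chromosome, else 'trans'.

    ``annot`` is indexed by gene with a ``chrom`` column.
    """
    for gene in (regulator, target):
        if gene not in annot.index:
            raise KeyError(f"gene {gene!r} has no transcript annotation")
    return "cis" if annot.loc[regulator, "chrom"] == annot.loc[target, "chrom"] else "trans"


def annotate_interaction_region(
    site: tuple[int, int], annot_row: Mapping[str, int]
) -> dict:
    """Assign an mRNA interaction site to 5'UTR, CDS or 3'UTR.

    ``site`` is a 1-based inclusive (start, end) interval in transcript
    coordinates; ``annot_row`` carries utr5/cds/utr3 start/end columns.
    The region containing the site midpoint is reported, alongside the
    fraction of the site overlapping each region (boundary-spanning
    sites are common in binding predictions).
    """
    start, end = int(site[0]), int(site[1])
    if start > end:
        raise ValueError("site start must not exceed end")
    t_start = int(annot_row["utr5_start"])
    t_end = int(annot_row["utr3_end"])
    if start < t_start or end > t_end:
        raise ValueError(
            f"site {start}-{end} outside transcript bounds {t_start}-{t_end}"
        )
    regions = {
        "5'UTR": (int(annot_row["utr5_start"]), int(annot_row["utr5_end"])),
        "CDS": (int(annot_row["cds_start"]), int(annot_row["cds_end"])),
        "3'UTR": (int(annot_row["utr3_start"]), int(annot_row["utr3_end"])),
    }
    mid = (start + end) // 2
    site_len = end - start + 1
    overlap = {}
    assigned = None
    for name, (rs, re_) in regions.items():
        ov = max(0, min(end, re_) - max(start, rs) + 1)
        overlap[name] = ov / site_len
        if rs <= mid <= re_:
            assigned = name
    return {"region": assigned, "overlap": overlap, "midpoint": mid}


def build_axis_report(
    net: nx.DiGraph,
    annot: pd.DataFrame | None = None,
    interaction_sites: pd.DataFrame | None = None,
    regulator_class: str = "lncRNA",
) -> AxisReport:
    """Assemble the regulatory-axis report for the top-ranked regulator.

    Nominates the highest out-degree/betweenness node of
    ``regulator_class``, then collects its direct targets by class, its
    2-hop indirect coding targets with mediating TFs, mutual-edge
    partners, per-coding-target cis/trans calls (when ``annot`` gives
    chromosomes) and interaction-site regions (when ``interaction_sites``
    gives regulator-target site intervals with columns lncRNA, target,
    start, end).
    """
    if net.number_of_nodes() == 0:
        return AxisReport(regulator=None, no_regulator=True)
    cent = centrality_table(net)
    try:
        ranked = rank_regulators(cent, node_class=regulator_class)
    except ValueError:
        return AxisReport(regulator=None, no_regulator=True)
    reg = ranked[0]

    direct: dict[str, list[str]] = {}
    for tgt in net.successors(reg):
        cls = net.nodes[tgt].get("node_class", "unknown")
        direct.setdefault(cls, []).append(tgt)
    direct = {cls: sorted(v) for cls, v in sorted(direct.items())}

    indirect = [
        {"target": g, "via": tf} for g, tf in two_hop_indirect_targets(net, reg)
    ]
    mutual = sorted(
        v if u == reg else u for u, v in find_mutual_edges(net) if reg in (u, v)
    )

    coding_targets = sorted(
        set(direct.get("coding", []))
        | {d["target"] for d in indirect}
    )
    cis_trans: dict[str, str] = {}
    if annot is not None:
        for gene in coding_targets:
            if reg in annot.index and gene in annot.index:
                cis_trans[gene] = classify_cis_trans(reg, gene, annot)

    regions: dict[str, dict] = {}
    if interaction_sites is not None and annot is not None:
        sub = interaction_sites[interaction_sites["lncRNA"] == reg]
        for row in sub.itertuples(index=False):
            tgt = str(row.target)
            if tgt in annot.index:
                regions[tgt] = annotate_interaction_region(
                    (int(row.start), int(row.end)), annot.loc[tgt]
                )

    return AxisReport(
        regulator=reg,
        regulator_class=regulator_class,
        direct_targets=direct,
        indirect_targets=indirect,
        mutual_partners=mutual,
        cis_trans=cis_trans,
        interaction_regions=regions,
    )
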