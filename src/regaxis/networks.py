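"""Co-expression / protein-protein interaction networks and hub discovery.

Co-expression edges are thresholded gene-gene similarities computed from
the expression matrix; PPI edges are imported from SIF or 3-column TSV
edge lists with an optional confidence score (edges kept when score is
strictly above the cut, 0.400 by default — the usual medium-confidence
setting).  Hubs are selected by degree, communities by greedy modularity
maximization, and hub lists from co-expression and per-cluster PPI
networks are intersected to yield the shared "driver" genes, which can
then be counted across drugs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "HubSet",
    "CommunityPartition",
    "build_coexpression_network",
    "import_edge_list",
    "node_degrees",
    "select_hubs",
    "detect_communities",
    "intersect_hubs",
    "common_across_drugs",
]


@dataclass
class HubSet:
    """Hub nodes of one network with the selection rule that produced them."""

    hubs: list[str]
    rule: str
    lowest_degree: int
    drug: str | None = None
    provenance: str | None = None


@dataclass
class CommunityPartition:
    membership: dict[str, int]
    modularity: float
    communities: list[list[str]] = field(default_factory=list)


def build_coexpression_network(
    expr: pd.DataFrame,
    gene_subset: Sequence[str] | None = None,
    tau: float = 0.8,
    method: str = "uncentered",
    regulation: Mapping[str, str] | None = None,
) -> nx.Graph:
    """Thresholded similarity graph over genes.

    An edge joins genes g, h when |similarity(g, h)| >= tau; the signed
    similarity is stored as the edge weight.  ``method`` is 'uncentered'
    (cosine without centering) or 'pearson'.  Constant rows are excluded
    under pearson (similarity undefined).  A ``regulation`` map (gene ->
    up/down/predicted) is copied onto nodes when given.
    """
    if not 0.0 < tau <= 1.0:
        raise ValueError("tau must lie in (0, 1]")
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if gene_subset is not None:
        expr = expr.loc[[g for g in gene_subset if g in expr.index]]

    data = expr.to_numpy(dtype=float)
    genes = list(expr.index)
    if method == "pearson":
        keep = data.std(axis=1) > 0
        if not keep.all():
            import warnings

            dropped = [g for g, k in zip(genes, keep) if not k]
            warnings.warn(
                f"excluding {len(dropped)} constant gene row(s) under pearson"
            )
            data = data[keep]
            genes = [g for g, k in zip(genes, keep) if k]
        sim = np.corrcoef(data)
    elif method == "uncentered":
        norms = np.sqrt((data**2).sum(axis=1))
        if (norms == 0).any():
            raise ValueError("zero-norm gene rows: uncentered similarity undefined")
        unit = data / norms[:, None]
        sim = unit @ unit.T
    else:
        raise ValueError("method must be 'uncentered' or 'pearson'")

    g = nx.Graph(provenance="coexpression")
    g.add_nodes_from(genes)
    n = len(genes)
    iu, ju = np.triu_indices(n, k=1)
    hit = np.abs(sim[iu, ju]) >= tau
    for i, j in zip(iu[hit], ju[hit]):
        g.add_edge(genes[i], genes[j], weight=float(sim[i, j]))
    if regulation:
        for node in g.nodes:
            g.nodes[node]["regulation"] = regulation.get(node, "predicted")
    return g


def import_edge_list(path: str, min_confidence: float | None = 0.400) -> nx.Graph:
    """Read an undirected edge list from SIF or 2/3-column TSV.

    Lines are tab-split.  Three columns parse as (a, b, confidence) when
    the third field is numeric, otherwise as SIF (a, interaction, b);
    two columns are an unscored edge.  Scored edges are kept only when
    confidence is strictly greater than ``min_confidence``; unscored
    edges are kept only when ``min_confidence`` is None.  Duplicate
    edges keep the maximum confidence.
    """
    g = nx.Graph(provenance="imported")
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            conf: float | None = None
            if len(parts) == 2:
                a, b = parts
            elif len(parts) == 3:
                try:
                    conf = float(parts[2])
                    a, b = parts[0], parts[1]
                except ValueError:
                    a, _interaction, b = parts
            else:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 or 3 tab-separated fields, "
                    f"got {len(parts)}"
                )
            a, b = a.strip(), b.strip()
            if not a or not b:
                raise ValueError(f"{path}:{lineno}: empty node id")
            if a == b:
                continue
            if conf is None:
                if min_confidence is not None:
                    continue
                g.add_edge(a, b)
            else:
                if min_confidence is not None and not conf > min_confidence:
                    continue
                if g.has_edge(a, b):
                    prev = g.edges[a, b].get("confidence", float("-inf"))
                    conf = max(conf, prev)
                g.add_edge(a, b, confidence=conf, weight=conf)
    return g


def node_degrees(net: nx.Graph) -> dict[str, int]:
    """Degree (number of incident edges) per node."""
    return dict(net.degree())


def select_hubs(
    net: nx.Graph,
    min_degree: int | None = None,
    top_fraction: float | None = None,
    drug: str | None = None,
) -> HubSet:
    """Select hub nodes by an absolute degree cut or a top fraction.

    ``min_degree=k`` keeps nodes with degree >= k.  ``top_fraction=f``
    keeps the ceil(f * n) highest-degree nodes plus any node tied with
    the lowest selected degree.  Exactly one rule must be given; the
    default used by the pipeline is the top 20%.
    """
    if (min_degree is None) == (top_fraction is None):
        raise ValueError("give exactly one of min_degree or top_fraction")
    deg = node_degrees(net)
    if not deg:
        return HubSet(hubs=[], rule="empty", lowest_degree=0, drug=drug,
                      provenance=net.graph.get("provenance"))
    if min_degree is not None:
        hubs = sorted(v for v, d in deg.items() if d >= min_degree)
        rule = f"min_degree={min_degree}"
    else:
        if not 0.0 < top_fraction <= 1.0:
            raise ValueError("top_fraction must lie in (0, 1]")
        k = max(1, int(np.ceil(top_fraction * len(deg))))
        cut = sorted(deg.values(), reverse=True)[k - 1]
        hubs = sorted(v for v, d in deg.items() if d >= cut)
        rule = f"top_fraction={top_fraction}"
    lowest = min((deg[v] for v in hubs), default=0)
    return HubSet(
        hubs=hubs,
        rule=rule,
        lowest_degree=int(lowest),
        drug=drug,
        provenance=net.graph.get("provenance"),
    )


def detect_communities(net: nx.Graph) -> CommunityPartition:
    """Greedy modularity-maximization communities (deterministic).

    Communities are reported sorted by (size desc, smallest member) so
    ids are stable across runs and node-order permutations.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    if net.number_of_edges() == 0:
        comms = [{n} for n in net.nodes]
        mod = 0.0
    else:
        comms = [set(c) for c in nx.community.greedy_modularity_communities(net)]
        mod = nx.community.modularity(net, comms)
    ordered = sorted(comms, key=lambda c: (-len(c), min(c)))
    membership = {n: i for i, c in enumerate(ordered) for n in c}
    return CommunityPartition(
        membership=membership,
        modularity=float(mod),
        communities=[sorted(c) for c in ordered],
    )


def intersect_hubs(
    coexp_hubs: HubSet, ppi_hubs_by_cluster: Mapping[str, HubSet]
) -> dict[str, list[str] | None]:
    """Per-cluster common hubs between co-expression and PPI networks.

    Empty intersections are reported as None (table 'NA' convention).
    """
    coexp = set(coexp_hubs.hubs)
    out: dict[str, list[str] | None] = {}
    for cluster, hubset in ppi_hubs_by_cluster.items():
        common = sorted(coexp & set(hubset.hubs))
        out[cluster] = common if common else None
    return out


def common_across_drugs(
    per_drug_common_hubs: Mapping[str, set[str] | Sequence[str]],
) -> pd.DataFrame:
    """Count, per gene, the drugs whose common-hub set contains it.

    Input maps drug -> gene set (union over that drug's clusters).
    Output is indexed by gene with columns n_drugs and drugs, sorted by
    descending count then gene name.
    """
    if len(per_drug_common_hubs) < 2:
        raise ValueError("need common-hub sets for at least 2 drugs")
    counts: dict[str, list[str]] = {}
    for drug, genes in per_drug_common_hubs.items():
        for gene in set(genes):
            counts.setdefault(gene, []).append(drug)
    rows = {
        gene: {"n_drugs": len(drugs), "drugs": ",".join(sorted(drugs))}
        for gene, drugs in counts.items()
    }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "gene"
    return out.sort_index().sort_values("n_drugs", ascending=False, kind="stable")
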