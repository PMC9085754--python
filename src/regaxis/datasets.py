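"""Built-in worked-example data: the published MALAT1/EGR1 regulatory axis.

These small tables encode curated regulatory relationships around the
lncRNA MALAT1 and five drug-resistance driver genes (FN1, CD44, TIMP1,
SNAI2, SPARC), a well-characterized axis in the drug-resistance
literature:

* MALAT1 directly regulates the hub genes SPARC and SNAI2 and six
  transcription factors including EGR1 (out-degree 8).  Five of the six
  TF targets are not individually named in the curated data, so
  placeholder TF nodes stand in for them.
* EGR1 regulates FN1, CD44 and TIMP1, and also MALAT1 (the mutual
  EGR1<->MALAT1 feedback interaction), giving out-degree 4.
* YBX1 regulates CD44, FN1, SPARC and TIMP1 (out-degree 4); AR regulates
  CD44, FN1 and SPARC.
* MALAT1 and CD44 both reside on chromosome 11 (cis); the other drivers
  are on other chromosomes (trans).
* MALAT1 binds FN1 at the 5'UTR, TIMP1 and SNAI2 at the CDS, CD44 and
  SPARC at the 3'UTR.

Transcript coordinates and site intervals are synthetic: real transcript
lengths are irrelevant here, only the region each site falls in.  The
per-drug, per-cluster common-hub lists are reproduced as curated.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "DRIVER_GENES",
    "regulatory_axis_edges",
    "driver_transcript_annotation",
    "malat1_interaction_sites",
    "common_hub_table",
]

DRIVER_GENES = ["CD44", "FN1", "SNAI2", "SPARC", "TIMP1"]

_PLACEHOLDER_TFS = ["TFX1", "TFX2", "TFX3", "TFX4", "TFX5"]


def regulatory_axis_edges() -> pd.DataFrame:
    """Directed typed edge table of the curated MALAT1/EGR1 subnetwork."""
    edges: list[tuple[str, str, str, str]] = []
    # MALAT1 -> two hub genes + six TFs (EGR1 named; five placeholders)
    for tgt in ("SPARC", "SNAI2"):
        edges.append(("MALAT1", tgt, "lncRNA", "coding"))
    for tf in ("EGR1", *_PLACEHOLDER_TFS):
        edges.append(("MALAT1", tf, "lncRNA", "TF"))
    # EGR1 -> three hub genes, plus the feedback edge to MALAT1
    for tgt in ("FN1", "CD44", "TIMP1"):
        edges.append(("EGR1", tgt, "TF", "coding"))
    edges.append(("EGR1", "MALAT1", "TF", "lncRNA"))
    # YBX1 -> four hub genes; AR -> three
    for tgt in ("CD44", "FN1", "SPARC", "TIMP1"):
        edges.append(("YBX1", tgt, "TF", "coding"))
    for tgt in ("CD44", "FN1", "SPARC"):
        edges.append(("AR", tgt, "TF", "coding"))
    return pd.DataFrame(
        edges, columns=["source", "target", "source_class", "target_class"]
    ).assign(provenance="curated")


def driver_transcript_annotation() -> pd.DataFrame:
    """Chromosomes of MALAT1 and the driver genes, with synthetic
    transcript models placing each reported interaction site in its
    reported region (5'UTR 1-100, CDS 101-1100, 3'UTR 1101-1600)."""
    chroms = {
        "MALAT1": "chr11",
        "CD44": "chr11",
        "FN1": "chr2",
        "TIMP1": "chrX",
        "SNAI2": "chr8",
        "SPARC": "chr5",
    }
    rows = [
        {
            "gene": gene,
            "chrom": chrom,
            "utr5_start": 1,
            "utr5_end": 100,
            "cds_start": 101,
            "cds_end": 1100,
            "utr3_start": 1101,
            "utr3_end": 1600,
        }
        for gene, chrom in chroms.items()
    ]
    return pd.DataFrame(rows).set_index("gene")


def malat1_interaction_sites() -> pd.DataFrame:
    """Synthetic site intervals realizing the reported binding regions."""
    sites = [
        ("MALAT1", "FN1", 20, 60),  # 5'UTR
        ("MALAT1", "TIMP1", 400, 450),  # CDS
        ("MALAT1", "SNAI2", 700, 760),  # CDS
        ("MALAT1", "CD44", 1200, 1260),  # 3'UTR
        ("MALAT1", "SPARC", 1300, 1350),  # 3'UTR
    ]
    return pd.DataFrame(sites, columns=["lncRNA", "target", "start", "end"])


def common_hub_table() -> dict[str, dict[str, list[str]]]:
    """Curated per-drug, per-cluster common hubs between the
    co-expression and PPI networks (empty list = no common hubs)."""
    return {
        "Ponatinib": {
            "Cluster 1": [],
            "Cluster 2": ["TYR", "PMEL", "MLANA", "EDNRB"],
            "Cluster 3": [
                "FN1",
                "CD44",
                "MMP1",
                "TIMP1",
                "MMP14",
                "SPARC",
                "SNAI2",
                "VEGFC",
                "TIMP3",
            ],
        },
        "Foretinib": {"Cluster 2": ["FN1", "TIMP1", "CD44"]},
        "Selumetinib": {
            "Cluster 2": ["LCP2", "FYB", "IL7R", "CD38"],
            "Cluster 3": [
                "FN1",
                "CD44",
                "TIMP1",
                "CCND1",
                "CAV1",
                "PTGS2",
                "SNAI2",
                "LGALS1",
            ],
        },
        "Trametinib": {
            "Cluster 1": ["CD44", "CCL2", "ANXA1", "AHR"],
            "Cluster 2": ["FN1", "SPARC", "CYR61", "CTGF", "ITGB5", "LAMC1", "TGFB1"],
        },
        "CI-1040": {"Cluster 2": ["KRT7", "KRT8", "KRT19", "EPCAM"]},
    }
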