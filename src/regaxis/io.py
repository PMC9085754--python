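"""Readers and writers for the plain-text formats the pipeline exchanges.

Everything is tab-separated with a header row unless the format itself
says otherwise (GMT, SIF).  Matrices are written with the index label in
the top-left cell so round-trips are lossless.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd

from .simulate import AnnotationSet

__all__ = [
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_classes_tsv",
    "write_classes_tsv",
    "read_gmt",
    "write_gmt",
    "read_directed_edges",
    "write_directed_edges",
    "write_sif",
    "read_transcripts_tsv",
    "write_transcripts_tsv",
    "read_sites_tsv",
]


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Numeric matrix with row ids in the first column, headers in row 1.

    Floats are parsed with the round-trip parser so write/read cycles
    are lossless to the last bit.
    """
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    matrix.to_csv(path, sep="\t", index_label=index_label)


def read_classes_tsv(path: str | Path) -> dict[str, str]:
    """Two-column sample -> class table (header: sample, class)."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def write_classes_tsv(classes: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample": list(classes), "class": list(classes.values())}
    ).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> AnnotationSet:
    """Standard GMT: term <tab> description <tab> gene1 <tab> gene2 ..."""
    terms: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            term, desc, *genes = parts
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: empty term {term!r}")
            terms[term] = genes
            descriptions[term] = desc
    return AnnotationSet(terms=terms, descriptions=descriptions)


def write_gmt(annotations: AnnotationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, genes in annotations.terms.items():
            desc = annotations.descriptions.get(term, "")
            fh.write("\t".join([term, desc, *genes]) + "\n")


def read_directed_edges(path: str | Path) -> pd.DataFrame:
    """Directed typed edge table: source, target, source_class, target_class[, provenance]."""
    df = pd.read_csv(path, sep="\t")
    required = {"source", "target", "source_class", "target_class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_directed_edges(net: nx.DiGraph, path: str | Path) -> None:
    rows = []
    for u, v, data in sorted(net.edges(data=True)):
        rows.append(
            {
                "source": u,
                "target": v,
                "source_class": net.nodes[u].get("node_class", ""),
                "target_class": net.nodes[v].get("node_class", ""),
                "provenance": ";".join(data.get("provenance", []) or ["curated"]),
            }
        )
    pd.DataFrame(
        rows, columns=["source", "target", "source_class", "target_class", "provenance"]
    ).to_csv(path, sep="\t", index=False)


def write_sif(net: nx.Graph, path: str | Path, interaction: str = "pp") -> None:
    """SIF edge list: node <tab> interaction <tab> node (undirected)."""
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.edges):
            fh.write(f"{u}\t{interaction}\t{v}\n")


def read_transcripts_tsv(path: str | Path) -> pd.DataFrame:
    """Transcript models: gene, chrom, utr5/cds/utr3 start/end (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    required = {
        "chrom",
        "utr5_start",
        "utr5_end",
        "cds_start",
        "cds_end",
        "utr3_start",
        "utr3_end",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_transcripts_tsv(annot: pd.DataFrame, path: str | Path) -> None:
    annot.to_csv(path, sep="\t", index_label="gene")


def read_sites_tsv(path: str | Path) -> pd.DataFrame:
    """Interaction sites: lncRNA, target, start, end[, energy]."""
    df = pd.read_csv(path, sep="\t")
    required = {"lncRNA", "target", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df
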