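"""End-to-end orchestration: classify -> DGE -> networks -> axis -> enrichment.

One :class:`RunConfig` names every input file and threshold; `run_all`
executes the stages in analysis order, writes every intermediate table
as TSV under the output directory, and returns a machine-readable run
report.  Drugs whose selected extremes are all of one class are
excluded from differential expression with a logged reason, mirroring
the screen design this pipeline automates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import classify as _classify
from . import dge as _dge
from . import enrich as _enrich
from . import io as _io
from . import networks as _networks
from . import regnet as _regnet

__all__ = ["RunConfig", "validate_inputs", "run_all"]

log = logging.getLogger("regaxis")


@dataclass
class RunConfig:
    """Paths and thresholds for a full run.

    Optional inputs (ppi_edges, gmt, transcripts, sites) switch their
    stages on when present.
    """

    response: str
    expression: str
    regulatory_edges: str
    out_dir: str
    ppi_edges: str | None = None
    gmt: str | None = None
    transcripts: str | None = None
    sites: str | None = None
    sensitive_cut: float = -1.0
    resistant_cut: float = 1.0
    p_cut: float = 0.05
    fc_cut: float = 2.0
    min_drugs: int = 3
    tau: float = 0.8
    hub_top_fraction: float = 0.2
    ppi_min_confidence: float = 0.400
    fdr_cut: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def validate_inputs(config: RunConfig) -> list[dict]:
    """Pre-flight checks; returns severity-tagged findings (no raising)."""
    findings: list[dict] = []

    def finding(severity: str, message: str) -> None:
        findings.append({"severity": severity, "message": message})

    required = {"response": config.response, "expression": config.expression,
                "regulatory_edges": config.regulatory_edges}
    for name, path in required.items():
        if not Path(path).is_file():
            finding("error", f"{name} file not found: {path}")
    for name in ("ppi_edges", "gmt", "transcripts", "sites"):
        path = getattr(config, name)
        if path is not None and not Path(path).is_file():
            finding("error", f"{name} file not found: {path}")
    if any(f["severity"] == "error" for f in findings):
        return findings

    response = _io.read_matrix_tsv(config.response)
    expr = _io.read_matrix_tsv(config.expression)
    if response.index.duplicated().any():
        finding("warning", "duplicated cell-line ids in response table")
    if expr.index.duplicated().any():
        finding("warning", "duplicated gene rows in expression matrix")
    shared = set(response.index) & set(expr.columns)
    if not shared:
        finding(
            "error",
            "no cell line in the response table matches an expression column",
        )

    if config.sites and config.transcripts:
        annot = _io.read_transcripts_tsv(config.transcripts)
        sites = _io.read_sites_tsv(config.sites)
        for row in sites.itertuples(index=False):
            tgt = str(row.target)
            if tgt not in annot.index:
                finding("error", f"site target {tgt} missing from transcripts")
            elif not (
                int(annot.loc[tgt, "utr5_start"])
                <= int(row.start)
                <= int(row.end)
                <= int(annot.loc[tgt, "utr3_end"])
            ):
                finding(
                    "error",
                    f"site {row.start}-{row.end} outside transcript of {tgt}",
                )
    return findings


def run_all(config: RunConfig) -> dict:
    """Execute the full chain and write all outputs under ``out_dir``."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    findings = validate_inputs(config)
    errors = [f for f in findings if f["severity"] == "error"]
    if errors:
        raise ValueError("input validation failed: " + "; ".join(
            f["message"] for f in errors
        ))

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(config), "findings": findings, "stages": {}}

    # stage 1: response classification and extreme-responder selection
    response = _io.read_matrix_tsv(config.response)
    cls = _classify.select_extremes(
        response, config.sensitive_cut, config.resistant_cut
    )
    cls.table.to_csv(out / "classification.tsv", sep="\t", index=False)
    cls.per_drug.to_csv(out / "classification_per_drug.tsv", sep="\t")
    analyzable = cls.analyzable_drugs()
    excluded = [d for d in response.columns if d not in analyzable]
    for drug in excluded:
        log.info("excluding drug %s: single-class extreme selection", drug)
    report["stages"]["classification"] = {
        "n_drugs_in": int(response.shape[1]),
        "n_drugs_analyzed": len(analyzable),
        "n_drugs_excluded": len(excluded),
        "excluded_drugs": excluded,
    }

    if response.shape[0] >= 2 and response.shape[1] >= 2:
        _z, row_order = _classify.hierarchical_cluster(response, axis="rows")
        _z, col_order = _classify.hierarchical_cluster(response, axis="cols")
        _classify.export_heatmap_table(
            response, row_order, col_order, str(out / "response_heatmap.tsv")
        )

    # stage 2: per-drug differential expression
    expr = _io.read_matrix_tsv(config.expression)
    deg_tables: dict[str, pd.DataFrame] = {}
    for drug in analyzable:
        classes = {
            s: c for s, c in cls.selected_samples(drug).items() if s in expr.columns
        }
        n_res = sum(c == "resistant" for c in classes.values())
        n_sens = sum(c == "sensitive" for c in classes.values())
        if n_res < 2 or n_sens < 2:
            log.info("excluding drug %s: <2 samples in a class", drug)
            report["stages"]["classification"]["excluded_drugs"].append(drug)
            continue
        table = _dge.run_dge(
            expr, classes, p_cut=config.p_cut, fc_cut=config.fc_cut
        )
        deg_tables[drug] = table
        table.to_csv(out / f"deg_{drug}.tsv", sep="\t", index_label="gene")
    report["stages"]["dge"] = {
        drug: {"n_genes": int(t.shape[0]), "n_pass": int(t["pass"].sum())}
        for drug, t in deg_tables.items()
    }

    # stage 3: cross-drug DEG intersection
    intersection = (
        _dge.cross_drug_intersection(deg_tables, min_drugs=config.min_drugs)
        if deg_tables
        else pd.DataFrame(columns=["n_drugs", "drugs"])
    )
    intersection.to_csv(out / "deg_intersection.tsv", sep="\t", index_label="gene")
    report["stages"]["intersection"] = {"n_genes": int(intersection.shape[0])}

    # stage 4: per-drug co-expression network, hubs, communities; optional
    # PPI import and per-cluster hub intersection
    ppi_net = (
        _networks.import_edge_list(config.ppi_edges, config.ppi_min_confidence)
        if config.ppi_edges
        else None
    )
    per_drug_common: dict[str, set] = {}
    net_report: dict[str, dict] = {}
    for drug, table in deg_tables.items():
        pass_genes = list(table.index[table["pass"]])
        if len(pass_genes) < 2:
            continue
        regulation = dict(zip(table.index, table["direction"]))
        net = _networks.build_coexpression_network(
            expr, gene_subset=pass_genes, tau=config.tau, regulation=regulation
        )
        hubs = _networks.select_hubs(
            net, top_fraction=config.hub_top_fraction, drug=drug
        )
        partition = _networks.detect_communities(net)
        pd.DataFrame(
            {"gene": list(partition.membership),
             "community": list(partition.membership.values())}
        ).to_csv(out / f"communities_{drug}.tsv", sep="\t", index=False)
        deg_map = _networks.node_degrees(net)
        pd.DataFrame(
            {
                "gene": list(deg_map),
                "degree": list(deg_map.values()),
                "is_hub": [g in set(hubs.hubs) for g in deg_map],
            }
        ).to_csv(out / f"hubs_{drug}.tsv", sep="\t", index=False)
        net_report[drug] = {
            "n_nodes": net.number_of_nodes(),
            "n_edges": net.number_of_edges(),
            "n_hubs": len(hubs.hubs),
            "lowest_hub_degree": hubs.lowest_degree,
            "n_communities": len(partition.communities),
            "modularity": partition.modularity,
        }
        if ppi_net is not None:
            ppi_hubs_by_cluster = {}
            for cid, members in enumerate(partition.communities):
                sub = ppi_net.subgraph([g for g in members if g in ppi_net])
                if sub.number_of_nodes() == 0:
                    continue
                ppi_hubs_by_cluster[f"cluster_{cid}"] = _networks.select_hubs(
                    sub, top_fraction=config.hub_top_fraction, drug=drug
                )
            common = _networks.intersect_hubs(hubs, ppi_hubs_by_cluster)
            per_drug_common[drug] = set().union(
                *(set(v) for v in common.values() if v), set()
            )
    report["stages"]["networks"] = net_report

    if len(per_drug_common) >= 2:
        common_table = _networks.common_across_drugs(per_drug_common)
        common_table.to_csv(out / "common_hubs.tsv", sep="\t", index_label="gene")
        report["stages"]["common_hubs"] = {"n_genes": int(common_table.shape[0])}

    # stage 5: directed regulatory network and axis report
    edges = _io.read_directed_edges(config.regulatory_edges)
    regnet = _regnet.merge_networks([edges])
    cent = _regnet.centrality_table(regnet)
    cent.to_csv(out / "centralities.tsv", sep="\t")
    annot = (
        _io.read_transcripts_tsv(config.transcripts) if config.transcripts else None
    )
    sites = _io.read_sites_tsv(config.sites) if config.sites else None
    axis = _regnet.build_axis_report(regnet, annot=annot, interaction_sites=sites)
    with open(out / "axis_report.json", "w") as fh:
        json.dump(axis.to_dict(), fh, indent=2, sort_keys=True)
    report["stages"]["regulatory"] = {
        "n_nodes": regnet.number_of_nodes(),
        "n_edges": regnet.number_of_edges(),
        "regulator": axis.regulator,
    }
    report["axis_report"] = axis.to_dict()

    # stage 6: enrichment of the cross-drug intersection genes
    if config.gmt and not intersection.empty:
        annotations = _io.read_gmt(config.gmt)
        try:
            enr = _enrich.enrich(
                list(intersection.index), annotations, fdr_cut=config.fdr_cut
            )
        except ValueError as exc:
            log.warning("enrichment skipped: %s", exc)
        else:
            enr.to_csv(out / "enrichment.tsv", sep="\t")
            report["stages"]["enrichment"] = {
                "n_terms": int(enr.shape[0]),
                "n_significant": int(enr["significant"].sum()),
            }

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
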