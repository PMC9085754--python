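"""Synthetic pharmacogenomic data generator.

Produces every input the analysis chain consumes — a cell-line x drug
LN_IC50 response matrix with a bimodal sensitive/resistant structure, a
gene x sample log2 expression matrix with a planted differentially
expressed gene subset, a tripartite directed lncRNA-TF-coding regulatory
network with a planted high-out-degree regulator, GMT annotation sets
with an optionally planted enriched term, and transcript structure
tables — together with the ground-truth audit trail (true response
labels, planted gene list, planted regulator) needed for recovery tests.

All randomness flows through a single ``numpy.random.Generator`` seeded
from ``SimulationConfig.rng_seed``; identical config + seed gives
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "AnnotationSet",
    "simulate_drug_response",
    "simulate_expression",
    "simulate_regulatory_network",
    "simulate_annotations",
    "simulate_transcript_annotation",
]


@dataclass
class SimulationConfig:
    """Knobs for the synthetic study.

    Defaults mirror the shape of the real screen the generator stands in
    for: 41 cell lines responsive to 10 drugs, a resistant/sensitive
    LN_IC50 separation of +2/-2 (log units), RMA-like log2 expression
    around a baseline of 7, and a 48 lncRNA / 38 TF / 5 coding-gene
    tripartite regulatory network whose planted master regulator has
    out-degree 8 against a background capped at 3.
    """

    n_cell_lines: int = 41
    n_drugs: int = 10
    frac_resistant_per_drug: float = 0.5
    ic50_resistant_mean: float = 2.0
    ic50_sensitive_mean: float = -2.0
    ic50_sd: float = 0.5
    n_genes: int = 1000
    n_de_genes: int = 50
    de_effect_log2: float = 3.0
    expr_baseline_mean: float = 7.0
    expr_noise_sd: float = 0.5
    n_lncRNA: int = 48
    n_TF: int = 38
    n_coding: int = 5
    planted_regulator_outdegree: int = 8
    background_max_outdegree: int = 3
    plant_feedback_loop: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cell_lines <= 0:
            raise ValueError("n_cell_lines must be positive")
        if self.n_drugs <= 0:
            raise ValueError("n_drugs must be positive")
        if not 0.0 < self.frac_resistant_per_drug < 1.0:
            raise ValueError("frac_resistant_per_drug must lie in (0, 1)")
        if self.ic50_sd < 0 or self.expr_noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_de_genes < 0 or self.n_de_genes > self.n_genes:
            raise ValueError("n_de_genes must lie in [0, n_genes]")
        if min(self.n_lncRNA, self.n_TF, self.n_coding) <= 0:
            raise ValueError("node class sizes must be positive")
        if self.planted_regulator_outdegree > self.n_TF + self.n_coding:
            raise ValueError(
                "planted_regulator_outdegree exceeds available targets"
            )
        if self.background_max_outdegree >= self.planted_regulator_outdegree:
            raise ValueError(
                "background_max_outdegree must be below planted_regulator_outdegree"
            )

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


@dataclass
class AnnotationSet:
    """Term -> gene-set map with a background universe (GMT-serializable)."""

    terms: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.universe:
            seen: dict[str, None] = {}
            for genes in self.terms.values():
                for g in genes:
                    seen[g] = None
            self.universe = list(seen)


def simulate_drug_response(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a cell-line x drug LN_IC50 matrix with known class labels.

    Per drug, exactly ``round(n_cell_lines * frac_resistant_per_drug)``
    cell lines are resistant, drawn from
    ``Normal(ic50_resistant_mean, ic50_sd)``; the remainder are
    sensitive, drawn from ``Normal(ic50_sensitive_mean, ic50_sd)``.

    Returns ``(values, labels)``: the LN_IC50 matrix and a same-shaped
    matrix of true class labels ('resistant'/'sensitive').
    """
    rng = config.rng()
    cell_lines = [f"CL{i + 1:03d}" for i in range(config.n_cell_lines)]
    drugs = [f"DRUG{j + 1:02d}" for j in range(config.n_drugs)]
    n_res = int(round(config.n_cell_lines * config.frac_resistant_per_drug))

    values = np.empty((config.n_cell_lines, config.n_drugs))
    labels = np.empty((config.n_cell_lines, config.n_drugs), dtype=object)
    for j in range(config.n_drugs):
        resistant_idx = rng.choice(config.n_cell_lines, size=n_res, replace=False)
        is_res = np.zeros(config.n_cell_lines, dtype=bool)
        is_res[resistant_idx] = True
        col = np.where(
            is_res,
            rng.normal(config.ic50_resistant_mean, config.ic50_sd, config.n_cell_lines),
            rng.normal(config.ic50_sensitive_mean, config.ic50_sd, config.n_cell_lines),
        )
        values[:, j] = col
        labels[:, j] = np.where(is_res, "resistant", "sensitive")

    values_df = pd.DataFrame(values, index=cell_lines, columns=drugs)
    labels_df = pd.DataFrame(labels, index=cell_lines, columns=drugs)
    return values_df, labels_df


def simulate_expression(
    config: SimulationConfig,
    class_labels: Mapping[str, str],
) -> tuple[pd.DataFrame, list[str]]:
    """Draw a gene x sample log2 expression matrix with planted DE genes.

    Background genes are ``Normal(expr_baseline_mean, expr_noise_sd)``
    everywhere.  The first half of the planted set is shifted by
    ``+de_effect_log2`` and the second half by ``-de_effect_log2`` in
    resistant samples only, so both volcano tails are exercised.

    ``class_labels`` maps sample id -> 'sensitive' | 'resistant' and
    defines the column order.  Returns ``(matrix, planted_genes)``.
    """
    if not class_labels:
        raise ValueError("class_labels must name at least one sample")
    bad = {c for c in class_labels.values()} - {"sensitive", "resistant"}
    if bad:
        raise ValueError(f"unknown class labels: {sorted(bad)}")

    rng = config.rng()
    samples = list(class_labels)
    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    planted_idx = rng.choice(config.n_genes, size=config.n_de_genes, replace=False)
    planted_idx.sort()

    values = rng.normal(
        config.expr_baseline_mean,
        config.expr_noise_sd,
        size=(config.n_genes, len(samples)),
    )
    resistant_cols = np.array(
        [class_labels[s] == "resistant" for s in samples], dtype=bool
    )
    half = config.n_de_genes // 2
    up = planted_idx[:half] if half else planted_idx[:0]
    down = planted_idx[half:]
    values[np.ix_(up, np.flatnonzero(resistant_cols))] += config.de_effect_log2
    values[np.ix_(down, np.flatnonzero(resistant_cols))] -= config.de_effect_log2

    matrix = pd.DataFrame(values, index=genes, columns=samples)
    planted = [genes[i] for i in planted_idx]
    return matrix, planted


def simulate_regulatory_network(
    config: SimulationConfig,
) -> tuple[nx.DiGraph, str]:
    """Build a tripartite lncRNA -> TF -> coding regulatory network.

    One lncRNA (the planted master regulator) receives out-degree
    ``planted_regulator_outdegree`` with at least one TF target; every
    other source node gets a random out-degree of at most
    ``background_max_outdegree``.  Edge directions are restricted to
    lncRNA->{TF, coding} and TF->{coding, lncRNA}; coding genes are
    sinks.  If ``plant_feedback_loop`` is set, one TF target of the
    planted regulator carries an edge back to it, forming the single
    mutual pair in the graph.

    Returns ``(graph, planted_regulator)``.  Node attribute
    ``node_class`` is one of lncRNA/TF/coding.
    """
    rng = config.rng()
    lnc = [f"LNC{i + 1:03d}" for i in range(config.n_lncRNA)]
    tfs = [f"TF{i + 1:03d}" for i in range(config.n_TF)]
    coding = [f"CG{i + 1:03d}" for i in range(config.n_coding)]

    g = nx.DiGraph()
    for n in lnc:
        g.add_node(n, node_class="lncRNA")
    for n in tfs:
        g.add_node(n, node_class="TF")
    for n in coding:
        g.add_node(n, node_class="coding")

    planted = lnc[0]
    targets_pool = tfs + coding
    k = config.planted_regulator_outdegree
    # force >=1 TF target, then fill from the remaining pool
    first_tf = tfs[int(rng.integers(len(tfs)))]
    rest_pool = [t for t in targets_pool if t != first_tf]
    rest = rng.choice(len(rest_pool), size=k - 1, replace=False)
    planted_targets = [first_tf] + [rest_pool[i] for i in rest]
    for t in planted_targets:
        g.add_edge(planted, t)

    for src in lnc[1:] + tfs:
        pool = targets_pool if src in lnc else coding + lnc
        pool = [t for t in pool if t != src]
        d = int(rng.integers(0, config.background_max_outdegree + 1))
        if d:
            chosen = rng.choice(len(pool), size=min(d, len(pool)), replace=False)
            for i in chosen:
                # keep the planted regulator the unique out-degree maximum
                if g.out_degree(src) >= config.background_max_outdegree:
                    break
                # avoid accidental mutual pairs; the only one allowed is planted
                if g.has_edge(pool[i], src):
                    continue
                g.add_edge(src, pool[i])

    # background edges into the planted regulator would create extra
    # mutual pairs; strip any that arose by chance
    for u in list(g.predecessors(planted)):
        g.remove_edge(u, planted)

    if config.plant_feedback_loop:
        tf_targets = [t for t in planted_targets if t in tfs]
        g.add_edge(tf_targets[0], planted)

    return g, planted


def simulate_annotations(
    genes: Sequence[str],
    n_terms: int,
    term_size_range: tuple[int, int] = (10, 30),
    enriched_term: Sequence[str] | None = None,
    rng_seed: int = 0,
) -> AnnotationSet:
    """Random GMT-style annotation terms over a gene universe.

    If ``enriched_term`` is given, an extra term containing exactly that
    gene set plus random padding (up to the upper size bound) is planted
    as ``PLANTED``.
    """
    if not genes:
        raise ValueError("gene universe is empty")
    lo, hi = term_size_range
    if lo > hi or lo < 1 or hi > len(genes):
        raise ValueError("term_size_range inconsistent with universe size")

    rng = np.random.default_rng(rng_seed)
    genes = list(genes)
    terms: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for i in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        idx = rng.choice(len(genes), size=size, replace=False)
        name = f"TERM{i + 1:04d}"
        terms[name] = sorted(genes[j] for j in idx)
        descriptions[name] = f"random term {i + 1}"

    if enriched_term is not None:
        planted = list(dict.fromkeys(enriched_term))
        missing = set(planted) - set(genes)
        if missing:
            raise ValueError(f"planted genes outside universe: {sorted(missing)}")
        pad_pool = [g for g in genes if g not in set(planted)]
        n_pad = max(0, min(hi - len(planted), len(pad_pool)))
        if n_pad:
            idx = rng.choice(len(pad_pool), size=n_pad, replace=False)
            planted = planted + [pad_pool[j] for j in idx]
        terms["PLANTED"] = sorted(planted)
        descriptions["PLANTED"] = "planted enriched term"

    return AnnotationSet(terms=terms, descriptions=descriptions, universe=genes)


def simulate_transcript_annotation(
    genes: Sequence[str],
    n_chromosomes: int = 22,
    regulator_chromosome: str = "chr11",
    co_located_genes: Sequence[str] = (),
    rng_seed: int = 0,
    utr5_len_range: tuple[int, int] = (50, 200),
    cds_len_range: tuple[int, int] = (300, 2000),
    utr3_len_range: tuple[int, int] = (100, 800),
) -> pd.DataFrame:
    """Assign each gene a chromosome and a contiguous transcript model.

    ``co_located_genes`` are forced onto ``regulator_chromosome``; all
    other genes are placed on a different chromosome, so that a cis call
    (same chromosome as the regulator) holds exactly for the co-located
    set.  Transcript coordinates are 1-based inclusive with
    ``utr5.end + 1 == cds.start`` and ``cds.end + 1 == utr3.start``.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("gene list is empty")
    co = set(co_located_genes)
    missing = co - set(genes)
    if missing:
        raise ValueError(f"co_located_genes not in gene list: {sorted(missing)}")

    rng = np.random.default_rng(rng_seed)
    chroms = [f"chr{i + 1}" for i in range(n_chromosomes)]
    others = [c for c in chroms if c != regulator_chromosome] or ["chrX"]

    rows = []
    for gene in genes:
        if gene in co:
            chrom = regulator_chromosome
        else:
            chrom = others[int(rng.integers(len(others)))]
        u5 = int(rng.integers(*utr5_len_range))
        cds = int(rng.integers(*cds_len_range))
        u3 = int(rng.integers(*utr3_len_range))
        rows.append(
            {
                "gene": gene,
                "chrom": chrom,
                "utr5_start": 1,
                "utr5_end": u5,
                "cds_start": u5 + 1,
                "cds_end": u5 + cds,
                "utr3_start": u5 + cds + 1,
                "utr3_end": u5 + cds + u3,
            }
        )
    return pd.DataFrame(rows).set_index("gene")
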