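# Methods

## Response classification

LN_IC50 is a log-normalized half-maximal inhibitory concentration:
values above 0 mark resistance, below 0 sensitivity. `classify_response`
applies strict inequalities, so an exact 0 (and any missing value) is
*unclassified* — we prefer an explicit third state to an arbitrary side
assignment. `select_extremes` keeps entries outside the
(sensitive_cut, resistant_cut) band, default (−1, +1) in LN_IC50 units.
A drug whose selected extremes are all one class is flagged
`single_class`; downstream differential expression refuses such drugs
because no between-class contrast exists. Missing response entries are
excluded from classification and, pairwise, from clustering distances
(screen matrices are sparse in practice).

Heatmap clustering uses the uncentered correlation
s(x, y) = Σxy/√(Σx²·Σy²) — cosine similarity without mean-centering,
the convention of classic expression-heatmap tools — with dissimilarity
d = 1 − s and average linkage (UPGMA, via `scipy.cluster.hierarchy`).
Scipy leaves leaf orientation unspecified, so we impose our own rule:
at each merge the subtree containing the smaller original index goes
left. This makes exported heatmap tables reproducible byte-for-byte.

## Differential expression

Welch's unequal-variance t-test, two-sided, with Welch–Satterthwaite
degrees of freedom; the implementation delegates to
`scipy.stats.ttest_ind(equal_var=False)` for single contrasts and to a
vectorized formula evaluation over the whole matrix in `run_dge` (the
test suite checks both against a hand evaluation of the formulas to
1e-10). Fold change is the difference of log2 means (resistant −
sensitive), appropriate for RMA-style log2 expression values; the
double filtration is p < p_cut **and** |log2FC| > fc_cut, applied
two-sided because both up- and down-regulated genes matter.

Degenerate genes: zero variance in both groups with equal means is
reported as t = 0, p = 1 (no evidence, no NaNs); zero variance with
differing means gets p = the smallest positive float — on the observed
data the separation is infinite, and clamping keeps the p ∈ (0, 1]
contract. Multiple-testing correction (Benjamini–Hochberg) is available
behind a flag but off by default: the filtration this pipeline mirrors
operates on raw p-values, and we keep fidelity first.

`cross_drug_intersection` counts, per gene, the drugs whose DEG table
marks it as passing, keeping genes at or above `min_drugs` (default 3).

## Networks and hubs

Co-expression edges connect gene pairs whose similarity magnitude
reaches τ (default 0.8), with the signed similarity kept as the edge
weight. Two similarity choices are exposed: uncentered correlation and
Pearson. Note that uncentered similarity on raw log2 data with a large
common baseline is dominated by the mean and tends toward 1; it is most
informative on centered or factor-driven data, which is how the tests
exercise it. Constant rows are excluded under Pearson with a warning.
Edge-list import (SIF or 2/3-column TSV) retains scored edges only when
confidence is **strictly** above the cut (default 0.400, the
medium-confidence convention); duplicate edges keep the maximum
confidence — conservative retention.

Hub selection exposes both an absolute degree cut and a top-fraction
rule (ties at the cut all included); published hub tables follow no
single stated formula, so the pipeline defaults to the top 20% rather
than inventing one. Community detection uses greedy modularity
maximization (`networkx`), a stand-in from the same objective family as
the modularity-based cluster tools common in network GUIs; communities
are re-indexed by (size, smallest member) so ids are deterministic.
Per-cluster PPI hub lists are intersected with the co-expression hub
list; empty intersections are reported as NA. Per-drug common-hub sets
are unioned over clusters before cross-drug counting.

## Regulatory network and the axis report

Node classes are lncRNA, TF, coding; permitted regulation runs
lncRNA → {TF, coding} and TF → {coding, lncRNA}, so coding genes are
sinks. `merge_networks` unions edge tables, collapses parallel edges
while accumulating provenance tags, and rejects class conflicts.

Ranking is by out-degree first, betweenness second, name third.
Betweenness is directed shortest-path betweenness on unweighted edges
(the curated networks carry no weights), normalized by (n−1)(n−2) so
values lie in [0, 1]; `networkx.betweenness_centrality` computes it and
an exhaustive path-enumeration oracle verifies it in the tests.

Indirect regulation is exactly 2-hop: source → TF → coding, reported as
(target, mediator) pairs each certified by its two edges. Mutual edges
(u→v and v→u) are the feedback-loop candidates; a 3-cycle is not a
mutual pair. Cis vs trans is shared chromosome, symmetric by
construction. Interaction sites (1-based inclusive transcript
coordinates) are assigned to the region containing the site midpoint,
with per-region overlap fractions also reported for boundary-spanning
sites — published annotations give one region per site without stating
a boundary rule, so the midpoint is our explicit, reproducible choice.

The built-in worked example (`regaxis.datasets`) encodes the curated
MALAT1/EGR1 axis. Five of MALAT1's six TF targets are not individually
named in the curated data and appear as placeholder nodes; EGR1's
out-degree of 4 comprises its three hub-gene targets plus the feedback
edge to MALAT1. Transcript coordinates there are synthetic — only the
chromosome assignments and the region each site falls in are real
claims.

## Enrichment

Upper-tail hypergeometric P[X ≥ k] for a k-gene overlap between an
n-gene query and a K-gene term in an N-gene universe (equivalently
one-sided Fisher's exact on the 2×2 table; the tests assert the
equivalence). The universe defaults to the union of all term genes;
query genes outside the universe are dropped with a recorded count to
avoid silent inflation. BH correction runs across the tested terms;
only over-representation is scored.

## Synthetic data

The generator emulates the shapes of a real screen: 41 cell lines × 10
drugs, LN_IC50 means ±2 with sd 0.5 (a z > 4 class separation), log2
expression baseline 7 with sd 0.5, 50 planted DE genes at effect 3
(split 50/50 up/down in resistant samples), and a 48/38/5
lncRNA/TF/coding regulatory network whose planted regulator has
out-degree 8 against a background capped at 3, plus one planted
feedback loop. Per-drug resistant counts are exact —
round(n·fraction) — not binomial draws, so class balance is a testable
invariant. One `numpy.random.Generator` per config seed feeds all
draws in documented order; identical config + seed is byte-identical
output (TSV readers use round-trip float parsing to keep this true
across write/read cycles).

What the generator does **not** emulate: dose–response curve shapes,
tissue-of-origin structure, expression correlation beyond the planted
factors, mutation/copy-number covariates, and realistic network degree
distributions. Passing recovery tests therefore demonstrate the
correctness and calibration of the chain under its stated model, not
performance on real screens.

## Problem sizes and numerical choices

The calibration studies run at 10,000 genes (type-I error), 1,000 genes
with 50 planted DEGs (recovery), 50 network seeds (regulator
nomination), and 2×20-node planted partitions (community recovery) —
sizes at which the Monte-Carlo error of each estimate is well below the
acceptance margins while the full study runs in seconds. Ties anywhere
(ranking, hub cuts, leaf order, community ids) break deterministically
as described above; degenerate inputs (zero-variance genes, empty
networks, disjoint queries) produce either a defined convention or an
explicit error, never NaNs.

## Pipeline

`run_all` executes classify → DGE → intersection → networks → axis →
enrichment from one config, writes every intermediate table as TSV plus
the axis report and run report as JSON, and accounts for every drug:
n_in = n_analyzed + n_excluded with logged reasons. Stage outputs are
pure functions of (inputs, config, seed). The CLI is a thin wrapper
over the same functions.
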