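"""Hypergeometric over-representation of a gene list against GMT terms,
with a planted enriched term that should rank first."""

import regaxis as rx

genes = [f"G{i:03d}" for i in range(300)]
query = genes[:20]
ann = rx.simulate_annotations(
    genes, n_terms=25, term_size_range=(10, 40), enriched_term=query, rng_seed=3
)

result = rx.enrich(query, ann, fdr_cut=0.05)
top = result.iloc[0]
print(result[["k", "K", "n", "N", "p", "fdr", "significant"]].head(5).to_string())
print(f"top term: {result.index[0]} with overlap {top['k']}/{top['K']} "
      f"and p = {top['p']:.3g}")
print("the planted term contains the whole query, so its upper-tail "
      "hypergeometric p is the smallest by construction")
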