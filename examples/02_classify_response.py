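"""Classify cell lines as drug-sensitive/resistant from LN_IC50 values
and select extreme responders outside the +/-1 band."""

import pandas as pd

import regaxis as rx

cfg = rx.SimulationConfig(rng_seed=1)
values, truth = rx.simulate_drug_response(cfg)

cls = rx.select_extremes(values, sensitive_cut=-1.0, resistant_cut=1.0)
drug = values.columns[0]
row = cls.per_drug.loc[drug]
print(f"{drug}: {row['n_selected_sensitive']} extreme sensitives, "
      f"{row['n_selected_resistant']} extreme resistants, "
      f"single-class = {row['single_class']}")
print(f"analyzable drugs (both classes present): {len(cls.analyzable_drugs())}"
      f" of {values.shape[1]}")

predicted = values.map(rx.classify_response)
accuracy = (predicted.values == truth.values).mean()
print(f"sign-rule accuracy vs simulation truth: {accuracy:.1%} "
      "(LN_IC50 > 0 means resistant, < 0 sensitive)")

_z, col_order = rx.hierarchical_cluster(values, axis="cols")
print(f"heatmap column order after UPGMA on 1 - uncentered correlation, "
      f"first five: {col_order[:5]}")
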