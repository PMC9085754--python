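"""Generate a synthetic study bundle: drug-response matrix, expression
matrix with planted differentially expressed genes, and a regulatory
network with a planted master regulator."""

import regaxis as rx

cfg = rx.SimulationConfig(rng_seed=1)

values, labels = rx.simulate_drug_response(cfg)
print(f"response matrix: {values.shape[0]} cell lines x {values.shape[1]} drugs")
print(f"resistant per drug: {(labels == 'resistant').sum(axis=0).iloc[0]} "
      "(exactly round(n * fraction), by construction)")

classes = dict(zip(labels.index, labels.iloc[:, 0]))
expr, planted = rx.simulate_expression(cfg, classes)
print(f"expression matrix: {expr.shape[0]} genes x {expr.shape[1]} samples, "
      f"{len(planted)} planted DE genes at effect {cfg.de_effect_log2} log2 units")

net, regulator = rx.simulate_regulatory_network(cfg)
print(f"regulatory network: {net.number_of_nodes()} nodes, "
      f"{net.number_of_edges()} edges; planted regulator {regulator} "
      f"with out-degree {net.out_degree(regulator)}")
print("the planted structures are the ground truth every downstream "
      "stage is checked against")
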