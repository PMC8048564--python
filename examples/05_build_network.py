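"""The full pipeline: assemble the three-layer hierarchical network.

Layer 2 holds evidence-supported direct targets of the root regulator;
each TF among them is then screened against the remaining DEG pool to
produce layer 3 (purely statistical edges — binding data exist only for
the root).
"""

from mlhgrn import RunConfig
from mlhgrn.dap import prepare_dap_evidence
from mlhgrn.io import write_network
from mlhgrn.network import build_ml_hgrn
from mlhgrn.simulate import simulate_expression, simulate_genome_and_peaks, simulate_network_truth

truth = simulate_network_truth(20, 0.25, 50, 200, seed=1)
matrix = simulate_expression(truth, samples_per_group=25)
seqs, genes, (rep1, rep2), degs, _ = simulate_genome_and_peaks(truth)

cfg = RunConfig(seed=1)
evidence = prepare_dap_evidence(seqs, genes, rep1, rep2, cfg)
net = build_ml_hgrn(matrix, truth.regulator_id, degs, evidence, cfg, gene_models=genes)

print(f"layers: {[len(l) for l in net.layers]} (root, direct targets, layer 3)")
print(f"edges: {len(net.edges)}")

pred = {(e.regulator_id, e.target_id) for e in net.edges if e.target_layer == 3}
true_e = set(truth.layer3_edges)
tp = len(pred & true_e)
p, r = tp / len(pred), tp / len(true_e)
print(f"layer-3 edge recovery: precision {p:.2f}, recall {r:.2f}, "
      f"F1 {2 * p * r / (p + r):.2f}")

paths = write_network(net, "scratch/example_network")
print("wrote:", ", ".join(str(v) for v in paths.values()))
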