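"""Generate a synthetic regulator-perturbation dataset with planted truth.

Builds the standard benchmark — a hub regulator dosed across WT/low/medium/
high sample groups, 20 direct targets (5 of them TFs), 50 second-tier
targets and 200 decoys — and writes every file the pipeline consumes.
"""

from pathlib import Path

from mlhgrn.simulate import simulate_dataset

outdir = Path("scratch/example_data")
truth = simulate_dataset(outdir, seed=1)

print(f"dataset written to {outdir}/")
print(f"regulator: {truth.regulator_id}")
print(f"direct targets: {len(truth.layer2_ids)} (TFs: {len(truth.layer2_tfs)})")
print(f"layer-3 targets: {len(truth.layer3_ids)}, planted edges: {len(truth.layer3_edges)}")
print(f"decoys: {len(truth.decoy_genes)}")
# The planted effect sizes and wiring are in truth.tsv; the pipeline never
# sees them — they exist to score recovery.
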