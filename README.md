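# mlhgrn

Inference of a **multilayered hierarchical gene regulatory network (ML-hGRN)**
rooted at a single transcription factor, from a dose-graded overexpression
experiment plus in-vitro binding data.

The package targets the common design in plant functional genomics where a
candidate master regulator (for example a growth-regulating factor, GRF) is
overexpressed at several strengths (WT < low < medium < high lines),
RNA-seq yields a differential-expression gene (DEG) list, and DAP-seq gives
genome-wide binding peaks for the same protein. From these it reconstructs
who the regulator controls directly (layer 2), which of those direct targets
are themselves TFs, and what those TFs control in turn (layer 3).

## Method

The core is a two-step **top-down graphical Gaussian model** applied
recursively:

1. **Responsiveness screen.** Each DEG *g* is median-discretized against the
   regulator *z* across all samples and tested with Fisher's exact test on
   the 2×2 joint-state table (low stringency, *P* < 0.15) together with a
   folded binomial concordance probability, *P*(X ≥ k), k =
   max(#matches, #mismatches), X ~ Bin(n, ½). Both must pass.
2. **Interference testing.** For every pair (*x*, *y*) of responsive genes,
   the statistic *d* = r<sub>xy</sub> − r<sub>xy|z</sub> measures how much of
   their co-expression the regulator explains, where
   r<sub>xy|z</sub> = (r<sub>xy</sub> − r<sub>xz</sub>r<sub>yz</sub>) /
   √((1−r<sub>xz</sub>²)(1−r<sub>yz</sub>²)). Its standard error comes from
   the first-order multivariate delta method combined with the asymptotic
   covariance of correlated sample correlations
   (n·Var(r<sub>ab</sub>) = (1−r<sub>ab</sub>²)²,
   n·Cov(r<sub>ab</sub>, r<sub>ac</sub>) = r<sub>bc</sub>(1−r<sub>ab</sub>²−r<sub>ac</sub>²)
   − ½ r<sub>ab</sub>r<sub>ac</sub>(1−r<sub>ab</sub>²−r<sub>ac</sub>²−r<sub>bc</sub>²)),
   with Benjamini–Hochberg adjustment across each scan. Each gene's
   **interference frequency** is the fraction of its pairs flagged
   significant; the top-frequency group (largest-gap split of the sorted
   nonzero frequencies) are the statistical direct-target candidates.
3. **Binding evidence.** Candidates are kept only with a replicate-reproducible
   DAP-seq peak overlapping their promoter window (3 kb upstream to 100 bp
   downstream of the TSS, half-open coordinates) **and** a TGTCAG
   GRF-binding element in that window (both strands).
4. **Recursion.** Every TF among the called direct targets is screened with
   steps 1–2 (no binding filter — binding data exist only for the root)
   against the remaining DEG pool, producing layer 3.

A synthetic-data module generates the full input bundle (expression TSV,
GFF3, FASTA, BED peaks ×2, DEG table, TF list) with a planted three-layer
network so the whole pipeline is testable without any downloads.
Supporting analyses — Spearman association, hypergeometric GO enrichment
with BH correction (significant at corrected *P* < 0.01), and the
palisade-cells-per-leaf estimate — live in `mlhgrn.stats`.

## Worked example

```python
from mlhgrn import RunConfig
from mlhgrn.dap import prepare_dap_evidence
from mlhgrn.network import build_ml_hgrn
from mlhgrn.simulate import (simulate_network_truth, simulate_expression,
                             simulate_genome_and_peaks)

truth = simulate_network_truth(20, 0.25, 50, 200, seed=1)
matrix = simulate_expression(truth, samples_per_group=25)
seqs, genes, (rep1, rep2), degs, _ = simulate_genome_and_peaks(truth)

cfg = RunConfig(seed=1)
evidence = prepare_dap_evidence(seqs, genes, rep1, rep2, cfg)
net = build_ml_hgrn(matrix, truth.regulator_id, degs, evidence, cfg,
                    gene_models=genes)
print([len(l) for l in net.layers], len(net.edges))
```

prints `[1, 20, 51] 113`: the root regulator, 20 called direct targets and
51 layer-3 genes connected by 113 edges. Scored against the planted truth
this run has direct-target precision 1.00 and recall 1.00, and layer-3 edge
precision 0.97 / recall 0.90 (F1 0.93). The `examples/` directory walks
through each stage separately (`python examples/01_simulate_dataset.py` …)
and prints what every number means; a thin `grn` command-line interface
(`grn simulate`, `grn responsive`, `grn interfere`, `grn targets`,
`grn build`, …) wraps the same functions for shell use.

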