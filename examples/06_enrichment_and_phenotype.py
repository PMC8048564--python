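"""Supporting analyses: GO enrichment, Spearman association, phenotype math.

Hypergeometric over-representation with BH correction (significant at
corrected P < 0.01), rank correlation between candidate gene pairs, and
the palisade cells-per-leaf estimate used for leaf phenotyping.
"""

import pandas as pd

from mlhgrn.simulate import simulate_expression, simulate_network_truth
from mlhgrn.stats import cells_per_leaf, hypergeometric_enrichment, spearman_association

truth = simulate_network_truth(20, 0.25, 50, 200, seed=1)
matrix = simulate_expression(truth, samples_per_group=25)

# GO enrichment: a term loaded with direct targets versus a random term
background = truth.all_gene_ids
term_map = pd.DataFrame(
    [("GO:LEAF", g, "leaf development") for g in truth.layer2_ids]
    + [("GO:MISC", g, "miscellaneous") for g in truth.decoy_genes[:20]],
    columns=["term_id", "gene_id", "term_name"],
)
deg_list = truth.layer2_ids + truth.layer3_ids
for res in hypergeometric_enrichment(deg_list, term_map, background):
    print(f"{res.term_id:8s} k={res.k:3d}/{res.K:3d} p={res.p:.3g} "
          f"fdr={res.fdr:.3g} significant={res.significant}")

# Spearman association between the regulator and a direct vs a decoy gene
pairs = [(truth.regulator_id, truth.layer2_ids[5]),
         (truth.regulator_id, truth.decoy_genes[0])]
for r in spearman_association(matrix, pairs):
    print(f"rho({r.gene_a},{r.gene_b}) = {r.rho:+.3f} (p = {r.p:.2g})")

# Leaf phenotype: a 50 cm^2 leaf with 410 um^2 palisade cells
n_cells = cells_per_leaf(50, 410)
print(f"estimated palisade cells per leaf: {n_cells:.3g}")
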