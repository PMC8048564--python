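"""Synthetic regulator-perturbation data with a known planted network.

The generator emulates the study design the pipeline targets: a hub
regulator overexpressed at WT < low < medium < high doses across sample
groups, driving a layer of direct targets (some of them TFs), whose
independent regulatory activity in turn drives a third layer, on a
background of decoy genes.

Layer-2 genes respond linearly to the regulator's log-expression. Layer-3
genes are balanced incoherent integrations of two layer-2 TFs: the second
parent's coefficient cancels the dose component exactly, so a layer-3 gene
has zero net response to the root regulator while remaining strongly coupled
to each parent TF's independent variance. This is the regime in which a
top-down conditional-independence procedure can resolve layers at all: in a
fully coherent linear cascade the dose component dominates every layer and
direct and indirect targets are statistically indistinguishable (see
docs/methods.md for the identifiability argument).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import DEGTable, ExpressionMatrix, GeneModel, PeakSet

REGULATOR_ID = "REG1"

# frozen generator defaults (rationale in docs/methods.md)
BETA2_RANGE = (0.31, 0.38)       # non-TF direct targets: strong dose coupling
BETA2_TF_RANGE = (0.17, 0.23)    # TF direct targets: moderate dose coupling
BETA3_RANGE = (1.2, 1.8)         # layer-3 coupling to parent TFs
GROUP_MEANS = {"WT": 0.0, "low": 1.0, "medium": 2.0, "high": 3.0}
NOISE_SD = 0.3


@dataclass
class SyntheticTruth:
    """The planted network: identities, effect sizes and seeds."""

    regulator_id: str
    layer2_beta: dict[str, float]            # gene -> beta2 (signed)
    layer2_tfs: list[str]
    layer3_edges: dict[tuple[str, str], float]  # (tf, gene) -> beta3 (signed)
    decoy_genes: list[str]
    noise_sd: float
    group_means: dict[str, float]
    seed: int

    def __post_init__(self) -> None:
        l2, l3, dec = set(self.layer2_ids), set(self.layer3_ids), set(self.decoy_genes)
        if l2 & l3 or l2 & dec or l3 & dec:
            raise ValueError("layers must be disjoint")
        if self.regulator_id in l2 | l3 | dec:
            raise ValueError("regulator must not appear in any layer")
        if any(b == 0 for b in self.layer2_beta.values()):
            raise ValueError("all layer-2 effect sizes must be nonzero")
        if any(b == 0 for b in self.layer3_edges.values()):
            raise ValueError("all layer-3 effect sizes must be nonzero")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if set(self.layer2_tfs) - l2:
            raise ValueError("layer2_tfs must be a subset of layer-2 targets")

    @property
    def layer2_ids(self) -> list[str]:
        return list(self.layer2_beta)

    @property
    def layer3_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, gene in self.layer3_edges:
            seen.setdefault(gene, None)
        return list(seen)

    @property
    def layer3_parents(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for (tf, gene), _ in self.layer3_edges.items():
            out.setdefault(gene, []).append(tf)
        return out

    @property
    def all_gene_ids(self) -> list[str]:
        return self.layer2_ids + self.layer3_ids + list(self.decoy_genes)


def simulate_network_truth(
    n_layer2: int,
    tf_fraction: float,
    n_layer3: int,
    n_decoys: int,
    seed: int,
    beta2_range: tuple[float, float] = BETA2_RANGE,
    beta2_tf_range: tuple[float, float] = BETA2_TF_RANGE,
    beta3_range: tuple[float, float] = BETA3_RANGE,
    noise_sd: float = NOISE_SD,
) -> SyntheticTruth:
    """Draw a planted three-layer network topology with effect sizes."""
    if min(n_layer2, n_layer3, n_decoys) < 0:
        raise ValueError("counts must be >= 0")
    if not (0.0 <= tf_fraction <= 1.0):
        raise ValueError("tf_fraction must be in [0, 1]")
    if tf_fraction > 0 and n_layer2 == 0:
        raise ValueError("tf_fraction > 0 requires n_layer2 > 0")
    rng = np.random.default_rng([seed, 101])

    n_tf = int(round(tf_fraction * n_layer2))
    tf_ids = [f"L2TF{i:03d}" for i in range(n_tf)]
    other_ids = [f"L2G{i:03d}" for i in range(n_layer2 - n_tf)]
    layer2_beta: dict[str, float] = {}
    for gid in tf_ids:
        layer2_beta[gid] = rng.uniform(*beta2_tf_range) * rng.choice([-1.0, 1.0])
    for gid in other_ids:
        layer2_beta[gid] = rng.uniform(*beta2_range) * rng.choice([-1.0, 1.0])

    layer3_edges: dict[tuple[str, str], float] = {}
    if n_layer3 > 0:
        if n_tf == 0:
            raise ValueError("layer-3 targets require at least one layer-2 TF")
        for i in range(n_layer3):
            gid = f"L3G{i:03d}"
            if n_tf >= 2:
                a, b = rng.choice(n_tf, size=2, replace=False)
                b3a = rng.uniform(*beta3_range) * rng.choice([-1.0, 1.0])
                # balanced incoherent integration: dose components cancel
                b3b = -b3a * layer2_beta[tf_ids[a]] / layer2_beta[tf_ids[b]]
                layer3_edges[(tf_ids[a], gid)] = b3a
                layer3_edges[(tf_ids[b], gid)] = b3b
            else:
                b3 = rng.uniform(*beta3_range) * rng.choice([-1.0, 1.0])
                layer3_edges[(tf_ids[0], gid)] = b3

    decoys = [f"DEC{i:03d}" for i in range(n_decoys)]
    return SyntheticTruth(
        regulator_id=REGULATOR_ID,
        layer2_beta=layer2_beta,
        layer2_tfs=tf_ids,
        layer3_edges=layer3_edges,
        decoy_genes=decoys,
        noise_sd=noise_sd,
        group_means=dict(GROUP_MEANS),
        seed=seed,
    )


def simulate_expression(truth: SyntheticTruth, samples_per_group: int) -> ExpressionMatrix:
    """Draw the log-expression matrix implied by the planted network."""
    if samples_per_group < 1:
        raise ValueError("samples_per_group must be >= 1")
    rng = np.random.default_rng([truth.seed, 202])
    groups = list(truth.group_means)
    sample_groups = [g for g in groups for _ in range(samples_per_group)]
    n = len(sample_groups)
    sample_ids = [f"{g}_{i + 1}" for g in groups for i in range(samples_per_group)]

    mean_vec = np.array([truth.group_means[g] for g in sample_groups])
    reg = mean_vec + rng.normal(0.0, truth.noise_sd, n)

    values = {truth.regulator_id: reg}
    for gid, b2 in truth.layer2_beta.items():
        values[gid] = b2 * reg + rng.normal(0.0, truth.noise_sd, n)
    for gid in truth.layer3_ids:
        total = rng.normal(0.0, truth.noise_sd, n)
        for tf in truth.layer3_parents[gid]:
            total = total + truth.layer3_edges[(tf, gid)] * values[tf]
        values[gid] = total
    for gid in truth.decoy_genes:
        values[gid] = rng.standard_normal(n)

    gene_ids = [truth.regulator_id] + truth.all_gene_ids
    mat = np.vstack([values[g] for g in gene_ids])
    return ExpressionMatrix(gene_ids, sample_ids, mat, sample_groups)


# ---------------------------------------------------------------------------
# genome, peaks, DEG table


_REVCOMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_REVCOMP)[::-1]


def _scrub_motif(seq: np.ndarray, motif: str, rng: np.random.Generator) -> None:
    """Resample bases until neither the motif nor its reverse complement occurs."""
    alphabet = np.array(list("ACGT"))
    patterns = {motif, _revcomp(motif)}
    k = len(motif)
    for _ in range(200):
        s = "".join(seq)
        hit = -1
        for pat in patterns:
            pos = s.find(pat)
            if pos >= 0:
                hit = pos
                break
        if hit < 0:
            return
        seq[hit : hit + k] = rng.choice(alphabet, size=k)
    raise RuntimeError("failed to scrub accidental motif occurrences")


def simulate_genome_and_peaks(
    truth: SyntheticTruth,
    promoter_up: int = 3000,
    promoter_down: int = 100,
    decoy_peak_rate: float = 0.1,
    seed: int | None = None,
    motif: str = "TGTCAG",
    gene_length: int = 300,
):
    """Build promoter sequences, gene models, replicate peaks, DEGs, TF list.

    One synthetic chromosome per gene; every gene sits on the + strand with
    its TSS at ``promoter_up``, so the promoter window spans the chromosome
    start. Every layer-2 target's window carries one planted motif covered by
    a reproducible peak pair; decoy genes receive motif-free peaks at
    ``decoy_peak_rate``.

    Returns ``(sequences, gene_models, (rep1, rep2), deg_table, tf_ids)``.
    """
    window = promoter_up + promoter_down
    if window < len(motif):
        raise ValueError("promoter window shorter than the motif")
    rng = np.random.default_rng([seed if seed is not None else truth.seed, 303])
    alphabet = np.array(list("ACGT"))
    chrom_len = promoter_up + gene_length + 100

    sequences: dict[str, str] = {}
    genes: list[GeneModel] = []
    rep1: list[tuple[str, int, int, float]] = []
    rep2: list[tuple[str, int, int, float]] = []

    layer2 = set(truth.layer2_ids)
    for gid in truth.all_gene_ids:
        chrom = f"chr_{gid}"
        seq = rng.choice(alphabet, size=chrom_len)
        _scrub_motif(seq, motif, rng)
        tss = promoter_up
        if gid in layer2:
            # plant one motif in the proximal window, with a covering peak
            lo = max(0, tss - 1000)
            hi = tss + promoter_down - len(motif)
            pos = int(rng.integers(lo, hi))
            seq[pos : pos + len(motif)] = list(motif)
            half = 100
            j1, j2 = int(rng.integers(-25, 25)), int(rng.integers(-25, 25))
            s1 = max(0, pos - half + j1)
            s2 = max(0, pos - half + j2)
            rep1.append((chrom, s1, min(chrom_len, pos + half + j1), float(rng.uniform(5, 50))))
            rep2.append((chrom, s2, min(chrom_len, pos + half + j2), float(rng.uniform(5, 50))))
        elif gid in truth.decoy_genes and rng.random() < decoy_peak_rate:
            s = int(rng.integers(0, window - 200))
            rep1.append((chrom, s, s + 200, float(rng.uniform(5, 50))))
            rep2.append((chrom, s + int(rng.integers(-50, 50)), s + 200, float(rng.uniform(5, 50))))
        # planting may not create accidental extra motifs at junctions: verify
        s = "".join(seq)
        expected = 1 if gid in layer2 else 0
        found = s.count(motif) + s.count(_revcomp(motif))
        if found != expected:
            _scrub = np.array(list(s))
            # extremely rare; rebuild this chromosome deterministically
            _scrub_motif(_scrub, motif, rng)
            if expected:
                _scrub[pos : pos + len(motif)] = list(motif)
            seq = _scrub
        sequences[chrom] = "".join(seq)
        genes.append(GeneModel(gid, chrom, "+", tss, tss, tss + gene_length,
                               is_tf=gid in truth.layer2_tfs))

    deg = _simulate_deg_table(truth, rng)
    tf_ids = {truth.regulator_id, *truth.layer2_tfs}
    return sequences, genes, (PeakSet(rep1, "rep1"), PeakSet(rep2, "rep2")), deg, tf_ids


def _simulate_deg_table(truth: SyntheticTruth, rng: np.random.Generator) -> DEGTable:
    """All network genes (FDR < 0.05) plus decoys (FDR uniform)."""
    rows = []
    dose_span = max(truth.group_means.values()) - min(truth.group_means.values())
    for gid, b2 in truth.layer2_beta.items():
        lfc = b2 * dose_span
        rows.append((gid, lfc, 10 ** rng.uniform(-8, -3), 10 ** rng.uniform(-6, -1.35)))
    for gid in truth.layer3_ids:
        lfc = rng.uniform(0.3, 1.0) * rng.choice([-1.0, 1.0])
        rows.append((gid, lfc, 10 ** rng.uniform(-8, -3), 10 ** rng.uniform(-6, -1.35)))
    for gid in truth.decoy_genes:
        lfc = rng.uniform(0.1, 1.5) * rng.choice([-1.0, 1.0])
        rows.append((gid, lfc, rng.uniform(0, 1), rng.uniform(0, 1)))
    frame = pd.DataFrame(rows, columns=["gene_id", "log2fc", "p", "fdr"])
    frame["direction"] = np.where(frame["log2fc"] >= 0, "up", "down")
    return DEGTable(frame)


def simulate_dataset(
    outdir,
    n_layer2: int = 20,
    tf_fraction: float = 0.25,
    n_layer3: int = 50,
    n_decoys: int = 200,
    samples_per_group: int = 25,
    noise_sd: float = NOISE_SD,
    seed: int = 1,
    promoter_up: int = 3000,
    promoter_down: int = 100,
    decoy_peak_rate: float = 0.1,
) -> SyntheticTruth:
    """Write a complete fixture dataset in the standard formats."""
    from pathlib import Path

    from .io import write_degs, write_fasta, write_gene_models, write_peaks

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = simulate_network_truth(
        n_layer2, tf_fraction, n_layer3, n_decoys, seed, noise_sd=noise_sd
    )
    matrix = simulate_expression(truth, samples_per_group)
    seqs, genes, (rep1, rep2), degs, tf_ids = simulate_genome_and_peaks(
        truth, promoter_up, promoter_down, decoy_peak_rate
    )

    frame = matrix.to_frame()
    with open(outdir / "expression.tsv", "w") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        fh.write("group\t" + "\t".join(matrix.sample_groups) + "\n")
        frame.to_csv(fh, sep="\t", header=False, float_format="%.6g")
    write_fasta(seqs, outdir / "genome.fasta")
    write_gene_models(genes, outdir / "genes.gff3")
    write_peaks(rep1, outdir / "peaks_rep1.bed")
    write_peaks(rep2, outdir / "peaks_rep2.bed")
    write_degs(degs, outdir / "degs.tsv")
    (outdir / "tf_list.txt").write_text("\n".join(sorted(tf_ids)) + "\n")

    truth_rows = [("regulator", truth.regulator_id, "", 0.0)]
    truth_rows += [("layer2", g, "", b) for g, b in truth.layer2_beta.items()]
    truth_rows += [("layer3_edge", g, t, b) for (t, g), b in truth.layer3_edges.items()]
    pd.DataFrame(truth_rows, columns=["kind", "gene", "parent", "beta"]).to_csv(
        outdir / "truth.tsv", sep="\t", index=False
    )
    return truth
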