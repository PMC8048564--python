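# Methods

## The model

The pipeline treats log-scale expression as jointly Gaussian and asks a
conditional-independence question rooted at one regulator *z*: for genes
*x*, *y* co-expressed with *z*, does conditioning on *z* remove their
correlation? The interference statistic

d = r_xy − r_xy|z,  r_xy|z = (r_xy − r_xz·r_yz) / √((1−r_xz²)(1−r_yz²))

is large when *z* explains the x–y co-expression, i.e. when both genes sit
downstream of *z*. Aggregating over all pairs gives each gene an
interference frequency; genes the regulator jointly controls with most of
their partners form a distinguished top-frequency group. Direct targets are
the members of that group that also carry physical binding evidence
(replicate-reproducible peak + binding motif in the promoter window). The
same statistical screen, re-rooted at each called target that is a TF,
yields the next layer; those deeper edges are purely statistical and are
labelled as such (`has_peak`/`has_motif` false).

### Standard error of d

SE(d) uses the first-order multivariate delta method: the gradient of
f(r_xy, r_xz, r_yz) = r_xy − r_xy|z (central differences, step 1e−6 — the
function is smooth and an analytic gradient buys nothing) combined with the
standard asymptotic covariance of correlated sample correlations,

n·Var(r_ab) = (1 − r_ab²)²
n·Cov(r_ab, r_ac) = r_bc(1 − r_ab² − r_ac²) − ½·r_ab·r_ac·(1 − r_ab² − r_ac² − r_bc²).

The two-sided p-value is normal. On a fixed triple (r_xy = 0.7, r_xz = 0.6,
r_yz = 0.5, n = 100) this SE agrees with a 2000-replicate nonparametric
bootstrap to within ~5% (the acceptance script recomputes the ratio).

**Known limitation — degenerate null.** At the exact null "z independent of
(x, y)" the gradient of d vanishes (r_xz = r_yz = 0), so the Wald statistic
is Sobel-type conservative: its empirical size at α = 0.05 is ≈ 0 rather
than 0.05. The test loses no practical power in the pipeline because pairs
enter the scan only after both genes pass the responsiveness screen (they
are never jointly independent of z there), but the p-values near that null
are conservative, not calibrated. Power at the planted alternative
(z → x, z → y, β = 1, noise SD 0.5, n = 100) is ≈ 1.0.

### Multiplicity

A scan evaluates C(m, 2) dependent tests. With m ≈ 30 responsive genes that
is ~450 pairs; at raw α = 0.05 the scattered false flags of
responsive-by-chance genes measurably distort the frequency ranking.
Significance is therefore flagged on Benjamini–Hochberg-adjusted p-values
within each scan (default `multiplicity="bh"`; `"none"` is available). BH
adapts per scan: stringent where true pairs are few, permissive where they
dominate — exactly the behaviour the two very different scan regimes
(root screen vs per-TF recursion) need.

### The frequency cutoff

"Highest frequency" is operationalized as the largest-gap split of the
sorted nonzero frequencies (`cutoff_mode="gap"`). Rationale: true direct
targets share a baseline of jointly-controlled significant pairs (each is
significant with essentially every other true target), while
responsive-by-chance genes accumulate only scattered artifact flags; the
class boundary therefore appears as the dominant gap in the frequency
distribution, whereas within-cluster spread moves in small 1/(m−1)
increments. A fixed top-quantile rule (`cutoff_mode="quantile"`,
`top_fraction`, default top 25% of nonzero frequencies) is retained as an
alternative but systematically truncates the target cluster whenever true
targets make up more than the chosen fraction of the scan. Ties between
maximal gaps resolve to the most inclusive split (frequencies are rationals
k/(m−1), so exact ties are real; comparison uses a 1e−9 tolerance).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `fisher_alpha`, `concordance_alpha` | 0.15 | low-stringency responsiveness screens (both must pass) |
| `interference_alpha` | 0.05 | pair-level significance, after per-scan BH |
| `promoter_up` / `promoter_down` | 3000 / 100 bp | promoter window around the TSS (gene 5′ end; translation-start anchoring available via `anchor="cds"` when CDS features exist) |
| `motif` | TGTCAG | GRF-binding cis-element, scanned on both strands |
| `cutoff_mode` / `top_fraction` | gap / 0.25 | direct-target frequency cutoff |
| `deg_fdr_max` | 0.05 | input filter on the DEG table (DEG calling itself is upstream) |
| `n_layers` | 3 | recursion depth |
| `next_layer_tf_count` | all | optional cap on TFs carried into the next layer, ranked by frequency |

All genomic intervals are 0-based half-open; GFF3 is converted on load,
BED consumed natively; boundary-touching intervals never overlap. Replicate
reproducibility keeps the rep1 interval unmodified (`peak_mode="intersect"`
clips instead). Correlations are Pearson on log expression (GGM assumption);
a Spearman mode exists. Sample groups are required metadata but correlations
always pool all samples, matching a design with few libraries per dose.

## The synthetic benchmark

The generator emulates the targeted study design: a regulator whose
log-expression mean steps through (0, 1, 2, 3) for the WT/low/medium/high
groups (monotone dose; the spacing is arbitrary since all statistics are
correlation-based), Gaussian noise SD 0.3 on every gene, 25 samples per
group, 20 direct targets of which 5 are TFs, 50 layer-3 genes, 200 decoys.

Effect sizes (frozen defaults, chosen for identifiability before the
validation suite was written):

- non-TF direct targets: |β₂| ~ U(0.31, 0.38), signs ±; dose–response
  correlation with the regulator ≈ 0.77–0.83.
- TF direct targets: |β₂| ~ U(0.17, 0.23); correlation ≈ 0.53–0.68. TFs are
  coupled more weakly so that conditioning on a TF is not equivalent to
  conditioning on the regulator itself — if an intermediate TF is a perfect
  proxy for the dose, the recursion cannot distinguish its own targets from
  everything else the dose drives.
- layer-3 genes: two TF parents with |β₃| ~ U(1.2, 1.8), the second
  coefficient balanced (−β₃·β₂a/β₂b) so the net dose component cancels:
  a **balanced incoherent integration**. Layer-3 genes are therefore
  strongly coupled to each parent TF's independent regulatory variance but
  have zero net response to the root.

The balanced incoherence is the substantive modelling choice. In a fully
coherent linear-Gaussian cascade the dose term dominates every layer
(corr(layer-3, z) = corr(TF, z)·corr(layer-3, TF)); at n = 100 any gene
correlated with z strongly enough to pass the responsiveness screen also
saturates the pair test, every frequency ties near 1, and *no* ranking can
separate direct from indirect targets — the three-layer structure is
statistically unidentifiable. Hierarchies are resolvable precisely when
intermediate TFs contribute regulatory variance of their own; the balanced
form realizes that regime cleanly within a linear model.

The DEG table lists all network genes with FDR < 0.05 and decoys with
uniform FDR (decoys that land under 0.05 model false-positive DEGs).
Promoters are one synthetic chromosome per gene with the TSS at
`promoter_up`; accidental TGTCAG occurrences (either strand) are scrubbed by
rejection-resampling so motif counts equal planted counts exactly; every
direct target gets one planted motif covered by a jittered, overlapping
replicate peak pair; decoys get motif-free peaks at `decoy_peak_rate` = 0.1.

What the generator does **not** model: count-level noise (negative-binomial
sampling, library-size effects), shared confounding beyond the regulator
(batch, growth stage), feedback loops (the output is a DAG by
construction), motif-strength variation, and peak-shape detail. Passing the
recovery suite therefore demonstrates correctness of the inferential
machinery under the model's own assumptions, not robustness to real
RNA-seq artifacts.

Benchmark recovery at these settings (scored against the planted truth,
seeds 1–12): direct-target precision 1.0 and recall 1.0 on every seed,
layer-3 edge F1 0.87–0.99; in the noiseless limit (noise SD 0.01) the
called layer 2 equals the planted layer 2 exactly. The binding-evidence
conjunction is what pins precision at 1.0 — decoy peaks are motif-free and
layer-3 genes have no peaks, mirroring the role DAP-seq plays in the real
design.

## Numerical choices and degenerate inputs

- Correlations are clipped to ±(1 − 1e−12) before the variance formulas;
  |r_xz| or |r_yz| within 1e−8 of 1 raises "regulator collinear".
- SE = 0 with d = 0 (e.g. exactly independent inputs) returns z = 0, p = 1;
  non-finite or negative variance marks the record untestable (p = 1).
- Constant genes are untestable in every screen and never responsive; a
  constant regulator is a hard error.
- Median discretization sends ties at the median to state 0; a zero margin
  in the contingency table yields p = 1 with a warning.
- A gene eligible for several layers is fixed to the earliest layer; a gene
  selected by several TFs appears once with multiple incoming edges; the
  per-target edge statistic is the significant record with largest |d|
  involving that target (falling back to the overall largest |d|).
- All outputs are byte-deterministic under a fixed seed (stable sort keys
  everywhere; DOT and TSV writers sort explicitly).

## Problem sizes in the validation suite

The acceptance checks run the full benchmark (270 genes × 100 samples,
three replicates plus a noiseless run), a 2000-replicate bootstrap, a
2000-replicate null-size simulation and 200-replicate power simulation at
n = 100, and 20-seed null screens — sizes at which every Monte-Carlo
estimate above is stable to well under its acceptance margin while the
whole suite stays interactive.
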