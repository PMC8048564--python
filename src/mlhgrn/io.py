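"""Typed readers/writers for the formats the pipeline touches.

All internal coordinates are 0-based half-open. GFF3 (1-based closed) is
converted on load; BED intervals are consumed natively. Boundary-touching
intervals never overlap under these semantics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_STRANDS = ("+", "-")


# ---------------------------------------------------------------------------
# domain types


@dataclass
class ExpressionMatrix:
    """Log-scale expression values for genes (rows) across grouped samples.

    ``sample_groups`` carries one label per sample (e.g. WT / low / medium /
    high overexpression lines). Correlations are always computed across all
    samples pooled.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # genes x samples
    sample_groups: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dup = _first_duplicate(self.gene_ids)
            raise ValueError(f"duplicate gene id: {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise ValueError(f"duplicate sample id: {dup!r}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.sample_groups) != len(self.sample_ids):
            raise ValueError("one group label required per sample")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self._index()[gene_id]]

    def _index(self) -> dict[str, int]:
        if not hasattr(self, "_idx"):
            self._idx = {g: i for i, g in enumerate(self.gene_ids)}
        return self._idx

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index()

    def subset(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self._index()[g] for g in gene_ids]
        return ExpressionMatrix(
            list(gene_ids), list(self.sample_ids), self.values[idx], list(self.sample_groups)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class GeneModel:
    """One gene: 0-based half-open span, TSS approximated by the 5' end."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    start: int
    end: int
    is_tf: bool = False

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"gene {self.gene_id!r}: strand must be + or -, got {self.strand!r}")
        if not (self.start <= self.tss < self.end):
            raise ValueError(f"gene {self.gene_id!r}: tss {self.tss} outside span [{self.start},{self.end})")


@dataclass
class PeakSet:
    """Peak intervals from one replicate, sorted per chromosome after load."""

    peaks: list[tuple[str, int, int, float]]  # (chrom, start, end, score)
    replicate_id: str = ""

    def __post_init__(self) -> None:
        for chrom, start, end, _ in self.peaks:
            if end < start:
                raise ValueError(f"negative-length peak {chrom}:{start}-{end}")
        self.peaks = sorted(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    def by_chrom(self) -> dict[str, list[tuple[int, int, float]]]:
        out: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, score in self.peaks:
            out.setdefault(chrom, []).append((start, end, score))
        return out


@dataclass
class DEGTable:
    """Differential-expression calls: gene, log2FC, p, FDR, direction."""

    frame: pd.DataFrame  # columns: gene_id, log2fc, p, fdr, direction

    REQUIRED = ("gene_id", "log2fc", "p", "fdr", "direction")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"DEG table missing columns: {missing}")
        f = self.frame
        if ((f["fdr"] < 0) | (f["fdr"] > 1)).any():
            raise ValueError("DEG fdr outside [0, 1]")
        expected = np.where(f["log2fc"] >= 0, "up", "down")
        bad = f.loc[f["direction"].to_numpy() != expected, "gene_id"]
        if len(bad):
            raise ValueError(f"direction inconsistent with log2fc sign for {bad.iloc[0]!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.frame["gene_id"])

    def filtered(self, fdr_max: float) -> "DEGTable":
        return DEGTable(self.frame[self.frame["fdr"] < fdr_max].reset_index(drop=True))


@dataclass
class RunConfig:
    """Thresholds and options for the full pipeline.

    ``fisher_alpha`` is the low-stringency responsiveness screen (P < 0.15); the
    concordance screen mirrors it. ``interference_alpha`` applies to the
    pair-level delta-method test, after the per-scan ``multiplicity``
    adjustment (Benjamini-Hochberg by default: each scan evaluates C(m,2)
    dependent tests and an uncorrected threshold saturates the frequency
    ranking).
    """

    fisher_alpha: float = 0.15
    concordance_alpha: float = 0.15
    interference_alpha: float = 0.05
    promoter_up: int = 3000
    promoter_down: int = 100
    motif: str = "TGTCAG"
    top_fraction: float = 0.25
    cutoff_mode: str = "gap"  # gap | quantile
    next_layer_tf_count: int | None = None  # None = all selected TFs
    n_layers: int = 3
    seed: int = 0
    multiplicity: str = "bh"  # none | bh
    deg_fdr_max: float = 0.05
    responsive_rule: str = "and"  # and | or
    motif_both_strands: bool = True
    peak_mode: str = "rep1"  # rep1 | intersect
    correlation: str = "pearson"  # pearson | spearman

    def __post_init__(self) -> None:
        for name in ("fisher_alpha", "concordance_alpha", "interference_alpha"):
            a = getattr(self, name)
            if not (0.0 < a < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {a}")
        if self.promoter_up < 0 or self.promoter_down < 0:
            raise ValueError("promoter window extents must be >= 0")
        if set(self.motif.upper()) - set("ACGT"):
            raise ValueError(f"motif must be over ACGT, got {self.motif!r}")
        if self.cutoff_mode not in ("gap", "quantile"):
            raise ValueError("cutoff_mode must be 'gap' or 'quantile'")
        if self.multiplicity not in ("none", "bh"):
            raise ValueError("multiplicity must be 'none' or 'bh'")
        if self.responsive_rule not in ("and", "or"):
            raise ValueError("responsive_rule must be 'and' or 'or'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _first_duplicate(items: Iterable[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""


# ---------------------------------------------------------------------------
# loaders


def load_expression(path: str | Path, groups_path: str | Path | None = None) -> ExpressionMatrix:
    """Read a genes x samples TSV.

    First column holds gene ids, header row sample ids. Group labels come
    from an optional second header row whose first cell is ``group``, or from
    a sidecar TSV (sample_id <tab> group). Non-numeric cells are rejected
    with their coordinates.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty expression file")
    header = lines[0].split("\t")
    sample_ids = header[1:]
    body_start = 1
    groups: list[str] | None = None
    if len(lines) > 1:
        second = lines[1].split("\t")
        if second and second[0].lower() in ("group", "#group", "!group"):
            groups = second[1:]
            if len(groups) != len(sample_ids):
                raise ValueError(f"{path}: group row has {len(groups)} labels for {len(sample_ids)} samples")
            body_start = 2
    if groups is None and groups_path is not None:
        gmap: dict[str, str] = {}
        with open(groups_path) as fh:
            for ln in fh:
                if ln.strip():
                    sid, grp = ln.rstrip("\n").split("\t")[:2]
                    gmap[sid] = grp
        missing = [s for s in sample_ids if s not in gmap]
        if missing:
            raise ValueError(f"group file lacks labels for samples: {missing}")
        groups = [gmap[s] for s in sample_ids]
    if groups is None:
        raise ValueError(f"{path}: missing sample group labels (group header row or sidecar file required)")

    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for li, ln in enumerate(lines[body_start:], start=body_start + 1):
        parts = ln.split("\t")
        gene_ids.append(parts[0])
        vals = []
        for ci, cell in enumerate(parts[1:], start=2):
            try:
                vals.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell {cell!r} at line {li}, column {ci} "
                    f"(gene {parts[0]!r}, sample {sample_ids[ci - 2]!r})"
                ) from None
        if len(vals) != len(sample_ids):
            raise ValueError(f"{path}: line {li} has {len(vals)} values for {len(sample_ids)} samples")
        rows.append(vals)
    return ExpressionMatrix(gene_ids, sample_ids, np.array(rows, dtype=float), groups)


def load_tf_list(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {ln.strip() for ln in fh if ln.strip()}


def load_gene_models(
    path: str | Path, tf_list: str | Path | set[str] | None = None, anchor: str = "gene"
) -> list[GeneModel]:
    """Read gene features from GFF3 and convert to 0-based half-open.

    ``anchor`` selects the window anchor: ``gene`` uses the gene feature's 5'
    end as TSS; ``cds`` uses the 5'-most CDS coordinate when CDS features are
    present (translation-start anchoring).
    """
    import gffutils

    tfs: set[str]
    if tf_list is None:
        tfs = set()
    elif isinstance(tf_list, set):
        tfs = tf_list
    else:
        tfs = load_tf_list(tf_list)

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    out: list[GeneModel] = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gid = feat.attributes.get("ID", [feat.id])[0]
        if feat.start is None or feat.end is None:
            logger.warning("gene %s has no coordinates; skipped", gid)
            continue
        if feat.strand not in VALID_STRANDS:
            raise ValueError(f"gene {gid!r}: strand must be + or -, got {feat.strand!r}")
        start0, end0 = feat.start - 1, feat.end  # 1-based closed -> 0-based half-open
        anchor_start, anchor_end = start0, end0
        if anchor == "cds":
            cds = list(db.children(feat, featuretype="CDS"))
            if cds:
                anchor_start = min(c.start for c in cds) - 1
                anchor_end = max(c.end for c in cds)
        tss = anchor_start if feat.strand == "+" else anchor_end - 1
        out.append(GeneModel(gid, feat.seqid, feat.strand, tss, start0, end0, gid in tfs))
    return out


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write GFF3 (1-based closed); inverse of :func:`load_gene_models`."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            fh.write(
                f"{g.chrom}\tmlhgrn\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


def load_peaks(path: str | Path, replicate_id: str = "") -> PeakSet:
    """Read BED6 / ENCODE narrowPeak intervals (natively 0-based half-open)."""
    peaks = []
    with open(path) as fh:
        for ln in fh:
            if not ln.strip() or ln.startswith(("#", "track", "browser")):
                continue
            parts = ln.rstrip("\n").split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            peaks.append((chrom, start, end, score))
    return PeakSet(peaks, replicate_id or Path(path).stem)


def write_peaks(peaks: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, (chrom, start, end, score) in enumerate(peaks.peaks):
            fh.write(f"{chrom}\t{start}\t{end}\tpeak_{i}\t{score:g}\t.\n")


def load_degs(path: str | Path) -> DEGTable:
    frame = pd.read_csv(path, sep="\t")
    if "direction" not in frame.columns and "log2fc" in frame.columns:
        frame["direction"] = np.where(frame["log2fc"] >= 0, "up", "down")
    return DEGTable(frame)


def write_degs(degs: DEGTable, path: str | Path) -> None:
    degs.frame.to_csv(path, sep="\t", index=False)


def load_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def load_go_map(path: str | Path) -> pd.DataFrame:
    """GO term map TSV: term_id, gene_id, term_name."""
    return pd.read_csv(path, sep="\t", names=["term_id", "gene_id", "term_name"], header=None)


# ---------------------------------------------------------------------------
# replicate reproducibility


def intervals_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    """>= 1 bp overlap under half-open semantics; touching ends do not count."""
    return a_start < b_end and b_start < a_end


def reproducible_peaks(rep1: PeakSet, rep2: PeakSet, mode: str = "rep1") -> PeakSet:
    """Keep rep1 peaks that overlap (>= 1 bp) any rep2 peak.

    ``mode='rep1'`` keeps the rep1 interval unmodified; ``mode='intersect'``
    clips it to the union of overlapping rep2 intervals. A chromosome present
    in one set only simply yields no matches. Idempotent for fixed rep2.
    """
    rep2_by_chrom = rep2.by_chrom()
    kept: list[tuple[str, int, int, float]] = []
    for chrom, start, end, score in rep1.peaks:
        hits = [
            (s2, e2)
            for s2, e2, _ in rep2_by_chrom.get(chrom, [])
            if intervals_overlap(start, end, s2, e2)
        ]
        if not hits:
            continue
        if mode == "intersect":
            s = max(start, min(h[0] for h in hits))
            e = min(end, max(h[1] for h in hits))
            kept.append((chrom, s, e, score))
        else:
            kept.append((chrom, start, end, score))
    return PeakSet(kept, replicate_id=rep1.replicate_id)


# ---------------------------------------------------------------------------
# network serialization

EDGE_COLUMNS = ["regulator", "target", "target_layer", "d", "p", "frequency", "has_peak", "has_motif"]


def write_network(net, prefix: str | Path) -> dict[str, Path]:
    """Write edges TSV, DOT and a JSON run summary for a LayeredNetwork."""
    from .network import export_dot

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    edges_path = prefix.with_suffix(".edges.tsv")
    dot_path = prefix.with_suffix(".dot")
    json_path = prefix.with_suffix(".summary.json")

    rows = [
        {
            "regulator": e.regulator_id,
            "target": e.target_id,
            "target_layer": e.target_layer,
            "d": e.d,
            "p": e.p,
            "frequency": e.frequency,
            "has_peak": e.has_peak,
            "has_motif": e.has_motif,
        }
        for e in net.edges
    ]
    frame = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    frame.to_csv(edges_path, sep="\t", index=False)

    dot_path.write_text(export_dot(net))

    summary = {
        "root": net.root,
        "n_layers": len(net.layers),
        "layer_sizes": [len(l) for l in net.layers],
        "n_edges": len(net.edges),
        "config": asdict(net.config) if net.config is not None else None,
    }
    json_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return {"edges": edges_path, "dot": dot_path, "summary": json_path}


def read_network_edges(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    for col in ("has_peak", "has_motif"):
        if col in frame.columns:
            frame[col] = frame[col].astype(bool)
    return frame
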