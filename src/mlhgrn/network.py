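"""Assembly of the regulator-rooted multilayered hierarchical GRN.

Layer 2 holds direct targets of the root regulator (responsiveness +
interference + DAP/motif evidence); deeper layers are built by recursively
applying the statistical screen (without binding evidence, which exists
only for the root) to each TF among the previous layer's targets, over the
remaining DEG pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dap import DirectTargetCall, call_direct_targets, calls_to_frame
from .interference import FrequencyTable, InterferenceRecord, interference_scan
from .io import DEGTable, ExpressionMatrix, GeneModel, RunConfig
from .responsiveness import responsive_ids, select_responsive

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GRNEdge:
    regulator_id: str
    target_id: str
    target_layer: int
    d: float
    p: float
    frequency: float
    has_peak: bool = False
    has_motif: bool = False

    def __post_init__(self) -> None:
        if self.regulator_id == self.target_id:
            raise ValueError(f"self-edge on {self.regulator_id!r}")


@dataclass
class LayeredNetwork:
    root: str
    layers: list[list[str]]  # layers[0] == [root]
    edges: list[GRNEdge]
    config: RunConfig | None = None

    def validate(self) -> None:
        assert self.layers and self.layers[0] == [self.root]
        seen: set[str] = set()
        layer_of: dict[str, int] = {}
        for i, layer in enumerate(self.layers):
            genes = set(layer)
            if genes & seen:
                raise AssertionError(f"layers not disjoint: {genes & seen}")
            seen |= genes
            for g in layer:
                layer_of[g] = i + 1
        incoming: dict[str, int] = {}
        for e in self.edges:
            if layer_of[e.target_id] != layer_of[e.regulator_id] + 1:
                raise AssertionError(
                    f"edge {e.regulator_id}->{e.target_id} does not connect consecutive layers"
                )
            if e.target_layer != layer_of[e.target_id]:
                raise AssertionError("edge target_layer inconsistent with layer membership")
            incoming[e.target_id] = incoming.get(e.target_id, 0) + 1
        for layer in self.layers[1:]:
            for g in layer:
                if incoming.get(g, 0) < 1:
                    raise AssertionError(f"non-root node {g!r} has no incoming edge")

    @property
    def n_nodes(self) -> int:
        return sum(len(l) for l in self.layers)


def _pool_as_degs(pool: list[str]) -> DEGTable:
    frame = pd.DataFrame(
        {"gene_id": pool, "log2fc": 0.0, "p": 0.0, "fdr": 0.0, "direction": "up"}
    )
    return DEGTable(frame)


def _best_edge_stat(
    records: list[InterferenceRecord], target: str
) -> tuple[float, float]:
    """(d, p) of the significant record with largest |d| involving target,
    falling back to the overall largest-|d| record when none is significant."""
    mine = [r for r in records if target in (r.x_id, r.y_id)]
    sig = [r for r in mine if r.significant]
    chosen = max(sig or mine, key=lambda r: abs(r.d))
    return chosen.d, chosen.p


def build_layer(
    matrix: ExpressionMatrix,
    regulator_id: str,
    candidate_pool: list[str],
    config: RunConfig | None = None,
    evidence: dict | None = None,
    target_layer: int = 2,
):
    """One top-down GGM step: responsiveness, interference, target calling.

    With ``evidence`` (dict of ``peak_map``, ``motif_hits``, ``genes``)
    selection requires the full conjunction; without it, the frequency
    cutoff alone decides. Returns ``(selected_ids, edges, records, freq)``.
    """
    config = config or RunConfig()
    pool = [g for g in candidate_pool if g != regulator_id]
    if not pool:
        raise ValueError("pool must exclude regulator and be non-empty")

    results = select_responsive(matrix, regulator_id, _pool_as_degs(pool), config)
    resp = responsive_ids(results)
    if len(resp) < 2:
        logger.warning("regulator %s: fewer than 2 responsive candidates; empty layer", regulator_id)
        return [], [], [], None

    records, freq = interference_scan(matrix, regulator_id, resp, config)

    if evidence is not None:
        calls = call_direct_targets(
            freq, evidence["peak_map"], evidence["motif_hits"], evidence["genes"], config
        )
        selected = [c.gene_id for c in calls if c.selected]
        flags = {c.gene_id: (c.has_peak, c.has_motif) for c in calls}
    else:
        from .dap import frequency_cutoff

        freqs = freq.frame["frequency"].to_numpy()
        if (freqs == 0).all():
            logger.warning("all frequencies zero for %s; empty selection", regulator_id)
            return [], [], records, freq
        cutoff = frequency_cutoff(freqs, config.top_fraction, config.cutoff_mode)
        selected = [g for g, f in zip(freq.frame["gene_id"], freqs) if f >= cutoff]
        flags = {}

    edges = []
    for gid in sorted(selected):
        d, p = _best_edge_stat(records, gid)
        has_peak, has_motif = flags.get(gid, (False, False))
        edges.append(
            GRNEdge(regulator_id, gid, target_layer, d, p, freq.frequency(gid),
                    has_peak, has_motif)
        )
    return sorted(selected), edges, records, freq


def build_ml_hgrn(
    matrix: ExpressionMatrix,
    regulator_id: str,
    degs: DEGTable,
    dap_evidence: dict | None,
    config: RunConfig | None = None,
    gene_models: list[GeneModel] | None = None,
) -> LayeredNetwork:
    """Assemble the full multilayered network rooted at ``regulator_id``.

    Layer 2 comes from DAP-filtered direct-target calls; each TF among the
    called targets is then screened against the remaining DEG pool (without
    binding evidence) to produce the next layer, recursively up to
    ``config.n_layers``.
    """
    config = config or RunConfig()
    deg_pool = [g for g in degs.filtered(config.deg_fdr_max).gene_ids if g != regulator_id]
    if not deg_pool:
        raise ValueError("no DEGs pass the FDR filter")

    tf_map: dict[str, bool] = {}
    if dap_evidence is not None:
        tf_map = {g.gene_id: g.is_tf for g in dap_evidence["genes"]}
    if gene_models is not None:
        tf_map.update({g.gene_id: g.is_tf for g in gene_models})

    selected, edges, _, freq = build_layer(
        matrix, regulator_id, deg_pool, config, evidence=dap_evidence, target_layer=2
    )
    layers: list[list[str]] = [[regulator_id], sorted(selected)]
    all_edges: list[GRNEdge] = list(edges)
    assigned = {regulator_id, *selected}

    current_layer = sorted(selected)
    layer_idx = 2
    while layer_idx < config.n_layers:
        tfs = [g for g in current_layer if tf_map.get(g, False)]
        if not tfs:
            logger.warning(
                "no TFs among layer-%d targets; stopping at %d layers", layer_idx, layer_idx
            )
            break
        if config.next_layer_tf_count is not None and freq is not None:
            tfs = sorted(tfs, key=lambda g: (-freq.frequency(g), g))[: config.next_layer_tf_count]
        pool = sorted(set(deg_pool) - assigned)
        next_genes: set[str] = set()
        next_edges: list[GRNEdge] = []
        for tf in sorted(tfs):
            if len(pool) < 2:
                break
            sel_t, edges_t, _, _ = build_layer(
                matrix, tf, pool, config, evidence=None, target_layer=layer_idx + 1
            )
            next_genes.update(sel_t)
            next_edges.extend(edges_t)
        if not next_genes:
            break
        layers.append(sorted(next_genes))
        all_edges.extend(next_edges)
        assigned |= next_genes
        current_layer = sorted(next_genes)
        layer_idx += 1

    net = LayeredNetwork(regulator_id, layers, all_edges, config)
    net.validate()
    return net


def export_dot(net: LayeredNetwork) -> str:
    """Rank-constrained DOT with one rank per layer; byte-stable output."""
    lines = ["digraph mlhgrn {", "  rankdir=TB;", '  node [shape=box, fontsize=10];']
    for i, layer in enumerate(net.layers):
        names = "; ".join(f'"{g}"' for g in sorted(layer))
        lines.append(f"  {{ rank=same; {names}; }}  // layer {i + 1}")
    for e in sorted(net.edges, key=lambda e: (e.target_layer, e.regulator_id, e.target_id)):
        lines.append(f'  "{e.regulator_id}" -> "{e.target_id}";')
    lines.append("}")
    return "\n".join(lines) + "\n"
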