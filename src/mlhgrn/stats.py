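"""Supporting analyses: Spearman association, GO enrichment, phenotype math."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class AssociationResult:
    gene_a: str
    gene_b: str
    rho: float
    p: float
    dataset_id: str = ""
    testable: bool = True


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # DEGs in term
    K: int  # background genes in term
    n: int  # DEG count
    N: int  # background size
    p: float
    fdr: float
    significant: bool


def spearman_association(
    matrix: ExpressionMatrix,
    pairs: list[tuple[str, str]],
    dataset_id: str = "",
) -> list[AssociationResult]:
    """Spearman rank correlation (mean ranks for ties) with t-approximation p.

    t = rho * sqrt((n-2)/(1-rho^2)); |rho| = 1 gives p = 0. Constant genes
    are flagged untestable.
    """
    if matrix.n_samples < 4:
        raise ValueError("Spearman association requires >= 4 samples")
    out: list[AssociationResult] = []
    for a, b in pairs:
        xa, xb = matrix.row(a), matrix.row(b)
        if np.allclose(xa, xa[0]) or np.allclose(xb, xb[0]):
            out.append(AssociationResult(a, b, float("nan"), 1.0, dataset_id, testable=False))
            continue
        rho, p = stats.spearmanr(xa, xb)
        if abs(rho) >= 1.0 - 1e-12:  # perfectly monotone: p is exactly 0
            rho, p = float(np.sign(rho)), 0.0
        out.append(AssociationResult(a, b, float(rho), float(p), dataset_id))
    return out


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    adj_i = min over j >= i (sorted order) of p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if ((p < 0) | (p > 1)).any() or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def hypergeometric_enrichment(
    deg_ids: set[str] | list[str],
    term_map: pd.DataFrame,
    background_ids: set[str] | list[str],
    fdr_threshold: float = 0.01,
) -> list[EnrichmentResult]:
    """Over-representation of GO terms in a DEG list.

    Per term: p = P(X >= k), X ~ Hypergeometric(N, K, n); BH adjustment
    across tested terms; significance at corrected p < 0.01. DEG ids outside
    the background are logged and dropped.
    """
    background = set(background_ids)
    if not background:
        raise ValueError("background gene set is empty")
    degs = set(deg_ids)
    stray = degs - background
    if stray:
        logger.warning("%d DEG ids outside the background were dropped", len(stray))
        degs &= background
    N, n = len(background), len(degs)

    terms = []
    for term_id, grp in term_map.groupby("term_id", sort=True):
        genes = set(grp["gene_id"]) & background
        if not genes:
            continue
        K = len(genes)
        k = len(genes & degs)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        name = str(grp["term_name"].iloc[0]) if "term_name" in grp else ""
        terms.append((str(term_id), name, k, K, p))
    if not terms:
        return []
    fdrs = bh_adjust(np.array([t[4] for t in terms]))
    return [
        EnrichmentResult(tid, name, k, K, n, N, p, float(fdr), bool(fdr < fdr_threshold))
        for (tid, name, k, K, p), fdr in zip(terms, fdrs)
    ]


UM2_PER_CM2 = 1e8  # 1 cm^2 = 10^8 um^2


def cells_per_leaf(leaf_area_cm2: float, mean_cell_area_um2: float) -> float:
    """Estimated palisade cell count: leaf area divided by mean cell area."""
    if leaf_area_cm2 <= 0 or mean_cell_area_um2 <= 0:
        raise ValueError("areas must be positive")
    return leaf_area_cm2 * UM2_PER_CM2 / mean_cell_area_um2
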