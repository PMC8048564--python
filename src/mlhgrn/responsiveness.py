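"""Stage 1 of the top-down GGM: the regulator-responsiveness screen.

Each candidate gene from the DEG list is tested for association with the
regulator across all samples, using two complementary screens on
median-discretized states: Fisher's exact test on the 2x2 joint-state table
(a low-stringency screen at P < 0.15) and a binomial concordance
probability. A gene is responsive when both screens pass (configurable to
either-passes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import DEGTable, ExpressionMatrix, RunConfig

logger = logging.getLogger(__name__)


@dataclass
class ResponsivenessResult:
    gene_id: str
    table: np.ndarray  # 2x2 counts of (regulator state x gene state)
    fisher_p: float
    concordance_k: int
    concordance_p: float
    responsive: bool
    testable: bool = True


def discretize_expression(values: np.ndarray) -> np.ndarray:
    """Median-split a per-gene vector: 1 above the median, 0 at or below."""
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("discretization requires >= 4 samples")
    if np.allclose(values, values[0]):
        raise ValueError("constant gene: expression vector cannot be discretized")
    return (values > np.median(values)).astype(int)


def fisher_responsiveness(reg_states: np.ndarray, gene_states: np.ndarray) -> tuple[np.ndarray, float]:
    """2x2 joint-state table and its two-sided Fisher exact p-value.

    The two-sided p sums hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed the observed table's.
    A zero margin leaves no association to test: p = 1 with a warning.
    """
    reg_states = np.asarray(reg_states, dtype=int)
    gene_states = np.asarray(gene_states, dtype=int)
    if reg_states.shape != gene_states.shape or reg_states.size < 4:
        raise ValueError("state vectors must have equal length >= 4")
    table = np.array(
        [[np.sum((reg_states == a) & (gene_states == b)) for b in (0, 1)] for a in (0, 1)]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        logger.warning("zero margin in contingency table; no association testable (p = 1)")
        return table, 1.0
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return table, float(p)


def concordance_probability(reg_states: np.ndarray, gene_states: np.ndarray) -> tuple[int, float]:
    """Folded binomial concordance: k = max(#matches, #mismatches).

    p = P(X >= k) for X ~ Binomial(n, 1/2); folding over matches versus
    mismatches makes the screen two-sided, so perfectly anti-concordant
    vectors score the same as perfectly concordant ones.
    """
    reg_states = np.asarray(reg_states, dtype=int)
    gene_states = np.asarray(gene_states, dtype=int)
    if reg_states.shape != gene_states.shape or reg_states.size < 4:
        raise ValueError("state vectors must have equal length >= 4")
    n = reg_states.size
    matches = int(np.sum(reg_states == gene_states))
    k = max(matches, n - matches)
    p = float(stats.binom.sf(k - 1, n, 0.5))
    return k, p


def select_responsive(
    matrix: ExpressionMatrix,
    regulator_id: str,
    degs: DEGTable,
    config: RunConfig | None = None,
) -> list[ResponsivenessResult]:
    """Screen every testable DEG for responsiveness to the regulator."""
    config = config or RunConfig()
    if regulator_id not in matrix:
        raise KeyError(f"regulator {regulator_id!r} not in expression matrix")
    try:
        reg_states = discretize_expression(matrix.row(regulator_id))
    except ValueError as exc:
        raise ValueError(f"regulator {regulator_id!r} is constant; screen undefined") from exc

    candidates = [g for g in degs.gene_ids if g != regulator_id]
    missing = [g for g in candidates if g not in matrix]
    if missing:
        logger.warning(
            "%d DEG ids absent from the expression matrix were skipped (e.g. %s)",
            len(missing), missing[0],
        )
    present = [g for g in candidates if g in matrix]
    if not present:
        logger.warning("no DEG ids found in the expression matrix; empty result")

    results: list[ResponsivenessResult] = []
    for gid in present:
        try:
            gene_states = discretize_expression(matrix.row(gid))
        except ValueError:
            results.append(
                ResponsivenessResult(gid, np.zeros((2, 2), int), 1.0, 0, 1.0,
                                     responsive=False, testable=False)
            )
            continue
        table, fp = fisher_responsiveness(reg_states, gene_states)
        k, cp = concordance_probability(reg_states, gene_states)
        fisher_ok = fp < config.fisher_alpha
        conc_ok = cp < config.concordance_alpha
        if config.responsive_rule == "and":
            responsive = fisher_ok and conc_ok
        else:
            responsive = fisher_ok or conc_ok
        results.append(ResponsivenessResult(gid, table, fp, k, cp, responsive))
    return results


def responsive_ids(results: list[ResponsivenessResult]) -> list[str]:
    return [r.gene_id for r in results if r.responsive]
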