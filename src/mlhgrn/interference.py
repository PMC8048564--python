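"""Stage 2 of the top-down GGM: triple-block interference testing.

For regulator z and every pair (x, y) of responsive genes, the interference
statistic d = r_xy - r_xy|z measures how much of the x-y co-expression the
regulator explains. Its standard error comes from the first-order
multivariate delta method combined with the asymptotic covariance of
correlated sample correlations; significance from the standard normal. The
per-gene interference frequency is the fraction of pairs involving the gene
whose interference is significant.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, RunConfig

logger = logging.getLogger(__name__)

_EPS = 1e-8
_CLIP = 1.0 - 1e-12
_FD_STEP = 1e-6  # central-difference step for the gradient


@dataclass(frozen=True)
class CorrelationTriple:
    """Sample correlations among regulator z and genes x, y."""

    x_id: str
    y_id: str
    z_id: str
    r_xy: float
    r_xz: float
    r_yz: float
    n: int

    def __post_init__(self) -> None:
        for name in ("r_xy", "r_xz", "r_yz"):
            r = getattr(self, name)
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"{name} = {r} outside [-1, 1]")
        if self.n < 4:
            raise ValueError("correlation requires n >= 4")
        # implied correlation matrix must be (near) positive semidefinite
        mat = np.array(
            [[1.0, self.r_xy, self.r_xz], [self.r_xy, 1.0, self.r_yz], [self.r_xz, self.r_yz, 1.0]]
        )
        if np.linalg.eigvalsh(mat).min() < -1e-8:
            raise ValueError("implied correlation matrix is not positive semidefinite")


@dataclass
class InterferenceRecord:
    x_id: str
    y_id: str
    r_xy_given_z: float
    d: float
    se_d: float
    z_stat: float
    p: float
    significant: bool
    testable: bool = True


def partial_correlation(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation r_xy|z."""
    denom_sq = (1.0 - r_xz ** 2) * (1.0 - r_yz ** 2)
    if denom_sq < _EPS:
        raise ValueError("regulator collinear with gene: |r_xz| or |r_yz| too close to 1")
    return (r_xy - r_xz * r_yz) / np.sqrt(denom_sq)


def _d_of_r(r: np.ndarray) -> np.ndarray:
    """d = r_xy - r_xy|z on an array of shape (..., 3)."""
    rxy, rxz, ryz = r[..., 0], r[..., 1], r[..., 2]
    denom = np.sqrt((1.0 - rxz ** 2) * (1.0 - ryz ** 2))
    return rxy - (rxy - rxz * ryz) / denom


def _corr_cov(rab: np.ndarray, rac: np.ndarray, rbc: np.ndarray) -> np.ndarray:
    """n * Cov(r_ab, r_ac) for sample correlations sharing index a."""
    return rbc * (1 - rab ** 2 - rac ** 2) - 0.5 * rab * rac * (1 - rab ** 2 - rac ** 2 - rbc ** 2)


def _delta_arrays(rxy, rxz, ryz, n):
    """Vectorized delta-method test. Returns (d, se, z, p) arrays."""
    r = np.stack(
        [np.clip(np.asarray(a, float), -_CLIP, _CLIP) for a in (rxy, rxz, ryz)], axis=-1
    )
    d = _d_of_r(r)
    grad = np.empty_like(r)
    for i in range(3):
        rp, rm = r.copy(), r.copy()
        rp[..., i] += _FD_STEP
        rm[..., i] -= _FD_STEP
        grad[..., i] = (_d_of_r(rp) - _d_of_r(rm)) / (2 * _FD_STEP)

    v_xy = (1 - r[..., 0] ** 2) ** 2
    v_xz = (1 - r[..., 1] ** 2) ** 2
    v_yz = (1 - r[..., 2] ** 2) ** 2
    c_xy_xz = _corr_cov(r[..., 0], r[..., 1], r[..., 2])  # share x
    c_xy_yz = _corr_cov(r[..., 0], r[..., 2], r[..., 1])  # share y
    c_xz_yz = _corr_cov(r[..., 1], r[..., 2], r[..., 0])  # share z

    g0, g1, g2 = grad[..., 0], grad[..., 1], grad[..., 2]
    var = (
        g0 ** 2 * v_xy + g1 ** 2 * v_xz + g2 ** 2 * v_yz
        + 2 * (g0 * g1 * c_xy_xz + g0 * g2 * c_xy_yz + g1 * g2 * c_xz_yz)
    ) / n

    var = np.asarray(var, float)
    se = np.sqrt(np.clip(var, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, d / np.where(se > 0, se, 1.0), 0.0)
    p = np.where(se > 0, 2 * stats.norm.sf(np.abs(z)), 1.0)
    return d, se, z, p


def delta_method_test(triple: CorrelationTriple, alpha: float = 0.05) -> InterferenceRecord:
    """Test whether conditioning on z significantly changes r_xy."""
    d, se, z, p = (float(np.squeeze(a)) for a in _delta_arrays(
        triple.r_xy, triple.r_xz, triple.r_yz, triple.n
    ))
    testable = np.isfinite(se) and se >= 0
    if not testable or (se == 0 and d != 0):
        return InterferenceRecord(
            triple.x_id, triple.y_id,
            partial_correlation(triple.r_xy, triple.r_xz, triple.r_yz),
            d, max(se, 0.0), 0.0, 1.0, significant=False, testable=False,
        )
    r_cond = partial_correlation(
        np.clip(triple.r_xy, -_CLIP, _CLIP),
        np.clip(triple.r_xz, -_CLIP, _CLIP),
        np.clip(triple.r_yz, -_CLIP, _CLIP),
    )
    return InterferenceRecord(triple.x_id, triple.y_id, r_cond, d, se, z, p,
                              significant=p < alpha)


@dataclass
class FrequencyTable:
    """Per-gene interference frequencies over all C(m, 2) pairs."""

    frame: pd.DataFrame  # gene_id, n_significant_pairs, n_pairs, frequency, rank

    def frequency(self, gene_id: str) -> float:
        row = self.frame.loc[self.frame["gene_id"] == gene_id, "frequency"]
        return float(row.iloc[0]) if len(row) else 0.0

    @property
    def gene_ids(self) -> list[str]:
        return list(self.frame["gene_id"])


def _pair_pvalues(matrix: ExpressionMatrix, regulator_id: str, gene_ids: list[str],
                  method: str = "pearson"):
    """Correlate all genes + regulator, return pairwise triples and p-values."""
    sub = np.vstack([matrix.row(g) for g in gene_ids] + [matrix.row(regulator_id)])
    if method == "spearman":
        sub = np.apply_along_axis(stats.rankdata, 1, sub)
    R = np.corrcoef(sub)
    m = len(gene_ids)
    pairs = list(itertools.combinations(range(m), 2))
    ai = np.array([a for a, _ in pairs])
    bi = np.array([b for _, b in pairs])
    rxy = R[ai, bi]
    rxz = R[ai, m]
    ryz = R[bi, m]
    d, se, z, p = _delta_arrays(rxy, rxz, ryz, matrix.n_samples)
    return pairs, rxy, rxz, ryz, d, se, z, p


def interference_scan(
    matrix: ExpressionMatrix,
    regulator_id: str,
    responsive_ids: list[str],
    config: RunConfig | None = None,
) -> tuple[list[InterferenceRecord], FrequencyTable]:
    """Evaluate all pairs of responsive genes against the regulator.

    Output ordering is deterministic (lexicographic pair ids). With
    ``config.multiplicity == 'bh'`` the pair p-values are Benjamini-Hochberg
    adjusted across the scan before significance flagging.
    """
    config = config or RunConfig()
    if regulator_id not in matrix:
        raise KeyError(f"regulator {regulator_id!r} not in expression matrix")
    gene_ids = sorted(set(responsive_ids))
    if regulator_id in gene_ids:
        gene_ids.remove(regulator_id)
    if len(gene_ids) < 2:
        raise ValueError("interference scan requires >= 2 responsive genes")

    pairs, rxy, rxz, ryz, d, se, z, p = _pair_pvalues(
        matrix, regulator_id, gene_ids, config.correlation
    )
    p_flag = p.copy()
    if config.multiplicity == "bh":
        from .stats import bh_adjust

        p_flag = bh_adjust(p_flag)

    testable = np.isfinite(se) & ~((se == 0) & (d != 0))
    sig = testable & (p_flag < config.interference_alpha)

    records: list[InterferenceRecord] = []
    n_sig = {g: 0 for g in gene_ids}
    denom = np.sqrt((1 - np.clip(rxz, -_CLIP, _CLIP) ** 2) * (1 - np.clip(ryz, -_CLIP, _CLIP) ** 2))
    r_cond = (rxy - rxz * ryz) / denom
    for k, (a, b) in enumerate(pairs):
        rec = InterferenceRecord(
            gene_ids[a], gene_ids[b], float(r_cond[k]), float(d[k]), float(se[k]),
            float(z[k]) if testable[k] else 0.0,
            float(p_flag[k]) if testable[k] else 1.0,
            significant=bool(sig[k]), testable=bool(testable[k]),
        )
        records.append(rec)
        if rec.significant:
            n_sig[rec.x_id] += 1
            n_sig[rec.y_id] += 1

    m = len(gene_ids)
    frame = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "n_significant_pairs": [n_sig[g] for g in gene_ids],
            "n_pairs": m - 1,
            "frequency": [n_sig[g] / (m - 1) for g in gene_ids],
        }
    )
    frame["rank"] = frame["frequency"].rank(ascending=False, method="min").astype(int)
    frame = frame.sort_values(["rank", "gene_id"], kind="stable").reset_index(drop=True)
    return records, FrequencyTable(frame)
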