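"""The responsiveness screen: discretization, Fisher, concordance, selection."""

import itertools
import math

import numpy as np
import pytest

from mlhgrn.io import DEGTable, ExpressionMatrix, RunConfig
from mlhgrn.responsiveness import (
    concordance_probability,
    discretize_expression,
    fisher_responsiveness,
    responsive_ids,
    select_responsive,
)
import pandas as pd


class TestDiscretize:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([1, 2, 3, 4], [0, 0, 1, 1]),
            ([1, 2, 2, 3], [0, 0, 0, 1]),  # ties at the median go to state 0
        ],
    )
    def test_median_split(self, values, expected):
        assert discretize_expression(np.array(values, float)).tolist() == expected

    def test_constant_gene_is_an_error(self):
        with pytest.raises(ValueError, match="constant"):
            discretize_expression(np.array([5.0, 5, 5, 5]))


def _brute_force_fisher(table):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-12))


class TestFisher:
    def test_perfectly_concordant_table(self):
        reg = np.array([1] * 5 + [0] * 5)
        gene = reg.copy()
        table, p = fisher_responsiveness(reg, gene)
        assert table.tolist() == [[5, 0], [0, 5]]
        assert p == pytest.approx(2 / 252, rel=1e-9)

    def test_balanced_table_has_p_one(self):
        reg = np.array([0, 0, 0, 1, 1, 1] * 2)
        gene = np.array([0, 0, 1, 0, 1, 1, 1, 1, 0, 1, 0, 0])
        table, p = fisher_responsiveness(reg, gene)
        assert table.tolist() == [[3, 3], [3, 3]]
        assert p == pytest.approx(1.0)

    def test_zero_margin_gives_p_one(self, caplog):
        reg = np.ones(8, dtype=int)
        gene = np.array([0, 1] * 4)
        with caplog.at_level("WARNING"):
            _, p = fisher_responsiveness(reg, gene)
        assert p == 1.0
        assert "margin" in caplog.text

    def test_matches_brute_force_enumeration_exactly(self, rng):
        """Implementation equals full enumeration over all margins, n <= 30."""
        for _ in range(300):
            n = int(rng.integers(4, 31))
            reg = (rng.random(n) < rng.uniform(0.2, 0.8)).astype(int)
            gene = (rng.random(n) < rng.uniform(0.2, 0.8)).astype(int)
            table, p = fisher_responsiveness(reg, gene)
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                continue
            assert p == pytest.approx(_brute_force_fisher(table.tolist()), rel=1e-9)


class TestConcordance:
    def test_perfect_concordance_n10(self):
        v = np.array([0, 1] * 5)
        k, p = concordance_probability(v, v)
        assert k == 10
        assert p == pytest.approx(1 / 1024)

    def test_half_concordance_n10(self):
        reg = np.array([0] * 5 + [1] * 5)
        gene = np.array([0, 0, 0, 1, 1, 0, 0, 0, 1, 1])
        k, p = concordance_probability(reg, gene)
        assert k == 5
        assert p == pytest.approx(0.623046875)

    def test_anti_concordant_scores_like_concordant(self, rng):
        reg = (rng.random(20) < 0.5).astype(int)
        _, p_conc = concordance_probability(reg, reg)
        _, p_anti = concordance_probability(reg, 1 - reg)
        assert p_conc == p_anti

    def test_flip_invariance(self, rng):
        for _ in range(20):
            a = (rng.random(16) < 0.5).astype(int)
            b = (rng.random(16) < 0.5).astype(int)
            baseline = concordance_probability(a, b)[1]
            assert concordance_probability(1 - a, b)[1] == pytest.approx(baseline)
            assert concordance_probability(a, 1 - b)[1] == pytest.approx(baseline)


def _deg_table(ids):
    return DEGTable(
        pd.DataFrame(
            {"gene_id": list(ids), "log2fc": 1.0, "p": 1e-4, "fdr": 1e-3, "direction": "up"}
        )
    )


class TestSelectResponsive:
    def test_planted_direct_targets_all_flagged(self, default_truth, default_matrix):
        degs = _deg_table(default_truth.layer2_ids)
        res = select_responsive(default_matrix, default_truth.regulator_id, degs)
        assert set(responsive_ids(res)) == set(default_truth.layer2_ids)

    def test_null_flag_rate_bounded(self):
        """On pure-noise decoys the responsive fraction stays below 2x alpha."""
        from mlhgrn.simulate import simulate_expression, simulate_network_truth

        rates = []
        for seed in range(50):
            t = simulate_network_truth(0, 0.0, 0, 60, seed=seed)
            mat = simulate_expression(t, 10)  # n = 40
            res = select_responsive(mat, t.regulator_id, _deg_table(t.decoy_genes))
            rates.append(len(responsive_ids(res)) / len(res))
        assert np.mean(rates) <= 2 * 0.15

    def test_degs_absent_from_matrix_are_skipped(self, default_matrix, default_truth, caplog):
        degs = _deg_table(["nope1", "nope2"])
        with caplog.at_level("WARNING"):
            res = select_responsive(default_matrix, default_truth.regulator_id, degs)
        assert res == []
        assert "skipped" in caplog.text or "empty" in caplog.text

    def test_constant_regulator_is_a_hard_error(self):
        mat = ExpressionMatrix(
            ["z", "a"], ["s1", "s2", "s3", "s4"],
            np.array([[1.0, 1, 1, 1], [1, 2, 3, 4]]), ["WT"] * 4,
        )
        with pytest.raises(ValueError, match="constant"):
            select_responsive(mat, "z", _deg_table(["a"]))

    def test_constant_gene_reported_untestable(self, default_truth):
        from mlhgrn.simulate import simulate_expression

        mat = simulate_expression(default_truth, 5)
        mat.values[mat._index()["DEC000"]] = 3.14
        res = select_responsive(mat, default_truth.regulator_id, _deg_table(["DEC000"]))
        assert len(res) == 1 and not res[0].testable and not res[0].responsive

    def test_shrinking_alpha_shrinks_selection(self, default_truth, default_matrix):
        degs = _deg_table(default_truth.layer2_ids + default_truth.decoy_genes[:50])
        loose = RunConfig(fisher_alpha=0.15, concordance_alpha=0.15)
        tight = RunConfig(fisher_alpha=0.01, concordance_alpha=0.01)
        r_loose = set(responsive_ids(select_responsive(
            default_matrix, default_truth.regulator_id, degs, loose)))
        r_tight = set(responsive_ids(select_responsive(
            default_matrix, default_truth.regulator_id, degs, tight)))
        assert r_tight <= r_loose
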