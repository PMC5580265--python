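"""Summary-table arithmetic, Fisher/FDR, trend test, Wilcoxon."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from orthotss.stats_report import (
    class_count_row,
    fisher_conservation_fdr,
    fisher_exact_p,
    trend_test_linear,
    wilcoxon_paired,
)


def enumerate_fisher_p(table):
    """Independent oracle: two-sided Fisher p by hypergeometric enumeration."""
    a, b = table[0]
    c, d = table[1]
    r1, c1, n = a + b, a + c, a + b + c + d
    k_min, k_max = max(0, r1 + c1 - n), min(r1, c1)
    pmf = {k: sps.hypergeom.pmf(k, n, r1, c1) for k in range(k_min, k_max + 1)}
    p_obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-7)))


def enumerate_signed_rank_p(d):
    """Independent oracle: exact two-sided signed-rank p by 2^n enumeration."""
    d = np.asarray(d, float)
    d = d[d != 0]
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.asarray(ws)
    eps = 1e-9
    p_low = np.mean(ws <= w_obs + eps)
    p_high = np.mean(ws >= w_obs - eps)
    return float(min(1.0, 2 * min(p_low, p_high)))


class TestClassCountRow:
    def test_row_identity(self):
        row = class_count_row("g", 100, 40, 30)
        assert row["n_ortho_tss"] + row["n_singleton"] == row["n_tss"]
        assert row["pct_ortho"] + row["pct_singleton"] == 100
        assert row["mean_tss_per_pair"] == 2.5

    def test_empty_class_is_all_zero(self):
        row = class_count_row("a", 0, 0, 0)
        assert row["n_tss"] == 0 and row["mean_tss_per_pair"] == 0.0
        assert row["pct_ortho"] == 0


class TestFisher:
    def test_uniform_table_carries_no_signal(self):
        assert fisher_exact_p(np.array([[1, 1], [1, 1]])) == 1.0

    def test_zero_margin_convention(self):
        assert fisher_exact_p(np.array([[0, 0], [3, 5]])) == 1.0

    def test_matches_enumeration_on_random_tables(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            table = rng.integers(0, 12, size=(2, 2))
            if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
                continue
            assert fisher_exact_p(table) == pytest.approx(
                enumerate_fisher_p(table), rel=1e-8, abs=1e-12
            )

    def test_bh_q_monotone_in_p_rank(self):
        tables = {
            "t1": np.array([[20, 5], [5, 20]]),
            "t2": np.array([[10, 8], [8, 10]]),
            "t3": np.array([[9, 9], [9, 9]]),
        }
        out = fisher_conservation_fdr(tables)
        ordered = out.sort_values("p")
        assert ordered["q"].is_monotonic_increasing
        assert (out["q"] >= out["p"]).all()


class TestTrend:
    def test_flat_profile(self):
        z, p, direction = trend_test_linear([(10, 100), (10, 100), (10, 100)])
        assert (z, p, direction) == (0.0, 1.0, "none")

    def test_strong_increasing_trend(self):
        z, p, direction = trend_test_linear([(10, 100), (50, 100), (90, 100)])
        assert direction == "increasing"
        assert z == pytest.approx(80 / np.sqrt(50))
        assert p < 1e-3

    def test_decreasing_trend(self):
        _, p, direction = trend_test_linear([(90, 100), (50, 100), (10, 100)])
        assert direction == "decreasing" and p < 1e-3

    def test_too_few_bins_error(self):
        with pytest.raises(ValueError):
            trend_test_linear([(5, 10), (0, 0)])

    def test_empty_bins_ignored(self):
        z1 = trend_test_linear([(10, 100), (0, 0), (90, 100)])[0]
        assert z1 != 0.0


class TestWilcoxon:
    def test_identical_vectors(self):
        assert wilcoxon_paired([1, 2, 3], [1, 2, 3]) == (1.0, "none")

    def test_ten_constant_positive_differences(self):
        x = np.arange(10, dtype=float) + 5
        y = np.arange(10, dtype=float)
        p, direction = wilcoxon_paired(x, y)
        assert p == pytest.approx(2 / 2**10)
        assert direction == "greater"

    def test_matches_enumeration_small_n(self):
        rng = np.random.default_rng(8)
        for n in (5, 8, 11):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            p, _ = wilcoxon_paired(x, y)
            assert p == pytest.approx(enumerate_signed_rank_p(x - y), abs=1e-12)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            wilcoxon_paired([1, 2], [1, 2, 3])


def test_conservation_power_at_planted_effect():
    """a-vs-g contrast rejects with power >= 0.8 at a planted conservation gap.

    Simulates the class-level ortholog/singleton counts at pipeline scale
    (400 TSSs per class, 45% vs 30% orthologous) 200 times and requires the
    BH-adjusted a-vs-g Fisher comparison to reject at alpha = 0.05 in at
    least 80% of replicates.
    """
    rng = np.random.default_rng(12)
    n, p_a, p_g, p_i = 400, 0.45, 0.30, 0.30
    rejections = 0
    for _ in range(200):
        k_a = rng.binomial(n, p_a)
        k_g = rng.binomial(n, p_g)
        k_i = rng.binomial(n, p_i)
        tables = {
            "g-a": np.array([[k_g, k_a], [n - k_g, n - k_a]]),
            "g-i": np.array([[k_g, k_i], [n - k_g, n - k_i]]),
            "a-i": np.array([[k_a, k_i], [n - k_a, n - k_i]]),
        }
        out = fisher_conservation_fdr(tables)
        if out.loc["g-a", "q"] < 0.05:
            rejections += 1
    assert rejections / 200 >= 0.8
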