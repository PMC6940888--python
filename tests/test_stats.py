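"""Nonparametric battery: oracle agreement, hand-computed cases, invariances."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from pecktrack.stats import (
    bonferroni,
    catch_and_throw_summary,
    chi_square_independence,
    descriptive_table,
    moods_median_test,
    run_battery,
    spearman,
)


def _textbook_spearman(x, y):
    """Independent oracle: explicit average ranks + explicit Pearson sums."""
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den


class TestSpearman:
    def test_perfect_monotone_is_one(self):
        x = np.array([1.0, 2.5, 3.0, 7.0, 9.0])
        assert spearman(x, np.exp(x)).statistic == 1.0

    def test_antitone_is_minus_one(self):
        x = np.array([1.0, 2.5, 3.0, 7.0, 9.0])
        assert spearman(x, -x).statistic == -1.0

    def test_matches_textbook_formula_with_ties(self):
        x = [1.0, 2.0, 2.0, 4.0, 5.0, 6.0]
        y = [3.0, 1.0, 4.0, 4.0, 6.0, 5.0]
        assert spearman(x, y).statistic == pytest.approx(
            _textbook_spearman(x, y), abs=1e-12
        )

    def test_matches_scipy_on_random_tied_data(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(5, 50))
            x = np.round(rng.normal(size=n), 1)
            y = np.round(rng.normal(size=n) + 0.3 * x, 1)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            mine = spearman(x, y)
            ref = sps.spearmanr(x, y)
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-12)
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_constant_input_flagged(self):
        res = spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert math.isnan(res.statistic)
        assert "constant-input" in res.flags

    def test_exact_permutation_small_n(self):
        # perfect monotone n=6 without ties: only the identity and the full
        # reversal reach |rho| = 1, hence p = 2/720
        x = np.arange(6.0)
        res = spearman(x, x * 2 + 1, method="exact")
        assert res.p_value == pytest.approx(2 / 720, abs=1e-12)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        base = spearman(x, y).statistic
        assert spearman(np.exp(x), y).statistic == pytest.approx(base, abs=1e-12)
        assert spearman(x, 3 * y + 7).statistic == pytest.approx(base, abs=1e-12)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestMoodsMedian:
    def test_identical_groups_give_zero_statistic(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = moods_median_test([g, g])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_fully_separated_two_groups(self):
        """{1,1,1,1} vs {9,9,9,9}: table (0,4;4,0), chi-square 8 with 1 df."""
        res = moods_median_test([[1.0] * 4, [9.0] * 4])
        assert res.statistic == pytest.approx(8.0, abs=1e-12)
        assert res.df == 1

    def test_matches_explicit_count_oracle(self):
        """Equality with the hand-built 2xk table fed to the chi-square test,
        and with scipy's implementation, over 100 random datasets."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            k = int(rng.integers(2, 5))
            groups = [
                np.round(rng.normal(rng.uniform(-1, 1), 1, size=int(rng.integers(5, 30))), 1)
                for _ in range(k)
            ]
            res = moods_median_test(groups)
            grand = np.median(np.concatenate(groups))
            table = np.array(
                [[int((g > grand).sum()) for g in groups],
                 [int((g <= grand).sum()) for g in groups]]
            )
            if table.sum(axis=1).min() == 0:
                continue
            oracle = chi_square_independence(table)
            assert res.statistic == pytest.approx(oracle.statistic, abs=1e-12)
            assert res.p_value == pytest.approx(oracle.p_value, abs=1e-12)
            s, p, _, _ = sps.median_test(*groups, ties="below", correction=False)
            assert res.statistic == pytest.approx(s, abs=1e-12)
            assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_tie_handling_options(self):
        groups = [[1.0, 2.0, 2.0], [2.0, 3.0, 4.0]]  # grand median = 2
        below = moods_median_test(groups, ties="below")
        above = moods_median_test(groups, ties="above")
        ignore = moods_median_test(groups, ties="ignore")
        assert below.auxiliary["table"].tolist() == [[0, 2], [3, 1]]
        assert above.auxiliary["table"].tolist() == [[2, 3], [1, 0]]
        assert ignore.auxiliary["table"].tolist() == [[0, 2], [1, 0]]

    def test_degenerate_identical_values_flagged(self):
        res = moods_median_test([[5.0, 5.0], [5.0, 5.0]])
        assert "degenerate" in res.flags
        assert math.isnan(res.statistic)

    def test_low_expected_counts_flagged(self):
        res = moods_median_test([[1.0, 2.0], [3.0, 4.0]])
        assert "low-expected-counts" in res.flags


class TestChiSquare:
    def test_independent_table_scores_zero(self):
        assert chi_square_independence([[10, 20], [10, 20]]).statistic == pytest.approx(
            0.0, abs=1e-12
        )

    def test_hand_computed_2x2(self):
        """(10,20;20,10): all expected counts 15, chi-square = 4*25/15."""
        res = chi_square_independence([[10, 20], [20, 10]])
        assert res.statistic == pytest.approx(20.0 / 3.0, abs=1e-12)
        assert res.df == 1

    def test_2x3_has_two_df(self):
        assert chi_square_independence([[5, 6, 7], [7, 6, 5]]).df == 2

    def test_zero_margin_is_hard_error(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_independence([[0, 0], [5, 5]])

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            t = rng.integers(1, 40, size=(2, int(rng.integers(2, 6))))
            res = chi_square_independence(t)
            ref = sps.chi2_contingency(t, correction=False)
            assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)
            assert res.df == ref.dof


def _records_df(rows):
    return pd.DataFrame(
        rows, columns=["feed_type", "order", "max_gape_mm", "catch_and_throw"]
    )


class TestDescriptives:
    def test_two_value_cell(self):
        df = _records_df([("F1", 1, 2.0, False), ("F1", 1, 4.0, False)])
        out = descriptive_table(df, ["max_gape_mm"])
        row = out.iloc[0]
        assert (row["mean"], row["se"], row["median"], row["n"]) == (3.0, 1.0, 3.0, 2)

    def test_single_value_cell_has_no_se(self):
        df = _records_df([("F1", 1, 2.0, False)])
        out = descriptive_table(df, ["max_gape_mm"])
        assert math.isnan(out.iloc[0]["se"])

    def test_matches_two_pass_bruteforce(self):
        rng = np.random.default_rng(9)
        df = _records_df(
            [
                (f"F{rng.integers(1, 4)}", int(rng.integers(1, 5)),
                 float(rng.normal(3, 1)), False)
                for _ in range(200)
            ]
        )
        out = descriptive_table(df, ["max_gape_mm"])
        for _, row in out.iterrows():
            vals = df.loc[
                (df.feed_type == row["feed_type"]) & (df["order"] == row["order"]),
                "max_gape_mm",
            ].to_numpy()
            mean = sum(vals) / len(vals)
            if len(vals) > 1:
                sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (len(vals) - 1))
                assert row["se"] == pytest.approx(sd / math.sqrt(len(vals)), abs=1e-12)
            assert row["mean"] == pytest.approx(mean, abs=1e-12)

    def test_monte_carlo_mean_recovery(self):
        """1000 draws from Normal(4.3, 1): the cell mean lands within 0.1 of
        the population mean (chick-scale gape magnitudes)."""
        rng = np.random.default_rng(12)
        df = _records_df([("F1", 1, float(v), False) for v in rng.normal(4.3, 1.0, 1000)])
        out = descriptive_table(df, ["max_gape_mm"])
        assert out.iloc[0]["mean"] == pytest.approx(4.3, abs=0.1)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            descriptive_table(_records_df([]))


class TestCatchAndThrowSummary:
    def test_simple_ratio(self):
        rows = [("F1", 1, 3.0, i < 26) for i in range(100)]
        out = catch_and_throw_summary(_records_df(rows))
        assert out["per_feed_pct"]["F1"] == pytest.approx(26.0)

    def test_all_flagged_is_hundred_percent(self):
        rows = [("F2", 1, 3.0, True) for _ in range(7)]
        out = catch_and_throw_summary(_records_df(rows))
        assert out["per_feed_pct"]["F2"] == 100.0

    def test_missing_feed_absent(self):
        out = catch_and_throw_summary(_records_df([("F1", 1, 3.0, False)]))
        assert "F3" not in out["per_feed_pct"]

    def test_scripted_rate_within_binomial_ci(self):
        """551 Bernoulli(0.33) flags: the recovered percentage falls inside
        the binomial 95% interval around 33%."""
        rng = np.random.default_rng(33)
        n = 551
        rows = [("F3", 1, 3.0, bool(rng.random() < 0.33)) for _ in range(n)]
        out = catch_and_throw_summary(_records_df(rows))
        half = 1.96 * math.sqrt(0.33 * 0.67 / n) * 100
        assert abs(out["per_feed_pct"]["F3"] - 33.0) <= half


def test_bonferroni_caps_at_one():
    assert bonferroni([0.01, 0.4, 0.9]) == [0.03, 1.0, 1.0]


def test_run_battery_structure():
    rng = np.random.default_rng(2)
    rows = []
    for feed in ("F1", "F2", "F3"):
        for order in (1, 2, 3, 4):
            for _ in range(12):
                rows.append(
                    {
                        "feed_type": feed,
                        "order": order,
                        "max_gape_mm": float(rng.normal(3.5, 0.5)),
                        "displacement_mm": float(rng.gamma(2.0, 1.0)),
                        "duration_ms": float(rng.normal(85, 10)),
                        "speed_mm_s": float(rng.gamma(3.0, 10.0)),
                        "catch_and_throw": bool(rng.random() < 0.25),
                    }
                )
    out = run_battery(pd.DataFrame(rows))
    assert set(out) >= {"spearman", "spearman_by_order", "moods", "descriptives",
                        "catch_and_throw", "catch_and_throw_chi2"}
    for res in out["moods"].values():
        assert 0.0 <= res["p_value"] <= 1.0
    assert 0.0 <= out["catch_and_throw_chi2"]["p_value"] <= 1.0
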