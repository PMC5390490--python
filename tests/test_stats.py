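"""Factorial ANOVA arithmetic, Duncan's test vs. brute force, OLS."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from photolim import ValidationError, duncan_test, factorial_anova, simple_regression
from photolim.stats import DUNCAN_TABLE_5PCT, duncan_q


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

def balanced_2x2(cell_means, n, sd, rng):
    rows = []
    for (a, b), mu in cell_means.items():
        for _ in range(n):
            rows.append({"A": a, "B": b, "y": mu + rng.normal(0, sd)})
    return pd.DataFrame(rows)


class TestFactorialAnova:
    def test_additive_effects_have_zero_interaction(self, rng):
        cells = {("a1", "b1"): 10.0, ("a1", "b2"): 12.0,
                 ("a2", "b1"): 20.0, ("a2", "b2"): 22.0}
        df = balanced_2x2(cells, n=3, sd=0.0, rng=rng)
        table = factorial_anova(df, "y", ["A", "B"]).table
        assert table.loc["A:B", "SS"] == pytest.approx(0.0, abs=1e-10)

    def test_single_factor_f_equals_t_squared(self, rng):
        g1 = rng.normal(10, 1, size=8)
        g2 = rng.normal(12, 1, size=8)
        df = pd.DataFrame(
            {"g": ["x"] * 8 + ["y"] * 8, "y": np.concatenate([g1, g2])}
        )
        f = factorial_anova(df, "y", ["g"]).table.loc["g", "F"]
        t = sps.ttest_ind(g1, g2).statistic
        assert f == pytest.approx(t**2, rel=1e-10)

    def test_hand_computed_2x2_partition(self, rng):
        """Balanced 2x2, n=2: SS from the textbook mean-decomposition
        formulas computed independently here."""
        cells = {("a1", "b1"): 10.0, ("a1", "b2"): 12.0,
                 ("a2", "b1"): 20.0, ("a2", "b2"): 26.0}
        df = balanced_2x2(cells, n=2, sd=1.0, rng=rng)
        y = df["y"].to_numpy()
        grand = y.mean()
        n, a_levels, b_levels = 2, ("a1", "a2"), ("b1", "b2")
        mean_a = {a: df[df.A == a].y.mean() for a in a_levels}
        mean_b = {b: df[df.B == b].y.mean() for b in b_levels}
        mean_ab = {
            (a, b): df[(df.A == a) & (df.B == b)].y.mean()
            for a in a_levels for b in b_levels
        }
        ss_a = n * len(b_levels) * sum((m - grand) ** 2 for m in mean_a.values())
        ss_b = n * len(a_levels) * sum((m - grand) ** 2 for m in mean_b.values())
        ss_ab = n * sum(
            (mean_ab[(a, b)] - mean_a[a] - mean_b[b] + grand) ** 2
            for a in a_levels for b in b_levels
        )
        ss_res = sum(
            (v - mean_ab[(a, b)]) ** 2
            for a, b, v in zip(df.A, df.B, df.y)
        )
        table = factorial_anova(df, "y", ["A", "B"]).table
        assert table.loc["A", "SS"] == pytest.approx(ss_a, abs=1e-8)
        assert table.loc["B", "SS"] == pytest.approx(ss_b, abs=1e-8)
        assert table.loc["A:B", "SS"] == pytest.approx(ss_ab, abs=1e-8)
        assert table.loc["Residual", "SS"] == pytest.approx(ss_res, abs=1e-8)
        # exact orthogonal partition for balanced data
        total = ((y - grand) ** 2).sum()
        assert table["SS"].sum() == pytest.approx(total, rel=1e-8)

    def test_empty_cell_is_an_error(self, rng):
        cells = {("a1", "b1"): 10.0, ("a1", "b2"): 12.0, ("a2", "b1"): 20.0}
        df = balanced_2x2(cells, n=2, sd=1.0, rng=rng)
        with pytest.raises(ValidationError, match="empty design cell"):
            factorial_anova(df, "y", ["A", "B"])

    def test_unbalanced_warns_type_ii(self, rng):
        cells = {("a1", "b1"): 10.0, ("a1", "b2"): 12.0,
                 ("a2", "b1"): 20.0, ("a2", "b2"): 26.0}
        df = balanced_2x2(cells, n=3, sd=1.0, rng=rng).drop(index=[0])
        with pytest.warns(UserWarning, match="Type II"):
            res = factorial_anova(df, "y", ["A", "B"])
        assert not res.balanced


# ---------------------------------------------------------------------------
# Duncan's multiple range test
# ---------------------------------------------------------------------------

def brute_force_duncan(means, ms_error, df_error, n, alpha=0.05):
    """Independent oracle: a pair is non-significant iff ANY enclosing
    span (itself included) has a range not exceeding its own least
    significant range."""
    order = np.argsort(means, kind="stable")
    sorted_means = np.asarray(means)[order]
    k = len(means)
    se = np.sqrt(ms_error / n)
    sig = {}
    for i in range(k):
        for j in range(i + 1, k):
            nonsig = False
            for a in range(0, i + 1):
                for b in range(j, k):
                    p = b - a + 1
                    if sorted_means[b] - sorted_means[a] <= duncan_q(alpha, p, df_error) * se:
                        nonsig = True
            sig[(order[i], order[j])] = not nonsig
    return sig


class TestDuncan:
    def test_wide_separation_distinct_letters(self, rng):
        groups = [
            ("lo", rng.normal(10, 0.1, 5)),
            ("hi", rng.normal(25, 0.1, 5)),
        ]
        res = duncan_test(groups)
        assert res.letters["lo"] != res.letters["hi"]
        assert res.significant[("lo", "hi")]

    def test_identical_groups_share_a_letter(self, rng):
        base = rng.normal(10, 1.0, 5)
        res = duncan_test([("g1", base), ("g2", base + 1e-9), ("g3", base - 1e-9)])
        assert len({res.letters[g] for g in ("g1", "g2", "g3")}) == 1

    def test_matches_brute_force_on_random_instances(self):
        """200 random <= 6-group instances agree with the exhaustive
        pairwise least-significant-range oracle."""
        master = np.random.default_rng(202)
        for trial in range(200):
            k = int(master.integers(2, 7))
            n = int(master.integers(3, 7))
            spread = float(master.uniform(0.5, 4.0))
            data = [
                (f"g{i}", master.normal(master.uniform(0, spread), 1.0, n))
                for i in range(k)
            ]
            res = duncan_test(data)
            means = [v.mean() for _, v in data]
            df_err = sum(len(v) - 1 for _, v in data)
            ms = sum(((v - v.mean()) ** 2).sum() for _, v in data) / df_err
            oracle = brute_force_duncan(means, ms, df_err, n)
            for (i, j), expected in oracle.items():
                got = res.significant[(f"g{i}", f"g{j}")]
                assert got == expected, f"trial {trial}: pair g{i},g{j}"

    def test_shared_letter_iff_not_significant(self, rng):
        data = [(f"g{i}", rng.normal(mu, 1.0, 5))
                for i, mu in enumerate((0.0, 0.5, 3.0, 6.0))]
        res = duncan_test(data)
        for a, _ in data:
            for b, _ in data:
                if a == b:
                    continue
                shares = bool(set(res.letters[a]) & set(res.letters[b]))
                assert shares == (not res.significant[(a, b)])

    def test_unequal_n_uses_harmonic_mean_with_warning(self, rng):
        data = [("a", rng.normal(0, 1, 4)), ("b", rng.normal(5, 1, 6))]
        with pytest.warns(UserWarning, match="harmonic"):
            duncan_test(data)

    def test_critical_values_match_classical_table(self):
        """Numerical inversion reproduces the published 5% significant
        ranges; the p=2 column equals sqrt(2)*t."""
        for df, row in DUNCAN_TABLE_5PCT.items():
            for p, expected in zip(range(2, 7), row):
                assert duncan_q(0.05, p, df) == pytest.approx(expected, abs=5e-3)
            t_based = np.sqrt(2) * sps.t.ppf(0.975, df)
            assert duncan_q(0.05, 2, df) == pytest.approx(t_based, rel=1e-6)


# ---------------------------------------------------------------------------
# regressions
# ---------------------------------------------------------------------------

class TestRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = simple_regression(x, 2 * x)
        assert res.slope == pytest.approx(2.0)
        assert res.r2 == pytest.approx(1.0)

    def test_orthogonal_sample_r2_zero(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        y = np.array([1.0, -1.0, 0.0, -1.0, 1.0])  # <x, y> = 0 by design
        res = simple_regression(x, y)
        assert res.r2 == pytest.approx(0.0, abs=1e-12)

    def test_generator_with_target_r2(self, rng):
        # y = x + e with Var(e) = Var(x) targets R2 = 0.5
        x = rng.normal(0, 1, 200)
        y = x + rng.normal(0, 1, 200)
        res = simple_regression(x, y)
        assert res.r2 == pytest.approx(0.5, abs=0.1)
        assert res.p < 1e-6

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError, match="variance"):
            simple_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
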