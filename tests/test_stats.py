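"""Tests of the cohort statistics: group comparisons, screening, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from hbkg.stats import (
    anova_from_summary,
    benjamini_hochberg,
    compare_k_groups,
    compare_two_groups,
    correlate_age,
    pooled_mean,
    scheffe_pairs,
    screen_predictors,
    t_from_summary,
)

# published subgroup summaries of the index (mean, sd, n)
GENDER = {"male": (1.98, 0.69, 134), "female": (1.76, 0.76, 61)}
BMI = {"I": (2.08, 0.73, 56), "II": (2.06, 0.71, 67), "III": (1.64, 0.64, 72)}
CTD = {"I": (1.84, 0.72, 145), "II": (2.11, 0.68, 50)}


class TestTwoGroups:
    def test_degrees_of_freedom_from_group_sizes(self, rng):
        values = rng.normal(2.0, 0.7, 195)
        labels = np.array(["a"] * 134 + ["b"] * 61)
        comp = compare_two_groups(values, labels)
        assert comp.dfs == (193,)
        assert comp.group_ns == [134, 61]

    def test_summary_entry_point_reproduces_published_t(self):
        t, p, df = t_from_summary(*GENDER["male"], *GENDER["female"])
        assert df == 193
        assert t == pytest.approx(2.031, abs=0.1)
        assert p < 0.06

    def test_zero_variance_degenerate_flag(self):
        comp = compare_two_groups([1.0, 1.0, 1.0, 1.0], ["a", "a", "b", "b"])
        assert comp.degenerate and np.isnan(comp.statistic)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            compare_two_groups([1.0, 2.0, 3.0], ["a", "a", "b"])

    def test_matches_scipy_on_random_data(self, rng):
        x = rng.normal(size=80)
        labels = np.repeat(["a", "b"], 40)
        comp = compare_two_groups(x, labels)
        t, p = sps.ttest_ind(x[:40], x[40:])
        assert comp.statistic == pytest.approx(t)
        assert comp.p_value == pytest.approx(p)


class TestAnova:
    def test_degrees_of_freedom(self, rng):
        values = rng.normal(2.0, 0.7, 195)
        labels = np.array(["I"] * 56 + ["II"] * 67 + ["III"] * 72)
        comp = compare_k_groups(values, labels)
        assert comp.dfs == (2, 192)

    def test_summary_entry_point_reproduces_published_f(self):
        f, p, dfs, eta2 = anova_from_summary(
            *zip(*[BMI[g] for g in ("I", "II", "III")]))
        assert dfs == (2, 192)
        assert f == pytest.approx(8.367, abs=0.5)
        assert p < 0.001
        assert eta2 == pytest.approx(0.08, abs=0.02)

    def test_constant_groups_degenerate(self):
        comp = compare_k_groups([5.0] * 9, ["a", "b", "c"] * 3)
        assert comp.degenerate and comp.eta_squared == 0.0

    def test_f_equals_t_squared_for_two_groups(self, rng):
        x = rng.normal(size=60)
        labels = np.repeat(["a", "b"], 30)
        t = compare_two_groups(x, labels).statistic
        f, _ = sps.f_oneway(x[:30], x[30:])
        assert f == pytest.approx(t**2, rel=1e-10)

    def test_eta_squared_matches_two_pass_oracle(self, rng):
        values = rng.normal(size=90)
        labels = rng.choice(list("abc"), size=90)
        comp = compare_k_groups(values, labels)
        grand = values.mean()
        ss_b = sum((values[labels == g].mean() - grand) ** 2 * (labels == g).sum()
                   for g in "abc")
        ss_t = ((values - grand) ** 2).sum()
        assert comp.eta_squared == pytest.approx(ss_b / ss_t, rel=1e-10)

    def test_scheffe_detects_the_separated_pair(self, rng):
        groups = [rng.normal(0, 1, 50), rng.normal(0.1, 1, 50), rng.normal(2.0, 1, 50)]
        pairs = dict(scheffe_pairs(groups))
        assert pairs[(0, 2)] < 0.001
        assert pairs[(1, 2)] < 0.001
        assert pairs[(0, 1)] > 0.05


class TestPartitionConsistency:
    def test_published_partitions_imply_the_same_cohort_mean(self):
        # internal-consistency check across three partitions of one cohort
        means = [
            pooled_mean(*zip(*[(m, n) for m, _, n in part.values()]))
            for part in (GENDER, BMI, CTD)
        ]
        for a in means:
            for b in means:
                assert abs(a - b) < 0.01


class TestCorrelateAge:
    def test_identity_and_antisymmetry(self):
        x = np.arange(10.0)
        assert correlate_age(x, x)[0] == pytest.approx(1.0)
        assert correlate_age(-x, x)[0] == pytest.approx(-1.0)

    def test_degenerate_constant_vector(self):
        r, p = correlate_age([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(r)

    def test_null_type_i_error_rate(self):
        # 10^4 independent pairs at n = 195: empirical alpha within 3 SE
        rng = np.random.default_rng(202)
        n, reps, alpha = 195, 10_000, 0.05
        x = rng.normal(size=(reps, n))
        y = rng.normal(size=(reps, n))
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        r = (xc * yc).sum(axis=1) / np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p = 2 * sps.t.sf(np.abs(t), n - 2)
        rate = (p < alpha).mean()
        se = np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rate - alpha) < 3 * se
        # and the vectorised null agrees with correlate_age on one pair
        r0, p0 = correlate_age(y[0], x[0])
        assert r0 == pytest.approx(r[0], abs=1e-12)


class TestScreening:
    def test_target_as_its_own_predictor(self, rng):
        df = pd.DataFrame({"y_copy": np.arange(20.0), "noise": rng.normal(size=20)})
        out = screen_predictors(df, np.arange(20.0), ["y_copy", "noise"])
        row = out.set_index("predictor").loc["y_copy"]
        assert row["rho"] == pytest.approx(1.0)
        assert bool(row["retained"])

    def test_constant_predictor_excluded_with_flag(self, rng):
        df = pd.DataFrame({"const": np.ones(30), "x": rng.normal(size=30)})
        out = screen_predictors(df, rng.normal(size=30), ["const", "x"])
        row = out.set_index("predictor").loc["const"]
        assert bool(row["degenerate"]) and not bool(row["retained"])

    def test_matches_scipy_spearman(self, rng):
        df = pd.DataFrame(rng.normal(size=(60, 5)), columns=list("abcde"))
        y = rng.normal(size=60)
        out = screen_predictors(df, y).set_index("predictor")
        for c in "abcde":
            rho, p = sps.spearmanr(df[c], y)
            assert out.loc[c, "rho"] == pytest.approx(rho, abs=1e-12)
            assert out.loc[c, "p_value"] == pytest.approx(p, rel=1e-6)

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_rho_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        df = pd.DataFrame({"x": x, "xt": np.exp(2 * x)})
        out = screen_predictors(df, y, ["x", "xt"]).set_index("predictor")
        assert out.loc["x", "rho"] == pytest.approx(out.loc["xt", "rho"], abs=1e-12)
        yt = y**3  # strictly monotone on all reals
        out2 = screen_predictors(df, yt, ["x"]).set_index("predictor")
        assert out2.loc["x", "rho"] == pytest.approx(out.loc["x", "rho"], abs=1e-12)

    def test_bh_flag_is_more_conservative(self, rng):
        df = pd.DataFrame(rng.normal(size=(100, 40)),
                          columns=[f"n{i}" for i in range(40)])
        y = rng.normal(size=100)
        raw = screen_predictors(df, y, alpha=0.05)
        adj = screen_predictors(df, y, alpha=0.05, bh=True)
        assert adj["retained"].sum() <= raw["retained"].sum()

    def test_bh_matches_reference_on_known_pvalues(self):
        p = np.array([0.01, 0.02, 0.03, 0.5])
        expected = np.array([0.04, 0.04, 0.04, 0.5])
        np.testing.assert_allclose(benjamini_hochberg(p), expected)
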