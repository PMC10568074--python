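"""Group statistics: ANOVA, Games-Howell, normality, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from stairmwi import (
    GroupSample,
    games_howell,
    ks_normality,
    one_way_anova,
    summarize_cohort,
)
from stairmwi.errors import DegenerateDataError, DomainError


class TestAnova:
    def test_hand_computed_example(self):
        # SSB = 42, SSW = 6 -> F = (42/2)/(6/6) = 21
        groups = [GroupSample("a", [1, 2, 3]), GroupSample("b", [2, 3, 4]),
                  GroupSample("c", [6, 7, 8])]
        f, df1, df2, p = one_way_anova(groups)
        assert f == pytest.approx(21.0, rel=1e-12)
        assert (df1, df2) == (2, 6)
        assert p == pytest.approx(float(sps.f.sf(21.0, 2, 6)), rel=1e-12)

    def test_identical_groups_give_zero_f(self):
        groups = [GroupSample("a", [1, 2, 3]), GroupSample("b", [1, 2, 3])]
        f, *_ = one_way_anova(groups)
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_two_groups_equals_squared_pooled_t(self, rng):
        x = rng.normal(0, 1, 12)
        y = rng.normal(0.5, 1, 15)
        f, _, _, p_f = one_way_anova([GroupSample("x", x), GroupSample("y", y)])
        t, p_t = sps.ttest_ind(x, y, equal_var=True)
        assert f == pytest.approx(t**2, rel=1e-10)
        assert p_f == pytest.approx(p_t, rel=1e-10)

    def test_affine_invariance(self, rng):
        groups = [GroupSample(str(i), rng.normal(i, 1, 9)) for i in range(3)]
        scaled = [GroupSample(g.name, 3.7 * np.asarray(g.values) - 11.0)
                  for g in groups]
        assert one_way_anova(groups)[0] == pytest.approx(
            one_way_anova(scaled)[0], rel=1e-10)

    def test_degenerate_inputs(self):
        with pytest.raises(DomainError):
            one_way_anova([GroupSample("a", [1, 2, 3])])
        with pytest.raises(DegenerateDataError):
            one_way_anova([GroupSample("a", [1.0, 1.0]),
                           GroupSample("b", [2.0, 2.0])])

    def test_type_i_error_calibration(self, rng):
        """Null ANOVA rejects at ~5% with n=7 per group (vectorised sim)."""
        n_sim, k, n = 10_000, 3, 7
        x = rng.normal(size=(n_sim, k, n))
        gm = x.mean(axis=(1, 2), keepdims=True)
        ssb = n * ((x.mean(axis=2, keepdims=True) - gm) ** 2).sum(axis=(1, 2))
        ssw = ((x - x.mean(axis=2, keepdims=True)) ** 2).sum(axis=(1, 2))
        f = (ssb / (k - 1)) / (ssw / (k * (n - 1)))
        rej = np.mean(f > sps.f.ppf(0.95, k - 1, k * (n - 1)))
        assert rej == pytest.approx(0.05, abs=0.01)


class TestGamesHowell:
    def test_hand_computed_welch_pair(self):
        groups = [GroupSample("a", [1, 2, 3]), GroupSample("b", [2, 3, 4]),
                  GroupSample("c", [6, 7, 8])]
        res = {c.pair: c for c in games_howell(groups)}
        ac = res[("a", "c")]
        assert ac.statistic == pytest.approx(-6.12372, abs=1e-4)
        assert ac.welch_df == pytest.approx(4.0, rel=1e-10)

    def test_identical_groups_not_significant(self):
        g = [GroupSample("a", [1, 2, 3, 4]), GroupSample("b", [1, 2, 3, 4])]
        res = games_howell(g)
        assert res[0].mean_diff == 0.0
        assert res[0].p_adjusted == pytest.approx(1.0, abs=1e-9)

    def test_matches_pingouin_reference(self, rng):
        """Cross-check t, df and adjusted p against pingouin."""
        pingouin = pytest.importorskip("pingouin")
        vals = np.concatenate([rng.normal(0, 1, 8), rng.normal(0.8, 2, 12),
                               rng.normal(-0.5, 0.5, 7)])
        labels = ["a"] * 8 + ["b"] * 12 + ["c"] * 7
        df = pd.DataFrame({"y": vals, "g": labels})
        ref = pingouin.pairwise_gameshowell(data=df, dv="y", between="g")
        groups = [GroupSample(n, df.loc[df.g == n, "y"]) for n in ("a", "b", "c")]
        mine = {tuple(sorted(c.pair)): c for c in games_howell(groups)}
        for _, row in ref.iterrows():
            c = mine[tuple(sorted((row["A"], row["B"])))]
            assert abs(c.statistic) == pytest.approx(abs(row["T"]), rel=1e-6)
            assert c.welch_df == pytest.approx(row["df"], rel=1e-6)
            assert c.p_adjusted == pytest.approx(row["pval"], abs=1e-6)

    def test_reduces_to_tukey_for_large_balanced_groups(self, rng):
        """With equal variances/sizes and large n, GH converges to Tukey."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        n = 400
        base = rng.normal(0, 1, n)
        groups = [GroupSample(name, base + shift)
                  for name, shift in (("a", 0.0), ("b", 0.05), ("c", 0.1))]
        gh = {tuple(sorted(c.pair)): c.p_adjusted for c in games_howell(groups)}
        vals = np.concatenate([np.asarray(g.values) for g in groups])
        labs = np.repeat(["a", "b", "c"], n)
        tk = pairwise_tukeyhsd(vals, labs)
        for (g1, g2), p_adj in zip(
                [tuple(sorted((a, b))) for a, b in
                 zip(tk.groupsunique[tk._multicomp.pairindices[0]],
                     tk.groupsunique[tk._multicomp.pairindices[1]])],
                tk.pvalues):
            assert gh[(g1, g2)] == pytest.approx(p_adj, abs=2e-3)

    def test_degenerate_variance_names_group(self):
        groups = [GroupSample("flat", [2.0, 2.0, 2.0]),
                  GroupSample("ok", [1.0, 2.0, 3.0])]
        with pytest.raises(DegenerateDataError, match="flat"):
            games_howell(groups)

    def test_familywise_error_calibrated(self, rng):
        """Family-wise type-I error ~5% under the global null (n=7, k=3).

        Vectorised oracle: per simulation compute all pairwise q = |t|*sqrt(2)
        and Welch dfs directly, and reject when any q exceeds the
        interpolated studentized-range critical value for its df.
        """
        n_sim, k, n = 10_000, 3, 7
        x = rng.normal(size=(n_sim, k, n))
        m = x.mean(axis=2)
        v = x.var(axis=2, ddof=1) / n
        pairs = [(0, 1), (0, 2), (1, 2)]
        df_grid = np.linspace(6.0, 12.0, 61)
        crit = sps.studentized_range.ppf(0.95, k, df_grid)
        any_reject = np.zeros(n_sim, dtype=bool)
        for i, j in pairs:
            se2 = v[:, i] + v[:, j]
            q = np.abs(m[:, i] - m[:, j]) / np.sqrt(se2) * np.sqrt(2.0)
            df = se2**2 / (v[:, i] ** 2 / (n - 1) + v[:, j] ** 2 / (n - 1))
            any_reject |= q > np.interp(df, df_grid, crit)
        fwer = float(np.mean(any_reject))
        assert fwer == pytest.approx(0.05, abs=0.01)
        # spot-check the vectorised oracle against games_howell itself
        for s in range(25):
            groups = [GroupSample(str(g), x[s, g]) for g in range(k)]
            res = games_howell(groups)
            assert any(c.p_adjusted < 0.05 for c in res) == bool(any_reject[s])


class TestKsNormality:
    def test_normal_samples_usually_pass(self, rng):
        n_pass = 0
        for _ in range(200):
            sample = GroupSample("g", rng.normal(3.0, 0.5, 1000))
            _, p = ks_normality(sample)
            n_pass += p > 0.05
        assert n_pass >= 180

    def test_perfect_normal_quantiles_minimise_statistic(self, rng):
        n = 100
        q = sps.norm.ppf((np.arange(n) + 0.5) / n)
        stat_q, _ = ks_normality(GroupSample("q", q))
        stat_r, _ = ks_normality(GroupSample("r", rng.normal(size=n)))
        assert stat_q < stat_r
        assert stat_q < 1.0 / np.sqrt(n)

    def test_bimodal_sample_rejected(self, rng):
        vals = np.concatenate([rng.normal(-5, 1, 50), rng.normal(5, 1, 50)])
        _, p = ks_normality(GroupSample("bi", vals))
        assert p < 0.01

    def test_plain_ks_variant_available(self, rng):
        sample = GroupSample("g", rng.normal(0, 1, 50))
        stat_l, _ = ks_normality(sample, lilliefors_correction=True)
        stat_k, p_k = ks_normality(sample, lilliefors_correction=False)
        assert stat_l == pytest.approx(stat_k, rel=1e-10)
        assert 0 <= p_k <= 1

    def test_degenerate_and_tiny_samples(self):
        with pytest.raises(DomainError):
            ks_normality(GroupSample("tiny", [1, 2, 3]))
        with pytest.raises(DegenerateDataError):
            ks_normality(GroupSample("flat", [1.0] * 10))


class TestSummarizeCohort:
    @staticmethod
    def _table(rng):
        rows = []
        for g, mu in (("NWM", 0.099), ("NAWM", 0.085), ("lesion", 0.036)):
            for i in range(20):
                rows.append({"subject_id": f"{g}{i}", "group": g,
                             "roi_name": "r", "value": rng.normal(mu, 0.013)})
        return pd.DataFrame(rows)

    def test_report_structure_and_ci_contains_mean(self, rng):
        report = summarize_cohort(self._table(rng))
        assert [g.name for g in report.groups] == ["NWM", "NAWM", "lesion"]
        for g in report.groups:
            lo, hi = g.ci95()
            assert lo < g.mean < hi
        assert len(report.pairwise) == 3
        assert 0 <= report.anova_p <= 1
        tab = report.group_table()
        assert set(tab.columns) >= {"group", "n", "mean_pct", "sd_pct"}

    def test_single_group_rejected(self):
        df = pd.DataFrame({"group": ["a"] * 5, "value": range(5)})
        with pytest.raises(DomainError):
            summarize_cohort(df)

    def test_identical_observations_surface_degenerate_error(self):
        df = pd.DataFrame({"group": ["a"] * 3 + ["b"] * 3, "value": [1.0] * 6})
        with pytest.raises(DegenerateDataError):
            summarize_cohort(df)

    def test_ci_coverage(self, rng):
        """95% t-intervals cover the true mean 95% of the time (n=7)."""
        n_sim, n = 10_000, 7
        x = rng.normal(5.0, 2.0, size=(n_sim, n))
        m = x.mean(axis=1)
        se = x.std(axis=1, ddof=1) / np.sqrt(n)
        tcrit = sps.t.ppf(0.975, n - 1)
        cover = np.mean((m - tcrit * se <= 5.0) & (5.0 <= m + tcrit * se))
        assert cover == pytest.approx(0.95, abs=0.01)
        # the vectorised interval matches GroupSample.ci95
        g = GroupSample("g", x[0])
        lo, hi = g.ci95()
        assert lo == pytest.approx(m[0] - tcrit * se[0], rel=1e-10)
        assert hi == pytest.approx(m[0] + tcrit * se[0], rel=1e-10)
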