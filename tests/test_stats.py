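"""Mixed-design rmANOVA, Bonferroni post hocs, one-way ANOVA + Tukey HSD
and Pearson correlation, each checked against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, special
from scipy import stats as sps

from dtiq import (
    oneway_anova_tukey,
    pearson_with_regression,
    posthoc_bonferroni,
    rm_anova,
)


def _long_table(data):
    """data[group][subject] = (value_day50, value_day90) -> long DataFrame."""
    rows = []
    for group, subjects in data.items():
        for sid, values in subjects.items():
            for tp, v in zip(("day50", "day90"), values):
                rows.append(
                    {"subject_id": sid, "group": group, "timepoint": tp, "value": v}
                )
    return pd.DataFrame(rows)


def brute_force_rm_anova(table):
    """Independent sums-of-squares decomposition via explicit loops over
    cell means (balanced designs)."""
    groups = list(dict.fromkeys(table["group"]))
    times = list(dict.fromkeys(table["timepoint"]))
    subjects = list(dict.fromkeys(table["subject_id"]))
    y = {
        (r["subject_id"], r["timepoint"]): r["value"] for _, r in table.iterrows()
    }
    group_of = {r["subject_id"]: r["group"] for _, r in table.iterrows()}
    gm = np.mean(list(y.values()))
    b = len(times)

    subj_mean = {s: np.mean([y[(s, t)] for t in times]) for s in subjects}
    grp_subj = {g: [s for s in subjects if group_of[s] == g] for g in groups}
    grp_mean = {g: np.mean([subj_mean[s] for s in grp_subj[g]]) for g in groups}
    time_mean = {t: np.mean([y[(s, t)] for s in subjects]) for t in times}
    cell_mean = {
        (g, t): np.mean([y[(s, t)] for s in grp_subj[g]]) for g in groups for t in times
    }

    ss_group = b * sum(len(grp_subj[g]) * (grp_mean[g] - gm) ** 2 for g in groups)
    ss_subj = b * sum(
        (subj_mean[s] - grp_mean[group_of[s]]) ** 2 for s in subjects
    )
    ss_time = len(subjects) * sum((time_mean[t] - gm) ** 2 for t in times)
    ss_inter = sum(
        len(grp_subj[g]) * (cell_mean[(g, t)] - grp_mean[g] - time_mean[t] + gm) ** 2
        for g in groups
        for t in times
    )
    ss_err = sum(
        (
            y[(s, t)]
            - subj_mean[s]
            - cell_mean[(group_of[s], t)]
            + grp_mean[group_of[s]]
        )
        ** 2
        for s in subjects
        for t in times
    )
    a, n = len(groups), len(subjects)
    out = {}
    for name, ss_e, df1, ss_r, df2 in [
        ("group", ss_group, a - 1, ss_subj, n - a),
        ("time", ss_time, b - 1, ss_err, (n - a) * (b - 1)),
        ("interaction", ss_inter, (a - 1) * (b - 1), ss_err, (n - a) * (b - 1)),
    ]:
        f = (ss_e / df1) / (ss_r / df2)
        out[name] = (f, float(sps.f.sf(f, df1, df2)))
    return out


def studentized_range_tail(q, k, df):
    """P(Q > q) by direct numerical integration of the studentized-range
    distribution (outer integral over the pooled-SD scale, inner over the
    range of k standard normals)."""

    def inner(s):
        w = q * s

        def integrand(z):
            return sps.norm.pdf(z) * (sps.norm.cdf(z) - sps.norm.cdf(z - w)) ** (k - 1)

        val, _ = integrate.quad(integrand, -9, 9, epsabs=1e-13, limit=300)
        return k * val

    log_c = (df / 2) * np.log(df) - special.gammaln(df / 2) - (df / 2 - 1) * np.log(2)

    def outer(s):
        return np.exp(log_c + (df - 1) * np.log(s) - df * s**2 / 2) * inner(s)

    cdf, _ = integrate.quad(outer, 0, 6, epsabs=1e-12, limit=300)
    return 1.0 - cdf


class TestRmAnova:
    def test_zero_group_ss_gives_zero_f(self):
        # subject means {1, 3} and {0, 4}: both group means 2, values
        # constant across time -> between-group SS is exactly zero
        table = _long_table(
            {
                "A": {"a1": (1, 1), "a2": (3, 3)},
                "B": {"b1": (0, 0), "b2": (4, 4)},
            }
        )
        res = rm_anova(table)
        assert res.group.F == 0.0
        assert res.group.p == 1.0

    def test_constant_within_subject_gives_zero_time_f(self):
        # every subject identical across days: time and interaction SS are
        # zero even though the error stratum is also empty (0/0 -> F = 0)
        table = _long_table(
            {
                "A": {"a1": (1.0, 1.0), "a2": (2.5, 2.5)},
                "B": {"b1": (4.0, 4.0), "b2": (0.5, 0.5)},
            }
        )
        res = rm_anova(table)
        assert res.time.F == 0.0 and res.time.p == 1.0
        assert res.interaction.F == 0.0 and res.interaction.p == 1.0

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(314)
        data = {
            g: {
                f"{g}{i}": tuple(rng.normal(loc, 1.0, size=2))
                for i in range(4)
            }
            for g, loc in (("sham", 0.0), ("short", 1.0), ("long", 0.3))
        }
        table = _long_table(data)
        res = rm_anova(table)
        oracle = brute_force_rm_anova(table)
        for effect in ("group", "time", "interaction"):
            f, p = oracle[effect]
            assert res.effect(effect).F == pytest.approx(f, abs=1e-10)
            assert res.effect(effect).p == pytest.approx(p, abs=1e-10)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(99)
        data = {
            g: {f"{g}{i}": tuple(rng.normal(loc, 1.0, size=2)) for i in range(6)}
            for g, loc in (("sham", 0.0), ("short", 0.8), ("long", 0.2))
        }
        table = _long_table(data)
        res = rm_anova(table)
        pg = pingouin.mixed_anova(
            data=table, dv="value", within="timepoint", between="group",
            subject="subject_id",
        ).set_index("Source")
        assert res.group.F == pytest.approx(pg.loc["group", "F"], rel=1e-8)
        assert res.time.F == pytest.approx(pg.loc["timepoint", "F"], rel=1e-8)
        assert res.interaction.F == pytest.approx(pg.loc["Interaction", "F"], rel=1e-8)

    def test_incomplete_design_rejected(self):
        table = _long_table({"A": {"a1": (1, 2), "a2": (3, 4)}, "B": {"b1": (0, 1), "b2": (2, 0)}})
        table = table[~((table.subject_id == "a2") & (table.timepoint == "day90"))]
        with pytest.raises(ValueError, match="incomplete"):
            rm_anova(table)


class TestPosthocBonferroni:
    def test_identical_groups_not_significant(self):
        base = {"s1": (1.0, 1.2), "s2": (0.8, 1.1), "s3": (1.3, 0.9)}
        table = _long_table(
            {g: {f"{g}_{k}": v for k, v in base.items()} for g in ("A", "B", "C")}
        )
        post = posthoc_bonferroni(table)
        assert not post["significant"].any()
        assert (post["p_bonf"] >= post["p_raw"]).all()

    def test_extreme_separation_detected(self):
        rng = np.random.default_rng(1)
        data = {
            g: {f"{g}{i}": tuple(rng.normal(loc, 1.0, size=2)) for i in range(6)}
            for g, loc in (("A", 0.0), ("B", 0.0), ("C", 10.0))
        }
        post = posthoc_bonferroni(_long_table(data))
        involving_c = post["contrast"].str.contains("C")
        assert post[involving_c]["significant"].all()
        assert not post[~involving_c]["significant"].any()

    def test_averaged_mode_uses_subject_means(self):
        table = _long_table(
            {
                "A": {"a1": (0.0, 2.0), "a2": (1.0, 1.0), "a3": (2.0, 0.0)},
                "B": {"b1": (5.0, 5.0), "b2": (4.0, 6.0), "b3": (6.0, 4.0)},
            }
        )
        post = posthoc_bonferroni(table, mode="averaged")
        assert len(post) == 1
        assert post["mean_diff"].item() == pytest.approx(-4.0)

    def test_insufficient_group_rejected(self):
        table = _long_table({"A": {"a1": (1, 2)}, "B": {"b1": (0, 1), "b2": (2, 3)}})
        with pytest.raises(ValueError, match=">= 2 subjects"):
            posthoc_bonferroni(table)


class TestOnewayTukey:
    FIXED = pd.DataFrame(
        {
            "group": ["sham"] * 4 + ["short"] * 4 + ["long"] * 4,
            "count": [12.0, 15.0, 11.0, 14.0, 22.0, 25.0, 20.0, 24.0, 13.0, 16.0, 12.0, 17.0],
        }
    )

    def test_identical_groups_zero_f(self):
        df = pd.DataFrame(
            {"group": ["A", "A", "B", "B", "C", "C"], "count": [1.0, 2.0, 1.0, 2.0, 1.0, 2.0]}
        )
        anova, _ = oneway_anova_tukey(df)
        assert anova.F == 0.0

    def test_outlier_group_has_smallest_p(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {
                "group": ["A"] * 3 + ["B"] * 3 + ["C"] * 3,
                "count": np.concatenate(
                    [np.zeros(3), np.zeros(3), np.full(3, 10.0)]
                )
                + rng.normal(0, 1e-3, 9),
            }
        )
        _, tukey = oneway_anova_tukey(df)
        with_c = tukey[tukey["contrast"].str.contains("C")]["p_adj"]
        without_c = tukey[~tukey["contrast"].str.contains("C")]["p_adj"]
        assert with_c.max() < without_c.min()

    def test_matches_integration_oracle(self):
        """Adjusted p equals direct studentized-range tail integration."""
        anova, tukey = oneway_anova_tukey(self.FIXED)
        k, dfe = 3, len(self.FIXED) - 3
        for _, row in tukey.iterrows():
            oracle_p = studentized_range_tail(row["q"], k, dfe)
            assert row["p_adj"] == pytest.approx(oracle_p, abs=1e-8)

    def test_matches_statsmodels(self):
        sm_multicomp = pytest.importorskip("statsmodels.stats.multicomp")
        res = sm_multicomp.pairwise_tukeyhsd(
            self.FIXED["count"], self.FIXED["group"]
        )
        _, tukey = oneway_anova_tukey(self.FIXED)
        mine = {
            frozenset(row["contrast"].split(" - ")): row["p_adj"]
            for _, row in tukey.iterrows()
        }
        for row, p in zip(res._results_table.data[1:], res.pvalues):
            key = frozenset((str(row[0]), str(row[1])))
            assert mine[key] == pytest.approx(p, abs=2e-3)

    def test_unequal_n_tukey_kramer(self):
        # histology-style 4/3/4 subgroup sizes are handled
        df = pd.DataFrame(
            {
                "group": ["sham"] * 4 + ["short"] * 3 + ["long"] * 4,
                "count": [10.0, 12.0, 9.0, 11.0, 20.0, 22.0, 19.0, 10.5, 12.5, 9.5, 11.5],
            }
        )
        anova, tukey = oneway_anova_tukey(df)
        assert len(tukey) == 3
        assert anova.p < 0.01

    def test_degenerate_variance_rejected(self):
        df = pd.DataFrame(
            {"group": ["A", "A", "B", "B"], "count": [1.0, 1.0, 5.0, 5.0]}
        )
        with pytest.raises(ValueError, match="degenerate"):
            oneway_anova_tukey(df)


class TestPearson:
    def test_perfect_positive(self):
        res = pearson_with_regression([1, 2, 3], [2, 4, 6])
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)

    def test_perfect_negative(self):
        res = pearson_with_regression([1, 2, 3, 4], [-1, -2, -3, -4])
        assert res.r == pytest.approx(-1.0)

    def test_product_moment_example(self):
        # hand evaluation: x=(1,2,3,4), y=(2,1,4,3) -> r = 0.6
        res = pearson_with_regression([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.r == pytest.approx(0.6, abs=1e-12)
        assert res.r_squared == pytest.approx(0.36, abs=1e-12)
        assert np.sign(res.slope) == np.sign(res.r)
        # two-sided p via the t transform with n-2 df
        t = 0.6 * np.sqrt(2 / (1 - 0.36))
        assert res.p == pytest.approx(2 * sps.t.sf(t, 2), rel=1e-10)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_with_regression([1, 1, 1], [2, 3, 4])
        with pytest.raises(ValueError, match="constant"):
            pearson_with_regression([1, 2, 3], [4, 4, 4])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            pearson_with_regression([1, 2], [3, 4])
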