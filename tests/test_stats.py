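"""Group-comparison statistics against hand-computed oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from cordivim import (
    demographics_tests,
    generate_cohort,
    linreg_pearson,
    percent_difference,
    round_half_away,
    run_group_study,
    two_sample_ttest,
    two_way_anova_posthoc,
)
from conftest import small_config


class TestPercentDifference:
    @pytest.mark.parametrize(
        "ref, test, expected",
        [
            (63.5, 57.6, -9.3),   # white-matter CSA
            (8.2, 7.6, -7.3),     # anterior-posterior diameter
            (14.4, 13.5, -6.3),   # grey-matter CSA (half-away rounding)
            (10.0, 10.0, 0.0),
        ],
    )
    def test_group_mean_deltas(self, ref, test, expected):
        assert percent_difference(ref, test) == pytest.approx(expected)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            percent_difference(0.0, 1.0)

    def test_half_away_rounding(self):
        assert round_half_away(-6.25, 1) == -6.3
        assert round_half_away(6.25, 1) == 6.3
        assert round_half_away(2.349, 1) == 2.3


class TestTTest:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = two_sample_ttest(x, x, tails="two")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_textbook_pooled_t(self):
        res = two_sample_ttest([1, 2, 3, 4, 5], [2, 3, 4, 5, 6], tails="two")
        assert res.statistic == pytest.approx(-1.0)
        assert res.df == pytest.approx(8)

    def test_one_tailed_ps_sum_to_one(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        p_less = two_sample_ttest(x, y, tails="one", direction="less").p_value
        p_greater = two_sample_ttest(x, y, tails="one", direction="greater").p_value
        assert p_less + p_greater == pytest.approx(1.0)
        p_two = two_sample_ttest(x, y, tails="two").p_value
        assert min(p_less, p_greater) == pytest.approx(p_two / 2)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            two_sample_ttest([1.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="constant"):
            two_sample_ttest([1.0, 1.0], [2.0, 2.0])


class TestAnova:
    @staticmethod
    def _balanced(mean_shift=0.0):
        # 2 groups x 3 subregions, 6 observations per cell, identical
        # within-cell deviations so effect sums of squares are exact
        dev = np.array([-1.5, -0.5, -0.25, 0.25, 0.5, 1.5])
        rows = []
        for g in ("HC", "DCM"):
            for r in ("a", "b", "c"):
                mu = 10.0 + (mean_shift if (g == "DCM" and r == "b") else 0.0)
                for v in mu + dev:
                    rows.append({"value": v, "group": g, "subregion": r})
        return pd.DataFrame(rows)

    def test_equal_cell_means_give_null_f(self):
        main, _ = two_way_anova_posthoc(self._balanced(0.0))
        for res in main:
            assert res.statistic == pytest.approx(0.0, abs=1e-20)
            assert res.p_value == pytest.approx(1.0)

    def test_f_matches_hand_sums_of_squares(self):
        # independent oracle: direct sums-of-squares computation
        rng = np.random.default_rng(4)
        rows = []
        for gi, g in enumerate(("HC", "DCM")):
            for ri, r in enumerate(("a", "b")):
                for v in rng.normal(10 + gi - 0.5 * ri, 1.0, 5):
                    rows.append({"value": v, "group": g, "subregion": r})
        df = pd.DataFrame(rows)

        y = df["value"].to_numpy()
        cells = {
            (g, r): df[(df.group == g) & (df.subregion == r)]["value"].to_numpy()
            for g in ("HC", "DCM")
            for r in ("a", "b")
        }
        n = 5
        grand = y.mean()
        g_means = {g: np.mean([cells[(g, r)].mean() for r in ("a", "b")]) for g in ("HC", "DCM")}
        r_means = {r: np.mean([cells[(g, r)].mean() for g in ("HC", "DCM")]) for r in ("a", "b")}
        ss_g = 2 * n * sum((m - grand) ** 2 for m in g_means.values())
        ss_r = 2 * n * sum((m - grand) ** 2 for m in r_means.values())
        ss_int = n * sum(
            (cells[(g, r)].mean() - g_means[g] - r_means[r] + grand) ** 2
            for g in ("HC", "DCM")
            for r in ("a", "b")
        )
        ss_err = sum(((c - c.mean()) ** 2).sum() for c in cells.values())
        df_err = 4 * (n - 1)
        expected_f = {
            "group": (ss_g / 1) / (ss_err / df_err),
            "subregion": (ss_r / 1) / (ss_err / df_err),
            "interaction": (ss_int / 1) / (ss_err / df_err),
        }

        main, _ = two_way_anova_posthoc(df)
        by_name = {res.name: res.statistic for res in main}
        assert by_name["ANOVA group main effect"] == pytest.approx(expected_f["group"])
        assert by_name["ANOVA subregion main effect"] == pytest.approx(expected_f["subregion"])
        assert by_name["ANOVA group x subregion interaction"] == pytest.approx(
            expected_f["interaction"]
        )

    def test_shifted_subregion_flagged_by_posthoc(self):
        # a deficit confined to one subregion of the patient group is
        # detected by the interaction and localized by post-hoc tests
        # in the majority of noisy replicates
        rng = np.random.default_rng(8)
        hits, interactions = 0, 0
        n_rep = 20
        for _ in range(n_rep):
            rows = []
            for g in ("HC", "DCM"):
                for r in ("a", "b", "c"):
                    mu = 10.0 - (3.0 if (g == "DCM" and r == "b") else 0.0)
                    for v in rng.normal(mu, 1.0, 12):
                        rows.append({"value": v, "group": g, "subregion": r})
            main, posthoc = two_way_anova_posthoc(pd.DataFrame(rows))
            inter = [r for r in main if "interaction" in r.name][0]
            interactions += inter.p_value < 0.05
            ps = {r.extra["subregion"]: r.p_value for r in posthoc}
            hits += ps["b"] < 0.05 and ps["a"] > 0.05 and ps["c"] > 0.05
        assert interactions > n_rep / 2
        assert hits > n_rep / 2

    def test_missing_cells_rejected(self):
        df = self._balanced().query("~(group == 'DCM' and subregion == 'b')")
        with pytest.raises(ValueError, match="cells"):
            two_way_anova_posthoc(df)


class TestRegression:
    def test_exact_line(self):
        x = np.arange(10, dtype=float)
        res = linreg_pearson(x, 2 * x + 1)
        assert res.estimate == pytest.approx(1.0)
        assert res.extra["slope"] == pytest.approx(2.0)
        assert res.extra["intercept"] == pytest.approx(1.0)

    def test_symmetric_three_points_have_zero_r(self):
        res = linreg_pearson([0.0, 1.0, 2.0], [0.0, 1.0, 0.0])
        assert res.estimate == pytest.approx(0.0, abs=1e-12)

    def test_independent_draws_have_near_zero_r(self):
        rng = np.random.default_rng(2)
        res = linreg_pearson(rng.normal(size=5000), rng.normal(size=5000))
        assert abs(res.estimate) < 0.05
        assert res.extra["r_squared"] == pytest.approx(res.estimate**2)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            linreg_pearson([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])


class TestDemographics:
    @staticmethod
    def _table(age_dcm_shift=0.0, sex_pattern=None):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(20):
            rows.append({"group": "HC", "age": 50 + i, "sex": "F" if i < 10 else "M"})
        for i in range(20):
            sex = "F" if (sex_pattern or (lambda j: j < 10))(i) else "M"
            rows.append({"group": "DCM", "age": 50 + i + age_dcm_shift, "sex": sex})
        return pd.DataFrame(rows)

    def test_identical_age_distributions(self):
        age_res, _ = demographics_tests(self._table())
        # U sits at its null mean n1*n2/2 and p is ~1
        assert age_res.statistic == pytest.approx(200.0)
        assert age_res.p_value > 0.95

    def test_balanced_sex_table_gives_fisher_p1(self):
        _, sex_res = demographics_tests(self._table())
        assert sex_res.p_value == pytest.approx(1.0)

    def test_fully_separated_sex_table_matches_enumeration(self):
        # hypergeometric oracle: 2x2 table {5,0;0,5} has two-sided
        # Fisher p = 2 / C(10,5) = 2/252
        rows = [{"group": "HC", "age": 50.0 + i, "sex": "F"} for i in range(5)]
        rows += [{"group": "DCM", "age": 55.0 + i, "sex": "M"} for i in range(5)]
        _, sex_res = demographics_tests(pd.DataFrame(rows))
        assert sex_res.p_value == pytest.approx(2 / math.comb(10, 5))

    def test_single_group_rejected(self):
        df = pd.DataFrame({"group": ["HC"] * 4, "age": [1, 2, 3, 4], "sex": list("FFMM")})
        with pytest.raises(ValueError, match="two groups"):
            demographics_tests(df)


class TestGroupStudy:
    def test_full_report_on_simulated_cohort(self, tmp_path):
        from cordivim import PhantomConfig

        study = generate_cohort(PhantomConfig(), n_hc=15, n_dcm=15, seed=21, images=False)
        out = run_group_study(study.table, out_dir=tmp_path)
        assert (tmp_path / "comparisons.tsv").exists()
        assert (tmp_path / "summary.json").exists()
        comp = out["comparisons"]
        assert set(comp["status"]) == {"ok"}
        assert out["anova"]["status"] == "ok"
        # perfusion metrics use one-tailed tests, morphometry two-tailed
        assert (comp.loc[comp.metric == "dstar_wm", "tails"] == "one").all()
        assert (comp.loc[comp.metric == "wm_csa", "tails"] == "two").all()

    def test_minimal_cohort_reports_na_instead_of_crashing(self):
        study = generate_cohort(small_config(), n_hc=2, n_dcm=2, seed=1, images=False)
        out = run_group_study(study.table)
        assert len(out["comparisons"]) > 0  # produced despite tiny n

    def test_missing_columns_named_in_error(self):
        df = pd.DataFrame({"group": ["HC", "HC", "DCM", "DCM"], "age": [1, 2, 3, 4]})
        with pytest.raises(ValueError, match="sex"):
            run_group_study(df)
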