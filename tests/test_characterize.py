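import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ltcnlp import characterize as ch
from ltcnlp.types import CaseCategory

# Published subgroup counts used as worked examples: totals 428/449/160.
SUBGROUP_TOTALS = (428, 449, 160)
MALE_COUNTS = (277, 360, 128)
PHYS_COUNTS = (217, 351, 64)
DEPR_COUNTS = (168, 202, 98)


def counts_to_frame(yes_counts, totals, var, yes="yes", no="no"):
    """Expand a 2x3 count table into a per-record data frame."""
    cats = [c.value for c in
            (CaseCategory.IN_LTC, CaseCategory.TRANSITIONING,
             CaseCategory.OTHERWISE_ASSOCIATED)]
    rows = []
    for cat, k, n in zip(cats, yes_counts, totals):
        rows += [{var: yes, "category": cat}] * k
        rows += [{var: no, "category": cat}] * (n - k)
    return pd.DataFrame(rows)


class TestPearsonChi2:
    def test_brute_force_oracle_1000_tables(self, rng):
        """Explicit sum((O-E)^2/E) loop matches exactly."""
        for _ in range(1000):
            t = rng.integers(1, 80, size=(rng.integers(2, 4), rng.integers(2, 4)))
            res = ch.pearson_chi2(t)
            total = t.sum()
            stat = 0.0
            for i in range(t.shape[0]):
                for j in range(t.shape[1]):
                    e = t[i].sum() * t[:, j].sum() / total
                    stat += (t[i, j] - e) ** 2 / e
            assert res.statistic == pytest.approx(stat, rel=1e-12)
            assert res.df == (t.shape[0] - 1) * (t.shape[1] - 1)

    def test_matches_scipy_without_correction(self, rng):
        t = rng.integers(5, 50, size=(2, 3))
        res = ch.pearson_chi2(t)
        ref = stats.chi2_contingency(t, correction=False)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_identical_distributions_zero(self):
        t = [[10, 20, 30], [20, 40, 60]]
        assert ch.pearson_chi2(t).statistic == pytest.approx(0.0, abs=1e-12)

    def test_low_expected_flagged(self):
        res = ch.pearson_chi2([[1, 0], [0, 1]])
        assert res.flagged

    def test_published_sex_statistic(self):
        t = [list(MALE_COUNTS),
             [n - k for k, n in zip(MALE_COUNTS, SUBGROUP_TOTALS)]]
        res = ch.pearson_chi2(t)
        assert round(res.statistic) == 31 and res.df == 2

    def test_published_physical_health_statistic(self):
        t = [list(PHYS_COUNTS),
             [n - k for k, n in zip(PHYS_COUNTS, SUBGROUP_TOTALS)]]
        assert round(ch.pearson_chi2(t).statistic) == 104

    def test_published_depressed_mood_statistic(self):
        t = [list(DEPR_COUNTS),
             [n - k for k, n in zip(DEPR_COUNTS, SUBGROUP_TOTALS)]]
        assert round(ch.pearson_chi2(t).statistic) == 23


class TestKruskalWallis:
    def test_closed_form_untied_toy(self):
        """Rank-based closed form H = 12/(N(N+1)) * sum n_i rbar_i^2 - 3(N+1)."""
        groups = [[1.0, 3.0, 5.0], [2.0, 4.0, 9.0], [6.0, 7.0, 8.0]]
        res = ch.kruskal_wallis(groups)
        allv = sorted(v for g in groups for v in g)
        ranks = {v: i + 1 for i, v in enumerate(allv)}
        N = len(allv)
        H = 12 / (N * (N + 1)) * sum(
            len(g) * np.mean([ranks[v] for v in g]) ** 2 for g in groups
        ) - 3 * (N + 1)
        assert res.statistic == pytest.approx(H, rel=1e-12)
        assert res.df == 2

    def test_needs_two_groups(self):
        with pytest.raises(ValueError):
            ch.kruskal_wallis([[1, 2, 3]])


class TestGroupTest:
    def test_sex_via_frame_api(self):
        df = counts_to_frame(MALE_COUNTS, SUBGROUP_TOTALS, "sex",
                             yes="male", no="female")
        res = ch.group_test(df, "sex", "categorical")
        assert round(res.statistic) == 31
        assert res.df == 2 and res.p_value < 0.001

    def test_missing_level_excluded(self):
        df = counts_to_frame(MALE_COUNTS, SUBGROUP_TOTALS, "sex",
                             yes="male", no="female")
        extra = pd.DataFrame(
            [{"sex": "missing", "category": CaseCategory.IN_LTC.value}] * 30
        )
        res = ch.group_test(pd.concat([df, extra]), "sex", "categorical")
        assert round(res.statistic) == 31  # missing rows do not perturb it

    def test_continuous_kruskal(self):
        rng = np.random.default_rng(0)
        rows = []
        for cat, mu in [("in_ltc", 70.0), ("transitioning", 80.0),
                        ("otherwise_associated", 75.0)]:
            for _ in range(40):
                rows.append({"age": float(rng.normal(mu, 5)), "category": cat})
        res = ch.group_test(pd.DataFrame(rows), "age", "continuous")
        assert res.test == "kruskal-wallis" and res.p_value < 0.01

    def test_anova_flag(self):
        rows = [{"age": float(v), "category": c}
                for c, vals in [("in_ltc", [60, 61, 62]),
                                ("transitioning", [80, 81, 82]),
                                ("otherwise_associated", [70, 71, 72])]
                for v in vals]
        res = ch.group_test(pd.DataFrame(rows), "age", "continuous",
                            use_anova=True)
        assert res.test == "anova"


class TestSummarizeGroups:
    def _frame(self):
        rows = [
            {"age": 60, "sex": "male", "category": "not_associated"},
            {"age": 70, "sex": "female", "category": "not_associated"},
            {"age": 80, "sex": "male", "category": "in_ltc"},
            {"age": 90, "sex": "female", "category": "in_ltc"},
            {"age": 75, "sex": "male", "category": "transitioning"},
            {"age": 85, "sex": "male", "category": "otherwise_associated"},
        ]
        return pd.DataFrame(rows)

    def test_hand_computed_cells(self):
        table = ch.summarize_groups(self._frame(), categorical=["sex"])
        # in_ltc ages 80, 90: median 85, IQR 5
        assert table.loc["age, median (IQR)", "in_ltc"] == "85 (5)"
        assert table.loc["sex=male", "in_ltc"] == "1 (50.0)"
        # all-LTC column pools the three subgroups (n=4, 3 male)
        assert table.loc["sex=male", "all_ltc"] == "3 (75.0)"

    def test_single_category_corpus(self):
        df = pd.DataFrame(
            [{"age": 70, "sex": "male", "category": "in_ltc"}] * 5
        )
        table = ch.summarize_groups(df, categorical=["sex"])
        assert table.loc["sex=male", "in_ltc"] == "5 (100.0)"
        assert table.loc["sex=male", "not_associated"] == "(empty)"

    def test_percentages_within_block_bounded(self):
        table = ch.summarize_groups(self._frame(), categorical=["sex"])
        for col in table.columns:
            pcts = []
            for label in ["sex=male", "sex=female"]:
                cell = table.loc[label, col]
                if cell != "(empty)":
                    pcts.append(float(cell.split("(")[1].rstrip(")")))
            assert sum(pcts) <= 100.0 + 1e-9


class TestSuppressCells:
    def test_small_cell_suppressed(self):
        t = pd.DataFrame([[3, 50]])
        out = ch.suppress_cells(t, threshold=6, complementary=False)
        assert out.iat[0, 0] == "S"

    def test_zero_not_suppressed(self):
        t = pd.DataFrame([[0, 50]])
        out = ch.suppress_cells(t, threshold=6)
        assert out.iat[0, 0] == 0

    def test_complementary_suppression(self):
        """One small cell in a row with printed margins forces a second."""
        t = pd.DataFrame([[3, 20, 100]])
        out = ch.suppress_cells(t, threshold=6)
        assert out.iat[0, 0] == "S"
        assert out.iat[0, 1] == "S"  # next-smallest cell also masked
        assert out.iat[0, 2] == 100

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ch.suppress_cells(pd.DataFrame([[-1, 5]]))

    @given(
        data=st.lists(
            st.lists(st.integers(min_value=0, max_value=30), min_size=3,
                     max_size=3),
            min_size=1, max_size=6,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_never_alters_unsuppressed_values(self, data):
        t = pd.DataFrame(data)
        out = ch.suppress_cells(t, threshold=6)
        for i in range(t.shape[0]):
            for j in range(t.shape[1]):
                if out.iat[i, j] != "S":
                    assert out.iat[i, j] == t.iat[i, j]
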