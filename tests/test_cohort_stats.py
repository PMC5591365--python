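import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gbmgrade import (
    ContingencyTable,
    cohens_kappa,
    crosstab,
    is_major_complication,
    pearson_chi2,
    rater_crosstab,
    summarize_features,
    summarize_grades,
)
from gbmgrade.cohort_stats import major_complication, round_half_up


def ct(counts, rows=None, cols=None):
    counts = np.asarray(counts)
    rows = rows or tuple(range(counts.shape[0]))
    cols = cols or tuple(range(counts.shape[1]))
    return ContingencyTable(counts, rows, cols)


class TestMajorComplication:
    @pytest.mark.parametrize(
        "grade,expected",
        [("none", False), ("1", False), ("2", False), ("3a", False),
         ("3b", True), ("4a", True), ("4b", True), ("5", True)],
    )
    def test_strictly_above_3a(self, grade, expected):
        assert is_major_complication(grade) is expected

    def test_unknown_grade_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            is_major_complication("6")
        with pytest.raises(ValueError, match="unknown"):
            major_complication(pd.Series(["none", "x"]))


class TestCrosstab:
    def test_outcome_cohort_row_totals(self, outcome_cohort):
        df = outcome_cohort.copy()
        df["complete_resection"] = df["complete_resection"].astype(bool)
        tab = crosstab(df, "complexity", "complete_resection")
        assert tab.row_labels == ("low", "moderate", "high")
        assert tab.counts.sum(axis=1).tolist() == [14, 45, 29]
        assert tab.n == 88

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            crosstab(pd.DataFrame(columns=["a", "b"]), "a", "b")

    def test_single_record(self):
        df = pd.DataFrame({"subject_id": ["s"], "complexity": ["high"], "x": [True]})
        tab = crosstab(df, "complexity", "x")
        assert tab.counts.tolist() == [[1]]

    def test_missing_values_rejected_with_ids(self):
        df = pd.DataFrame(
            {"subject_id": ["s1", "s2"], "complexity": ["low", None], "x": [1, 0]}
        )
        with pytest.raises(ValueError, match="s2"):
            crosstab(df, "complexity", "x")


class TestPearsonChi2:
    def test_proportional_rows_give_zero(self):
        res = pearson_chi2(ct([[10, 20], [5, 10]]))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_two_by_two_closed_form(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a, b, c, d = rng.integers(1, 40, size=4)
            n = a + b + c + d
            expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
            res = pearson_chi2(ct([[a, b], [c, d]]))
            assert res.statistic == pytest.approx(expected, rel=1e-12)
            assert res.df == 1

    def test_invariant_under_permutation_and_transpose(self):
        t = np.array([[7, 7], [7, 38], [1, 28]])
        base = pearson_chi2(ct(t))
        assert pearson_chi2(ct(t[::-1])).statistic == pytest.approx(base.statistic)
        assert pearson_chi2(ct(t[:, ::-1])).statistic == pytest.approx(base.statistic)
        assert pearson_chi2(ct(t.T)).statistic == pytest.approx(base.statistic)

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            pearson_chi2(ct([[3, 4]]))

    def test_all_zero_row_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="all-zero"):
            res = pearson_chi2(ct([[5, 5], [0, 0], [2, 8]]))
        assert res.df == 1

    def test_low_expected_flagged(self):
        res = pearson_chi2(ct([[1, 1], [1, 50]]))
        assert res.warning_low_expected is True

    def test_matches_permutation_oracle_mid_p(self):
        """Fixed-margin Monte-Carlo null of the statistic reproduces the
        asymptotic p (mid-p convention for the discrete atom) within 3 MC SE."""
        obs = np.array([[120, 180], [150, 150]])
        res = pearson_chi2(ct(obs))
        n, r, c = obs.sum(), obs.sum(axis=1), obs.sum(axis=0)
        rng = np.random.default_rng(2024)
        a = rng.hypergeometric(c[0], c[1], r[0], size=100_000)
        tables = np.stack([a, r[0] - a, c[0] - a, c[1] - r[0] + a], axis=1).reshape(-1, 2, 2)
        E = np.outer(r, c) / n
        null_stats = ((tables - E) ** 2 / E).sum(axis=(1, 2))
        p_ge = (null_stats >= res.statistic - 1e-9).mean()
        p_gt = (null_stats > res.statistic + 1e-9).mean()
        mid_p = 0.5 * (p_ge + p_gt)
        se = np.sqrt(p_ge * (1 - p_ge) / len(null_stats))
        assert abs(res.p - mid_p) <= 3 * se


class TestCohensKappa:
    def test_diagonal_table_is_one(self):
        assert cohens_kappa(ct(np.diag([5, 7, 3]))).kappa == pytest.approx(1.0)

    def test_margin_outer_product_is_zero(self):
        assert cohens_kappa(ct([[4, 4], [4, 4]])).kappa == pytest.approx(0.0, abs=1e-12)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            cohens_kappa(ct([[1, 2, 3], [4, 5, 6]]))

    def test_degenerate_margins_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            cohens_kappa(ct([[9, 0], [0, 0]]))

    def test_matches_direct_definition(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            t = rng.integers(0, 50, size=(3, 3))
            t[0, 0] += 2  # keep the table non-degenerate
            res = cohens_kappa(ct(t))
            p = t / t.sum()
            p_o = np.trace(p)
            p_e = p.sum(axis=1) @ p.sum(axis=0)
            assert res.kappa == pytest.approx((p_o - p_e) / (1 - p_e), rel=1e-12)

    def test_asymptotic_se_matches_statsmodels(self):
        sm_kappa = pytest.importorskip("statsmodels.stats.inter_rater").cohens_kappa
        rng = np.random.default_rng(3)
        for _ in range(5):
            t = rng.integers(1, 50, size=(3, 3))
            res = cohens_kappa(ct(t))
            ref = sm_kappa(t, return_results=True)
            assert res.kappa == pytest.approx(ref.kappa, rel=1e-10)
            assert res.se == pytest.approx(np.sqrt(ref.var_kappa), rel=1e-8)

    def test_se_within_10pct_of_bootstrap(self):
        rng = np.random.default_rng(21)
        t = np.array([[30, 8, 2], [6, 40, 9], [3, 7, 25]])
        res = cohens_kappa(ct(t))
        n = t.sum()
        probs = (t / n).ravel()
        boots = rng.multinomial(n, probs, size=10_000).reshape(-1, 3, 3) / n
        p_o = np.trace(boots, axis1=1, axis2=2)
        p_e = (boots.sum(axis=2) * boots.sum(axis=1)).sum(axis=1)
        kappas = (p_o - p_e) / (1 - p_e)
        assert res.se == pytest.approx(kappas.std(ddof=1), rel=0.10)

    def test_simple_se_formula(self):
        t = np.array([[20, 5], [4, 30]])
        res = cohens_kappa(ct(t), se_formula="simple")
        p = t / t.sum()
        p_o, p_e = np.trace(p), p.sum(axis=1) @ p.sum(axis=0)
        expected = np.sqrt(p_o * (1 - p_o) / (t.sum() * (1 - p_e) ** 2))
        assert res.se == pytest.approx(expected, rel=1e-12)

    def test_relabelling_invariance(self):
        t = np.array([[12, 3, 1], [4, 20, 2], [0, 5, 9]])
        perm = [2, 0, 1]
        k1 = cohens_kappa(ct(t)).kappa
        k2 = cohens_kappa(ct(t[np.ix_(perm, perm)])).kappa
        assert k1 == pytest.approx(k2)

    def test_rater_crosstab_pads_absent_levels(self):
        df = pd.DataFrame({"complexity": ["low", "low"], "grade_rater2": ["low", "moderate"]})
        tab = rater_crosstab(df)
        assert tab.counts.shape == (3, 3)
        assert tab.counts.sum() == 2


class TestSummaries:
    def test_prevalence_reconstruction_matches_published_percentages(self, prevalence_cohort):
        summary = summarize_features(prevalence_cohort)
        present = summary[summary["level"] == "present"].set_index("feature")["pct"]
        assert present["periventricular"] == 77.3
        assert present["callosal_or_bilateral"] == 33.0
        assert present["eloquent"] == 43.2
        assert present["large"] == 70.5
        assert present["oedema"] == 69.3

    def test_prevalence_counts_sum_to_cohort_size(self, prevalence_cohort):
        summary = summarize_features(prevalence_cohort)
        assert (summary.groupby("feature")["count"].sum() == 88).all()

    def test_all_zero_cohort(self):
        df = pd.DataFrame(
            0,
            index=range(4),
            columns=["periventricular", "callosal_or_bilateral", "eloquent", "large", "oedema"],
        )
        summary = summarize_features(df)
        present = summary[summary["level"] == "present"]
        assert (present["pct"] == 0.0).all()

    def test_single_patient_all_flags(self):
        df = pd.DataFrame([[1, 1, 1, 1, 1]],
                          columns=["periventricular", "callosal_or_bilateral", "eloquent", "large", "oedema"])
        present = summarize_features(df).query("level == 'present'")
        assert (present["pct"] == 100.0).all()

    def test_grade_outcome_reconstruction(self, outcome_cohort):
        summary = summarize_grades(outcome_cohort).set_index("complexity")
        assert summary.loc["low", "complete_resection_pct"] == 50.0
        assert summary.loc["moderate", "complete_resection_pct"] == 15.6
        assert summary.loc["high", "complete_resection_pct"] == 3.4
        assert summary.loc["total", "complete_resection_pct"] == 17.0
        assert summary.loc["low", "major_complication_pct"] == 0.0
        assert summary.loc["moderate", "major_complication_pct"] == 2.2
        assert summary.loc["high", "major_complication_pct"] == 6.9
        assert summary.loc["total", "major_complication_pct"] == 3.4

    def test_no_resections_column_all_zero(self, outcome_cohort):
        df = outcome_cohort.copy()
        df["complete_resection"] = 0
        summary = summarize_grades(df)
        assert (summary["complete_resection_pct"] == 0.0).all()

    def test_percentages_consistent_with_counts(self, outcome_cohort):
        summary = summarize_grades(outcome_cohort)
        for _, row in summary.iterrows():
            assert row["complete_resection_pct"] == round_half_up(
                100 * row["complete_resection_n"] / row["n"]
            )


def test_round_half_up_ties_go_up():
    assert round_half_up(0.05, 1) == 0.1
    assert round_half_up(2.25, 1) == 2.3
    assert round_half_up(17.045, 1) == 17.0  # not a true tie: 17.045 < 17.05
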