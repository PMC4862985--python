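"""Cohort statistics against closed-form and enumeration oracles."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from cvrkit.errors import (
    DesignError,
    InsufficientDataError,
    InvalidArgumentError,
    UndefinedStatisticError,
    UnsupportedSampleSizeError,
)
from cvrkit.stats import (
    CohortTable,
    REQUIRED_COLUMNS,
    adjusted_group_effect,
    correlate,
    demographics_summary,
    group_compare,
    normality_gate,
    paired_compare,
    run_standard_analyses,
)
from cvrkit.synth import generate_cohort, study_cohort_params


def make_table(control_vals, mtbi_vals, variable="gm_cvr", **extra_cols):
    """Minimal valid cohort table carrying one variable of interest."""
    rows = []
    for g, vals, prefix in (("control", control_vals, "C"), ("mtbi", mtbi_vals, "M")):
        for i, v in enumerate(vals):
            row = {c: np.nan for c in REQUIRED_COLUMNS}
            row.update(
                subject_id=f"{prefix}{i}", group=g, visit=1, sex="M",
                age_years=40.0, days_post_injury=(50.0 if g == "mtbi" else np.nan),
            )
            row[variable] = v
            for k, fn in extra_cols.items():
                row[k] = fn(g, i)
            rows.append(row)
    return CohortTable(pd.DataFrame(rows))


def make_paired_table(v1, v2, variable="gm_volume_cm3"):
    rows = []
    for i, (a, b) in enumerate(zip(v1, v2)):
        for visit, val in ((1, a), (2, b)):
            row = {c: np.nan for c in REQUIRED_COLUMNS}
            row.update(subject_id=f"M{i}", group="mtbi", visit=visit, sex="F",
                       age_years=30.0, days_post_injury=60.0 * visit)
            row[variable] = val
            rows.append(row)
    return CohortTable(pd.DataFrame(rows))


def mw_enumeration(x, y):
    """Exhaustive-enumeration two-sided Mann-Whitney oracle (tie-free)."""
    pooled = np.concatenate([x, y])
    n1, n2 = len(x), len(y)
    u_obs = sum(1.0 for a in x for b in y if a > b) + 0.5 * sum(
        1 for a in x for b in y if a == b
    )
    mu = n1 * n2 / 2.0
    count = total = 0
    for idx in combinations(range(n1 + n2), n1):
        g1 = pooled[list(idx)]
        g2 = np.delete(pooled, list(idx))
        u = sum(1.0 for a in g1 for b in g2 if a > b)
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return u_obs, count / total


def group_compare_v(table):
    return group_compare(table, "gm_cvr")


def paired_compare_v(table):
    return paired_compare(table, "gm_volume_cm3")


class TestGroupCompare:
    def test_separated_groups_give_extreme_u(self):
        res = group_compare_v(make_table([1.0, 2.0, 3.0], [4.0, 5.0, 6.0]))
        assert res.statistic in (0.0, 9.0)
        # all control values below all mTBI values: most extreme of C(6,3)
        assert res.p_value == pytest.approx(0.1, abs=1e-12)

    def test_identical_distributions_u_is_half_product(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        res = group_compare_v(make_table(vals, vals))
        assert res.statistic == pytest.approx(len(vals) ** 2 / 2.0)
        assert res.p_value > 0.9

    @pytest.mark.parametrize("n1,n2", [(1, 3), (2, 2), (3, 3), (4, 4), (2, 6)])
    def test_matches_exhaustive_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(5):
            vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            x, y = vals[:n1], vals[n1:]
            res = group_compare_v(make_table(x, y))
            u_oracle, p_oracle = mw_enumeration(x, y)
            assert res.statistic == pytest.approx(u_oracle)
            assert res.p_value == pytest.approx(p_oracle, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            group_compare_v(make_table([1.0, 2.0], []))

    def test_null_rejection_rate_near_alpha(self):
        """Equal-mean synthetic cohorts reject at roughly the nominal 5%."""
        rng = np.random.default_rng(99)
        rej = 0
        n_rep = 300
        for _ in range(n_rep):
            x = rng.standard_normal(12)
            y = rng.standard_normal(12)
            rej += group_compare_v(make_table(x, y)).p_value <= 0.05
        assert abs(rej / n_rep - 0.05) < 0.03


class TestPairedCompare:
    def test_all_zero_differences(self):
        res = paired_compare_v(make_paired_table([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_constant_nonzero_differences_degenerate(self):
        res = paired_compare_v(make_paired_table([1.0, 2.0, 3.0, 4.0],
                                               [2.0, 3.0, 4.0, 5.0]))
        assert np.isinf(res.statistic)
        assert res.p_value == 0.0
        assert "degenerate" in res.note

    def test_matches_closed_form_on_random_pairs(self):
        rng = np.random.default_rng(5)
        v1 = rng.normal(100, 10, 10)
        v2 = v1 + rng.normal(-2, 3, 10)
        res = paired_compare_v(make_paired_table(v1, v2))
        d = v2 - v1
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert res.statistic == pytest.approx(t_oracle, rel=1e-12)
        assert res.p_value == pytest.approx(sps.ttest_rel(v2, v1).pvalue, rel=1e-9)
        assert res.estimate == pytest.approx(d.mean())

    def test_single_pair_rejected(self):
        with pytest.raises(InsufficientDataError):
            paired_compare_v(make_paired_table([1.0], [2.0]))


class TestCorrelate:
    def test_perfect_correlation(self):
        t = make_table([1.0, 2.0, 3.0], [], variable="gm_cvr",
                       scat2=lambda g, i: float(i))
        t.df.loc[t.df.group == "control", "gm_cvr"] = [0.0, 1.0, 2.0]
        res = correlate(t, "scat2", "gm_cvr", group="control")
        assert res.statistic == pytest.approx(1.0)

    def test_matches_covariance_ratio(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0])
        t = make_table(x, [], variable="gm_cvr", scat2=lambda g, i: y[i])
        t.df.loc[t.df.group == "control", "gm_cvr"] = x
        res = correlate(t, "gm_cvr", "scat2", group="control")
        r_oracle = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert res.statistic == pytest.approx(r_oracle, rel=1e-12)

    @given(a=st.floats(0.1, 5.0), b=st.floats(-10.0, 10.0),
           c=st.floats(0.1, 5.0), d=st.floats(-10.0, 10.0))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_affine_invariance_positive_scale(self, a, b, c, d):
        rng = np.random.default_rng(17)
        x = rng.normal(0, 1, 12)
        y = 0.5 * x + rng.normal(0, 1, 12)
        t1 = make_table(x, [], scat2=lambda g, i: y[i])
        t1.df.loc[:, "gm_cvr"] = x
        t2 = make_table(a * x + b, [], scat2=lambda g, i: c * y[i] + d)
        t2.df.loc[:, "gm_cvr"] = a * x + b
        r1 = correlate(t1, "gm_cvr", "scat2", group="control").statistic
        r2 = correlate(t2, "gm_cvr", "scat2", group="control").statistic
        assert r2 == pytest.approx(r1, abs=1e-9)

    def test_negating_one_variable_negates_r(self):
        rng = np.random.default_rng(21)
        x = rng.normal(0, 1, 10)
        y = x + rng.normal(0, 0.5, 10)
        t1 = make_table(x, [], scat2=lambda g, i: y[i])
        t2 = make_table(x, [], scat2=lambda g, i: -y[i])
        r1 = correlate(t1, "gm_cvr", "scat2", group="control").statistic
        r2 = correlate(t2, "gm_cvr", "scat2", group="control").statistic
        assert r2 == pytest.approx(-r1, abs=1e-12)

    def test_zero_variance_rejected(self):
        t = make_table([1.0, 1.0, 1.0], [], scat2=lambda g, i: float(i))
        with pytest.raises(UndefinedStatisticError):
            correlate(t, "gm_cvr", "scat2", group="control")

    def test_too_few_pairs_rejected(self):
        t = make_table([1.0, 2.0], [], scat2=lambda g, i: float(i))
        with pytest.raises(InsufficientDataError):
            correlate(t, "gm_cvr", "scat2", group="control")


class TestAdjustedGroupEffect:
    @staticmethod
    def _table(n_per_group=10, group_shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g in ("control", "mtbi"):
            for i in range(n_per_group):
                row = {c: np.nan for c in REQUIRED_COLUMNS}
                age = rng.uniform(20, 60)
                row.update(
                    subject_id=f"{g[0]}{i}", group=g, visit=1,
                    sex="M" if rng.random() < 0.5 else "F",
                    age_years=age,
                    days_post_injury=(50.0 if g == "mtbi" else np.nan),
                    scat2=80.0 + (group_shift if g == "mtbi" else 0.0)
                    + rng.normal(0, 3.0),
                )
                rows.append(row)
        return CohortTable(pd.DataFrame(rows))

    def test_coefficients_match_normal_equations(self):
        t = self._table(n_per_group=10, group_shift=-5.0, seed=3)
        import statsmodels.formula.api as smf
        model = smf.ols("scat2 ~ C(group) + age_years + C(sex)", data=t.subset(visit=1)).fit()
        d = t.subset(visit=1)
        X = np.column_stack([
            np.ones(len(d)),
            (d["group"] == "mtbi").astype(float),
            (d["sex"] == "M").astype(float),
            d["age_years"],
        ])
        beta = np.linalg.solve(X.T @ X, X.T @ d["scat2"].to_numpy())
        assert model.params["C(group)[T.mtbi]"] == pytest.approx(beta[1], rel=1e-9)
        # and the term test surfaces through the module API
        res = adjusted_group_effect(t, "scat2")
        assert set(res) == {"group", "age", "sex"}

    def test_pure_group_offset_recovered(self):
        t = self._table(n_per_group=20, group_shift=-8.0, seed=11)
        res = adjusted_group_effect(t, "scat2")
        assert res["group"].p_value < 1e-3
        assert res["age"].p_value > 0.01 or res["age"].p_value < 1  # noise terms finite
        import statsmodels.formula.api as smf
        fit = smf.ols("scat2 ~ C(group) + age_years + C(sex)",
                      data=t.subset(visit=1)).fit()
        coef = fit.params["C(group)[T.mtbi]"]
        se = fit.bse["C(group)[T.mtbi]"]
        assert abs(coef - (-8.0)) < 2 * se

    def test_without_covariates_equals_two_sample_t(self):
        t = self._table(n_per_group=12, group_shift=-4.0, seed=7)
        res = adjusted_group_effect(t, "scat2", covariates=())
        d = t.subset(visit=1)
        x = d.loc[d.group == "control", "scat2"]
        y = d.loc[d.group == "mtbi", "scat2"]
        t_p = sps.ttest_ind(x, y).pvalue
        assert res["group"].p_value == pytest.approx(t_p, rel=1e-9)

    def test_constant_response_flagged(self):
        t = self._table(n_per_group=6, seed=2)
        t.df["scat2"] = 80.0
        res = adjusted_group_effect(t, "scat2")
        assert not np.isfinite(res["group"].statistic) or res["group"].p_value > 0.99

    def test_rank_deficient_design_rejected(self):
        t = self._table(n_per_group=6, seed=4)
        t.df["age_years"] = 40.0  # constant covariate is collinear with intercept
        with pytest.raises(DesignError):
            adjusted_group_effect(t, "scat2")


class TestNormalityGate:
    def test_constant_input_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            normality_gate([1.0] * 10)

    @pytest.mark.parametrize("n", [2, 5001])
    def test_unsupported_n_rejected(self, n):
        with pytest.raises(UnsupportedSampleSizeError):
            normality_gate(np.arange(n, dtype=float))

    def test_skewed_data_rejected_often(self):
        """Exponential samples at n=50 fail the normality gate > 50%."""
        rng = np.random.default_rng(8)
        rejections = sum(
            not normality_gate(rng.exponential(1.0, 50)).parametric
            for _ in range(200)
        )
        assert rejections / 200 > 0.5

    def test_gaussian_data_mostly_passes(self):
        rng = np.random.default_rng(9)
        passes = sum(
            normality_gate(rng.standard_normal(50)).parametric for _ in range(200)
        )
        assert passes / 200 > 0.85


class TestCohortTableValidation:
    def test_duplicate_subject_visit_rejected(self):
        t = make_table([1.0, 2.0, 3.0], [4.0])
        df = pd.concat([t.df, t.df.iloc[[0]]], ignore_index=True)
        with pytest.raises(InvalidArgumentError):
            CohortTable(df)

    def test_visit2_without_visit1_rejected(self):
        t = make_table([1.0, 2.0, 3.0], [4.0])
        orphan = t.df.iloc[[0]].copy()
        orphan["subject_id"] = "GHOST"
        orphan["visit"] = 2
        with pytest.raises(InvalidArgumentError):
            CohortTable(pd.concat([t.df, orphan], ignore_index=True))

    def test_control_with_injury_date_rejected(self):
        t = make_table([1.0, 2.0], [3.0])
        df = t.df.copy()
        df.loc[df.group == "control", "days_post_injury"] = 12.0
        with pytest.raises(InvalidArgumentError):
            CohortTable(df)


class TestDriver:
    def test_report_contains_all_sections(self):
        table = generate_cohort(study_cohort_params(seed=42))
        res = run_standard_analyses(table)
        assert set(res["section"]) == {
            "demographics", "group_comparison", "paired", "correlation",
            "adjusted", "meta",
        }
        n_tests = res.loc[res.section == "meta", "statistic"].iloc[0]
        n_inferential = len(res[res.section.isin(
            ["group_comparison", "paired", "correlation", "adjusted"])])
        assert n_tests == n_inferential

    def test_demographics_percentages_from_counts(self):
        table = generate_cohort(study_cohort_params(seed=0))
        demo = demographics_summary(table)
        assert demo.loc["control", "pct_male"] == pytest.approx(100 * 11 / 18)
        assert demo.loc["mtbi", "pct_male"] == pytest.approx(72.0)
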