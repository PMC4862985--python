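"""Subject-level statistics for a two-group (control vs mTBI), two-visit
CVR cohort.

The analysis battery mirrors a standard small-cohort neuroimaging workup:
Shapiro–Wilk normality gating, Mann–Whitney U group comparisons (exact for
small samples, normal approximation with continuity and tie correction
otherwise), paired t-tests across visits within patients, Pearson
product-moment correlations, and an additive ANCOVA (response ~ group + age
+ sex) with type-II partial F tests.  All tests are two-sided; no
multiple-testing correction is applied, but the driver reports the number
of tests it ran.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .errors import (
    DesignError,
    InsufficientDataError,
    InvalidArgumentError,
    UndefinedStatisticError,
    UnsupportedSampleSizeError,
)

__all__ = [
    "CohortTable",
    "StatResult",
    "NormalityDecision",
    "group_compare",
    "paired_compare",
    "correlate",
    "adjusted_group_effect",
    "normality_gate",
    "demographics_summary",
    "run_standard_analyses",
]

GROUPS = ("control", "mtbi")

#: columns every cohort table must provide (one row per subject-visit)
REQUIRED_COLUMNS = (
    "subject_id",
    "group",
    "visit",
    "age_years",
    "sex",
    "days_post_injury",
    "scat2",
    "sss",
    "gm_cvr",
    "wm_cvr",
    "brain_cvr",
    "gm_volume_cm3",
    "wm_volume_cm3",
    "petco2_min",
    "petco2_max",
)


@dataclass(frozen=True)
class StatResult:
    """One test's outcome: statistic, two-sided p, sample size, effect."""

    method: str
    statistic: float
    p_value: float
    n: tuple[int, ...] | int
    estimate: float | None = None
    df: float | None = None
    note: str | None = None


@dataclass(frozen=True)
class NormalityDecision:
    """Shapiro–Wilk outcome plus the parametric/non-parametric verdict."""

    w: float
    p_value: float
    n: int
    alpha: float
    parametric: bool


@dataclass
class CohortTable:
    """Validated cohort table, one row per (subject, visit)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise InvalidArgumentError(f"cohort table missing columns: {missing}")
        bad_groups = set(df["group"]) - set(GROUPS)
        if bad_groups:
            raise InvalidArgumentError(f"unknown group labels: {sorted(bad_groups)}")
        if df.duplicated(subset=["subject_id", "visit"]).any():
            raise InvalidArgumentError("(subject_id, visit) pairs must be unique")
        v1 = set(df.loc[df["visit"] == 1, "subject_id"])
        v2 = set(df.loc[df["visit"] == 2, "subject_id"])
        if v2 - v1:
            raise InvalidArgumentError(
                f"visit-2 records without a visit-1 record: {sorted(v2 - v1)[:5]}"
            )
        ctrl_days = df.loc[df["group"] == "control", "days_post_injury"]
        if ctrl_days.notna().any():
            raise InvalidArgumentError("controls must have days_post_injury absent")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, group: str | None = None, visit: int | None = None) -> pd.DataFrame:
        d = self.df
        if group is not None:
            d = d[d["group"] == group]
        if visit is not None:
            d = d[d["visit"] == visit]
        return d

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


def _group_values(table: CohortTable, variable: str, visit: int):
    if variable not in table.df.columns:
        raise InvalidArgumentError(f"unknown variable '{variable}'")
    out = []
    for g in GROUPS:
        vals = table.subset(group=g, visit=visit)[variable].dropna().to_numpy(float)
        if len(vals) == 0:
            raise InsufficientDataError(f"group '{g}' empty for '{variable}' at visit {visit}")
        out.append(vals)
    return out


#: product-size bound below which the exact Mann-Whitney null is enumerated
EXACT_MW_LIMIT = 400


def group_compare(table: CohortTable, variable: str, visit: int = 1) -> StatResult:
    """Two-sided Mann–Whitney U comparing controls vs mTBI on one variable.

    Exact null distribution when ``n1*n2 <= 400`` and the data are tie-free;
    otherwise the normal approximation with continuity and tie correction.
    The reported U counts (control > mtbi) pairs, ties as 1/2; the
    complementary convention is ``n1*n2 - U``.
    """
    x, y = _group_values(table, variable, visit)
    n1, n2 = len(x), len(y)
    ties = len(np.unique(np.concatenate([x, y]))) < n1 + n2
    method = "exact" if (n1 * n2 <= EXACT_MW_LIMIT and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return StatResult(
        method=f"mann-whitney-u ({method})",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=(n1, n2),
        estimate=float(res.statistic) - n1 * n2 / 2.0,
        note="U is for the control sample; complementary U = n1*n2 - U",
    )


def paired_compare(table: CohortTable, variable: str, group: str = "mtbi") -> StatResult:
    """Two-sided paired t-test of visit-2 minus visit-1 within one group.

    Zero-variance differences are reported degenerately: t = 0, p = 1 when
    the mean difference is zero, otherwise p -> 0 with a flag.
    """
    d = table.subset(group=group)
    wide = d.pivot(index="subject_id", columns="visit", values=variable)
    if 1 not in wide.columns or 2 not in wide.columns:
        raise InsufficientDataError(f"no visit-1/visit-2 pairs for '{variable}'")
    wide = wide[[1, 2]].dropna()
    n = len(wide)
    if n < 2:
        raise InsufficientDataError(f"fewer than 2 complete pairs for '{variable}'")
    diff = wide[2].to_numpy(float) - wide[1].to_numpy(float)
    mean_d = float(diff.mean())
    sd_d = float(diff.std(ddof=1))
    if sd_d == 0.0:
        if mean_d == 0.0:
            return StatResult("paired-t", 0.0, 1.0, n, 0.0, float(n - 1),
                              note="all differences zero")
        return StatResult(
            "paired-t", float(np.sign(mean_d)) * np.inf, 0.0, n, mean_d, float(n - 1),
            note="degenerate zero-variance differences; p reported as limit 0",
        )
    t = mean_d / (sd_d / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return StatResult("paired-t", float(t), float(p), n, mean_d, float(n - 1))


def correlate(
    table: CohortTable,
    x: str,
    y: str,
    group: str | None = None,
    visit: int | None = 1,
) -> StatResult:
    """Pearson product-moment correlation with a two-sided t-transform p.

    Missing values are removed pairwise; requires >= 3 complete pairs and
    nonzero variance in both variables.
    """
    d = table.subset(group=group, visit=visit)
    for col in (x, y):
        if col not in d.columns:
            raise InvalidArgumentError(f"unknown variable '{col}'")
    pairs = d[[x, y]].dropna()
    n = len(pairs)
    if n < 3:
        raise InsufficientDataError(f"only {n} complete ({x}, {y}) pairs; need >= 3")
    xv = pairs[x].to_numpy(float)
    yv = pairs[y].to_numpy(float)
    if np.ptp(xv) == 0.0 or np.ptp(yv) == 0.0:
        raise UndefinedStatisticError(f"zero variance in '{x}' or '{y}'")
    r, p = sps.pearsonr(xv, yv)
    return StatResult("pearson-r", float(r), float(p), n, estimate=float(r), df=float(n - 2))


_COVARIATE_TERMS = {"age": "age_years", "age_years": "age_years", "sex": "C(sex)"}


def adjusted_group_effect(
    table: CohortTable,
    response: str,
    covariates: tuple[str, ...] = ("age", "sex"),
    visit: int = 1,
) -> dict[str, StatResult]:
    """Additive ANCOVA ``response ~ group + covariates`` via OLS.

    Returns one type-II partial-F :class:`StatResult` per model term
    (keys: 'group' plus each covariate).  Sex enters as a 0/1 indicator.
    """
    if response not in table.df.columns:
        raise InvalidArgumentError(f"unknown response '{response}'")
    terms = ["C(group)"]
    names = ["group"]
    for c in covariates:
        if c not in _COVARIATE_TERMS:
            raise InvalidArgumentError(f"unsupported covariate '{c}'")
        terms.append(_COVARIATE_TERMS[c])
        names.append("age" if "age" in c else "sex")
    cols = ["group", response] + [
        ("age_years" if "age" in c else "sex") for c in covariates
    ]
    d = table.subset(visit=visit)[list(dict.fromkeys(cols))].dropna()
    counts = d["group"].value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise InsufficientDataError("need >= 2 subjects per group")

    formula = f"{response} ~ " + " + ".join(terms)
    model = smf.ols(formula, data=d).fit()
    exog = model.model.exog
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise DesignError("rank-deficient design matrix (collinear terms)")

    with np.errstate(invalid="ignore", divide="ignore"):
        anova = anova_lm(model, typ=2)
    out: dict[str, StatResult] = {}
    for term, name in zip(terms, names):
        row = anova.loc[term]
        f = float(row["F"])
        p = float(row["PR(>F)"])
        note = None
        if not np.isfinite(f):
            note = "undefined F (zero residual or effect variance)"
        out[name] = StatResult(
            "ancova-type2-F", f, p, len(d), df=float(row["df"]), note=note
        )
    return out


def normality_gate(values, alpha: float = 0.05) -> NormalityDecision:
    """Shapiro–Wilk gate: 'parametric' iff p >= alpha (default 0.05)."""
    v = np.asarray(pd.Series(values).dropna(), dtype=float)
    n = len(v)
    if n < 3 or n > 5000:
        raise UnsupportedSampleSizeError(f"Shapiro-Wilk supports 3 <= n <= 5000, got {n}")
    if np.ptp(v) == 0.0:
        raise UndefinedStatisticError("Shapiro-Wilk W undefined for constant input")
    w, p = sps.shapiro(v)
    return NormalityDecision(float(w), float(p), n, alpha, bool(p >= alpha))


def demographics_summary(table: CohortTable) -> pd.DataFrame:
    """Per-group visit-1 demographics: n, male count and %, age, days.

    Percentages are computed from counts, e.g. male% = 100 * n_male / n.
    """
    rows = []
    for g in GROUPS:
        d = table.subset(group=g, visit=1)
        n = len(d)
        n_male = int((d["sex"] == "M").sum())
        row = {
            "group": g,
            "n": n,
            "n_male": n_male,
            "pct_male": 100.0 * n_male / n if n else np.nan,
            "age_mean": float(d["age_years"].mean()) if n else np.nan,
            "age_sd": float(d["age_years"].std(ddof=1)) if n > 1 else np.nan,
        }
        days = d["days_post_injury"].dropna()
        row["days_post_injury_mean"] = float(days.mean()) if len(days) else np.nan
        row["days_post_injury_sd"] = float(days.std(ddof=1)) if len(days) > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------------
# preset analysis driver

GROUP_COMPARE_VARS = (
    "sss", "scat2", "wm_cvr", "gm_cvr", "brain_cvr",
    "gm_volume_cm3", "wm_volume_cm3", "petco2_min", "petco2_max",
)
PAIRED_VARS = (
    "scat2", "sss", "wm_cvr", "gm_cvr", "brain_cvr", "gm_volume_cm3", "wm_volume_cm3",
)
CORRELATION_PAIRS = (
    ("scat2", "wm_cvr", "control"),
    ("scat2", "gm_cvr", "control"),
    ("scat2", "brain_cvr", "control"),
    ("scat2", "gm_volume_cm3", "control"),
    ("age_years", "scat2", "control"),
    ("scat2", "wm_cvr", "mtbi"),
    ("scat2", "gm_cvr", "mtbi"),
    ("scat2", "brain_cvr", "mtbi"),
    ("scat2", "gm_volume_cm3", "mtbi"),
    ("wm_cvr", "wm_volume_cm3", "mtbi"),
    ("age_years", "scat2", "mtbi"),
)


def _gated_group_compare(table: CohortTable, variable: str, visit: int, alpha: float):
    """Choose the comparison family by a per-group Shapiro–Wilk gate."""
    x, y = _group_values(table, variable, visit)
    try:
        parametric = all(normality_gate(v, alpha).parametric for v in (x, y))
    except (UndefinedStatisticError, UnsupportedSampleSizeError):
        parametric = False
    if parametric:
        t, p = sps.ttest_ind(x, y)
        return StatResult(
            "two-sample-t", float(t), float(p), (len(x), len(y)),
            estimate=float(np.mean(x) - np.mean(y)), df=float(len(x) + len(y) - 2),
        )
    return group_compare(table, variable, visit)


def run_standard_analyses(table: CohortTable, alpha: float = 0.05) -> pd.DataFrame:
    """Run the full preset battery and return one tidy results table.

    Sections: 'demographics', 'group_comparison' (visit 1, family chosen by
    the normality gate), 'paired' (mTBI visit 2 - visit 1), 'correlation'
    (per-group, visit 1), and 'adjusted' (SCAT2 ~ group + age + sex,
    type-II F).  A trailing 'meta' row records the number of inferential
    tests performed (no multiplicity correction is applied).
    """
    rows: list[dict] = []

    demo = demographics_summary(table)
    for g, r in demo.iterrows():
        rows.append({
            "section": "demographics", "variable": "male_pct", "group": g,
            "method": "count", "statistic": r["n_male"], "p_value": np.nan,
            "n": int(r["n"]), "estimate": r["pct_male"],
        })
        rows.append({
            "section": "demographics", "variable": "age_years", "group": g,
            "method": "mean_sd", "statistic": r["age_mean"], "p_value": np.nan,
            "n": int(r["n"]), "estimate": r["age_sd"],
        })

    n_tests = 0
    for var in GROUP_COMPARE_VARS:
        res = _gated_group_compare(table, var, 1, alpha)
        n_tests += 1
        rows.append({
            "section": "group_comparison", "variable": var, "group": "control-vs-mtbi",
            "method": res.method, "statistic": res.statistic, "p_value": res.p_value,
            "n": sum(res.n) if isinstance(res.n, tuple) else res.n,
            "estimate": res.estimate,
        })

    has_pairs = (table.df["visit"] == 2).any()
    if has_pairs:
        for var in PAIRED_VARS:
            res = paired_compare(table, var)
            n_tests += 1
            rows.append({
                "section": "paired", "variable": var, "group": "mtbi",
                "method": res.method, "statistic": res.statistic,
                "p_value": res.p_value, "n": res.n, "estimate": res.estimate,
            })

    for x, y, g in CORRELATION_PAIRS:
        try:
            res = correlate(table, x, y, group=g, visit=1)
        except (InsufficientDataError, UndefinedStatisticError):
            continue
        n_tests += 1
        rows.append({
            "section": "correlation", "variable": f"{x}~{y}", "group": g,
            "method": res.method, "statistic": res.statistic,
            "p_value": res.p_value, "n": res.n, "estimate": res.estimate,
        })

    for term, res in adjusted_group_effect(table, "scat2").items():
        n_tests += 1
        rows.append({
            "section": "adjusted", "variable": f"scat2~{term}", "group": "all",
            "method": res.method, "statistic": res.statistic,
            "p_value": res.p_value, "n": res.n, "estimate": res.estimate,
        })

    rows.append({
        "section": "meta", "variable": "n_tests_uncorrected", "group": "all",
        "method": "count", "statistic": float(n_tests), "p_value": np.nan,
        "n": len(table.df), "estimate": None,
    })
    return pd.DataFrame(rows)
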