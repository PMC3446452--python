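"""Group-comparison and correlation statistics for cohort tables.

The layer mirrors the analysis plan of a three-group (naive / sham /
operated) behavioral study:

* one-sample t tests of per-animal means against the null constants of
  balanced, symmetric gait (symmetry 0.5, stance-time balance 0, weight
  distribution 50%);
* full-factorial two-factor ANOVA (group x time) with Type II sums of
  squares for unbalanced designs, and Tukey HSD post hoc pairwise tests;
* a linear model adding trial velocity as a covariate for the
  velocity-dependent metrics (stride length, step width);
* Kruskal-Wallis rank tests for ordinal histology grades;
* a Shapiro-Wilk normality gate with log10 transform for cytokine panels,
  followed by one-factor ANOVA + Tukey;
* univariate regressions Y = b0 + b1*X of every lesion measure on every
  endpoint behavior, reported as R^2, slope +/- SE, and the p-value of b1.

Model fitting is delegated to statsmodels/scipy; this module owns the
study-specific contracts (null constants, degenerate-data conventions,
detection-limit handling, table shapes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

from .exceptions import InsufficientDataError, ParameterError

#: null constants of balanced, symmetric gait
NULL_CONSTANTS = {"symmetry": 0.5,
                  "stance_time_balance_pct": 0.0,
                  "weight_distribution_pct": 50.0}

_ZERO_SS_TOL = 1e-10


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    mean: float
    n: int
    degenerate: bool = False


def one_sample_repeated_t(values, null_constant: float) -> TTestResult:
    """One-sample t of per-animal means against a gait null constant.

    ``values`` holds one (already collapsed) mean per animal.  A
    zero-variance sample equal to the constant gives t=0, p=1; a
    zero-variance sample away from the constant is flagged degenerate.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InsufficientDataError(
            f"need at least 2 animals, got {values.size}")
    mean = float(values.mean())
    if float(values.std(ddof=1)) == 0.0:
        if mean == null_constant:
            return TTestResult(0.0, values.size - 1, 1.0, mean, values.size)
        return TTestResult(np.inf, values.size - 1, 0.0, mean, values.size,
                           degenerate=True)
    t, p = sps.ttest_1samp(values, null_constant)
    return TTestResult(float(t), values.size - 1, float(p), mean, values.size)


def collapse_to_animal_means(df: pd.DataFrame, value: str = "value",
                             by: tuple[str, ...] = ("animal",)) -> pd.Series:
    """Average repeated measures to one mean per animal (the test unit)."""
    return df.groupby(list(by), sort=True)[value].mean()


def _clean_term(term: str, factors: list[str]) -> str:
    for f in factors:
        term = term.replace(f"C(Q('{f}'))", f)
    return term


def factorial_anova(df: pd.DataFrame, response: str,
                    factors: list[str], interaction: bool = True,
                    covariates: list[str] | None = None) -> pd.DataFrame:
    """Factorial ANOVA with Type II sums of squares.

    Returns one row per term: ``term, sum_sq, df, F, p, estimable``.  Terms
    with (numerically) zero sum of squares in a zero-residual fit are
    reported as F=0, p=1; terms made inestimable by empty cells carry
    ``estimable=False``.  Type II sums of squares keep main-effect tests
    order-independent in unbalanced designs.
    """
    for col in [response, *factors, *(covariates or [])]:
        if col not in df.columns:
            raise ParameterError(f"column {col!r} missing from the table")
    for f in factors:
        if df[f].nunique() < 2:
            raise ParameterError(f"factor {f!r} needs at least 2 levels")
    rhs = " * ".join(f"C(Q('{f}'))" for f in factors) if interaction \
        else " + ".join(f"C(Q('{f}'))" for f in factors)
    for cov in covariates or []:
        rhs += f" + Q('{cov}')"
    model = smf.ols(f"Q('{response}') ~ {rhs}", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels divide-by-zero noise
        table = anova_lm(model, typ=2)

    total_ss = float(np.nansum(table["sum_sq"]))
    tol = _ZERO_SS_TOL * max(total_ss, 1.0)
    resid_ss = float(table.loc["Residual", "sum_sq"])
    rows = []
    for term, row in table.iterrows():
        if term == "Residual":
            continue
        name = _clean_term(str(term), [*factors, *(covariates or [])])
        name = name.replace("Q('", "").replace("')", "")
        ss, dff = float(row["sum_sq"]), float(row["df"])
        F, p = float(row["F"]), float(row["PR(>F)"])
        estimable = np.isfinite(ss) and dff > 0
        if estimable and resid_ss < tol:
            if ss < tol:
                F, p = 0.0, 1.0  # no variation anywhere: no effect
            else:
                F, p = np.inf, 0.0  # term explains a zero-noise response
        rows.append((name, ss, dff, F, p, estimable))
    rows.append(("Residual", resid_ss,
                 float(table.loc["Residual", "df"]), np.nan, np.nan, True))
    return pd.DataFrame(
        rows, columns=["term", "sum_sq", "df", "F", "p", "estimable"])


def tukey_hsd(*groups, labels: list[str] | None = None) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons sharing the ANOVA pooled variance.

    Returns one row per unordered pair with the studentized-range-based
    adjusted p-value.  With two groups the adjusted p equals the pooled
    two-sample t-test p.  Identical groups give statistic 0, p 1.
    """
    if len(groups) < 2:
        raise ParameterError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(arrays))]
    pooled_var = np.sum([(a.size - 1) * a.var(ddof=1) if a.size > 1 else 0.0
                         for a in arrays])
    rows = []
    if pooled_var == 0.0:  # degenerate: no within-group variance at all
        for i, j in combinations(range(len(arrays)), 2):
            same = arrays[i].mean() == arrays[j].mean()
            rows.append((labels[i], labels[j],
                         arrays[i].mean() - arrays[j].mean(),
                         0.0 if same else np.inf, 1.0 if same else 0.0))
    else:
        res = sps.tukey_hsd(*arrays)
        for i, j in combinations(range(len(arrays)), 2):
            rows.append((labels[i], labels[j],
                         float(res.statistic[i, j]),
                         float(res.statistic[i, j]),
                         float(res.pvalue[i, j])))
    return pd.DataFrame(
        rows, columns=["group1", "group2", "mean_diff", "statistic", "p"])


@dataclass(frozen=True)
class AncovaResult:
    anova: pd.DataFrame
    velocity_slope: float | None
    params: pd.Series
    covariate_dropped: bool = False


def ancova_velocity(df: pd.DataFrame, response: str = "value",
                    group: str = "group", time: str = "day",
                    velocity: str = "velocity") -> AncovaResult:
    """Group x time linear model with a velocity covariate.

    Stride length and step width correlate with an animal's self-selected
    walking speed; adding trial velocity as a linear covariate adjusts the
    group and time effects for it.  A constant velocity column is dropped
    with a warning.
    """
    covariates = [velocity]
    dropped = False
    if df[velocity].nunique() <= 1:
        warnings.warn("velocity is constant; covariate dropped",
                      stacklevel=2)
        covariates = []
        dropped = True
    table = factorial_anova(df, response, [group, time],
                            covariates=covariates)
    rhs = f"C(Q('{group}')) * C(Q('{time}'))"
    if covariates:
        rhs += f" + Q('{velocity}')"
    model = smf.ols(f"Q('{response}') ~ {rhs}", data=df).fit()
    slope = None if dropped else float(model.params[f"Q('{velocity}')"])
    return AncovaResult(anova=table, velocity_slope=slope,
                        params=model.params, covariate_dropped=dropped)


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    All-identical observations (zero rank variance) return H=0, p=1.
    """
    if len(groups) < 2:
        raise ParameterError("need at least 2 groups")
    for g in groups:
        if len(g) < 1:
            raise ParameterError("every group needs at least 1 observation")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.ptp(pooled) == 0.0:
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def cytokine_compare(df: pd.DataFrame, alpha_normality: float = 0.05
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normality-gated group comparison of cytokine concentrations.

    ``df`` columns: ``animal, group, analyte, value, below_detection``.
    Non-detects are excluded (never imputed) and reported as a
    detectability percentage.  Per analyte: Shapiro-Wilk on the raw
    detectable values; if W's p < ``alpha_normality`` the values are log10
    transformed; then one-factor ANOVA across groups with Tukey HSD
    pairwise tests.  Analytes below detection in all samples — or with
    fewer than two groups having two detectable values — are untestable.

    Returns ``(summary, pairwise)`` tables.
    """
    required = {"animal", "group", "analyte", "value", "below_detection"}
    missing = required - set(df.columns)
    if missing:
        raise ParameterError(f"missing columns {sorted(missing)}")
    summaries, pair_rows = [], []
    for analyte, sub in df.groupby("analyte", sort=True):
        n_total = len(sub)
        detectable = sub[~sub["below_detection"].astype(bool)
                         & sub["value"].notna()]
        pct = 100.0 * len(detectable) / n_total if n_total else 0.0
        base = {"analyte": analyte, "n_total": n_total,
                "pct_detectable": pct, "shapiro_p": np.nan,
                "log_transformed": False, "F": np.nan, "p": np.nan}
        if len(detectable) == 0:
            base["status"] = "untestable_all_below_detection"
            summaries.append(base)
            continue
        counts = detectable.groupby("group")["value"].count()
        usable = counts[counts >= 2].index.tolist()
        if len(usable) < 2:
            base["status"] = "untestable_insufficient_groups"
            summaries.append(base)
            continue
        values = detectable[detectable["group"].isin(usable)].copy()
        raw = values["value"].to_numpy(dtype=float)
        if raw.size >= 3 and np.ptp(raw) > 0:
            base["shapiro_p"] = float(sps.shapiro(raw).pvalue)
        if np.isfinite(base["shapiro_p"]) \
                and base["shapiro_p"] < alpha_normality:
            if (raw <= 0).any():
                raise ParameterError(
                    f"{analyte}: non-positive concentration cannot be "
                    "log-transformed")
            values["value"] = np.log10(values["value"])
            base["log_transformed"] = True
        arrays, labels = [], []
        for group, g in values.groupby("group", sort=True):
            arrays.append(g["value"].to_numpy(dtype=float))
            labels.append(group)
        if np.ptp(np.concatenate(arrays)) == 0.0:
            base.update(F=0.0, p=1.0, status="tested")
        else:
            F, p = sps.f_oneway(*arrays)
            base.update(F=float(F), p=float(p), status="tested")
            pairs = tukey_hsd(*arrays, labels=labels)
            pairs.insert(0, "analyte", analyte)
            pair_rows.append(pairs)
        summaries.append(base)
    summary = pd.DataFrame(summaries)
    pairwise = (pd.concat(pair_rows, ignore_index=True) if pair_rows
                else pd.DataFrame(columns=["analyte", "group1", "group2",
                                           "mean_diff", "statistic", "p"]))
    return summary, pairwise


@dataclass(frozen=True)
class RegressionResult:
    """Univariate linear fit Y = b0 + b1*X."""

    beta0: float
    beta1: float
    se_beta1: float
    r_squared: float
    p_beta1: float
    n: int
    flag: str = ""


def univariate_regression(x, y) -> RegressionResult:
    """Least-squares fit of Y on X with the significance of the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        return RegressionResult(np.nan, np.nan, np.nan, np.nan, np.nan,
                                int(x.size), flag="insufficient_n")
    if np.ptp(x) == 0.0:
        return RegressionResult(np.nan, np.nan, np.nan, np.nan, np.nan,
                                int(x.size), flag="constant_x")
    fit = sps.linregress(x, y)
    return RegressionResult(beta0=float(fit.intercept),
                            beta1=float(fit.slope),
                            se_beta1=float(fit.stderr),
                            r_squared=float(fit.rvalue ** 2),
                            p_beta1=float(fit.pvalue), n=int(x.size))


def correlation_table(data: pd.DataFrame, behaviors: list[str],
                      lesions: list[str],
                      adjust: str | None = None) -> pd.DataFrame:
    """Endpoint-behavior vs lesion regression matrix.

    ``data`` is wide (one row per animal).  Each (behavior, lesion) pair is
    fit as lesion = b0 + b1*behavior; the table reports R^2, b1 +/- SE, p,
    and n per cell.  ``adjust='bh'`` adds Benjamini-Hochberg adjusted
    p-values; the default reports unadjusted p-values.
    """
    rows = []
    for behavior in behaviors:
        for lesion in lesions:
            res = univariate_regression(data[behavior], data[lesion])
            rows.append({"behavior": behavior, "lesion": lesion,
                         "n": res.n, "beta0": res.beta0, "beta1": res.beta1,
                         "se_beta1": res.se_beta1,
                         "r_squared": res.r_squared, "p": res.p_beta1,
                         "flag": res.flag})
    table = pd.DataFrame(rows)
    if adjust == "bh":
        ok = table["p"].notna()
        adj = np.full(len(table), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(
                table.loc[ok, "p"], method="fdr_bh")[1]
        table["p_adj"] = adj
    elif adjust is not None:
        raise ParameterError(f"unknown adjustment {adjust!r}")
    return table


def paired_limb_tests(df: pd.DataFrame, value: str = "value",
                      limb: str = "limb", day: str = "day",
                      animal: str = "animal",
                      operated: str = "RH", contralateral: str = "LH"
                      ) -> pd.DataFrame:
    """Operated vs contralateral paired t per timepoint, Bonferroni-corrected
    across timepoints."""
    rows = []
    days = sorted(df[day].unique())
    for d in days:
        sub = df[df[day] == d].pivot_table(index=animal, columns=limb,
                                           values=value)
        if operated not in sub.columns or contralateral not in sub.columns:
            continue
        paired = sub[[operated, contralateral]].dropna()
        if len(paired) < 2:
            continue
        diff = paired[operated] - paired[contralateral]
        if float(diff.std(ddof=1)) == 0.0:
            t, p = (0.0, 1.0) if diff.mean() == 0 else (np.inf, 0.0)
        else:
            t, p = sps.ttest_rel(paired[operated], paired[contralateral])
        rows.append({"day": d, "n": len(paired), "t": float(t),
                     "p": float(p), "mean_diff": float(diff.mean())})
    table = pd.DataFrame(rows)
    if len(table):
        table["p_bonferroni"] = np.minimum(table["p"] * len(table), 1.0)
    return table
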