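"""Statistical layer for paired-eye cohort data.

Both eyes of a participant enter the analysis, so observations are
correlated within participant.  Group contrasts (DS vs CTRL reference)
are estimated with generalized estimating equations (GEE) under an
exchangeable working correlation, adjusted for age and sex, with robust
(sandwich) standard errors; linear models for continuous outcomes and
logistic models for binary ones.  Supporting pieces: descriptive tables,
chi-squared / Fisher / Wilcoxon group tests, a leave-one-out outlier
imputation rule (GEEs are sensitive to extreme values), Benjamini-
Hochberg FDR adjustment within outcome families, and a marginal R^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.genmod.cov_struct import Exchangeable, Independence
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GEEResult",
    "descriptive_table",
    "group_tests",
    "impute_outliers",
    "fit_gee",
    "fdr_adjust",
    "marginal_r2",
    "outcome_table",
]

GROUP_LEVELS = ("CTRL", "DS")     # CTRL is the reference arm


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention of reported percentages)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def descriptive_table(
    cohort: pd.DataFrame,
    variable: str,
    by: str = "group",
    categorical: bool | None = None,
) -> pd.DataFrame:
    """Descriptive summary of one variable per group.

    Categorical variables: absolute frequency and percentage (one
    decimal, half-up) of non-missing observations within each group.
    Continuous variables: mean, SD, min, max.
    """
    if variable not in cohort.columns:
        raise ValueError(f"no column {variable!r}")
    if categorical is None:
        categorical = (not pd.api.types.is_numeric_dtype(cohort[variable])
                       or pd.api.types.is_bool_dtype(cohort[variable]))
    rows = []
    for grp, sub in cohort.groupby(by, observed=True):
        vals = sub[variable].dropna()
        if categorical:
            n_total = len(vals)
            for level, n in vals.value_counts().sort_index().items():
                pct = round_half_up(100.0 * n / n_total, 1) if n_total else np.nan
                rows.append({by: grp, "level": level, "n": int(n), "pct": pct})
        else:
            rows.append({by: grp, "n": len(vals),
                         "mean": float(vals.mean()) if len(vals) else np.nan,
                         "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                         "min": float(vals.min()) if len(vals) else np.nan,
                         "max": float(vals.max()) if len(vals) else np.nan})
    return pd.DataFrame(rows)


def group_tests(
    cohort: pd.DataFrame,
    variable: str,
    by: str = "group",
    kind: str = "auto",
    fisher_expected_min: float = 5.0,
) -> tuple[float, float, str]:
    """Two-sided group difference test: chi-squared / Fisher exact / rank-sum.

    Categorical variables use Pearson's chi-squared, switching to
    Fisher's exact test when any expected cell count is at most
    ``fisher_expected_min`` (2x2 tables only).  Continuous variables use
    the Wilcoxon rank-sum (Mann-Whitney) test.

    Returns ``(statistic, p_value, test_name)``.
    """
    data = cohort[[by, variable]].dropna()
    groups = [g for _, g in data.groupby(by, observed=True)]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups with data")
    if kind == "auto":
        kind = ("categorical"
                if not pd.api.types.is_numeric_dtype(data[variable])
                or pd.api.types.is_bool_dtype(data[variable])
                else "continuous")
    if kind == "categorical":
        table = pd.crosstab(data[by], data[variable]).to_numpy()
        chi2, p, _, expected = sps.chi2_contingency(table, correction=False)
        if (expected <= fisher_expected_min).any() and table.shape == (2, 2):
            odds, p = sps.fisher_exact(table, alternative="two-sided")
            return float(odds), float(p), "fisher_exact"
        return float(chi2), float(p), "chi_squared"
    x, y = groups[0][variable].to_numpy(float), groups[1][variable].to_numpy(float)
    if np.ptp(np.concatenate([x, y])) == 0:
        raise ValueError("variable is constant; rank-sum test undefined")
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="exact" if len(x) + len(y) <= 25 else "auto")
    return float(res.statistic), float(res.pvalue), "wilcoxon_rank_sum"


def impute_outliers(
    values: np.ndarray,
    groups: np.ndarray,
    k_sd: float = 3.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Single-pass imputation of extreme values to the group mean.

    A value is extreme when it lies more than ``k_sd`` leave-one-out
    standard deviations from the leave-one-out mean of its group; it is
    replaced by that leave-one-out mean.  Flags are decided on the
    original data, then all replacements applied at once.  Returns the
    cleaned vector and a log with one row per replacement.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    cleaned = values.copy()
    log_rows = []
    for g in pd.unique(groups):
        idx = np.flatnonzero((groups == g) & ~np.isnan(values))
        if len(idx) < 3:
            continue
        v = values[idx]
        n = len(v)
        s, ss = v.sum(), (v ** 2).sum()
        for j, val in zip(idx, v):
            mean_loo = (s - val) / (n - 1)
            # leave-one-out sample variance (ddof=1 over the n-1 kept values)
            var_loo = (ss - val ** 2 - (n - 1) * mean_loo ** 2) / (n - 2)
            sd_loo = np.sqrt(max(var_loo, 0.0))
            if np.isfinite(k_sd) and abs(val - mean_loo) > k_sd * sd_loo:
                cleaned[j] = mean_loo
                log_rows.append({"index": int(j), "group": g,
                                 "original": float(val),
                                 "replacement": float(mean_loo),
                                 "k_sd": float(k_sd)})
    log = pd.DataFrame(log_rows,
                       columns=["index", "group", "original", "replacement", "k_sd"])
    return cleaned, log


@dataclass
class GEEResult:
    """Tidy GEE fit: one row per model term plus model-level metadata."""

    outcome: str
    family: str                        # "gaussian" | "binomial"
    table: pd.DataFrame                # term, estimate, robust_se, ci_low, ci_high, p
    n_obs: int
    n_clusters: int
    working_correlation: float
    fitted_values: np.ndarray
    observed: np.ndarray
    linear_predictor: np.ndarray

    def term(self, name: str) -> pd.Series:
        return self.table.set_index("term").loc[name]


def fit_gee(
    cohort: pd.DataFrame,
    outcome: str,
    family: str = "gaussian",
    covariates: tuple[str, ...] = ("group", "age", "sex"),
    cluster: str = "participant_id",
    corstr: str = "exchangeable",
    maxiter: int = 100,
) -> GEEResult:
    """Fit a GEE model of ``outcome`` on group (+ adjustments), clustered by participant.

    ``group`` is coded with CTRL as the reference level, so the group
    coefficient is the DS-vs-CTRL mean difference (gaussian) or log odds
    ratio (binomial).  Robust sandwich standard errors, Wald CIs and
    p-values are reported.
    """
    cols = [outcome, cluster, *covariates]
    data = cohort[cols].dropna().copy()
    n_clusters = data[cluster].nunique()
    if n_clusters < 10:
        raise ValueError(f"need >= 10 clusters, got {n_clusters}")
    y = data[outcome].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("outcome is constant")

    X = pd.DataFrame({"Intercept": np.ones(len(data))}, index=data.index)
    for cov in covariates:
        col = data[cov]
        if cov == "group":
            levels = [l for l in GROUP_LEVELS if l in set(col)]
            extra = sorted(set(col) - set(GROUP_LEVELS))
            for level in levels[1:] + extra:
                X[f"group[{level}]"] = (col == level).astype(float)
        elif not pd.api.types.is_numeric_dtype(col) or pd.api.types.is_bool_dtype(col):
            ref, *others = sorted(col.unique())
            for level in others:
                X[f"{cov}[{level}]"] = (col == level).astype(float)
        else:
            X[cov] = col.astype(float)

    fam = {"gaussian": sm.families.Gaussian(),
           "binomial": sm.families.Binomial()}[family]
    cov_struct = {"exchangeable": Exchangeable(),
                  "independence": Independence()}[corstr]
    if family == "binomial":
        # flag complete separation: a predictor perfectly splits the outcome
        for name in X.columns[1:]:
            grp0 = y[X[name] <= X[name].median()]
            grp1 = y[X[name] > X[name].median()]
            if len(grp0) and len(grp1) and (grp0.max() < y.min() + 1e-12
                                            or grp1.min() > y.max() - 1e-12):
                import warnings
                warnings.warn(f"possible separation on term {name!r}")

    model = sm.GEE(y, X, groups=data[cluster].to_numpy(), family=fam,
                   cov_struct=cov_struct)
    res = model.fit(maxiter=maxiter)
    if not np.all(np.isfinite(res.params)):
        raise RuntimeError(
            f"GEE did not converge for outcome {outcome!r} within {maxiter} iterations")

    ci = res.conf_int()
    table = pd.DataFrame({
        "term": X.columns,
        "estimate": np.asarray(res.params),
        "robust_se": np.asarray(res.bse),
        "ci_low": np.asarray(ci)[:, 0],
        "ci_high": np.asarray(ci)[:, 1],
        "p": np.asarray(res.pvalues),
    })
    if family == "binomial":
        table["odds_ratio"] = np.exp(table["estimate"])
    dep_raw = cov_struct.dep_params
    if dep_raw is None:
        dep = 0.0            # independence working correlation
    elif np.isscalar(dep_raw):
        dep = float(dep_raw)
    else:
        dep = float(np.atleast_1d(dep_raw)[0])
    lin = np.asarray(X.to_numpy(dtype=float) @ np.asarray(res.params))
    return GEEResult(
        outcome=outcome, family=family, table=table,
        n_obs=len(data), n_clusters=n_clusters,
        working_correlation=float(dep),
        fitted_values=np.asarray(res.fittedvalues),
        observed=y, linear_predictor=lin,
    )


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone in the raw ranks)."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def marginal_r2(result: GEEResult) -> float:
    """Squared Pearson correlation between the linear predictor and the outcome."""
    lp = result.linear_predictor
    if np.ptp(lp) == 0:
        return 0.0
    return float(np.corrcoef(lp, result.observed)[0, 1] ** 2)


def outcome_table(
    cohort: pd.DataFrame,
    outcomes: dict[str, str],
    fdr_families: dict[str, list[str]] | None = None,
    **gee_kwargs,
) -> pd.DataFrame:
    """Fit GEE models for several outcomes and FDR-adjust within families.

    ``outcomes`` maps outcome column -> family ("gaussian"/"binomial");
    ``fdr_families`` maps a family label -> list of outcome columns
    sharing one FDR adjustment (default: all outcomes form one family).
    Returns a tidy table of the group term per outcome.
    """
    rows = []
    for outcome, family in outcomes.items():
        res = fit_gee(cohort, outcome, family=family, **gee_kwargs)
        grp_terms = [t for t in res.table["term"] if t.startswith("group[")]
        row = res.term(grp_terms[0]).to_dict() if grp_terms else {}
        row.update({"outcome": outcome, "family": family,
                    "n_clusters": res.n_clusters,
                    "working_correlation": res.working_correlation})
        rows.append(row)
    table = pd.DataFrame(rows)
    table["p_fdr"] = np.nan
    families = fdr_families or {"all": list(outcomes)}
    for _, members in families.items():
        sel = table["outcome"].isin(members)
        if sel.any():
            table.loc[sel, "p_fdr"] = fdr_adjust(table.loc[sel, "p"].to_numpy())
    return table
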