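"""Concordance analysis of the five inbreeding coefficients.

Descriptive statistics, Shapiro-Wilk normality tests, Spearman rank
correlations among F_PED, F_HOM, F_ROH, F_HBD and F_GRM, ordinary
least-squares regressions of F_PED on each genomic coefficient, the
partitioning of autozygosity into length/age classes, and birth-year
medians.  Missing values are handled pairwise; p < 0.05 is reported as
significant with no multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

COEFFICIENTS = ["f_ped", "f_hom", "f_roh", "f_hbd", "f_grm"]
GENOMIC_COEFFICIENTS = ["f_hom", "f_roh", "f_hbd", "f_grm"]


@dataclass
class RegressionResult:
    predictor: str
    slope: float
    intercept: float
    r2: float
    adj_r2: float
    p_value: float
    n: int
    fitted: np.ndarray
    residuals: np.ndarray


def _clean(values) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no non-missing values")
    return x


def describe(values) -> dict[str, float]:
    """Mean, sample sd (n-1), min, max, n and median over non-missing
    values; raises if nothing remains."""
    x = _clean(values)
    return {
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0,
        "min": float(x.min()),
        "max": float(x.max()),
        "n": int(x.size),
        "median": float(np.median(x)),
    }


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p; defined for 3 <= n <= 5000."""
    x = _clean(values)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation on pairwise-complete observations, average
    ranks for ties, p from the t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete pairs")
    rho, p = sps.spearmanr(x[ok], y[ok])
    return float(rho), float(p)


def regress_fped(table: pd.DataFrame, predictor: str) -> RegressionResult:
    """OLS of F_PED on one genomic coefficient (pairwise-complete rows).

    Returns slope, intercept, R², adjusted R² and the slope p-value (for a
    single predictor this equals the model F-test p), plus fitted values
    and residuals for visual diagnostics.
    """
    sub = table[["f_ped", predictor]].dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 complete pairs")
    x = sub[predictor].to_numpy()
    if np.ptp(x) == 0:
        raise ValueError(f"predictor {predictor} has zero variance")
    model = sm.OLS(sub["f_ped"].to_numpy(), sm.add_constant(x)).fit()
    return RegressionResult(
        predictor=predictor,
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r2=float(model.rsquared),
        adj_r2=float(model.rsquared_adj),
        p_value=float(model.pvalues[1]),
        n=int(model.nobs),
        fitted=np.asarray(model.fittedvalues),
        residuals=np.asarray(model.resid),
    )


def summary_table(table: pd.DataFrame,
                  coefficients: list[str] | None = None) -> pd.DataFrame:
    """Descriptive statistics per coefficient plus Shapiro-Wilk normality."""
    rows = []
    for c in coefficients or COEFFICIENTS:
        if c not in table:
            continue
        try:
            d = describe(table[c])
        except ValueError:  # estimator produced no values for this cohort
            d = {k: np.nan for k in ("mean", "sd", "min", "max", "median")}
            d["n"] = 0
        try:
            w, p = shapiro_wilk(table[c])
        except ValueError:
            w, p = np.nan, np.nan
        rows.append({"coefficient": c, **d, "shapiro_w": w, "shapiro_p": p})
    return pd.DataFrame(rows).set_index("coefficient")


def correlation_matrix(table: pd.DataFrame,
                       coefficients: list[str] | None = None) -> pd.DataFrame:
    """Pairwise Spearman correlations (pairwise-complete)."""
    cols = [c for c in (coefficients or COEFFICIENTS) if c in table]
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            try:
                rho, _ = spearman(table[a], table[b])
            except ValueError:  # fewer than 3 complete pairs
                rho = np.nan
            out.loc[a, b] = out.loc[b, a] = rho
    return out


def regression_table(table: pd.DataFrame,
                     predictors: list[str] | None = None) -> pd.DataFrame:
    rows = []
    for c in predictors or GENOMIC_COEFFICIENTS:
        if c not in table:
            continue
        try:
            r = regress_fped(table, c)
        except ValueError:  # too few complete pairs or constant predictor
            continue
        rows.append({"predictor": c, "slope": r.slope,
                     "intercept": r.intercept, "r2": r.r2,
                     "adj_r2": r.adj_r2, "p_value": r.p_value, "n": r.n})
    return pd.DataFrame(rows).set_index("predictor")


def partition_autozygosity(table: pd.DataFrame, total_col: str,
                           class_cols: list[str]) -> pd.DataFrame:
    """Mean proportional contribution of each class to the total.

    Per individual, a class's share is class F / total F; individuals with
    zero (or missing) total are excluded rather than contributing 0/0.
    Returns one row per class with the across-individual mean share.
    """
    sub = table[[total_col] + class_cols].dropna()
    sub = sub[sub[total_col] > 0]
    if sub.empty:
        raise ValueError("no individuals with positive total autozygosity")
    shares = sub[class_cols].div(sub[total_col], axis=0)
    return pd.DataFrame({
        "mean_share": shares.mean(axis=0),
        "n": len(sub),
    })


def segment_class_summary(segments: pd.DataFrame,
                          class_col: str = "length_class") -> pd.DataFrame:
    """Per-class segment counts and length descriptives (N, min, max, mean)."""
    if segments.empty:
        return pd.DataFrame(columns=["n", "min_mb", "max_mb", "mean_mb"])
    grp = segments.groupby(class_col)["length_bp"]
    return pd.DataFrame({
        "n": grp.size(),
        "min_mb": grp.min() / 1e6,
        "max_mb": grp.max() / 1e6,
        "mean_mb": grp.mean() / 1e6,
    })


def birth_year_trend(table: pd.DataFrame, min_cohort: int = 1,
                     coefficients: list[str] | None = None) -> pd.DataFrame:
    """Per-birth-year median of each coefficient; cohorts smaller than
    ``min_cohort`` are flagged so readers can discount noisy years."""
    if "birth_year" not in table:
        raise ValueError("table lacks a birth_year column")
    cols = [c for c in (coefficients or COEFFICIENTS) if c in table]
    sub = table.dropna(subset=["birth_year"])
    grp = sub.groupby(sub["birth_year"].astype(int))
    out = grp[cols].median()
    out["n"] = grp.size()
    out["small_cohort"] = out["n"] < min_cohort
    out.index.name = "birth_year"
    return out
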