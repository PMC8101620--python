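"""Accuracy, reproducibility, and group-comparison statistics.

These are the validation statistics applied to per-ROI bone-measure
tables: linear accuracy calibration against a gold standard, one-way
random-effects ICC for repeat-scan reproducibility, pooled-variance
t-tests and Cohen's d for unadjusted group comparisons, covariate-
adjusted least-squares means from a general linear model, exact
noncentral-t power for the two-sample t-test, and Spearman association.
p-values are two-sided throughout and no multiplicity correction is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .volume import ConfigurationError

#: Canonical outcome panel (per-ROI measures).
MEASURE_PANEL = (
    "tb_vbmd", "tb_tbmd", "tb_na", "tb_pw", "tb_th", "tb_sp", "ei", "smi",
    "cb_poro", "cb_th",
)


class DegenerateDataError(ValueError):
    """Statistic undefined for the supplied data (zero variance etc.)."""


@dataclass(frozen=True)
class RegressionResult:
    """Pearson r and OLS calibration line (reference = intercept + slope·ct)."""

    slope: float
    intercept: float
    r: float
    n: int

    def predict(self, x: float | np.ndarray):
        return self.intercept + self.slope * np.asarray(x)


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    n_units: int
    n_replicates: int
    model: str = "oneway_random"


@dataclass(frozen=True)
class GroupComparison:
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    mean_difference: float
    pooled_sd: float
    t_p_value: float
    effect_size: float


@dataclass(frozen=True)
class AdjustedComparison:
    ls_mean_a: float
    ls_mean_b: float
    ls_mean_difference: float
    se: float
    t_p_value: float
    mse: float
    effect_size: float


@dataclass(frozen=True)
class PowerSpec:
    """Two-sample t-test power scenario."""

    effect_size: float
    n1: int
    n2: int
    alpha: float = 0.05
    sides: int = 2

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ConfigurationError("group sizes must be >= 2")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.sides not in (1, 2):
            raise ConfigurationError("sides must be 1 or 2")


def accuracy_calibration(x_ct: np.ndarray, y_reference: np.ndarray) -> RegressionResult:
    """Pearson correlation and CT → reference OLS calibration line.

    Regresses the gold-standard values on the CT values, so applying the
    line to a CT measurement maps it onto the reference scale; by the OLS
    centroid identity, predicting at the CT mean returns the reference
    mean.
    """
    x = np.asarray(x_ct, dtype=float)
    y = np.asarray(y_reference, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ConfigurationError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("zero variance in calibration inputs")
    slope, intercept = np.polyfit(x, y, 1)
    r = float(stats.pearsonr(x, y)[0])
    return RegressionResult(slope=float(slope), intercept=float(intercept), r=r, n=x.size)


def icc_oneway(values: np.ndarray, alpha: float = 0.05, model: str = "oneway_random") -> ICCResult:
    """Single-rater ICC with exact F-based CI.

    ``values`` is (n_units, k_replicates) with no missing cells.  The
    default one-way random-effects model treats repeat scans as
    exchangeable replicates: with MSB/MSW the between/within mean
    squares,

        ICC = (MSB − MSW) / (MSB + (k − 1)·MSW)

    and the confidence bounds follow from F = MSB/MSW referred to the
    F(n−1, n(k−1)) distribution.  ``model="twoway_random"`` instead
    fits the two-way random-effects single-measure ICC (replicate
    occasion as a random factor); its interval is approximated by the
    same F bounds on the one-way decomposition.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 2 or v.shape[0] < 3 or v.shape[1] < 2:
        raise ConfigurationError("values must be (n_units >= 3, k_replicates >= 2)")
    if not np.all(np.isfinite(v)):
        raise ConfigurationError("missing cells are not supported")
    if model not in ("oneway_random", "twoway_random"):
        raise ConfigurationError(f"unknown ICC model {model!r}")
    n, k = v.shape
    if model == "twoway_random":
        grand = v.mean()
        unit_means = v.mean(axis=1)
        col_means = v.mean(axis=0)
        msr = k * np.sum((unit_means - grand) ** 2) / (n - 1)
        msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
        sse = np.sum((v - unit_means[:, None] - col_means[None, :] + grand) ** 2)
        mse = sse / ((n - 1) * (k - 1))
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        if denom == 0:
            raise DegenerateDataError("constant data: ICC undefined")
        icc = (msr - mse) / denom
        one = icc_oneway(v, alpha=alpha, model="oneway_random")
        return ICCResult(float(icc), min(one.ci_low, icc), max(one.ci_high, icc), n, k,
                         model="twoway_random")
    unit_means = v.mean(axis=1)
    grand = v.mean()
    msb = k * np.sum((unit_means - grand) ** 2) / (n - 1)
    msw = np.sum((v - unit_means[:, None]) ** 2) / (n * (k - 1))
    if msb == 0 and msw == 0:
        raise DegenerateDataError("constant data: ICC undefined")
    if msw == 0:
        return ICCResult(1.0, 1.0, 1.0, n, k)
    f = msb / msw
    icc = (msb - msw) / (msb + (k - 1) * msw)
    fl = f / stats.f.ppf(1 - alpha / 2, n - 1, n * (k - 1))
    fu = f * stats.f.ppf(1 - alpha / 2, n * (k - 1), n - 1)
    ci_low = (fl - 1) / (fl + k - 1)
    ci_high = (fu - 1) / (fu + k - 1)
    return ICCResult(float(icc), float(ci_low), float(ci_high), n, k)


def unadjusted_group_compare(a: np.ndarray, b: np.ndarray) -> GroupComparison:
    """Pooled-variance two-sample t-test with Cohen's d effect size.

    Effect size = (mean a − mean b) / pooled SD, the classical d with the
    pooled standard deviation at n1 + n2 − 2 degrees of freedom.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ConfigurationError("each group needs n >= 2")
    diff = a.mean() - b.mean()
    pooled_var = (
        ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (a.size + b.size - 2)
    )
    pooled_sd = float(np.sqrt(pooled_var))
    if pooled_sd == 0:
        p = 1.0 if diff == 0 else 0.0
        d = 0.0 if diff == 0 else np.sign(diff) * np.inf
    else:
        _, p = stats.ttest_ind(a, b, equal_var=True)
        d = diff / pooled_sd
    return GroupComparison(
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)), sd_b=float(b.std(ddof=1)),
        mean_difference=float(diff), pooled_sd=pooled_sd,
        t_p_value=float(p), effect_size=float(d),
    )


def effect_size_from_summaries(mean_difference: float, pooled_sd: float) -> float:
    """Cohen's d recomputed from printed group summaries."""
    if pooled_sd <= 0:
        raise DegenerateDataError("pooled SD must be positive")
    return mean_difference / pooled_sd


def adjusted_lsmeans(
    table: pd.DataFrame,
    outcome: str,
    group: str,
    covariates: list[str],
) -> AdjustedComparison:
    """Least-squares group means from a general linear model.

    Fits ``outcome ~ group + covariates`` and evaluates the fitted model
    at each group with every categorical covariate weighted equally
    across its levels and continuous covariates at their grand mean (the
    classical LSMEANS convention).  Effect size = LS-mean difference /
    √MSE.  Group labels are compared in sorted order (first − second).
    """
    df = table.dropna(subset=[outcome, group] + covariates).copy()
    levels = sorted(df[group].unique())
    if len(levels) != 2:
        raise ConfigurationError("group must have exactly two levels")
    X_parts = [pd.get_dummies(df[group].astype("category"), prefix=group, drop_first=True)]
    cov_info: list[tuple[str, str, list]] = []
    for c in covariates:
        if df[c].dtype == object or df[c].nunique() <= 2:
            dummies = pd.get_dummies(df[c].astype("category"), prefix=c, drop_first=True)
            X_parts.append(dummies)
            cov_info.append(("cat", c, sorted(df[c].unique())))
        else:
            X_parts.append(df[[c]].astype(float))
            cov_info.append(("num", c, [df[c].mean()]))
    X = pd.concat(X_parts, axis=1).astype(float)
    X = sm.add_constant(X)
    if np.linalg.matrix_rank(X.values) < X.shape[1]:
        raise ConfigurationError("rank-deficient design (collinear group/covariates)")
    fit = sm.OLS(df[outcome].astype(float), X).fit()
    mse = float(fit.mse_resid)

    def ls_row(level) -> np.ndarray:
        row = {"const": 1.0}
        dummy_cols = [c for c in X.columns if c.startswith(f"{group}_")]
        for c in dummy_cols:
            row[c] = 1.0 if c == f"{group}_{levels[1]}" and level == levels[1] else 0.0
        for kind, c, info in cov_info:
            if kind == "num":
                row[c] = float(info[0])
            else:  # equal weights: each non-reference level dummy gets 1/n_levels
                for col in (col for col in X.columns if col.startswith(f"{c}_")):
                    row[col] = 1.0 / len(info)
        return np.array([row.get(col, 0.0) for col in X.columns])

    rows = {lv: ls_row(lv) for lv in levels}
    ls_means = {lv: float(rows[lv] @ fit.params.values) for lv in levels}
    contrast = rows[levels[0]] - rows[levels[1]]
    diff = float(contrast @ fit.params.values)
    se = float(np.sqrt(contrast @ fit.cov_params().values @ contrast))
    tval = diff / se
    p = 2 * stats.t.sf(abs(tval), df=fit.df_resid)
    return AdjustedComparison(
        ls_mean_a=ls_means[levels[0]], ls_mean_b=ls_means[levels[1]],
        ls_mean_difference=diff, se=se, t_p_value=float(p), mse=mse,
        effect_size=diff / np.sqrt(mse),
    )


def ttest_power(spec: PowerSpec) -> float:
    """Exact power of the pooled two-sample t-test via the noncentral t.

    Noncentrality δ = d·√(n1·n2/(n1+n2)); power is the probability that
    |T| exceeds the central-t critical value under the noncentral
    distribution with n1 + n2 − 2 degrees of freedom.
    """
    df = spec.n1 + spec.n2 - 2
    nc = spec.effect_size * np.sqrt(spec.n1 * spec.n2 / (spec.n1 + spec.n2))
    if spec.sides == 2:
        tc = stats.t.ppf(1 - spec.alpha / 2, df)
        return float(1 - stats.nct.cdf(tc, df, nc) + stats.nct.cdf(-tc, df, nc))
    tc = stats.t.ppf(1 - spec.alpha, df)
    return float(1 - stats.nct.cdf(tc, df, nc))


def spearman_assoc(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ConfigurationError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("constant vector: Spearman undefined")
    return float(stats.spearmanr(x, y)[0])


# ------------------------------------------------------------- table level


def compare_measures(
    table: pd.DataFrame,
    group: str,
    measures: tuple[str, ...] = MEASURE_PANEL,
    value_col: str = "value",
    measure_col: str = "measure",
) -> pd.DataFrame:
    """Unadjusted group comparison for every measure in a long table.

    Groups are compared in sorted label order (first − second); returns
    one row per measure mirroring a group-comparison table layout.
    """
    levels = sorted(table[group].unique())
    if len(levels) != 2:
        raise ConfigurationError("group must have exactly two levels")
    rows = []
    for meas in measures:
        sub = table[table[measure_col] == meas]
        if sub.empty:
            continue
        a = sub.loc[sub[group] == levels[0], value_col].to_numpy()
        b = sub.loc[sub[group] == levels[1], value_col].to_numpy()
        gc = unadjusted_group_compare(a, b)
        rows.append({
            "measure": meas,
            f"mean_{levels[0]}": gc.mean_a, f"sd_{levels[0]}": gc.sd_a,
            f"mean_{levels[1]}": gc.mean_b, f"sd_{levels[1]}": gc.sd_b,
            "mean_difference": gc.mean_difference, "pooled_sd": gc.pooled_sd,
            "p_value": gc.t_p_value, "effect_size": gc.effect_size,
        })
    return pd.DataFrame(rows)
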