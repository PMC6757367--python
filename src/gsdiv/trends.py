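"""Before/after trend analysis: the piecewise linear model with a slope
change at the switch from progeny-testing to genomic selection.

For a per-individual variable Y (a merit index, F_ped, mean kinship,
F_ROH, mean ROH length) observed against birth year x, the model is two
straight lines with separate intercepts and a slope change delta:

    Y = a1 + b1 x + e           for pre-period years  (2005-2010)
    Y = a2 + (b1 + delta) x + e for post-period years (2012-2015)

fit jointly by ordinary least squares (one regression with a period
indicator and its interaction with year; no continuity constraint at the
break — the intercepts may jump).  Individuals born in the transition
year (2011) are excluded.  The significance of delta comes from the
F-test of the interaction term, and the headline effect size is the
relative change RC = delta / |b1|: its sign gives the direction of the
slope change and its magnitude the change relative to the pre-period
slope.  Annual rates convert to per-generation rates by multiplying by
the mean parental generation interval in years.

Supporting statistics used alongside the model: Welch two-sample t-tests
for period means, Pearson correlation (Fisher-z interval) between
pedigree- and ROH-based inbreeding, coefficients of variation, and
studentized-residual diagnostics of each fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

PRE_YEARS = (2005, 2010)
POST_YEARS = (2012, 2015)


@dataclass
class TrendFit:
    """Fitted piecewise trend for one variable."""

    variable: str
    a1: float
    a2: float
    b1: float
    delta: float
    se_b1: float
    se_delta: float
    p_delta: float
    n_pre: int
    n_post: int
    se_a1: float = float("nan")
    se_a2: float = float("nan")
    ci_b1: tuple[float, float] = (float("nan"), float("nan"))
    ci_delta: tuple[float, float] = (float("nan"), float("nan"))
    ci_b2: tuple[float, float] = (float("nan"), float("nan"))

    @property
    def b2(self) -> float:
        return self.b1 + self.delta

    @property
    def RC(self) -> float:
        # NaN (rather than an error) when the pre-slope is exactly zero, so
        # bulk tables over degenerate variables stay writable
        if self.b1 == 0:
            return float("nan")
        return relative_change(self.b1, self.delta)

    def to_row(self) -> dict:
        return {
            "variable": self.variable,
            "b1": self.b1,
            "se_b1": self.se_b1,
            "b2": self.b2,
            "delta": self.delta,
            "se_delta": self.se_delta,
            "p_delta": self.p_delta,
            "RC": self.RC,
            "n_pre": self.n_pre,
            "n_post": self.n_post,
        }


def fit_piecewise(
    birth_year: np.ndarray,
    y: np.ndarray,
    pre_years: tuple[int, int] = PRE_YEARS,
    post_years: tuple[int, int] = POST_YEARS,
    variable: str = "y",
) -> TrendFit:
    """Least-squares fit of the two-segment trend model.

    ``birth_year`` and ``y`` are per-individual; observations outside both
    windows (including the transition year) are dropped.  Years are
    centered at the first pre-period year internally for conditioning;
    reported intercepts are on the original year scale.
    """
    if pre_years[1] >= post_years[0]:
        raise ValueError("period windows overlap")
    x = np.asarray(birth_year, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    pre = (x >= pre_years[0]) & (x <= pre_years[1])
    post = (x >= post_years[0]) & (x <= post_years[1])
    for name, mask in (("pre", pre), ("post", post)):
        if len(np.unique(x[mask])) < 2:
            raise ValueError(
                f"{name}-period has fewer than 2 distinct years; slope unidentifiable"
            )
    sel = pre | post
    x, y, post = x[sel], y[sel], post[sel]
    x0 = x - pre_years[0]
    X = np.column_stack([np.ones_like(x0), post.astype(float), x0, post * x0])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 4:
        raise ValueError("design matrix is rank deficient")
    resid = y - X @ beta
    dof = len(y) - 4
    if dof <= 0:
        raise ValueError("not enough observations for the 4-parameter model")
    s2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(s2 * np.diag(XtX_inv))
    # F-test of the slope-change term (1 df) == squared t-test
    t_delta = beta[3] / se[3] if se[3] > 0 else np.inf
    p_delta = float(stats.f.sf(t_delta**2, 1, dof)) if np.isfinite(t_delta) else 0.0
    p_delta = min(max(p_delta, np.finfo(float).tiny), 1.0)
    tcrit = stats.t.ppf(0.975, dof)
    # back-transform intercepts to the original year scale
    a1 = beta[0] - beta[2] * pre_years[0]
    a2 = (beta[0] + beta[1]) - (beta[2] + beta[3]) * pre_years[0]
    b2 = beta[2] + beta[3]
    var_b2 = XtX_inv[2, 2] + XtX_inv[3, 3] + 2 * XtX_inv[2, 3]
    se_b2 = np.sqrt(s2 * var_b2)
    return TrendFit(
        variable=variable,
        a1=float(a1),
        a2=float(a2),
        b1=float(beta[2]),
        delta=float(beta[3]),
        se_b1=float(se[2]),
        se_delta=float(se[3]),
        p_delta=p_delta,
        n_pre=int((~post).sum()),
        n_post=int(post.sum()),
        se_a1=float(se[0]),
        se_a2=float(np.sqrt(s2 * (XtX_inv[0, 0] + XtX_inv[1, 1] + 2 * XtX_inv[0, 1]))),
        ci_b1=(float(beta[2] - tcrit * se[2]), float(beta[2] + tcrit * se[2])),
        ci_delta=(float(beta[3] - tcrit * se[3]), float(beta[3] + tcrit * se[3])),
        ci_b2=(float(b2 - tcrit * se_b2), float(b2 + tcrit * se_b2)),
    )


def relative_change(b1: float, delta: float) -> float:
    """RC = delta / |b1|; sign follows delta, magnitude is scaled by |b1|."""
    if b1 == 0:
        raise ValueError("RC undefined for b1 = 0")
    return delta / abs(b1)


def per_generation(annual_rate: float, gen_interval_years: float) -> float:
    """Convert an annual rate to a per-generation rate.

    Multiplies the annual rate by the mean parental generation interval of
    the period, in years.  Units of the input rate are preserved.
    """
    if gen_interval_years <= 0:
        raise ValueError("generation interval must be positive")
    return annual_rate * gen_interval_years


def compare_means(a, b) -> tuple[float, float]:
    """Welch two-sample t-test; returns (t, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        raise ValueError("both groups have zero variance; t undefined")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def correlation(x, y, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Pearson r with a (1-alpha) Fisher-z confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need >= 4 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance; correlation undefined")
    r, _ = stats.pearsonr(x, y)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(x.size - 3)
    zc = stats.norm.ppf(1 - alpha / 2)
    lo, hi = np.tanh(z - zc * se), np.tanh(z + zc * se)
    return float(r), (float(lo), float(hi))


def coefficient_of_variation(values) -> float:
    """CV = sample standard deviation (n-1) / mean."""
    v = np.asarray(values, dtype=float)
    m = v.mean()
    if m == 0:
        raise ValueError("CV undefined for zero mean")
    return float(v.std(ddof=1) / m)


def residual_diagnostics(
    fit: TrendFit,
    birth_year: np.ndarray,
    y: np.ndarray,
    pre_years: tuple[int, int] = PRE_YEARS,
    post_years: tuple[int, int] = POST_YEARS,
) -> pd.DataFrame:
    """Square root of |internally studentized residuals| per observation.

    The standard scale-location diagnostic: residuals divided by
    s * sqrt(1 - h_ii) with h the hat matrix of the piecewise design.
    Columns: birth_year, period, residual, sqrt_abs_std_resid.
    """
    x = np.asarray(birth_year, dtype=float)
    y = np.asarray(y, dtype=float)
    pre = (x >= pre_years[0]) & (x <= pre_years[1])
    post = (x >= post_years[0]) & (x <= post_years[1])
    sel = pre | post
    x, y, post = x[sel], y[sel], post[sel]
    x0 = x - pre_years[0]
    X = np.column_stack([np.ones_like(x0), post.astype(float), x0, post * x0])
    beta = np.array(
        [fit.a1 + fit.b1 * pre_years[0],
         (fit.a2 - fit.a1) + fit.delta * pre_years[0],
         fit.b1,
         fit.delta]
    )
    resid = y - X @ beta
    dof = len(y) - 4
    s2 = float(resid @ resid) / dof if dof > 0 else 0.0
    H_diag = np.einsum("ij,jk,ik->i", X, np.linalg.pinv(X.T @ X), X)
    denom = np.sqrt(np.maximum(s2 * (1.0 - H_diag), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        std_resid = np.where(denom > 0, resid / denom, 0.0)
    return pd.DataFrame(
        {
            "birth_year": x.astype(int),
            "period": np.where(post, "post", "pre"),
            "residual": resid,
            "sqrt_abs_std_resid": np.sqrt(np.abs(std_resid)),
        }
    )


def fit_trend_table(
    data: pd.DataFrame,
    variables: list[str],
    year_col: str = "birth_year",
    pre_years: tuple[int, int] = PRE_YEARS,
    post_years: tuple[int, int] = POST_YEARS,
) -> pd.DataFrame:
    """Piecewise fits for several variables; one row per variable.

    Mirrors the usual presentation: b1 (SE), b2, delta (SE), p, RC.
    """
    rows = []
    for var in variables:
        sub = data[[year_col, var]].dropna()
        fit = fit_piecewise(
            sub[year_col].to_numpy(),
            sub[var].to_numpy(),
            pre_years,
            post_years,
            variable=var,
        )
        rows.append(fit.to_row())
    return pd.DataFrame(rows)


def classical_delta_f(mean_f_by_year: pd.Series) -> pd.Series:
    """Classical per-year inbreeding rate dF = (F_t - F_{t-1}) / (1 - F_{t-1}).

    Optional alternative to the regression-slope definition of the annual
    inbreeding rate; indexed by the later year of each pair.
    """
    f = mean_f_by_year.sort_index()
    prev = f.shift(1)
    out = (f - prev) / (1.0 - prev)
    return out.dropna()
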