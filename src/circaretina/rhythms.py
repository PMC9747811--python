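"""Relative qPCR expression and cosinor rhythm analysis of clock genes.

Expression at Zeitgeber times 0/6/12/18 is quantified by the delta-delta-Ct
method (fold change vs the housekeeping gene and the control ZT0 mean).
Rhythmicity is assessed by fitting a fixed-24 h-period cosine

    Y(t) = baseline + amplitude * cos(2*pi*(t - acrophase)/24)

by least squares through the standard linearization
``Y = M + beta*cos(w t) + gamma*sin(w t)`` (w = 2*pi/24), so the fit is a
linear regression: amplitude = sqrt(beta^2 + gamma^2) and the acrophase
(clock time of the fitted peak) is atan2(gamma, beta)/w modulo 24.  The
cosine fit is compared against a horizontal line with the extra
sum-of-squares F test (2 extra parameters); if the cosine is not
supported, a linear trend is tried next, and otherwise the series is
called flat.  Residual normality is checked with the D'Agostino-Pearson
omnibus K2 test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CosinorFit",
    "delta_delta_ct",
    "cosinor_fit",
    "select_model",
    "residual_normality",
    "per_zt_genotype_tests",
]

PERIOD_H = 24.0


@dataclass
class CosinorFit:
    baseline: float
    amplitude: float  # >= 0 by construction
    acrophase: float  # h in [0, 24)
    period: float
    rss_cosine: float
    rss_flat: float
    rss_linear: float
    f_stat: float
    p_vs_flat: float
    p_linear: float
    n: int
    residuals: np.ndarray
    selected_model: str = ""


def delta_delta_ct(
    records: pd.DataFrame,
    reference: float | None = None,
    gene_col: str = "gene",
) -> pd.DataFrame:
    """Fold change by the delta-delta-Ct method.

    ``records`` needs columns ct_target and ct_housekeeping (plus
    genotype/zt for the reference).  Per gene, dCt = ct_target -
    ct_housekeeping; the reference is the mean dCt of control ZT0 for
    that gene unless given explicitly; fold = 2**(-(dCt - reference)).
    Rows lacking a housekeeping Ct are dropped with a reason column.
    """
    df = records.copy()
    missing = df["ct_housekeeping"].isna() | df["ct_target"].isna()
    dropped = df[missing].assign(drop_reason="missing_ct")
    df = df[~missing].copy()
    df["dct"] = df["ct_target"] - df["ct_housekeeping"]
    out = []
    for gene, sub in df.groupby(gene_col):
        if reference is None:
            ref_rows = sub[(sub["genotype"] == "Ctrl") & (sub["zt"] == 0)]
            if ref_rows.empty:
                raise ValueError(f"{gene}: no control ZT0 rows to anchor the reference")
            ref = ref_rows["dct"].mean()
        else:
            ref = reference
        sub = sub.assign(ddct=sub["dct"] - ref)
        sub = sub.assign(fold=np.power(2.0, -sub["ddct"]))
        out.append(sub)
    result = pd.concat(out, ignore_index=True)
    result.attrs["dropped"] = dropped
    return result


def cosinor_fit(
    times: np.ndarray, values: np.ndarray, period: float = PERIOD_H
) -> CosinorFit:
    """Least-squares fixed-period cosine fit with model-comparison stats.

    F = ((rss_flat - rss_cosine)/2) / (rss_cosine/(n-3)) with p from
    F(2, n-3); the competing straight line's slope p-value is recorded
    for :func:`select_model`.  Exact on noiseless cosine input.
    """
    t = np.asarray(times, float)
    y = np.asarray(values, float)
    n = t.size
    if n <= 3:
        raise ValueError("cosinor fit needs more than 3 observations")
    if np.unique(t).size < 3:
        raise ValueError("cosinor fit needs at least 3 distinct time points")
    w = 2.0 * np.pi / period
    X = np.column_stack([np.ones(n), np.cos(w * t), np.sin(w * t)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    m, beta, gamma = coef
    fitted = X @ coef
    resid = y - fitted
    rss_cos = float(resid @ resid)
    rss_flat = float(np.sum((y - y.mean()) ** 2))
    lin = stats.linregress(t, y)
    rss_lin = float(np.sum((y - (lin.intercept + lin.slope * t)) ** 2))
    amplitude = float(np.hypot(beta, gamma))
    acrophase = float(np.arctan2(gamma, beta) / w % period)
    denom = rss_cos / (n - 3)
    if denom <= 0:  # perfect fit: infinitely strong evidence for the cosine
        f_stat, p_flat = np.inf, 0.0
    else:
        f_stat = ((rss_flat - rss_cos) / 2.0) / denom
        p_flat = float(stats.f.sf(f_stat, 2, n - 3))
    fit = CosinorFit(
        baseline=float(m),
        amplitude=amplitude,
        acrophase=acrophase,
        period=period,
        rss_cosine=rss_cos,
        rss_flat=rss_flat,
        rss_linear=rss_lin,
        f_stat=float(f_stat),
        p_vs_flat=p_flat,
        p_linear=float(lin.pvalue),
        n=n,
        residuals=resid,
    )
    fit.selected_model = select_model(fit)
    return fit


def select_model(fit: CosinorFit, alpha: float = 0.05) -> str:
    """Best-supported description of the series: cosine, linear, or flat."""
    if fit.p_vs_flat < alpha:
        return "cosine"
    if fit.p_linear < alpha:
        return "linear"
    return "flat"


def residual_normality(fit: CosinorFit | np.ndarray) -> tuple[float, float] | None:
    """D'Agostino-Pearson omnibus K2 on the cosine-fit residuals.

    Returns None (skipped) below the test's validity floor of 8
    observations or on degenerate (constant) residuals.
    """
    resid = fit.residuals if isinstance(fit, CosinorFit) else np.asarray(fit, float)
    if resid.size < 8 or np.allclose(resid, resid[0]):
        return None
    k2, p = stats.normaltest(resid)
    return float(k2), float(p)


def per_zt_genotype_tests(
    expression: pd.DataFrame,
    value_col: str = "value",
    zts: tuple[int, ...] = (0, 6, 12, 18),
) -> pd.DataFrame:
    """Per-ZT two-sample t-tests (Ctrl vs cKO) with Holm-Sidak correction.

    ``expression`` needs columns genotype, zt and ``value_col`` for one
    gene.  ZTs lacking >=2 replicates in either arm are skipped; the
    correction family is the set of tested ZTs.
    """
    rows = []
    for zt in zts:
        sub = expression[expression["zt"] == zt]
        a = sub.loc[sub["genotype"] == "Ctrl", value_col].to_numpy(float)
        b = sub.loc[sub["genotype"] == "cKO", value_col].to_numpy(float)
        if a.size < 2 or b.size < 2:
            continue
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b)
        rows.append({"zt": zt, "t": float(t), "p": float(p)})
    out = pd.DataFrame(rows)
    if not out.empty:
        # Sidak step uses log1p(-p): nudge exact-1 p-values off the boundary
        out["p_adj"] = multipletests(
            np.clip(out["p"], 0.0, 1.0 - 1e-12), method="holm-sidak"
        )[1]
    return out
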