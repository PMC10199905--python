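"""Trait-severity regression: VIF screen, ridge with GCV, OLS diagnostics.

The 13 trait scales are strongly intercorrelated, so ordinary least squares
on all of them is variance-inflated; the module screens predictors with the
variance inflation factor, fits a ridge model minimizing
sum_i (y_i - yhat_i)^2 + lambda sum_k a_k^2 with the penalty chosen by
generalized cross-validation, and provides approximate inference for the
penalized coefficients. Single-predictor relations (trait score vs cluster
ERSP) go through OLS with Durbin-Watson / Shapiro-Wilk / Breusch-Pagan
residual diagnostics and Bonferroni correction, with robust-ellipse
("bivariate boxplot") outlier exclusion and sensitivity reruns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def vif(x: pd.DataFrame | np.ndarray) -> pd.Series:
    """Variance inflation factor per predictor: 1 / (1 - R^2_k).

    Perfectly collinear columns get the +inf sentinel.
    """
    xdf = pd.DataFrame(x)
    arr = xdf.to_numpy(dtype=float)
    n, k = arr.shape
    if n < k + 2:
        raise ValueError("need at least K + 2 rows for the VIF screen")
    out = {}
    for j, name in enumerate(xdf.columns):
        others = np.delete(arr, j, axis=1)
        design = np.column_stack([np.ones(n), others])
        beta, *_ = np.linalg.lstsq(design, arr[:, j], rcond=None)
        resid = arr[:, j] - design @ beta
        tss = ((arr[:, j] - arr[:, j].mean()) ** 2).sum()
        r2 = 1 - resid @ resid / tss if tss > 0 else 1.0
        out[name] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


@dataclass
class RidgeModel:
    """Ridge fit on standardized predictors with GCV-selected penalty."""

    lam: float
    coef: np.ndarray             # standardized scale
    coef_raw: np.ndarray         # original predictor scale
    intercept_raw: float
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    gcv_score: float
    edf: float                   # trace of the hat matrix
    lambda_grid: np.ndarray
    gcv_path: np.ndarray
    coef_path: np.ndarray        # grid x predictors
    y: np.ndarray
    y_hat: np.ndarray
    predictors: tuple


def default_lambda_grid() -> np.ndarray:
    """50 log-spaced penalties in [1e-4, 1e3] (standardized predictors)."""
    return np.logspace(-4, 3, 50)


def ridge_gcv(x: pd.DataFrame | np.ndarray, y: np.ndarray,
              lambda_grid: np.ndarray | None = None,
              standardize: bool = True) -> RidgeModel:
    """Ridge regression with the penalty chosen by generalized cross-validation.

    Predictors are centered and scaled to unit variance internally (pass
    ``standardize=False`` for a design already on the intended scale, e.g.
    an orthonormal basis), the outcome centered;
    GCV(lambda) = N RSS(lambda) / (N - tr H(lambda))^2 is minimized over the
    grid. Standard errors use the sandwich variance of the linear ridge
    estimator with residual df N - tr H; the resulting T / p values are
    approximate.
    """
    if lambda_grid is None:
        lambda_grid = default_lambda_grid()
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise ValueError("empty lambda grid")
    xdf = pd.DataFrame(x)
    arr = xdf.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = arr.shape
    if standardize:
        x_mean, x_sd = arr.mean(axis=0), arr.std(axis=0, ddof=1)
        if np.any(x_sd <= 0):
            raise ValueError("constant predictor column")
    else:
        x_mean, x_sd = np.zeros(k), np.ones(k)
    xs = (arr - x_mean) / x_sd
    y_mean = y.mean()
    yc = y - y_mean

    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    uty = u.T @ yc
    gcv_path = np.empty(len(lambda_grid))
    coef_path = np.empty((len(lambda_grid), k))
    for i, lam in enumerate(lambda_grid):
        shrink = s / (s ** 2 + lam)
        beta = vt.T @ (shrink * uty)
        coef_path[i] = beta
        fitted = xs @ beta
        rss = float(((yc - fitted) ** 2).sum())
        tr_h = float((s ** 2 / (s ** 2 + lam)).sum())
        if n <= tr_h:
            raise ValueError("effective df exceeds the sample size")
        gcv_path[i] = n * rss / (n - tr_h) ** 2
    best = int(np.argmin(gcv_path))
    lam = float(lambda_grid[best])
    beta = coef_path[best]
    fitted = xs @ beta
    rss = float(((yc - fitted) ** 2).sum())
    tr_h = float((s ** 2 / (s ** 2 + lam)).sum())
    sigma2 = rss / (n - tr_h)
    # var(beta) = sigma^2 V diag(s^2/(s^2+lam)^2) V'
    var_beta = (vt.T * (s ** 2 / (s ** 2 + lam) ** 2)) @ vt * sigma2
    se = np.sqrt(np.diag(var_beta))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    p = 2 * stats.t.sf(np.abs(t), max(n - tr_h, 1.0))
    coef_raw = beta / x_sd
    intercept_raw = y_mean - float(coef_raw @ x_mean)
    return RidgeModel(
        lam=lam, coef=beta, coef_raw=coef_raw, intercept_raw=intercept_raw,
        se=se, t=t, p=p, gcv_score=float(gcv_path[best]), edf=tr_h,
        lambda_grid=lambda_grid, gcv_path=gcv_path, coef_path=coef_path,
        y=y, y_hat=fitted + y_mean, predictors=tuple(xdf.columns))


@dataclass
class OlsReport:
    """Simple/multiple OLS fit with residual diagnostics."""

    estimate: np.ndarray         # intercept first
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    durbin_watson: float
    shapiro_w: float
    shapiro_p: float
    breusch_pagan: float
    breusch_pagan_p: float
    p_bonferroni: np.ndarray
    excluded: tuple = ()
    degenerate: bool = False
    names: tuple = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.durbin_watson <= 4.0):
            raise ValueError("Durbin-Watson statistic must lie in [0, 4]")


def ols_with_diagnostics(x: np.ndarray, y: np.ndarray,
                         n_tests: int = 1) -> OlsReport:
    """OLS with Durbin-Watson, Shapiro-Wilk and Breusch-Pagan diagnostics.

    ``x`` may be one predictor (1-D) or a predictor matrix; an intercept is
    added. ``n_tests`` is the size of the model family for the Bonferroni
    column. Perfectly linear data flags the residual tests as degenerate.
    """
    import statsmodels.api as sm
    from statsmodels.stats.diagnostic import het_breuschpagan
    from statsmodels.stats.stattools import durbin_watson

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if len(y) < 4:
        raise ValueError("need at least 4 observations")
    if np.any(x.std(axis=0) <= 0):
        raise ValueError("zero-variance predictor")
    design = sm.add_constant(x)
    fit = sm.OLS(y, design).fit()
    resid = fit.resid
    degenerate = float(resid.std()) < 1e-10 * max(float(np.abs(y).max()), 1.0)
    if degenerate:
        sw_w, sw_p, bp, bp_p = 1.0, 1.0, 0.0, 1.0
        dw = 2.0
    else:
        sw_w, sw_p = stats.shapiro(resid)
        bp, bp_p, *_ = het_breuschpagan(resid, design)
        dw = float(np.clip(durbin_watson(resid), 0.0, 4.0))
    return OlsReport(
        estimate=np.asarray(fit.params), se=np.asarray(fit.bse),
        t=np.asarray(fit.tvalues), p=np.asarray(fit.pvalues),
        durbin_watson=dw, shapiro_w=float(sw_w), shapiro_p=float(sw_p),
        breusch_pagan=float(bp), breusch_pagan_p=float(bp_p),
        p_bonferroni=np.minimum(1.0, np.asarray(fit.pvalues) * n_tests),
        degenerate=bool(degenerate),
        names=("const",) + tuple(f"x{i}" for i in range(x.shape[1])))


def _mad(v: np.ndarray) -> float:
    return float(1.4826 * np.median(np.abs(v - np.median(v))))


def bivariate_outliers(x: np.ndarray, y: np.ndarray,
                       quantile: float = 0.99) -> np.ndarray:
    """Robust-ellipse outlier flags (bivariate-boxplot style fence).

    Center = coordinate-wise medians; spread = MAD scales with a
    Gnanadesikan-Kettenring robust correlation; points whose robust squared
    Mahalanobis distance exceeds the chi-square(2) ``quantile`` fence are
    flagged. Affine-equivariant under axis scaling. Returns flagged indices.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 10:
        raise ValueError("need at least 10 paired points")
    mx, my = np.median(x), np.median(y)
    sx, sy = _mad(x), _mad(y)
    if sx <= 0 or sy <= 0:
        raise ValueError("degenerate spread (zero MAD)")
    u = (x - mx) / sx
    v = (y - my) / sy
    splus, sminus = _mad(u + v), _mad(u - v)
    denom = splus ** 2 + sminus ** 2
    r = (splus ** 2 - sminus ** 2) / denom if denom > 0 else 0.0
    r = float(np.clip(r, -0.999, 0.999))
    d2 = (u ** 2 - 2 * r * u * v + v ** 2) / (1 - r ** 2)
    fence = stats.chi2.ppf(quantile, df=2)
    return np.flatnonzero(d2 > fence)


def sensitivity_rerun(model_fn, args_with: tuple, flagged: np.ndarray) -> dict:
    """Refit with and without flagged rows; report coefficient agreement.

    ``model_fn(*arrays)`` must return an object with ``estimate``/``p`` or
    ``coef``/``p`` attributes; ``args_with`` are the row-aligned data arrays.
    """
    full = model_fn(*args_with)
    keep = np.ones(len(args_with[0]), dtype=bool)
    keep[np.asarray(flagged, dtype=int)] = False
    reduced = model_fn(*(np.asarray(a)[keep] for a in args_with)) \
        if len(flagged) else full

    def coef_p(m):
        if hasattr(m, "estimate"):
            return np.asarray(m.estimate), np.asarray(m.p)
        return np.asarray(m.coef), np.asarray(m.p)

    cf, pf = coef_p(full)
    cr, pr = coef_p(reduced)
    return {"full": full, "reduced": reduced,
            "flagged": np.asarray(flagged, dtype=int),
            "sign_agreement": bool(np.all(np.sign(cf) == np.sign(cr))),
            "significance_agreement": bool(np.all((pf < 0.05) == (pr < 0.05)))}
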