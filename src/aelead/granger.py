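"""Bivariate VAR estimation, lag selection, and Granger causality.

The system is

    y_t = c_y + sum_{i=1..p} alpha_i y_{t-i} + sum_{i=1..p} beta_i x_{t-i} + u_t
    x_t = c_x + sum_{i=1..p} gamma_i x_{t-i} + sum_{i=1..p} delta_i y_{t-i} + v_t

estimated equation-by-equation with ordinary least squares (the OLS
estimates are the maximum-likelihood estimates of a Gaussian VAR). The
series x "Granger-causes" y when the joint null beta_1 = ... = beta_p = 0
is rejected; the primary statistic is the Wald chi-square on the
y-equation's cross-lag coefficients, with a likelihood-ratio variant
reported as a cross-check. The lag order is chosen by sequential
likelihood-ratio tests stepping down from a maximum lag, all candidate
orders fitted on the common sample implied by the maximum lag so the
tests are nested.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .timeseries import CountSeries


class CollinearityError(ValueError):
    """The VAR design matrix is rank deficient (e.g. x identical to y,
    or a constant series)."""


def _as_array(series) -> np.ndarray:
    if isinstance(series, CountSeries):
        return series.to_numpy()
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 1:
        raise ValueError("series must be one-dimensional")
    return arr


@dataclass
class VARFit:
    """OLS fit of the bivariate VAR(p).

    ``coef`` has shape (1 + 2p, 2): rows are (const, y lags 1..p,
    x lags 1..p); column 0 is the y equation, column 1 the x equation.
    ``sigma`` is the MLE residual covariance (divisor n_obs); the
    per-equation coefficient covariance uses the finite-sample divisor
    n_obs - (2p + 1).
    """

    p: int
    n_obs: int
    coef: np.ndarray
    sigma: np.ndarray
    loglik: float
    xtx_inv: np.ndarray
    resid: np.ndarray
    s2: np.ndarray  # per-equation residual variance, df-adjusted

    @property
    def intercepts(self) -> np.ndarray:
        return self.coef[0]

    def own_lags(self, eq: int = 0) -> np.ndarray:
        sl = slice(1, 1 + self.p) if eq == 0 else slice(1 + self.p, 1 + 2 * self.p)
        return self.coef[sl, eq]

    def cross_lags(self, eq: int = 0) -> np.ndarray:
        sl = slice(1 + self.p, 1 + 2 * self.p) if eq == 0 else slice(1, 1 + self.p)
        return self.coef[sl, eq]

    def coef_cov(self, eq: int = 0) -> np.ndarray:
        return self.s2[eq] * self.xtx_inv


def _design(y: np.ndarray, x: np.ndarray, p: int, offset: int) -> tuple[np.ndarray, np.ndarray]:
    T = len(y)
    rows = np.arange(offset, T)
    Z = np.empty((len(rows), 1 + 2 * p))
    Z[:, 0] = 1.0
    for i in range(1, p + 1):
        Z[:, i] = y[rows - i]
        Z[:, p + i] = x[rows - i]
    Y = np.column_stack([y[rows], x[rows]])
    return Z, Y


def fit_var(y, x, p: int, offset: int | None = None, log_transform: bool = False) -> VARFit:
    """Estimate the bivariate VAR(p) by per-equation OLS.

    ``offset`` (>= p) fixes the first modelled index, letting several lag
    orders share one estimation sample. ``log_transform`` fits on
    log(1 + count), an optional variance-stabilising switch for
    heteroskedastic count series.
    """
    y = _as_array(y)
    x = _as_array(x)
    if len(y) != len(x):
        raise ValueError("series must have equal length")
    if p < 1:
        raise ValueError("lag order must be >= 1")
    if len(y) <= 2 * p + 3:
        raise ValueError(f"need length > {2 * p + 3} for a VAR({p}); got {len(y)}")
    if log_transform:
        y = np.log1p(y)
        x = np.log1p(x)
    if offset is None:
        offset = p
    if offset < p:
        raise ValueError("offset must be >= p")
    Z, Y = _design(y, x, p, offset)
    n_obs, k = Z.shape
    if n_obs <= k:
        raise ValueError(f"too few observations ({n_obs}) for {k} parameters")
    rank = np.linalg.matrix_rank(Z)
    if rank < k:
        raise CollinearityError(
            f"design matrix rank {rank} < {k}; collinear or constant regressors"
        )
    coef, *_ = np.linalg.lstsq(Z, Y, rcond=None)
    resid = Y - Z @ coef
    sigma = resid.T @ resid / n_obs
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        raise CollinearityError("singular residual covariance")
    loglik = -0.5 * n_obs * (2 * np.log(2 * np.pi) + logdet + 2.0)
    xtx_inv = np.linalg.inv(Z.T @ Z)
    s2 = (resid ** 2).sum(axis=0) / (n_obs - k)
    return VARFit(
        p=p, n_obs=n_obs, coef=coef, sigma=sigma, loglik=loglik,
        xtx_inv=xtx_inv, resid=resid, s2=s2,
    )


@dataclass
class LagSelection:
    """Outcome of the sequential lag search."""

    p: int
    method: str
    max_lag: int
    table: pd.DataFrame  # lag, loglik, logdet_sigma, lr, lr_pvalue


def select_lag(y, x, max_lag: int = 12, alpha: float = 0.05, method: str = "lr",
               log_transform: bool = False) -> LagSelection:
    """Choose the VAR order by sequential likelihood-ratio tests.

    All candidate orders 1..max_lag are fitted on the common sample
    implied by ``max_lag``. Stepping down from max_lag, the test of
    VAR(m) against VAR(m-1) uses LR = n_obs (ln|S_{m-1}| - ln|S_m|),
    asymptotically chi-square with 4 df (one extra lag of both variables
    in both equations); the chosen order is the largest m whose test is
    significant at ``alpha``, else 1. ``method`` may also be ``aic`` or
    ``bic`` (minimise the multivariate information criterion over the
    same common-sample fits).
    """
    y = _as_array(y)
    x = _as_array(x)
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    min_len = 2 * max_lag + 4
    if len(y) < min_len:
        raise ValueError(
            f"series length {len(y)} too short for max_lag={max_lag}; need >= {min_len}"
        )
    fits = {
        m: fit_var(y, x, m, offset=max_lag, log_transform=log_transform)
        for m in range(1, max_lag + 1)
    }
    n_obs = fits[max_lag].n_obs
    logdets = {m: np.linalg.slogdet(fits[m].sigma)[1] for m in fits}
    rows = []
    for m in range(1, max_lag + 1):
        if m == 1:
            lr, pv = np.nan, np.nan
        else:
            lr = n_obs * (logdets[m - 1] - logdets[m])
            pv = float(stats.chi2.sf(lr, 4))
        rows.append(
            {"lag": m, "loglik": fits[m].loglik, "logdet_sigma": logdets[m],
             "lr": lr, "lr_pvalue": pv}
        )
    table = pd.DataFrame(rows)
    if method == "lr":
        p_star = 1
        for m in range(max_lag, 1, -1):
            if table.loc[table["lag"] == m, "lr_pvalue"].iloc[0] <= alpha:
                p_star = m
                break
    elif method in ("aic", "bic"):
        penalty = 2.0 if method == "aic" else np.log(n_obs)
        crit = {m: logdets[m] + penalty * (2 * (2 * m + 1)) / n_obs for m in fits}
        p_star = min(crit, key=lambda m: (crit[m], m))
    else:
        raise ValueError("method must be 'lr', 'aic' or 'bic'")
    return LagSelection(p=p_star, method=method, max_lag=max_lag, table=table)


@dataclass
class GrangerResult:
    """Granger causality test of x -> y at a fixed lag order."""

    direction: str
    p: int
    wald: float
    df: int
    p_value: float
    lr_stat: float
    lr_p_value: float
    n_obs: int
    significant: bool
    fit: VARFit

    def __post_init__(self):
        assert self.df == self.p


def granger_test(y, x, p: int, alpha: float = 0.05, log_transform: bool = False,
                 direction: str = "x->y") -> GrangerResult:
    """Test whether lags of x improve prediction of y (x -> y).

    Primary statistic: Wald W = b' V^{-1} b on the y-equation's cross-lag
    coefficients b, compared to chi-square with p df. The
    likelihood-ratio variant refits the y equation without any x lags on
    the same sample and reports n ln(RSS_r / RSS_u); both are returned,
    the decision is taken on the Wald p-value at ``alpha``.
    """
    fit = fit_var(y, x, p, log_transform=log_transform)
    idx = np.arange(1 + p, 1 + 2 * p)
    b = fit.coef[idx, 0]
    V = fit.s2[0] * fit.xtx_inv[np.ix_(idx, idx)]
    try:
        W = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError as e:  # pragma: no cover - guarded by rank check
        raise CollinearityError(str(e))
    p_wald = float(stats.chi2.sf(W, p))

    yy = _as_array(y)
    xx = _as_array(x)
    if log_transform:
        yy, xx = np.log1p(yy), np.log1p(xx)
    Z, Y = _design(yy, xx, p, p)
    Zr = Z[:, : 1 + p]  # const + own lags only
    coef_r, *_ = np.linalg.lstsq(Zr, Y[:, 0], rcond=None)
    rss_r = float(((Y[:, 0] - Zr @ coef_r) ** 2).sum())
    rss_u = float((fit.resid[:, 0] ** 2).sum())
    lr = fit.n_obs * np.log(rss_r / rss_u)
    p_lr = float(stats.chi2.sf(lr, p))
    return GrangerResult(
        direction=direction, p=p, wald=W, df=p, p_value=p_wald,
        lr_stat=float(lr), lr_p_value=p_lr, n_obs=fit.n_obs,
        significant=bool(p_wald <= alpha), fit=fit,
    )


def _check_aligned(y, x) -> None:
    if isinstance(y, CountSeries) and isinstance(x, CountSeries):
        if not y.values.index.equals(x.values.index):
            raise ValueError("series spans differ; align before testing")
    else:
        if len(_as_array(y)) != len(_as_array(x)):
            raise ValueError("series lengths differ; align before testing")


def analyze_pair(y, x, max_lag: int = 12, alpha: float = 0.05,
                 log_transform: bool = False) -> GrangerResult:
    """Select the lag order, then run the Granger test at that order."""
    _check_aligned(y, x)
    n = len(_as_array(y))
    eff_max = min(max_lag, (n - 4) // 2)
    if eff_max < 1:
        raise ValueError(f"series too short ({n} months) for any lag")
    sel = select_lag(y, x, max_lag=eff_max, alpha=alpha, log_transform=log_transform)
    return granger_test(y, x, sel.p, alpha=alpha, log_transform=log_transform)


def run_paper_design(
    sm_all, reg_all, sm_specific=None, reg_specific=None,
    max_lag: int = 12, alpha: float = 0.05, labels: tuple[str, ...] = ("all", "specific"),
    log_transform: bool = False,
) -> pd.DataFrame:
    """Lag selection plus Granger tests for the all-reports pair and,
    when supplied, the specific-AE pair (or a PRR sensitivity series).

    Returns the four-column report (AE set, sample size in months, chosen
    lag, Wald chi-square, p-value) with one row per pair.
    """
    pairs = [(labels[0], reg_all, sm_all)]
    if sm_specific is not None and reg_specific is not None:
        pairs.append((labels[1], reg_specific, sm_specific))
    rows = []
    for label, y, x in pairs:
        _check_aligned(y, x)
        res = analyze_pair(y, x, max_lag=max_lag, alpha=alpha, log_transform=log_transform)
        rows.append(
            {
                "ae_set": label,
                "months": len(_as_array(y)),
                "lag": res.p,
                "chi2": res.wald,
                "p_value": res.p_value,
                "significant": res.significant,
            }
        )
    return pd.DataFrame(rows)
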