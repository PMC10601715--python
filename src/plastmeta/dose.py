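"""Dose-response model cascade and broken-stick threshold estimation.

For a response y (observation-level lnRR) against a continuous predictor x
(plastic amount, particle size, or incubation time) the cascade fits

1. ordinary least squares (unweighted),
2. weighted least squares meta-regression (weights 1/(v + tau^2)),
3. a penalized-spline generalized additive model,

and selects the GAM only when its AIC is at least 2 units below the linear
model's. When the nonlinear model is selected, the broken-stick model

    Y = b0 + b1 X + b2 (X - c)_+ + eps

is fitted to locate the threshold ("inflection point") c where the slope
changes from b1 to b1 + b2; the zero crossing of the fitted mean response
gives the dose/size at which the effect changes sign.

The breakpoint is estimated by iterative linearization: at a working
breakpoint c the model is linear in (1, X, (X-c)_+, -1[X>c]) and the
coefficient on the indicator term updates c by gamma/b2. A dense grid
search over candidate breakpoints serves as the oracle and the fallback
when iteration fails to settle.
"""

from __future__ import annotations

import logging
import math
import warnings
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .records import ModelFit

logger = logging.getLogger(__name__)

__all__ = [
    "PiecewiseRegression",
    "fit_linear",
    "fit_gam",
    "fit_segmented",
    "grid_search_breakpoint",
    "select_model",
    "zero_crossing",
]


def _as_xyw(x, y, weights):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if weights is None:
        w = np.ones_like(x)
    else:
        w = np.asarray(weights, dtype=float).ravel()
        if w.shape != x.shape:
            raise ValueError("weights must match x in length")
        if np.any(w <= 0):
            raise ValueError("weights must be strictly positive")
    return x, y, w


def _weighted_gaussian_aic(y, fitted, w, n_params: float) -> tuple[float, float]:
    """AIC from the weighted Gaussian log-likelihood.

    Weights are normalized to sum to n so AICs are comparable across
    candidate models fitted to the same data with the same weights.
    Returns (aic, residual_se).
    """
    n = len(y)
    wn = w * n / w.sum()
    resid = y - fitted
    sigma2 = float(np.sum(wn * resid**2) / n)
    sigma2 = max(sigma2, 1e-300)
    llf = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1) + 0.5 * float(
        np.sum(np.log(wn))
    )
    aic = -2 * llf + 2 * n_params
    return aic, math.sqrt(sigma2)


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares via the normal equations; returns (beta, cov)."""
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design (constant predictor?)")
    resid = y - X @ beta
    dof = max(len(y) - X.shape[1], 1)
    sigma2 = float(np.sum(w * resid**2) / dof)
    cov = sigma2 * np.linalg.inv(Xw.T @ Xw)
    return beta, cov


def fit_linear(x, y, weights=None) -> ModelFit:
    """(Weighted) straight-line fit with AIC, R^2, and model p-value."""
    x, y, w = _as_xyw(x, y, weights)
    if len(x) < 3:
        raise ValueError("linear fit needs n >= 3")
    if np.ptp(x) == 0:
        raise np.linalg.LinAlgError("constant predictor: slope is unidentified")
    X = np.column_stack([np.ones_like(x), x])
    beta, cov = _wls(X, y, w)
    fitted = X @ beta
    aic, res_se = _weighted_gaussian_aic(y, fitted, w, n_params=3)
    ybar = np.sum(w * y) / np.sum(w)
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    ss_res = float(np.sum(w * (y - fitted) ** 2))
    r2 = 1 - ss_res / ss_tot if ss_tot > 0 else 1.0
    se_b1 = math.sqrt(max(cov[1, 1], 0.0))
    if se_b1 > 0:
        p = float(2 * stats.t.sf(abs(beta[1]) / se_b1, df=len(x) - 2))
    else:
        p = 0.0
    b0, b1 = float(beta[0]), float(beta[1])
    return ModelFit(
        model_kind="ols" if weights is None else "wls",
        beta0=b0,
        beta1=b1,
        residual_se=res_se,
        aic=aic,
        r2=r2,
        p_model=p,
        n=len(x),
        predict=lambda xq, b0=b0, b1=b1: b0 + b1 * np.asarray(xq, dtype=float),
    )


def fit_gam(x, y, weights=None, df: int = 10, degree: int = 3) -> ModelFit:
    """Penalized B-spline smooth of y on x (generalized additive model).

    The smoothing penalty is chosen by minimizing AIC over a grid of
    penalty weights (a generalized cross-validation analogue); the model's
    AIC uses the smoother's effective degrees of freedom. For small n the
    basis dimension is reduced with a warning.
    """
    from statsmodels.gam.api import BSplines, GLMGam

    x, y, w = _as_xyw(x, y, weights)
    n = len(x)
    if n < 10:
        raise ValueError("GAM needs n >= 10")
    if np.ptp(y) == 0:
        level = float(y[0])
        aic, res_se = _weighted_gaussian_aic(y, y, w, n_params=2)
        return ModelFit(
            model_kind="gam",
            residual_se=res_se,
            aic=aic,
            r2=1.0,
            n=n,
            predict=lambda xq: np.full(np.shape(np.asarray(xq, dtype=float).ravel()), level),
            beta1=1.0,
        )
    max_df = max(4, min(df, n - 4))
    if max_df < df:
        warnings.warn(
            f"n = {n} too small for a df={df} basis; reduced to df={max_df}",
            stacklevel=2,
        )
    bs = BSplines(x[:, None], df=[max_df], degree=[degree])
    const = np.ones((n, 1))
    # the fit is invariant to the weights' scale; mean-1 normalization
    # keeps the penalized IRLS numerically stable
    w = w * n / w.sum()

    # penalty weight chosen by generalized cross-validation; the model AIC
    # is then computed once, at the selected fit
    best = None
    for alpha in np.logspace(-4, 7, 23):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = GLMGam(
                    y, exog=const, smoother=bs, alpha=[alpha], var_weights=w
                ).fit()
            except Exception:  # singular penalty corner cases
                continue
        edf = float(np.sum(res.edf))
        fitted = np.asarray(res.fittedvalues)
        wn = w * n / w.sum()
        sse = float(np.sum(wn * (y - fitted) ** 2))
        gcv = (sse / n) / max(1.0 - (edf + 1) / n, 1e-6) ** 2
        if best is None or gcv < best[0]:
            best = (gcv, res, edf, fitted)
    if best is None:
        raise RuntimeError("GAM fitting failed for every penalty weight")
    _, res, edf, fitted = best
    aic, res_se = _weighted_gaussian_aic(y, fitted, w, n_params=edf + 1)

    def predict(xq, _res=res):
        xq = np.asarray(xq, dtype=float).ravel()
        # clamp to the training range: B-spline bases do not extrapolate
        xq = np.clip(xq, x.min(), x.max())
        return np.asarray(
            _res.predict(exog=np.ones((len(xq), 1)), exog_smooth=xq[:, None])
        )

    fitted = np.asarray(res.fittedvalues)
    ybar = np.sum(w * y) / np.sum(w)
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    ss_res = float(np.sum(w * (y - fitted) ** 2))
    r2 = 1 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return ModelFit(
        model_kind="gam",
        residual_se=res_se,
        aic=aic,
        r2=r2,
        n=n,
        predict=predict,
        beta1=edf,  # effective df stored for diagnostics; no single slope exists
    )


def _segment_design(x: np.ndarray, c: float) -> np.ndarray:
    above = x > c
    return np.column_stack([np.ones_like(x), x, np.where(above, x - c, 0.0)])


def grid_search_breakpoint(
    x, y, weights=None, n_grid: int = 500
) -> tuple[float, float]:
    """Dense grid search for the breakpoint: returns (c_best, weighted SSE).

    Candidate breakpoints span the interior of the observed x range;
    candidates leaving fewer than two distinct x values on either side are
    skipped. This is the shipped oracle for the iterative estimator.
    """
    x, y, w = _as_xyw(x, y, weights)
    xs = np.unique(x)
    lo, hi = xs[1], xs[-2] if len(xs) > 3 else xs[-1]
    grid = np.linspace(xs[0], xs[-1], n_grid + 2)[1:-1]
    best_c, best_sse = None, np.inf
    for c in grid:
        if np.sum(xs < c) < 2 or np.sum(xs > c) < 2:
            continue
        X = _segment_design(x, c)
        try:
            beta, _ = _wls(X, y, w)
        except np.linalg.LinAlgError:
            continue
        sse = float(np.sum(w * (y - X @ beta) ** 2))
        if sse < best_sse:
            best_c, best_sse = float(c), sse
    if best_c is None:
        raise ValueError("no admissible breakpoint candidate in the x range")
    return best_c, best_sse


def davies_test(x, y, weights=None, n_grid: int = 20) -> float:
    """Davies-bound p-value for a slope change at an unknown breakpoint.

    The t statistic for the slope-change term is evaluated on a grid of
    candidate breakpoints; since the breakpoint is a nuisance parameter
    present only under the alternative, the naive sup-|t| p-value is
    corrected with Davies' upper bound using the total variation of the
    statistic across the grid. Conservative by construction.
    """
    x, y, w = _as_xyw(x, y, weights)
    xs = np.unique(x)
    if len(xs) < 5:
        return 1.0
    grid = np.linspace(np.quantile(x, 0.1), np.quantile(x, 0.9), n_grid)
    tstats = []
    for c in grid:
        if np.sum(xs < c) < 2 or np.sum(xs > c) < 2:
            continue
        X = _segment_design(x, c)
        try:
            beta, cov = _wls(X, y, w)
        except np.linalg.LinAlgError:
            continue
        se = math.sqrt(max(cov[2, 2], 0.0))
        if se == 0:
            return 0.0 if abs(beta[2]) > 0 else 1.0
        tstats.append(beta[2] / se)
    if not tstats:
        return 1.0
    t = np.asarray(tstats)
    s = float(np.max(np.abs(t)))
    total_variation = float(np.sum(np.abs(np.diff(t))))
    correction = total_variation * math.exp(-0.5 * s**2) / math.sqrt(8 * math.pi)
    p = 2 * (stats.norm.sf(s) + correction)
    return float(min(1.0, p))


class PiecewiseRegression(BaseEstimator, RegressorMixin):
    """Broken-stick (segmented) regression with one breakpoint.

    Fits Y = b0 + b1 X + b2 (X - c)_+ + eps by Muggeo-style iterative
    linearization from ``c_init`` (the sample median by default), refined
    until the breakpoint update falls below ``tol``. When iteration leaves
    the admissible range or cycles, a dense grid search takes over.

    Attributes (after ``fit``)
    --------------------------
    intercept_ : float
    coef_ : ndarray (b1, b2) — pre-break slope and slope change
    breakpoint_ : float
    breakpoint_se_ : float — delta-method SE from the final linearization
    n_iter_ : int
    converged_ : bool — False when the grid-search fallback produced c
    """

    def __init__(
        self,
        c_init: float | None = None,
        max_iter: int = 50,
        tol: float = 1e-8,
        n_grid: int = 500,
    ):
        self.c_init = c_init
        self.max_iter = max_iter
        self.tol = tol
        self.n_grid = n_grid

    def fit(self, X, y, sample_weight=None) -> "PiecewiseRegression":
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            if x.shape[1] != 1:
                raise ValueError("PiecewiseRegression takes a single predictor")
            x = x[:, 0]
        x, y, w = _as_xyw(x, y, sample_weight)
        if len(x) < 8:
            raise ValueError("segmented fit needs n >= 8")
        xs = np.unique(x)
        if len(xs) < 5:
            raise ValueError("need >= 2 distinct x values on each side of a breakpoint")

        c = float(np.median(x)) if self.c_init is None else float(self.c_init)
        c = float(np.clip(c, xs[1], xs[-2]))
        converged = False
        n_iter = 0
        beta = cov = None
        for n_iter in range(1, self.max_iter + 1):
            above = x > c
            if above.sum() < 2 or (~above).sum() < 2:
                break
            # working design: the -1[X>c] column linearizes the breakpoint
            Xd = np.column_stack(
                [np.ones_like(x), x, np.where(above, x - c, 0.0), -above.astype(float)]
            )
            try:
                beta, cov = _wls(Xd, y, w)
            except np.linalg.LinAlgError:
                break
            b2, gamma = beta[2], beta[3]
            if abs(b2) < 1e-12:
                break
            step = gamma / b2
            c_new = c + step
            if not (xs[0] < c_new < xs[-1]):
                break
            c = c_new
            if abs(step) < self.tol:
                converged = True
                break

        if not converged or beta is None:
            c, _ = grid_search_breakpoint(x, y, w, n_grid=self.n_grid)
            converged = False

        Xf = _segment_design(x, c)
        beta_f, cov_f = _wls(Xf, y, w)
        self.intercept_ = float(beta_f[0])
        self.coef_ = np.array([beta_f[1], beta_f[2]])
        self.breakpoint_ = float(c)
        if converged and cov is not None and abs(beta[2]) > 1e-12:
            self.breakpoint_se_ = float(math.sqrt(max(cov[3, 3], 0.0)) / abs(beta[2]))
        else:
            se_b2 = math.sqrt(max(cov_f[2, 2], 0.0))
            span = xs[-1] - xs[0]
            self.breakpoint_se_ = float(
                se_b2 / abs(beta_f[2]) * span / 4 if abs(beta_f[2]) > 1e-12 else span
            )
        self.n_iter_ = n_iter
        self.converged_ = converged
        self._x_range = (float(xs[0]), float(xs[-1]))
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "breakpoint_")
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            x = x[:, 0]
        u = np.where(x > self.breakpoint_, x - self.breakpoint_, 0.0)
        return self.intercept_ + self.coef_[0] * x + self.coef_[1] * u


def fit_segmented(
    x,
    y,
    weights=None,
    c_init: float | None = None,
    davies_alpha: float | None = 0.05,
) -> ModelFit:
    """Broken-stick fit as a ModelFit; degenerate breakpoints fall back to linear.

    A breakpoint is only accepted when the slope change is supported: when
    no interior breakpoint improves on the straight line, or the Davies
    test for a slope change at an unknown breakpoint is non-significant at
    ``davies_alpha`` (set to None to disable the pretest), a
    degenerate-breakpoint warning is issued and the linear fit is returned
    with breakpoint None.
    """
    x, y, w = _as_xyw(x, y, weights)
    linear = fit_linear(x, y, weights)
    if davies_alpha is not None and davies_test(x, y, w) >= davies_alpha:
        warnings.warn(
            "no evidence of a slope change (Davies test); returning linear fit",
            stacklevel=2,
        )
        return linear
    try:
        est = PiecewiseRegression(c_init=c_init).fit(x, y, sample_weight=w)
    except (ValueError, np.linalg.LinAlgError) as err:
        warnings.warn(f"degenerate breakpoint ({err}); returning linear fit", stacklevel=2)
        return linear
    fitted = est.predict(x)
    sse_seg = float(np.sum(w * (y - fitted) ** 2))
    lin_fitted = linear.predict(x)
    sse_lin = float(np.sum(w * (y - lin_fitted) ** 2))
    ybar = np.sum(w * y) / np.sum(w)
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    if sse_lin - sse_seg <= 1e-10 * max(ss_tot, 1e-30):
        warnings.warn(
            "no interior breakpoint improves on the linear fit", stacklevel=2
        )
        return linear
    aic, res_se = _weighted_gaussian_aic(y, fitted, w, n_params=5)
    r2 = 1 - sse_seg / ss_tot if ss_tot > 0 else 1.0
    return ModelFit(
        model_kind="segmented",
        beta0=est.intercept_,
        beta1=float(est.coef_[0]),
        beta2=float(est.coef_[1]),
        breakpoint=est.breakpoint_,
        breakpoint_se=est.breakpoint_se_,
        residual_se=res_se,
        aic=aic,
        r2=r2,
        n=len(x),
        predict=est.predict,
    )


def select_model(fits: Sequence[ModelFit], aic_margin: float = 2.0) -> ModelFit:
    """AIC 2-unit selection between the linear and nonlinear candidates.

    The GAM is selected only when its AIC is at least ``aic_margin`` units
    below the linear candidate's; otherwise the linear model wins
    (parsimony, including ties). Candidates must be fitted to the same
    data (checked via n).
    """
    if len(fits) < 2:
        raise ValueError("model selection needs >= 2 candidate fits")
    ns = {f.n for f in fits}
    if len(ns) != 1:
        raise ValueError("candidate fits cover different data (mismatched n)")
    linear = [f for f in fits if f.model_kind in {"ols", "wls"}]
    gams = [f for f in fits if f.model_kind == "gam"]
    if not linear:
        raise ValueError("need at least one linear candidate")
    best_linear = min(linear, key=lambda f: f.aic)
    if gams:
        best_gam = min(gams, key=lambda f: f.aic)
        if best_gam.aic <= best_linear.aic - aic_margin:
            return best_gam
    return best_linear


def zero_crossing(
    fit: ModelFit, x_range: tuple[float, float], n_scan: int = 2001
) -> float | None:
    """Smallest x in x_range where the fitted mean response changes sign.

    The prediction function is scanned on a dense grid; the first bracketed
    sign change is refined by bisection. Returns None when the prediction
    keeps one sign across the range.
    """
    if fit.predict is None:
        raise ValueError("fit carries no prediction function")
    lo, hi = x_range
    xs = np.linspace(lo, hi, n_scan)
    ys = np.asarray(fit.predict(xs), dtype=float)
    sign = np.sign(ys)
    exact = np.nonzero(sign == 0)[0]
    changes = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    first_exact = xs[exact[0]] if len(exact) else np.inf
    if len(changes) == 0:
        return float(first_exact) if np.isfinite(first_exact) else None
    i = changes[0]
    if xs[i] >= first_exact:
        return float(first_exact)
    f = lambda xq: float(np.asarray(fit.predict([xq]))[0])
    root = optimize.brentq(f, xs[i], xs[i + 1], xtol=1e-10)
    return float(root)
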