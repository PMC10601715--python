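"""Random/mixed-effects pooling and subgroup heterogeneity.

Effect sizes e_i with sampling variances v_i are pooled under the
random-effects model e_i ~ N(mu, v_i + tau^2). The between-observation
heterogeneity tau^2 is estimated by REML (default) or the closed-form
DerSimonian-Laird moment estimator; pooling uses inverse-variance weights
w_i = 1/(v_i + tau^2). An effect is called significant when its 95% CI
excludes zero. Categorical moderators are tested with the between-group
heterogeneity statistic Qm = Q_total - sum of within-level Q, chi-squared
with (levels - 1) degrees of freedom under the null.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .records import PooledEstimate, SubgroupResult

logger = logging.getLogger(__name__)

__all__ = ["RandomEffectsMeta", "estimate_tau2", "pool", "subgroup_qm"]


def _check_inputs(effects, variances):
    e = np.asarray(effects, dtype=float).ravel()
    v = np.asarray(variances, dtype=float).ravel()
    if e.shape != v.shape:
        raise ValueError("effects and variances must have equal length")
    if np.any(v < 0):
        raise ValueError("variances must be non-negative")
    return e, v


def _dl_tau2(e: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / v
    mu = np.sum(w * e) / np.sum(w)
    q = float(np.sum(w * (e - mu) ** 2))
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    if c <= 0:
        return 0.0
    return max(0.0, (q - (len(e) - 1)) / c)


def _reml_nll(tau2: float, e: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / (v + tau2)
    mu = np.sum(w * e) / np.sum(w)
    return 0.5 * (
        np.sum(np.log(v + tau2)) + np.log(np.sum(w)) + np.sum(w * (e - mu) ** 2)
    )


def _reml_tau2(e: np.ndarray, v: np.ndarray) -> float:
    # bounded scalar search; upper bound generous relative to observed spread
    hi = max(10.0 * float(np.var(e)), 10.0 * float(np.max(v)), 1e-3)
    res = optimize.minimize_scalar(
        _reml_nll, args=(e, v), bounds=(0.0, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    tau2 = float(res.x)
    # the bounded optimum can sit a hair above 0 when the truth is 0
    if _reml_nll(0.0, e, v) <= _reml_nll(tau2, e, v):
        return 0.0
    return tau2


def estimate_tau2(
    effects: Sequence[float], variances: Sequence[float], method: str = "REML"
) -> float:
    """Estimate the between-observation heterogeneity variance tau^2.

    ``method="DL"`` is the closed-form DerSimonian-Laird moment estimator
    truncated at zero; ``"REML"`` (default) maximizes the restricted
    likelihood of the random-effects model. With fewer than two effects
    tau^2 is 0 (with a warning).
    """
    e, v = _check_inputs(effects, variances)
    if len(e) < 2:
        warnings.warn("tau2 requires k >= 2; returning 0", stacklevel=2)
        return 0.0
    if np.any(v == 0):
        v = np.maximum(v, 1e-12)
    method = method.upper()
    if method == "DL":
        return _dl_tau2(e, v)
    if method == "REML":
        return _reml_tau2(e, v)
    raise ValueError(f"unknown tau2 method {method!r}; use 'REML' or 'DL'")


def pool(
    effects: Sequence[float],
    variances: Sequence[float],
    tau2: float = 0.0,
    level: float = 0.95,
    use_t: bool = False,
) -> PooledEstimate:
    """Inverse-variance pooled estimate with CI and the significance rule.

    Weights are w_i = 1/(v_i + tau2); with tau2 = 0 this is the
    fixed-effects estimator. The CI uses the normal quantile by default
    (``use_t`` switches to a t quantile with k-1 df); an effect is
    significant when the CI excludes zero.
    """
    e, v = _check_inputs(effects, variances)
    if len(e) == 0:
        raise ValueError("cannot pool an empty effect set")
    w = 1.0 / (v + tau2)
    mean = float(np.sum(w * e) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    if use_t and len(e) > 1:
        crit = float(stats.t.ppf(0.5 + level / 2, df=len(e) - 1))
    else:
        crit = float(stats.norm.ppf(0.5 + level / 2))
    lo, hi = mean - crit * se, mean + crit * se
    # Q against the fixed-effects mean (heterogeneity statistic)
    w_fe = 1.0 / np.maximum(v, 1e-12)
    mu_fe = np.sum(w_fe * e) / np.sum(w_fe)
    q = float(np.sum(w_fe * (e - mu_fe) ** 2))
    p = float(2 * stats.norm.sf(abs(mean / se))) if se > 0 else 0.0
    return PooledEstimate(
        k=len(e),
        mean_effect=mean,
        se=se,
        ci_low=lo,
        ci_high=hi,
        tau2=float(tau2),
        q_total=q,
        significant=bool(lo > 0 or hi < 0),
        p_value=p,
    )


class RandomEffectsMeta(BaseEstimator):
    """Random-effects meta-analysis estimator.

    Parameters
    ----------
    method : {"REML", "DL"}, default "REML"
        tau^2 estimator.
    level : float, default 0.95
        Confidence level for the pooled-effect interval.
    use_t : bool, default False
        Use a t quantile (k-1 df) instead of the normal quantile.

    Attributes (after ``fit``)
    --------------------------
    mean_effect_, se_, ci_low_, ci_high_, tau2_, q_total_, k_, significant_,
    p_value_ : scalars summarizing the pooled analysis.
    """

    def __init__(self, method: str = "REML", level: float = 0.95, use_t: bool = False):
        self.method = method
        self.level = level
        self.use_t = use_t

    def fit(self, effects: Sequence[float], variances: Sequence[float]) -> "RandomEffectsMeta":
        e, v = _check_inputs(effects, variances)
        tau2 = estimate_tau2(e, v, method=self.method) if len(e) >= 2 else 0.0
        est = pool(e, v, tau2=tau2, level=self.level, use_t=self.use_t)
        self.k_ = est.k
        self.mean_effect_ = est.mean_effect
        self.se_ = est.se
        self.ci_low_ = est.ci_low
        self.ci_high_ = est.ci_high
        self.tau2_ = est.tau2
        self.q_total_ = est.q_total
        self.significant_ = est.significant
        self.p_value_ = est.p_value
        self.estimate_ = est
        return self

    def summary(self) -> PooledEstimate:
        check_is_fitted(self, "estimate_")
        return self.estimate_


def subgroup_qm(
    effects: Sequence[float],
    variances: Sequence[float],
    group_labels: Sequence[str],
    min_n: int = 5,
    tau2: float | None = None,
    method: str = "REML",
    level: float = 0.95,
) -> SubgroupResult:
    """Categorical mixed-effects moderator analysis.

    Levels with ``min_n`` observations or fewer are excluded (the default
    keeps levels with more than 5 observations). A common tau^2 is
    estimated from the residual heterogeneity across all included levels
    (or supplied via ``tau2``); with weights w_i = 1/(v_i + tau2),

        Q_total = sum w_i (e_i - mu_hat)^2      (overall weighted mean)
        Q_within = sum over levels of the level-wise Q
        Qm = Q_total - Q_within,

    which is chi-squared with (levels - 1) df under moderator-free
    homogeneity. Per-level pooled estimates share the common tau^2.
    """
    e, v = _check_inputs(effects, variances)
    g = np.asarray(group_labels)
    if len(g) != len(e):
        raise ValueError("group_labels must match effects in length")

    levels, counts = np.unique(g, return_counts=True)
    included = [lv for lv, c in zip(levels, counts) if c > min_n]
    excluded = [str(lv) for lv, c in zip(levels, counts) if c <= min_n]
    if len(included) < 2:
        raise ValueError(
            f"subgroup analysis needs >= 2 levels with more than {min_n} observations; "
            f"excluded levels: {excluded or 'none'}"
        )
    mask = np.isin(g, included)
    e, v, g = e[mask], v[mask], g[mask]

    if tau2 is None:
        # residual heterogeneity: pool within-level centered effects
        resid = np.empty_like(e)
        for lv in included:
            m = g == lv
            w_fe = 1.0 / np.maximum(v[m], 1e-12)
            resid[m] = e[m] - np.sum(w_fe * e[m]) / np.sum(w_fe)
        tau2 = estimate_tau2(resid, v, method=method)

    w = 1.0 / (v + tau2)
    mu = np.sum(w * e) / np.sum(w)
    q_total = float(np.sum(w * (e - mu) ** 2))
    q_within = 0.0
    estimates: dict[str, PooledEstimate] = {}
    for lv in included:
        m = g == lv
        mu_l = np.sum(w[m] * e[m]) / np.sum(w[m])
        q_within += float(np.sum(w[m] * (e[m] - mu_l) ** 2))
        estimates[str(lv)] = pool(e[m], v[m], tau2=tau2, level=level)
    qm = max(0.0, q_total - q_within)
    df = len(included) - 1
    p_qm = float(stats.chi2.sf(qm, df))
    return SubgroupResult(
        estimates=estimates,
        qm=qm,
        df=df,
        p_qm=p_qm,
        q_total=q_total,
        q_within=q_within,
        excluded_levels=excluded,
    )


def benjamini_hochberg(p_values: Mapping[str, float]) -> dict[str, float]:
    """Benjamini-Hochberg adjusted p-values (optional multiplicity switch)."""
    names = list(p_values)
    p = np.array([p_values[n] for n in names], dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return dict(zip(names, adj))
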