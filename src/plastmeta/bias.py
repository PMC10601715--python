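"""Publication-bias diagnostics.

Two standard screens per parameter: Egger's regression test for
small-study (funnel-plot) asymmetry, and Rosenthal's fail-safe number —
the count of hypothetical zero-effect studies whose addition would render
the pooled effect non-significant. A symmetric funnel yields an Egger
intercept of exactly zero; a non-significant pooled effect yields a
fail-safe number of zero by convention.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy import stats

from .records import BiasResult

__all__ = ["egger_test", "failsafe_n", "bias_diagnostics"]


def egger_test(
    effects: Sequence[float], variances: Sequence[float]
) -> tuple[float, float, float]:
    """Egger's regression: standardized effect on precision.

    Regresses e_i / se_i on 1 / se_i by ordinary least squares; the
    intercept estimates funnel asymmetry (slope estimates the underlying
    effect). Returns (intercept, intercept SE, two-sided p from a t test
    with k - 2 df). Requires k >= 3 (k >= 10 recommended for power).
    """
    e = np.asarray(effects, dtype=float).ravel()
    v = np.asarray(variances, dtype=float).ravel()
    if len(e) != len(v):
        raise ValueError("effects and variances must have equal length")
    if len(e) < 3:
        raise ValueError("Egger test requires k >= 3")
    if np.any(v <= 0):
        raise ValueError("variances must be strictly positive")
    se = np.sqrt(v)
    t = e / se
    prec = 1.0 / se
    X = np.column_stack([np.ones_like(prec), prec])
    beta, _, rank, _ = np.linalg.lstsq(X, t, rcond=None)
    if rank < 2:
        raise ValueError("all standard errors equal: Egger regression degenerate")
    resid = t - X @ beta
    dof = len(e) - 2
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    intercept = float(beta[0])
    se_int = math.sqrt(max(cov[0, 0], 0.0))
    if se_int > 0:
        p = float(2 * stats.t.sf(abs(intercept) / se_int, df=dof))
    else:
        p = 0.0 if intercept != 0 else 1.0
    return intercept, se_int, p


def failsafe_n(
    effects: Sequence[float], variances: Sequence[float], alpha: float = 0.05
) -> int:
    """Rosenthal's fail-safe number by the z-sum method.

    Combines per-observation z_i = e_i / se_i into Z = sum(z_i) / sqrt(k)
    and returns the smallest number N of added zero-effect studies such
    that sum(z_i) / sqrt(k + N) drops below the one-sided critical value
    z_alpha (Rosenthal's convention). Returns 0 when the combined test is
    already non-significant.
    """
    e = np.asarray(effects, dtype=float).ravel()
    v = np.asarray(variances, dtype=float).ravel()
    if len(e) < 2:
        raise ValueError("fail-safe N requires k >= 2")
    if np.any(v <= 0):
        raise ValueError("variances must be strictly positive")
    k = len(e)
    z_sum = float(np.sum(e / np.sqrt(v)))
    z_crit = float(stats.norm.ppf(1 - alpha))
    if abs(z_sum) / math.sqrt(k) <= z_crit:
        return 0
    # |z_sum| / sqrt(k + N) <= z_crit  =>  N >= z_sum^2 / z_crit^2 - k
    n_exact = z_sum**2 / z_crit**2 - k
    return int(math.ceil(n_exact - 1e-12))


def bias_diagnostics(
    effects: Sequence[float], variances: Sequence[float], alpha: float = 0.05
) -> BiasResult:
    """Egger asymmetry + fail-safe N for one parameter's effect set."""
    intercept, se_int, p = egger_test(effects, variances)
    n_fs = failsafe_n(effects, variances, alpha=alpha)
    return BiasResult(
        egger_intercept=intercept,
        egger_se=se_int,
        egger_p=p,
        failsafe_n=n_fs,
        k=len(np.asarray(effects).ravel()),
    )
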