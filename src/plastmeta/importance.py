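"""Moderator importance for observation-level effect sizes.

Three tree-ensemble rankings of how strongly each moderator is associated
with a parameter's lnRR values:

* permutation importance from a bagged random forest (%IncMSE — the
  percentage increase in out-of-sample MSE when a predictor is permuted),
  with response-permutation p-values;
* relative influence from gradient-boosted regression trees, normalized to
  sum to 100 across predictors;
* a weighted variant in which bootstrap samples are drawn with probability
  proportional to the meta-analytic weights before each forest refit, so
  precise observations drive the ranking.

Rank order, not the raw importance value, is the stable quantity across
implementations and hyperparameters; downstream summaries are rank-based.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.inspection import permutation_importance

from .records import ImportanceResult

logger = logging.getLogger(__name__)

__all__ = [
    "encode_moderators",
    "rf_importance",
    "abt_importance",
    "weighted_rf_importance",
]

#: moderators entered in both continuous and categorical form, mirroring
#: how the predictor set is assembled for the tree models
DEFAULT_PREDICTORS = (
    "amount_g_per_kg",
    "amount_class",
    "size_um",
    "size_class",
    "incubation_days",
    "time_class",
    "plastic_type",
    "general_type",
    "ecosystem",
    "microbial_group",
)


def encode_moderators(
    table: pd.DataFrame, predictors: Sequence[str] = DEFAULT_PREDICTORS
) -> pd.DataFrame:
    """One-hot encode categorical moderators; drop rows with missing values.

    Rows missing any modeled predictor are dropped per-model (counts are
    logged); unordered categoricals expand into indicator columns named
    ``<predictor>=<level>`` so importances can be re-aggregated by source
    moderator.
    """
    cols = [c for c in predictors if c in table.columns]
    sub = table[cols].copy()
    n0 = len(sub)
    sub = sub.dropna()
    if len(sub) < n0:
        logger.info("dropped %d of %d rows with missing moderators", n0 - len(sub), n0)
    encoded = {}
    for c in cols:
        if sub[c].dtype.kind in "ifu":
            encoded[c] = sub[c].astype(float)
        else:
            for level in sorted(sub[c].astype(str).unique()):
                encoded[f"{c}={level}"] = (sub[c].astype(str) == level).astype(float)
    out = pd.DataFrame(encoded, index=sub.index)
    return out


def _check_xy(X: pd.DataFrame, y) -> tuple[pd.DataFrame, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    if len(X) != len(y):
        raise ValueError("X and y must have equal length")
    if np.ptp(y) == 0:
        raise ValueError("response is constant: importance undefined")
    return X, y


def _forest(n_trees: int, seed, max_features) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=n_trees,
        max_features=max_features,
        oob_score=False,
        random_state=seed,
        n_jobs=1,
    )


def _pct_inc_mse(model, X, y, rng, n_repeats: int = 5) -> np.ndarray:
    """%IncMSE: permutation importance scaled by the unpermuted MSE."""
    base_mse = float(np.mean((y - model.predict(X)) ** 2))
    perm = permutation_importance(
        model,
        X,
        y,
        scoring="neg_mean_squared_error",
        n_repeats=n_repeats,
        random_state=rng.integers(2**31 - 1),
        n_jobs=1,
    )
    # importances_mean is the increase in MSE; express relative to baseline
    denom = base_mse if base_mse > 0 else 1e-12
    return 100.0 * perm.importances_mean / denom


def rf_importance(
    X: pd.DataFrame,
    y,
    n_perm: int = 99,
    seed: int | None = None,
    n_trees: int = 1000,
) -> list[ImportanceResult]:
    """Random-forest permutation importance (%IncMSE) with permutation p-values.

    ``p_perm`` for each predictor is the fraction of ``n_perm``
    response-permuted refits whose importance meets or exceeds the observed
    one (with the +1 small-sample correction); set ``n_perm=0`` to skip the
    p-value pass when only the ranking is needed.
    """
    X, y = _check_xy(X, y)
    if len(X) < 30:
        raise ValueError("importance analysis needs n >= 30")
    rng = np.random.default_rng(seed)
    mtry = max(1, int(np.ceil(X.shape[1] / 3)))
    model = _forest(n_trees, int(rng.integers(2**31 - 1)), mtry).fit(X, y)
    observed = _pct_inc_mse(model, X, y, rng)

    p_perm = np.full(X.shape[1], np.nan)
    if n_perm > 0:
        # the null pass repeats the observed computation exactly (same
        # n_repeats) so the p-value is uniform under exchangeability
        observed_p = _pct_inc_mse(model, X, y, rng, n_repeats=3)
        exceed = np.zeros(X.shape[1])
        for _ in range(n_perm):
            y_null = rng.permutation(y)
            m0 = _forest(n_trees, int(rng.integers(2**31 - 1)), mtry).fit(X, y_null)
            null_imp = _pct_inc_mse(m0, X, y_null, rng, n_repeats=3)
            exceed += null_imp >= observed_p
        p_perm = (exceed + 1) / (n_perm + 1)

    return [
        ImportanceResult(
            predictor=col,
            inc_mse=float(observed[j]),
            p_perm=None if np.isnan(p_perm[j]) else float(p_perm[j]),
            n_obs=len(X),
        )
        for j, col in enumerate(X.columns)
    ]


def abt_importance(
    X: pd.DataFrame,
    y,
    seed: int | None = None,
    n_trees: int = 1000,
    learning_rate: float = 0.01,
    max_depth: int = 3,
) -> list[ImportanceResult]:
    """Boosted-tree relative influence, normalized to sum to 100."""
    X, y = _check_xy(X, y)
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if len(X) < 30:
        raise ValueError("importance analysis needs n >= 30")
    model = GradientBoostingRegressor(
        n_estimators=n_trees,
        learning_rate=learning_rate,
        max_depth=max_depth,
        random_state=seed,
    ).fit(X, y)
    imp = model.feature_importances_
    total = imp.sum()
    rel = 100.0 * imp / total if total > 0 else np.full_like(imp, 100.0 / len(imp))
    return [
        ImportanceResult(predictor=col, rel_influence=float(rel[j]), n_obs=len(X))
        for j, col in enumerate(X.columns)
    ]


def weighted_rf_importance(
    X: pd.DataFrame,
    y,
    weights,
    n_boot: int = 100,
    seed: int | None = None,
    n_trees: int = 500,
) -> list[ImportanceResult]:
    """Weight-aware forest importance via bootstrapped preselection.

    Each bootstrap replicate resamples observations with probability
    proportional to the meta-analytic weights, refits the forest, and the
    %IncMSE values are averaged across replicates, so high-precision
    observations dominate the ranking.
    """
    X, y = _check_xy(X, y)
    w = np.asarray(weights, dtype=float).ravel()
    if len(w) != len(y):
        raise ValueError("weights must match y in length")
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    p = w / w.sum()
    if p.max() > 0.99:
        warnings.warn(
            "one observation carries > 99% of the weight; ranking is degenerate",
            stacklevel=2,
        )
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if n_boot == 1:
        logger.warning("n_boot = 1: single-replicate importance, low confidence")
    rng = np.random.default_rng(seed)
    mtry = max(1, int(np.ceil(X.shape[1] / 3)))
    acc = np.zeros(X.shape[1])
    n = len(y)
    Xv = X.to_numpy()
    for _ in range(n_boot):
        idx = rng.choice(n, size=n, replace=True, p=p)
        Xb = pd.DataFrame(Xv[idx], columns=X.columns)
        yb = y[idx]
        if np.ptp(yb) == 0:
            continue
        m = _forest(n_trees, int(rng.integers(2**31 - 1)), mtry).fit(Xb, yb)
        acc += _pct_inc_mse(m, Xb, yb, rng, n_repeats=2)
    acc /= n_boot
    return [
        ImportanceResult(predictor=col, inc_mse=float(acc[j]), n_obs=len(X))
        for j, col in enumerate(X.columns)
    ]
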