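"""Observation-level effect sizes.

The effect size throughout is the natural-log response ratio

    lnRR = ln(x_t / x_c) = ln x_t - ln x_c

with sampling variance

    v = s_t^2 / (n_t x_t^2) + s_c^2 / (n_c x_c^2),

where (x, s, n) are the group mean, SD, and replicate count of the
treatment (t) and control (c) groups. Missing SDs are imputed from the
average coefficient of variation (CV) of complete observations. For
ordination-derived comparisons the module computes beta-diversity and
community-structure response ratios from mean pairwise Euclidean distances
on the first two ordination axes.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .records import (
    DEFAULT_FUNCTIONALITY_INDICATORS,
    EffectSize,
    ObservationRecord,
    OrdinationExtract,
)

logger = logging.getLogger(__name__)

__all__ = [
    "lnrr",
    "lnrr_variance",
    "impute_missing_sd",
    "compute_effect_sizes",
    "ordination_distances",
    "lnrr_beta_and_structure",
    "aggregate_functionality",
    "UndefinedEffectError",
]


class UndefinedEffectError(ValueError):
    """The response ratio is undefined for the given inputs."""


def lnrr(x_t: float, x_c: float) -> float:
    """Log response ratio ln(x_t) - ln(x_c); both means must be > 0."""
    if x_t <= 0 or x_c <= 0:
        raise UndefinedEffectError(
            f"lnRR undefined for non-positive means (x_t={x_t}, x_c={x_c})"
        )
    return math.log(x_t) - math.log(x_c)


def lnrr_variance(
    st: float, nt: int, x_t: float, sc: float, nc: int, x_c: float
) -> float:
    """Sampling variance of lnRR: st^2/(nt*x_t^2) + sc^2/(nc*x_c^2)."""
    if st is None or sc is None or (isinstance(st, float) and math.isnan(st)) or (
        isinstance(sc, float) and math.isnan(sc)
    ):
        raise ValueError("missing SD reached lnrr_variance; run impute_missing_sd first")
    if nt < 1 or nc < 1:
        raise ValueError("replicate counts must be >= 1")
    if x_t == 0 or x_c == 0:
        raise UndefinedEffectError("zero group mean: variance undefined")
    if st < 0 or sc < 0:
        raise ValueError("standard deviations must be non-negative")
    return st**2 / (nt * x_t**2) + sc**2 / (nc * x_c**2)


def _group_cvs(records: Iterable[ObservationRecord]) -> dict[str, list[float]]:
    """Collect control/treatment CVs of complete groups keyed by parameter."""
    pools: dict[str, list[float]] = {}
    for rec in records:
        for mean, sd in (
            (rec.mean_control, rec.sd_control),
            (rec.mean_treatment, rec.sd_treatment),
        ):
            if sd is None or (isinstance(sd, float) and math.isnan(sd)):
                continue
            if mean is None or mean <= 0:
                continue
            pools.setdefault(rec.parameter_name, []).append(sd / mean)
    return pools


def impute_missing_sd(
    records: Sequence[ObservationRecord], min_pool: int = 3
) -> tuple[list[ObservationRecord], list[bool]]:
    """Fill missing SDs as (average CV) x (that group's reported mean).

    The CV pool is built from complete groups sharing the record's
    parameter name; when that pool holds fewer than ``min_pool`` CVs, the
    dataset-wide pool is used instead. Returns the updated records and a
    parallel list of imputation flags.

    Raises
    ------
    ValueError
        If any SD is missing and no complete group exists anywhere to
        supply a CV.
    """
    per_param = _group_cvs(records)
    global_pool = [cv for cvs in per_param.values() for cv in cvs]

    def pool_for(param: str) -> list[float]:
        local = per_param.get(param, [])
        return local if len(local) >= min_pool else global_pool

    out: list[ObservationRecord] = []
    flags: list[bool] = []
    n_imputed = 0
    for rec in records:
        missing_c = rec.sd_missing("control")
        missing_t = rec.sd_missing("treatment")
        if not (missing_c or missing_t):
            out.append(rec)
            flags.append(False)
            continue
        pool = pool_for(rec.parameter_name)
        if not pool:
            raise ValueError(
                "cannot impute missing SDs: no complete observation provides a CV; "
                "drop SD-less records or supply SDs"
            )
        cv = float(np.mean(pool))
        changes: dict[str, float] = {}
        if missing_c:
            changes["sd_control"] = cv * rec.mean_control
        if missing_t:
            changes["sd_treatment"] = cv * rec.mean_treatment
        out.append(rec.copy(**changes))
        flags.append(True)
        n_imputed += 1
    if n_imputed:
        logger.info("imputed SDs for %d of %d records via mean CV", n_imputed, len(records))
    return out, flags


def compute_effect_sizes(
    records: Sequence[ObservationRecord],
    impute: bool = True,
    min_pool: int = 3,
) -> tuple[list[EffectSize], list[tuple[int, str]]]:
    """Compute lnRR and variance per record, with SD imputation.

    Records with non-positive means are excluded (the ratio is undefined)
    and reported in the second return value as (index, reason) pairs.
    """
    if impute:
        records_f, flags = impute_missing_sd(records, min_pool=min_pool)
    else:
        records_f, flags = list(records), [False] * len(records)

    effects: list[EffectSize] = []
    excluded: list[tuple[int, str]] = []
    for i, (rec, flag) in enumerate(zip(records_f, flags)):
        try:
            e = lnrr(rec.mean_treatment, rec.mean_control)
            v = lnrr_variance(
                rec.sd_treatment,
                rec.n_treatment,
                rec.mean_treatment,
                rec.sd_control,
                rec.n_control,
                rec.mean_control,
            )
        except (UndefinedEffectError, ValueError) as err:
            logger.warning("row %d excluded from effect sizes: %s", i, err)
            excluded.append((i, str(err)))
            continue
        effects.append(EffectSize(lnrr=e, variance=v, sd_imputed=flag, parent=rec))
    return effects, excluded


def ordination_distances(extract: OrdinationExtract) -> tuple[float, float, float]:
    """Mean pairwise Euclidean distances (Dc, Dt, Db) of ordination clouds.

    Dc and Dt average over all unordered within-group pairs; Db averages
    over all control x treatment pairs. Each group needs >= 2 points.
    """
    c = np.asarray(extract.control_points, dtype=float)
    t = np.asarray(extract.treatment_points, dtype=float)
    if len(c) < 2 or len(t) < 2:
        raise ValueError("need at least 2 points per group for within-group distances")
    dc = float(pdist(c).mean())
    dt = float(pdist(t).mean())
    db = float(cdist(c, t).mean())
    extract.Dc, extract.Dt, extract.Db = dc, dt, db
    return dc, dt, db


def lnrr_beta_and_structure(Dc: float, Dt: float, Db: float) -> tuple[float, float]:
    """Beta-diversity and structure response ratios from mean distances.

    lnRRb = ln(Dt / Dc) compares within-group dispersion; lnRRs =
    ln(Db / (Dc + Dt)) measures between-group separation relative to the
    combined within-group dispersion.
    """
    if Dc <= 0 or Dt <= 0 or Db <= 0:
        raise UndefinedEffectError(
            f"zero or negative distance (Dc={Dc}, Dt={Dt}, Db={Db}): ratios undefined"
        )
    return math.log(Dt / Dc), math.log(Db / (Dc + Dt))


def aggregate_functionality(
    effects: Sequence[EffectSize],
    indicator_list: Sequence[str] = DEFAULT_FUNCTIONALITY_INDICATORS,
) -> list[EffectSize]:
    """Select the effect sizes contributing to pooled soil functionality.

    Functionality is synthesized from individual microbial activity
    indicators (enzyme activities, soil respiration, nutrient acquisition);
    their lnRRs are pooled directly with no direction harmonization. The
    input effect sizes are returned unchanged, filtered by parameter name.
    """
    indicators = set(indicator_list)
    if not indicators:
        logger.warning("empty functionality indicator list; returning no effects")
        return []
    subset = [
        e
        for e in effects
        if e.parent is not None and e.parent.parameter_name in indicators
    ]
    if not subset:
        logger.warning("no effect sizes matched the functionality indicator list")
    return subset
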