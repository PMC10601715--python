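"""End-to-end orchestration: observations -> effect sizes -> pooled
estimates, subgroup heterogeneity, dose-response thresholds, moderator
importance, and publication-bias tables, under one config.

The config is a plain dict (or YAML file via the CLI) with defaults that
run the full cascade on either a user-supplied observation table or the
synthetic generator. All outputs are TSV tables plus a machine-readable
``report.json`` recording row counts, exclusions, seeds, and wall time per
stage; every number in the tables is re-derivable by calling the
underlying module functions directly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import bias as bias_mod
from . import dose as dose_mod
from . import importance as imp_mod
from .effects import aggregate_functionality, compute_effect_sizes
from .io import (
    classify_moderators,
    merge_richness,
    read_observations,
    records_to_frame,
    write_observations,
)
from .meta import estimate_tau2, pool, subgroup_qm
from .records import DEFAULT_FUNCTIONALITY_INDICATORS
from .synthetic import SyntheticConfig, SyntheticTruth, generate_meta_dataset

logger = logging.getLogger(__name__)

__all__ = ["default_config", "run_pipeline", "effects_table"]

SUBGROUP_MODERATORS = (
    "general_type",
    "ecosystem",
    "amount_class",
    "time_class",
    "size_class",
    "microbial_group",
)

DOSE_RESPONSES = ("functionality", "biomass", "richness", "shannon")
DOSE_PREDICTORS = ("amount_g_per_kg", "size_um", "incubation_days")


def default_config() -> dict[str, Any]:
    return {
        "dataset": None,  # path to CSV/TSV; None -> synthetic generator
        "schema": None,  # canonical -> file column-name map
        "seed": 0,
        "output_dir": "plastmeta_results",
        "tau2_method": "REML",
        "use_weights": True,
        "min_subgroup_n": 5,
        "min_dose_n": 30,
        "functionality_indicators": list(DEFAULT_FUNCTIONALITY_INDICATORS),
        "stages": {"subgroups": True, "dose": True, "importance": True, "bias": True},
        "importance": {"n_trees": 200, "n_perm": 0, "n_boot": 10},
        "synthetic": {},  # overrides for SyntheticConfig / SyntheticTruth
    }


def _merged_config(config: Mapping[str, Any] | None) -> dict[str, Any]:
    cfg = default_config()
    for k, v in (config or {}).items():
        if k not in cfg:
            raise ValueError(f"unknown config key {k!r}")
        if isinstance(cfg[k], dict) and isinstance(v, Mapping):
            cfg[k] = {**cfg[k], **v}
        else:
            cfg[k] = v
    return cfg


def effects_table(records: Sequence, indicators: Sequence[str]) -> tuple[pd.DataFrame, list]:
    """Effect-size table (one row per retained observation) + exclusions."""
    effects, excluded = compute_effect_sizes(records)
    base = records_to_frame([e.parent for e in effects])
    base["lnrr"] = [e.lnrr for e in effects]
    base["variance"] = [e.variance for e in effects]
    base["sd_imputed"] = [e.sd_imputed for e in effects]
    func_names = set(indicators)
    base["is_functionality"] = base["parameter_name"].isin(func_names)
    return base, excluded


def _parameter_sets(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Analysis sets: each named parameter plus the pooled functionality set."""
    out = {
        str(p): sub for p, sub in table.groupby("parameter_name") if len(sub) >= 2
    }
    func = table[table["is_functionality"]]
    if len(func) >= 2:
        out["functionality"] = func
    return out


def _forest_table(sets: Mapping[str, pd.DataFrame], method: str) -> pd.DataFrame:
    rows = []
    for name, sub in sorted(sets.items()):
        e, v = sub["lnrr"].to_numpy(), sub["variance"].to_numpy()
        tau2 = estimate_tau2(e, v, method=method)
        est = pool(e, v, tau2=tau2)
        rows.append({"parameter": name, **est.as_dict()})
    df = pd.DataFrame(rows)
    return df.rename(columns={"mean_effect": "mean", "k": "k"})


def _subgroup_table(
    sets: Mapping[str, pd.DataFrame], method: str, min_n: int
) -> pd.DataFrame:
    rows = []
    for name, sub in sorted(sets.items()):
        for mod in SUBGROUP_MODERATORS:
            if mod not in sub.columns:
                continue
            ok = sub.dropna(subset=[mod, "lnrr", "variance"])
            if len(ok) == 0:
                continue
            try:
                res = subgroup_qm(
                    ok["lnrr"].to_numpy(),
                    ok["variance"].to_numpy(),
                    ok[mod].astype(str).to_numpy(),
                    min_n=min_n,
                    method=method,
                )
            except ValueError:
                continue
            for level, est in res.estimates.items():
                rows.append(
                    {
                        "parameter": name,
                        "moderator": mod,
                        "level": level,
                        "k": est.k,
                        "mean": est.mean_effect,
                        "ci_low": est.ci_low,
                        "ci_high": est.ci_high,
                        "significant": est.significant,
                        "qm": res.qm,
                        "df": res.df,
                        "p_qm": res.p_qm,
                        "excluded_levels": ";".join(res.excluded_levels),
                    }
                )
    return pd.DataFrame(rows)


def _dose_table(
    sets: Mapping[str, pd.DataFrame],
    method: str,
    use_weights: bool,
    min_n: int,
) -> pd.DataFrame:
    rows = []
    for resp in DOSE_RESPONSES:
        if resp not in sets:
            continue
        sub = sets[resp]
        for pred in DOSE_PREDICTORS:
            ok = sub.dropna(subset=[pred, "lnrr", "variance"])
            if len(ok) < min_n:
                continue
            x = ok[pred].to_numpy(dtype=float)
            y = ok["lnrr"].to_numpy(dtype=float)
            v = ok["variance"].to_numpy(dtype=float)
            tau2 = estimate_tau2(y, v, method=method)
            w = 1.0 / (v + tau2) if use_weights else None
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    ols = dose_mod.fit_linear(x, y)
                    wls = dose_mod.fit_linear(x, y, weights=w) if use_weights else ols
                    gam = dose_mod.fit_gam(x, y, weights=w)
                    # AICs are only comparable between fits sharing weights
                    chosen = dose_mod.select_model([wls if use_weights else ols, gam])
                    seg = None
                    if chosen.model_kind == "gam":
                        seg = dose_mod.fit_segmented(x, y, weights=w)
                        if seg.model_kind == "segmented":
                            chosen = seg
            except (ValueError, np.linalg.LinAlgError) as err:
                logger.warning("dose fit skipped for %s ~ %s: %s", resp, pred, err)
                continue
            zc = dose_mod.zero_crossing(chosen, (float(x.min()), float(x.max())))
            rows.append(
                {
                    "parameter": resp,
                    "predictor": pred,
                    "model_kind": chosen.model_kind,
                    "aic_ols": ols.aic,
                    "aic_wls": wls.aic,
                    "aic_gam": gam.aic,
                    "aic_segmented": seg.aic if seg is not None and seg.model_kind == "segmented" else None,
                    "beta0": chosen.beta0,
                    "beta1": chosen.beta1,
                    "beta2": chosen.beta2,
                    "breakpoint": chosen.breakpoint,
                    "breakpoint_se": chosen.breakpoint_se,
                    "zero_crossing": zc,
                    "r2": chosen.r2,
                    "p_model": chosen.p_model,
                    "n": chosen.n,
                }
            )
    return pd.DataFrame(rows)


def _importance_table(
    sets: Mapping[str, pd.DataFrame],
    method: str,
    seed: int,
    settings: Mapping[str, Any],
) -> pd.DataFrame:
    rows = []
    for resp in DOSE_RESPONSES:
        if resp not in sets:
            continue
        sub = sets[resp].reset_index(drop=True)
        X = imp_mod.encode_moderators(sub)
        if len(X) < 30 or X.shape[1] < 2:
            continue
        y = sub.loc[X.index, "lnrr"].to_numpy()
        v = sub.loc[X.index, "variance"].to_numpy()
        tau2 = estimate_tau2(y, v, method=method)
        w = 1.0 / (v + tau2)
        rf = imp_mod.rf_importance(
            X, y, n_perm=settings["n_perm"], seed=seed, n_trees=settings["n_trees"]
        )
        abt = imp_mod.abt_importance(X, y, seed=seed, n_trees=settings["n_trees"])
        wrf = imp_mod.weighted_rf_importance(
            X, y, w, n_boot=settings["n_boot"], seed=seed,
            n_trees=settings["n_trees"],
        )
        for res, meth, val in (
            *((r, "rf_inc_mse", r.inc_mse) for r in rf),
            *((r, "abt_rel_influence", r.rel_influence) for r in abt),
            *((r, "weighted_rf_inc_mse", r.inc_mse) for r in wrf),
        ):
            rows.append(
                {
                    "parameter": resp,
                    "predictor": res.predictor,
                    "method": meth,
                    "value": val,
                    "p_perm": res.p_perm,
                    "n_obs": res.n_obs,
                }
            )
    return pd.DataFrame(rows)


def _bias_table(sets: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    rows = []
    for name, sub in sorted(sets.items()):
        if len(sub) < 3:
            continue
        res = bias_mod.bias_diagnostics(
            sub["lnrr"].to_numpy(), sub["variance"].to_numpy()
        )
        rows.append(
            {
                "parameter": name,
                "k": res.k,
                "egger_intercept": res.egger_intercept,
                "egger_se": res.egger_se,
                "egger_p": res.egger_p,
                "failsafe_n": res.failsafe_n,
            }
        )
    return pd.DataFrame(rows)


def _config_hash(cfg: Mapping[str, Any]) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config: Mapping[str, Any] | None = None) -> dict[str, Any]:
    """Run all enabled stages; returns the run report (also written to disk)."""
    cfg = _merged_config(config)
    outdir = Path(cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "config_hash": _config_hash(cfg),
        "seed": cfg["seed"],
        "stages": {},
    }

    def timed(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, *exc):
                report["stages"].setdefault(name, {})["wall_time_s"] = round(
                    time.perf_counter() - self.t0, 3
                )

        return _T()

    # --- input stage -----------------------------------------------------
    with timed("input"):
        if cfg["dataset"] is None:
            syn = dict(cfg["synthetic"])
            truth_overrides = {
                k: syn.pop(k)
                for k in list(syn)
                if k in SyntheticTruth.__dataclass_fields__
            }
            truth = SyntheticTruth(seed=cfg["seed"], **truth_overrides)
            records, truth = generate_meta_dataset(
                SyntheticConfig(**syn), truth, seed=cfg["seed"]
            )
            report["stages"]["input"] = {"source": "synthetic", "n_read": len(records)}
            write_observations(records, outdir / "observations.tsv")
            digest = hashlib.sha256(
                (outdir / "observations.tsv").read_bytes()
            ).hexdigest()[:16]
        else:
            records = read_observations(cfg["dataset"], schema=cfg["schema"])
            digest = hashlib.sha256(Path(cfg["dataset"]).read_bytes()).hexdigest()[:16]
            report["stages"]["input"] = {
                "source": str(cfg["dataset"]),
                "n_read": len(records),
            }
        report["input_digest"] = digest
        records = [classify_moderators(r) for r in merge_richness(records)]

    # --- effect sizes ----------------------------------------------------
    with timed("effects"):
        table, excluded = effects_table(records, cfg["functionality_indicators"])
        report["stages"]["effects"] = {
            "n_read": len(records),
            "n_analyzed": len(table),
            "n_excluded": len(excluded),
            "excluded": [{"row": i, "reason": r} for i, r in excluded],
            "n_sd_imputed": int(table["sd_imputed"].sum()),
        }
        table.to_csv(outdir / "effect_sizes.tsv", sep="\t", index=False)

    sets = _parameter_sets(table)
    method = cfg["tau2_method"]

    # --- pooling ---------------------------------------------------------
    with timed("pool"):
        forest = _forest_table(sets, method)
        forest.to_csv(outdir / "forest.tsv", sep="\t", index=False)
        report["stages"]["pool"] = {"n_parameters": len(forest)}

    stages = cfg["stages"]
    if stages.get("subgroups", True):
        with timed("subgroups"):
            sg = _subgroup_table(sets, method, cfg["min_subgroup_n"])
            sg.to_csv(outdir / "subgroups.tsv", sep="\t", index=False)
            report["stages"]["subgroups"] = {"n_rows": len(sg)}

    if stages.get("dose", True):
        with timed("dose"):
            dm = _dose_table(sets, method, cfg["use_weights"], cfg["min_dose_n"])
            dm.to_csv(outdir / "dose_models.tsv", sep="\t", index=False)
            report["stages"]["dose"] = {"n_models": len(dm)}

    if stages.get("importance", True):
        with timed("importance"):
            it = _importance_table(sets, method, cfg["seed"], cfg["importance"])
            it.to_csv(outdir / "importance.tsv", sep="\t", index=False)
            report["stages"]["importance"] = {"n_rows": len(it)}

    if stages.get("bias", True):
        with timed("bias"):
            bt = _bias_table(sets)
            bt.to_csv(outdir / "bias.tsv", sep="\t", index=False)
            report["stages"]["bias"] = {"n_parameters": len(bt)}

    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
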