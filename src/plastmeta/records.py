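"""Domain types shared across the meta-analysis pipeline.

One :class:`ObservationRecord` is a single control-vs-plastic comparison:
group means, standard deviations, replicate counts, and the moderators
describing the plastic treatment (type, amount, particle size, incubation
time, ecosystem). Downstream stages attach effect sizes, pooled estimates,
and model fits to these records without mutating them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any

__all__ = [
    "ModeratorSet",
    "ObservationRecord",
    "EffectSize",
    "OrdinationExtract",
    "PooledEstimate",
    "SubgroupResult",
    "ModelFit",
    "ImportanceResult",
    "BiasResult",
]

#: alpha-diversity metrics merged into a single "richness" variable
RICHNESS_ALIASES = frozenset({"chao1", "ace", "otu_count"})

#: parameter names treated as soil-functionality indicators by default.
#: The full indicator set lives in supplementary material we do not ship;
#: this default covers the individually named ones and is user-overridable.
DEFAULT_FUNCTIONALITY_INDICATORS = (
    "soil_respiration",
    "fda",
    "c_acq",
    "n_acq",
    "p_acq",
    "ox",
)

#: aliphatic backbones (polyolefins); everything else with additional
#: functional groups is "others"; biodegradable polyesters get their own class
ALIPHATIC_TYPES = frozenset({"PE", "PP", "HDPE", "LDPE"})
DEGRADABLE_TYPES = frozenset({"PLA", "PCL", "PBAT", "PHA", "PHB"})
KNOWN_PLASTIC_TYPES = ALIPHATIC_TYPES | DEGRADABLE_TYPES | frozenset(
    {"PS", "PVC", "PET", "PA", "PC", "PU", "PMMA"}
)


def _is_missing(x: Any) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass
class ModeratorSet:
    """Treatment-level moderators for one comparison.

    Continuous moderators may be missing (``None``); the derived class
    columns are filled deterministically by :func:`plastmeta.io.classify_moderators`.
    """

    plastic_type: str | None = None
    general_type: str | None = None  # aliphatic | others | degradable
    amount_g_per_kg: float | None = None
    amount_class: str | None = None  # low | high
    size_um: float | None = None
    size_class: str | None = None  # nano | micro | meso | macro
    incubation_days: float | None = None
    time_class: str | None = None  # short | long
    ecosystem: str | None = None  # bare | cropland | grassland | forest
    microbial_group: str | None = None

    def as_dict(self) -> dict[str, Any]:
        return {
            "plastic_type": self.plastic_type,
            "general_type": self.general_type,
            "amount_g_per_kg": self.amount_g_per_kg,
            "amount_class": self.amount_class,
            "size_um": self.size_um,
            "size_class": self.size_class,
            "incubation_days": self.incubation_days,
            "time_class": self.time_class,
            "ecosystem": self.ecosystem,
            "microbial_group": self.microbial_group,
        }


@dataclass
class ObservationRecord:
    """One control/treatment comparison from a primary study."""

    study_id: str
    parameter_name: str
    mean_control: float
    mean_treatment: float
    n_control: int
    n_treatment: int
    sd_control: float | None = None
    sd_treatment: float | None = None
    parameter_group: str | None = None
    moderators: ModeratorSet = field(default_factory=ModeratorSet)

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems: list[str] = []
        if self.n_control < 1:
            problems.append(f"n_control = {self.n_control} < 1")
        if self.n_treatment < 1:
            problems.append(f"n_treatment = {self.n_treatment} < 1")
        for name, sd in (("sd_control", self.sd_control), ("sd_treatment", self.sd_treatment)):
            if not _is_missing(sd) and sd < 0:
                problems.append(f"{name} = {sd} < 0")
        for name, m in (("mean_control", self.mean_control), ("mean_treatment", self.mean_treatment)):
            if _is_missing(m) or not math.isfinite(m):
                problems.append(f"{name} is missing or non-finite")
        return problems

    def sd_missing(self, group: str) -> bool:
        sd = self.sd_control if group == "control" else self.sd_treatment
        return _is_missing(sd)

    def copy(self, **changes: Any) -> "ObservationRecord":
        return replace(self, **changes)


@dataclass
class EffectSize:
    """lnRR with its sampling variance for one observation."""

    lnrr: float
    variance: float
    sd_imputed: bool = False
    weight: float | None = None  # filled by pooling: 1 / (v + tau2)
    parent: ObservationRecord | None = None


@dataclass
class OrdinationExtract:
    """Sample coordinates on the first two ordination axes, by group."""

    control_points: "list[tuple[float, float]]"
    treatment_points: "list[tuple[float, float]]"
    Dc: float | None = None  # mean within-control pairwise distance
    Dt: float | None = None  # mean within-treatment pairwise distance
    Db: float | None = None  # mean between-group pairwise distance


@dataclass
class PooledEstimate:
    """Random/mixed-effects summary for a set of effect sizes."""

    k: int
    mean_effect: float
    se: float
    ci_low: float
    ci_high: float
    tau2: float
    q_total: float
    significant: bool
    p_value: float | None = None

    def as_dict(self) -> dict[str, Any]:
        return {
            "k": self.k,
            "mean_effect": self.mean_effect,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "tau2": self.tau2,
            "q_total": self.q_total,
            "significant": self.significant,
            "p_value": self.p_value,
        }


@dataclass
class SubgroupResult:
    """Categorical mixed-effects moderator analysis with Qm heterogeneity."""

    estimates: dict[str, PooledEstimate]
    qm: float
    df: int
    p_qm: float
    q_total: float
    q_within: float
    excluded_levels: list[str] = field(default_factory=list)


@dataclass
class ModelFit:
    """A fitted dose-response candidate (linear, GAM, or broken-stick)."""

    model_kind: str  # ols | wls | gam | segmented
    beta0: float | None = None
    beta1: float | None = None
    beta2: float | None = None  # slope change at the breakpoint (segmented)
    breakpoint: float | None = None
    breakpoint_se: float | None = None
    residual_se: float | None = None
    aic: float = math.nan
    r2: float | None = None
    p_model: float | None = None
    n: int = 0
    zero_crossing: float | None = None
    predict: Any = None  # callable x -> fitted mean response

    @property
    def slope_post(self) -> float | None:
        """Post-breakpoint slope beta1 + beta2 (segmented fits only)."""
        if self.beta1 is None or self.beta2 is None:
            return None
        return self.beta1 + self.beta2


@dataclass
class ImportanceResult:
    """Per-predictor importance from one ranking method."""

    predictor: str
    inc_mse: float | None = None  # % increase in MSE under permutation
    rel_influence: float | None = None  # boosted trees, sums to 100
    p_perm: float | None = None
    n_obs: int = 0


@dataclass
class BiasResult:
    """Small-study asymmetry and robustness diagnostics for one parameter."""

    egger_intercept: float
    egger_se: float
    egger_p: float
    failsafe_n: int
    k: int
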