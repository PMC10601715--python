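"""Reading, validating, and moderator-classifying the observation table.

The observation table is a tidy CSV/TSV with one row per unique
control-vs-plastic comparison. Column names can be remapped through a
``schema`` dict so externally deposited tables can be ingested without
editing. Moderator classes (amount low/high, incubation short/long,
particle-size class, general polymer type) are derived deterministically
from the continuous moderators.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .records import (
    ALIPHATIC_TYPES,
    DEGRADABLE_TYPES,
    KNOWN_PLASTIC_TYPES,
    RICHNESS_ALIASES,
    ModeratorSet,
    ObservationRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_observations",
    "write_observations",
    "classify_moderators",
    "merge_richness",
    "read_ordination_table",
    "ValidationError",
    "OBSERVATION_COLUMNS",
]

MANDATORY_COLUMNS = (
    "study_id",
    "parameter_name",
    "mean_control",
    "mean_treatment",
    "n_control",
    "n_treatment",
)

OBSERVATION_COLUMNS = MANDATORY_COLUMNS + (
    "sd_control",
    "sd_treatment",
    "parameter_group",
    "plastic_type",
    "general_type",
    "amount_g_per_kg",
    "amount_class",
    "size_um",
    "size_class",
    "incubation_days",
    "time_class",
    "ecosystem",
    "microbial_group",
)


class ValidationError(ValueError):
    """Raised when the observation table violates row-level invariants."""

    def __init__(self, message: str, rows: list[tuple[int, str]] | None = None):
        super().__init__(message)
        self.rows = rows or []


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or pd.isna(value):
        return None
    return float(value)


def _opt_str(value) -> str | None:
    if value is None or pd.isna(value) or value == "":
        return None
    return str(value)


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_observations(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    classify: bool = True,
) -> list[ObservationRecord]:
    """Read and validate an observation table.

    Parameters
    ----------
    path
        CSV (comma) or TSV (tab) file with a header row; UTF-8, decimal point.
    schema
        Optional map from canonical column names (see
        ``OBSERVATION_COLUMNS``) to the column names used in the file, for
        ingesting externally deposited tables.
    classify
        When true (default), moderator classes are filled from the
        continuous moderators after reading.

    Raises
    ------
    ValidationError
        If a mandatory column is absent or any row violates an invariant
        (replicate count < 1, negative SD, missing mean); the error lists
        offending row numbers (1-based, excluding the header).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing mandatory column(s): {', '.join(missing)}")

    records: list[ObservationRecord] = []
    bad_rows: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        mods = ModeratorSet(
            plastic_type=_opt_str(row.get("plastic_type")),
            general_type=_opt_str(row.get("general_type")),
            amount_g_per_kg=_opt_float(row.get("amount_g_per_kg")),
            amount_class=_opt_str(row.get("amount_class")),
            size_um=_opt_float(row.get("size_um")),
            size_class=_opt_str(row.get("size_class")),
            incubation_days=_opt_float(row.get("incubation_days")),
            time_class=_opt_str(row.get("time_class")),
            ecosystem=_opt_str(row.get("ecosystem")),
            microbial_group=_opt_str(row.get("microbial_group")),
        )
        try:
            rec = ObservationRecord(
                study_id=str(row["study_id"]),
                parameter_name=str(row["parameter_name"]),
                mean_control=float(row["mean_control"]),
                mean_treatment=float(row["mean_treatment"]),
                n_control=int(row["n_control"]),
                n_treatment=int(row["n_treatment"]),
                sd_control=_opt_float(row.get("sd_control")),
                sd_treatment=_opt_float(row.get("sd_treatment")),
                parameter_group=_opt_str(row.get("parameter_group")),
                moderators=mods,
            )
        except (TypeError, ValueError) as err:
            bad_rows.append((i, str(err)))
            continue
        problems = rec.validate()
        if problems:
            bad_rows.append((i, "; ".join(problems)))
            continue
        records.append(rec)

    if bad_rows:
        detail = "; ".join(f"row {r}: {msg}" for r, msg in bad_rows[:20])
        raise ValidationError(
            f"{len(bad_rows)} row(s) failed validation: {detail}", rows=bad_rows
        )
    if classify:
        records = [classify_moderators(r) for r in records]
    return records


def records_to_frame(records: Sequence[ObservationRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = {
            "study_id": rec.study_id,
            "parameter_name": rec.parameter_name,
            "parameter_group": rec.parameter_group,
            "mean_control": rec.mean_control,
            "mean_treatment": rec.mean_treatment,
            "sd_control": rec.sd_control,
            "sd_treatment": rec.sd_treatment,
            "n_control": rec.n_control,
            "n_treatment": rec.n_treatment,
        }
        row.update(rec.moderators.as_dict())
        rows.append(row)
    return pd.DataFrame(rows, columns=list(OBSERVATION_COLUMNS))


def write_observations(records: Sequence[ObservationRecord], path: str | Path) -> None:
    """Write records as CSV/TSV (dialect chosen from the file suffix)."""
    path = Path(path)
    records_to_frame(records).to_csv(path, sep=_sep_for(path), index=False)


def classify_moderators(record: ObservationRecord, strict_two_class: bool = False) -> ObservationRecord:
    """Fill moderator class columns from the continuous moderators.

    Boundaries: amount < 10 g/kg is "low", >= 10 g/kg "high"; incubation
    <= 7 days is "short"; particle size < 1 um is "nano", 1 um - 5 mm
    "micro", 5 - 25 mm "meso", > 25 mm "macro". Polymer types PE/PP (and
    HDPE/LDPE) are "aliphatic"; biodegradable polyesters (PLA, PCL, ...)
    are "degradable" unless ``strict_two_class`` collapses them into
    "others"; everything else is "others". Idempotent and deterministic.
    """
    m = record.moderators
    amount_class = m.amount_class
    if m.amount_g_per_kg is not None:
        amount_class = "low" if m.amount_g_per_kg < 10 else "high"
    time_class = m.time_class
    if m.incubation_days is not None:
        time_class = "short" if m.incubation_days <= 7 else "long"
    size_class = m.size_class
    if m.size_um is not None:
        s = m.size_um
        if s < 1:
            size_class = "nano"
        elif s <= 5_000:
            size_class = "micro"
        elif s <= 25_000:
            size_class = "meso"
        else:
            size_class = "macro"
    general_type = m.general_type
    if m.plastic_type is not None:
        code = m.plastic_type.upper()
        if code in ALIPHATIC_TYPES:
            general_type = "aliphatic"
        elif code in DEGRADABLE_TYPES:
            general_type = "others" if strict_two_class else "degradable"
        else:
            if code not in KNOWN_PLASTIC_TYPES:
                logger.warning(
                    "unknown plastic_type code %r: assigned general_type 'others'", code
                )
            general_type = "others"
    new_mods = ModeratorSet(
        plastic_type=m.plastic_type,
        general_type=general_type,
        amount_g_per_kg=m.amount_g_per_kg,
        amount_class=amount_class,
        size_um=m.size_um,
        size_class=size_class,
        incubation_days=m.incubation_days,
        time_class=time_class,
        ecosystem=m.ecosystem,
        microbial_group=m.microbial_group,
    )
    return record.copy(moderators=new_mods)


def merge_richness(records: Iterable[ObservationRecord]) -> list[ObservationRecord]:
    """Relabel Chao1 / ACE / OTU-count observations as "richness".

    These three alpha-diversity metrics all estimate taxon counts and are
    merged into a single richness variable; all other parameter names are
    untouched and the record count is preserved.
    """
    out = []
    for rec in records:
        if rec.parameter_name.lower() in RICHNESS_ALIASES:
            out.append(rec.copy(parameter_name="richness"))
        else:
            out.append(rec)
    return out


def read_ordination_table(path: str | Path) -> dict[str, dict[str, list[tuple[float, float]]]]:
    """Read digitized ordination coordinates.

    Expected columns: ``comparison_id, sample_id, axis1, axis2, group``
    with group in {control, treatment}. Returns
    ``{comparison_id: {"control": [(x, y), ...], "treatment": [...]}}``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    required = {"comparison_id", "axis1", "axis2", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"ordination table missing column(s): {sorted(missing)}")
    out: dict[str, dict[str, list[tuple[float, float]]]] = {}
    for (cid, grp), sub in df.groupby(["comparison_id", "group"]):
        if grp not in {"control", "treatment"}:
            raise ValidationError(f"unknown group label {grp!r} in comparison {cid!r}")
        out.setdefault(str(cid), {}).setdefault(grp, []).extend(
            zip(sub["axis1"].astype(float), sub["axis2"].astype(float))
        )
    return out


def write_validation_report(
    path: str | Path,
    n_read: int,
    n_valid: int,
    excluded: list[tuple[int, str]],
) -> None:
    """Write a machine-readable JSON validation report."""
    report = {
        "n_read": n_read,
        "n_valid": n_valid,
        "n_excluded": len(excluded),
        "excluded_rows": [{"row": r, "reason": msg} for r, msg in excluded],
    }
    Path(path).write_text(json.dumps(report, indent=2))
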