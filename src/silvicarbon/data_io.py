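"""Compilation-table I/O: schema, validation, unit conversion, pairing.

One CSV row is one treatment–control comparison: arm means of aboveground
carbon (Mg C ha⁻¹) or live biomass (Mg ha⁻¹, converted on read), arm SDs
(blank when the study did not report them — never 0, which is a legal SD),
replicate counts, study/site identifiers, and the moderator columns used by
the meta-regression models. Several comparisons within one study may share a
control plot; that is recorded via ``control_id``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: Mass fraction of carbon in aboveground live tree biomass.
BIOMASS_CARBON_FRACTION = 0.47

TREATMENTS = ("interplant", "npk", "thin")
SOIL_MOISTURE_REGIMES = ("perudic", "udic", "ustic", "xeric")
WOOD_TYPES = ("hardwood", "softwood")
EXPERIMENTAL_DESIGNS = ("additive", "replacement")
APPLICATION_METHODS = ("continuous", "pulse")
UNITS = ("biomass", "carbon")
N_APPLIED_UNITS = ("kg_per_ha", "kg_per_tree")

#: Canonical CSV header, in column order.
CSV_COLUMNS = [
    "study_id",
    "site_id",
    "treatment",
    "units",
    "mean_treat",
    "mean_ctrl",
    "sd_treat",
    "sd_ctrl",
    "n_treat",
    "n_ctrl",
    "control_id",
    "tree_genus",
    "intercrop_genus",
    "prev_land_use",
    "soil_moisture_regime",
    "wood_type",
    "experimental_design",
    "application_method",
    "stand_age",
    "time_since_treatment",
    "map_mm",
    "basal_area_removed",
    "n_applied",
    "n_applied_unit",
    "stand_density",
]

MODERATOR_FIELDS = (
    "tree_genus",
    "intercrop_genus",
    "prev_land_use",
    "soil_moisture_regime",
    "wood_type",
    "experimental_design",
    "application_method",
)


class CompilationValidationError(ValueError):
    """Raised when compilation rows violate the schema invariants.

    ``errors`` is a list of ``(row_number, message)`` pairs, 1-based row
    numbers counting data rows (header excluded).
    """

    def __init__(self, errors: Sequence[tuple[int, str]]):
        self.errors = list(errors)
        lines = "; ".join(f"row {r}: {m}" for r, m in self.errors[:10])
        more = "" if len(self.errors) <= 10 else f" (+{len(self.errors) - 10} more)"
        super().__init__(f"{len(self.errors)} invalid row(s): {lines}{more}")

    def to_json(self) -> str:
        return json.dumps(
            [{"row": r, "message": m} for r, m in self.errors], indent=2
        )


@dataclass
class ObservationRecord:
    """One treatment–control comparison of aboveground carbon.

    Means and SDs are in Mg C ha⁻¹ once loaded (biomass rows are converted
    with :func:`biomass_to_carbon` on read). ``sd_treat``/``sd_ctrl`` are
    ``None`` when the study did not report them; imputation fills them and
    sets the provenance flags on the derived effect size.
    """

    study_id: str
    site_id: str
    treatment: str
    mean_treat: float
    mean_ctrl: float
    n_treat: int
    n_ctrl: int
    sd_treat: float | None = None
    sd_ctrl: float | None = None
    control_id: str | None = None
    tree_genus: str | None = None
    intercrop_genus: str | None = None
    prev_land_use: str | None = None
    soil_moisture_regime: str | None = None
    wood_type: str | None = None
    experimental_design: str | None = None
    application_method: str | None = None
    stand_age: float | None = None
    time_since_treatment: float | None = None
    map_mm: float | None = None
    basal_area_removed: float | None = None
    n_applied: float | None = None
    n_applied_unit: str | None = None
    stand_density: float | None = None
    units: str = "carbon"

    @property
    def moderators(self) -> Mapping[str, str | None]:
        """Categorical moderator values as a read-only mapping."""
        return {name: getattr(self, name) for name in MODERATOR_FIELDS}

    def validate(self) -> list[str]:
        """Return invariant violations for this record (empty = valid)."""
        problems: list[str] = []
        if self.treatment not in TREATMENTS:
            problems.append(f"unknown treatment {self.treatment!r}")
        if not (isinstance(self.mean_treat, (int, float)) and self.mean_treat > 0):
            problems.append(f"mean_treat must be > 0, got {self.mean_treat!r}")
        if not (isinstance(self.mean_ctrl, (int, float)) and self.mean_ctrl > 0):
            problems.append(f"mean_ctrl must be > 0, got {self.mean_ctrl!r}")
        for arm in ("treat", "ctrl"):
            sd = getattr(self, f"sd_{arm}")
            if sd is not None and (not math.isfinite(sd) or sd < 0):
                problems.append(f"sd_{arm} must be >= 0 when present, got {sd!r}")
            n = getattr(self, f"n_{arm}")
            if not (isinstance(n, int) and n >= 1):
                problems.append(f"n_{arm} must be an integer >= 1, got {n!r}")
        if self.units not in UNITS:
            problems.append(f"units must be one of {UNITS}, got {self.units!r}")
        if (
            self.soil_moisture_regime is not None
            and self.soil_moisture_regime not in SOIL_MOISTURE_REGIMES
        ):
            problems.append(
                f"soil_moisture_regime must be one of {SOIL_MOISTURE_REGIMES}, "
                f"got {self.soil_moisture_regime!r}"
            )
        if self.wood_type is not None and self.wood_type not in WOOD_TYPES:
            problems.append(f"unknown wood_type {self.wood_type!r}")
        if (
            self.experimental_design is not None
            and self.experimental_design not in EXPERIMENTAL_DESIGNS
        ):
            problems.append(f"unknown experimental_design {self.experimental_design!r}")
        if (
            self.application_method is not None
            and self.application_method not in APPLICATION_METHODS
        ):
            problems.append(f"unknown application_method {self.application_method!r}")
        if self.n_applied is not None and self.n_applied_unit not in N_APPLIED_UNITS:
            problems.append(
                f"n_applied requires n_applied_unit in {N_APPLIED_UNITS}, "
                f"got {self.n_applied_unit!r}"
            )
        # treatment-specific moderators stay with their treatment
        if self.treatment != "interplant":
            if self.intercrop_genus is not None:
                problems.append("intercrop_genus is only valid for interplant records")
            if self.experimental_design is not None:
                problems.append(
                    "experimental_design is only valid for interplant records"
                )
        if self.treatment != "npk":
            if self.application_method is not None:
                problems.append("application_method is only valid for npk records")
            if self.n_applied is not None:
                problems.append("n_applied is only valid for npk records")
        if self.treatment != "thin" and self.basal_area_removed is not None:
            problems.append("basal_area_removed is only valid for thin records")
        return problems


def biomass_to_carbon(biomass: float) -> float:
    """Convert aboveground live biomass (Mg ha⁻¹) to carbon (Mg C ha⁻¹).

    Uses the default biomass carbon fraction of 0.47.

    Raises
    ------
    ValueError
        If ``biomass`` is negative.
    """
    if biomass < 0:
        raise ValueError(f"biomass must be non-negative, got {biomass}")
    return biomass * BIOMASS_CARBON_FRACTION


def _convert_units(rec: ObservationRecord) -> ObservationRecord:
    """Apply the biomass→carbon conversion once, guarded by the units flag."""
    if rec.units == "carbon":
        return rec
    rec.mean_treat = biomass_to_carbon(rec.mean_treat)
    rec.mean_ctrl = biomass_to_carbon(rec.mean_ctrl)
    if rec.sd_treat is not None:
        rec.sd_treat = biomass_to_carbon(rec.sd_treat)
    if rec.sd_ctrl is not None:
        rec.sd_ctrl = biomass_to_carbon(rec.sd_ctrl)
    rec.units = "carbon"
    return rec


_FLOAT_FIELDS = {
    "mean_treat",
    "mean_ctrl",
    "sd_treat",
    "sd_ctrl",
    "stand_age",
    "time_since_treatment",
    "map_mm",
    "basal_area_removed",
    "n_applied",
    "stand_density",
}
_INT_FIELDS = {"n_treat", "n_ctrl"}


def _parse_row(row: Mapping[str, object], rownum: int) -> tuple[ObservationRecord | None, list[tuple[int, str]]]:
    errors: list[tuple[int, str]] = []
    kwargs: dict[str, object] = {}
    for f in dc_fields(ObservationRecord):
        raw = row.get(f.name)
        if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
            kwargs[f.name] = "carbon" if f.name == "units" else None
            continue
        if f.name in _FLOAT_FIELDS:
            try:
                kwargs[f.name] = float(raw)
            except (TypeError, ValueError):
                errors.append((rownum, f"malformed number in {f.name}: {raw!r}"))
                kwargs[f.name] = None
        elif f.name in _INT_FIELDS:
            try:
                val = float(raw)
                if not val.is_integer():
                    raise ValueError
                kwargs[f.name] = int(val)
            except (TypeError, ValueError):
                errors.append((rownum, f"malformed integer in {f.name}: {raw!r}"))
                kwargs[f.name] = 0
        else:
            kwargs[f.name] = str(raw).strip()
    required = ("study_id", "site_id", "treatment", "mean_treat", "mean_ctrl")
    missing = [name for name in required if kwargs.get(name) is None]
    if missing:
        errors.append((rownum, f"missing required field(s): {', '.join(missing)}"))
        return None, errors
    rec = ObservationRecord(**kwargs)  # type: ignore[arg-type]
    for msg in rec.validate():
        errors.append((rownum, msg))
    return (rec if not errors else None), errors


def read_compilation(path: str | Path) -> list[ObservationRecord]:
    """Read and validate a compilation CSV into observation records.

    Rows flagged ``units=biomass`` are converted to carbon. Missing SDs are
    read as ``None`` (empty cells). Any invariant violation raises
    :class:`CompilationValidationError` listing the offending row numbers.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    unknown = [c for c in df.columns if c not in CSV_COLUMNS]
    if unknown:
        raise CompilationValidationError(
            [(0, f"unknown column(s): {', '.join(unknown)}")]
        )
    records: list[ObservationRecord] = []
    errors: list[tuple[int, str]] = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        rec, errs = _parse_row(row, i)
        errors.extend(errs)
        if rec is not None:
            records.append(_convert_units(rec))
    if errors:
        raise CompilationValidationError(errors)
    return records


def records_to_frame(records: Iterable[ObservationRecord]) -> pd.DataFrame:
    """Tabulate records into a DataFrame with the canonical column order."""
    rows = []
    for rec in records:
        rows.append({c: getattr(rec, c) for c in CSV_COLUMNS})
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    return df


def frame_to_records(df: pd.DataFrame) -> list[ObservationRecord]:
    """Validate a DataFrame in the canonical schema into records."""
    records: list[ObservationRecord] = []
    errors: list[tuple[int, str]] = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        rec, errs = _parse_row(row, i)
        errors.extend(errs)
        if rec is not None:
            records.append(_convert_units(rec))
    if errors:
        raise CompilationValidationError(errors)
    return records


def write_compilation(records: Iterable[ObservationRecord], path: str | Path) -> None:
    """Write records to CSV; ``None`` becomes an empty cell."""
    df = records_to_frame(records)
    df.to_csv(path, index=False)


def group_shared_controls(
    records: Sequence[ObservationRecord],
) -> dict[str, list[ObservationRecord]]:
    """Group comparisons that were measured against the same control plot.

    Records without a ``control_id`` are treated as having a unique,
    unnamed control and keyed by ``"<study_id>:__row<i>"``. Useful as a
    diagnostic: several treatment arms compared to one control plot are not
    independent, and the meta-model handles this only through the
    publication-level random effect.
    """
    groups: dict[str, list[ObservationRecord]] = {}
    for i, rec in enumerate(records):
        key = rec.control_id if rec.control_id else f"{rec.study_id}:__row{i}"
        groups.setdefault(key, []).append(rec)
    return groups
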