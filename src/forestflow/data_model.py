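"""Domain types, CSV schemas and dataset validation.

The unit of analysis is a *catchment-year*: one annual observation of river
flow in a catchment undergoing forestation, together with the flow expected
under the pre-forestation land cover (the control flow), annual climate and
the state of the forest.  Static catchment descriptors (long-term climate,
land-use history, experimental design) live in :class:`CatchmentMeta`.

All tabular interchange is plain CSV: comma separated, UTF-8, ``.`` decimal,
mandatory header, missing values as empty strings (surfaced as ``None`` /
``NaN``).  Flows and precipitation are catchment-area-normalised depths in
mm/year; forest cover is percent of catchment area (0-100).  A negative flow
response means forestation reduced river flow.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CatchmentMeta",
    "AnnualRecord",
    "ResponseRecord",
    "SchemaError",
    "ReferentialError",
    "ParseError",
    "ValidationIssue",
    "ValidationReport",
    "load_dataset",
    "write_dataset",
    "validate_dataset",
    "apply_felling_truncation",
    "meta_to_frame",
    "records_to_frame",
    "frame_to_meta",
    "frame_to_records",
]

HISTORICAL_FOREST_LEVELS = ("present", "absent", "unknown")
PRIOR_LAND_USE_LEVELS = ("agriculture", "idle", "other")
PRIOR_LAND_COVER_LEVELS = ("grassland", "shrubland", "other")
FOREST_TYPE_LEVELS = ("coniferous", "broadleaf", "mixed", "unknown")
ESTABLISHMENT_LEVELS = ("planted", "spontaneous", "mixed")
DESIGN_LEVELS = ("single", "paired", "quasi_paired")
QC_SOURCE_LEVELS = ("measured", "calibrated")


class SchemaError(ValueError):
    """A required column is missing or an enum value is not recognised."""


class ReferentialError(ValueError):
    """An annual record refers to a catchment absent from the metadata."""


class ParseError(ValueError):
    """A cell could not be coerced to its declared type."""


@dataclass(frozen=True)
class CatchmentMeta:
    """Static descriptors of one forested catchment.

    ``map_mm`` and ``mean_pet_mm`` are the long-term mean annual
    precipitation and potential evapotranspiration; their ratio ``aridity``
    (higher = wetter) indexes water versus energy limitation.  ``fc_s`` is
    the catchment-mean percent forest cover (the spatial component of forest
    cover, distinguishing between-catchment from within-catchment change).
    """

    catchment_id: str
    country: str = ""
    area_km2: float = 1.0
    map_mm: float = 1000.0
    mean_pet_mm: float = 1000.0
    fc_s: float = 50.0
    historical_forest: str = "unknown"
    prior_land_use: str = "agriculture"
    prior_land_cover: str = "grassland"
    forest_type: str = "unknown"
    establishment: str = "planted"
    design: str = "single"

    @property
    def aridity(self) -> float:
        return self.map_mm / self.mean_pet_mm

    def __post_init__(self) -> None:
        if self.area_km2 <= 0:
            raise ParseError(f"{self.catchment_id}: area_km2 must be positive")
        if not 0.0 <= self.fc_s <= 100.0:
            raise ParseError(f"{self.catchment_id}: fc_s must lie in [0, 100]")
        if self.mean_pet_mm <= 0 or self.map_mm <= 0:
            raise ParseError(f"{self.catchment_id}: climate normals must be positive")
        _check_enum(self.historical_forest, HISTORICAL_FOREST_LEVELS, "historical_forest")
        _check_enum(self.prior_land_use, PRIOR_LAND_USE_LEVELS, "prior_land_use")
        _check_enum(self.prior_land_cover, PRIOR_LAND_COVER_LEVELS, "prior_land_cover")
        _check_enum(self.forest_type, FOREST_TYPE_LEVELS, "forest_type")
        _check_enum(self.establishment, ESTABLISHMENT_LEVELS, "establishment")
        _check_enum(self.design, DESIGN_LEVELS, "design")


@dataclass(frozen=True)
class AnnualRecord:
    """One catchment-year of flows, climate and forest state.

    ``q_f_mm`` is annual flow from the forested catchment; ``q_c_mm`` the
    control flow (measured twin catchment, or predicted by calibration —
    see ``q_c_source``).  ``age_years`` is the area-weighted mean forest
    age; rows with ``age_years == 0`` are pre-forestation (calibration
    period) observations.
    """

    catchment_id: str
    hydro_year: int
    age_years: float
    q_f_mm: float
    p_mm: float
    pet_mm: float
    forest_cover_pct: float
    q_c_mm: float | None = None
    q_c_source: str = "measured"
    felling_after: bool = False

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise ParseError(f"{self.catchment_id}/{self.hydro_year}: age_years < 0")
        _check_enum(self.q_c_source, QC_SOURCE_LEVELS, "q_c_source")


@dataclass(frozen=True)
class ResponseRecord:
    """An :class:`AnnualRecord` augmented with the flow response and the
    within-catchment climate/cover anomalies.

    ``q_mm = q_f_mm - q_c_mm`` (negative = reduction); ``p_t_mm``,
    ``pet_t_mm`` and ``fc_t_pct`` are deviations from the catchment means,
    so each averages to zero within a catchment.
    """

    catchment_id: str
    hydro_year: int
    age_years: float
    q_f_mm: float
    q_c_mm: float
    p_mm: float
    pet_mm: float
    forest_cover_pct: float
    q_mm: float
    p_t_mm: float
    pet_t_mm: float
    fc_t_pct: float
    q_c_source: str = "measured"
    zero_forested_flow: bool = False


META_COLUMNS = [
    "catchment_id", "country", "area_km2", "map_mm", "mean_pet_mm", "fc_s",
    "historical_forest", "prior_land_use", "prior_land_cover", "forest_type",
    "establishment", "design",
]
ANNUAL_COLUMNS = [
    "catchment_id", "hydro_year", "age_years", "q_f_mm", "q_c_mm", "p_mm",
    "pet_mm", "forest_cover_pct", "q_c_source", "felling_after",
]
_META_NUMERIC = ("area_km2", "map_mm", "mean_pet_mm", "fc_s")
_ANNUAL_NUMERIC = ("age_years", "q_f_mm", "q_c_mm", "p_mm", "pet_mm", "forest_cover_pct")


def _check_enum(value: str, levels: Sequence[str], name: str) -> None:
    if value not in levels:
        raise SchemaError(f"invalid {name} value {value!r}; expected one of {levels}")


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _coerce_numeric(df: pd.DataFrame, columns: Iterable[str], path: str) -> None:
    for col in columns:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                f"'{col}' at data row {row + 1}"
            )
        df[col] = coerced


def load_dataset(
    meta_path: str, records_path: str
) -> tuple[list[CatchmentMeta], list[AnnualRecord]]:
    """Read ``catchments.csv`` and ``annual.csv`` into validated domain objects.

    Raises :class:`SchemaError` for missing columns or bad enum values,
    :class:`ParseError` for uncoercible cells (naming the row), and
    :class:`ReferentialError` when an annual row references an unknown
    catchment.
    """
    meta_df = pd.read_csv(meta_path, dtype=str, keep_default_na=False)
    meta_df = meta_df.replace({"": None})
    _require_columns(meta_df, [c for c in META_COLUMNS if c != "country"], str(meta_path))
    _coerce_numeric(meta_df, _META_NUMERIC, str(meta_path))
    meta = frame_to_meta(meta_df)

    ann_df = pd.read_csv(records_path, dtype=str, keep_default_na=False)
    ann_df = ann_df.replace({"": None})
    required = [c for c in ANNUAL_COLUMNS if c not in ("q_c_mm", "q_c_source", "felling_after")]
    _require_columns(ann_df, required, str(records_path))
    _coerce_numeric(ann_df, _ANNUAL_NUMERIC + ("hydro_year",), str(records_path))
    records = frame_to_records(ann_df)

    known = {m.catchment_id for m in meta}
    for rec in records:
        if rec.catchment_id not in known:
            raise ReferentialError(
                f"annual record references unknown catchment_id {rec.catchment_id!r}"
            )
    return meta, records


def write_dataset(
    meta: Sequence[CatchmentMeta],
    records: Sequence[AnnualRecord],
    meta_path: str,
    records_path: str,
) -> None:
    """Write the two CSVs in the dialect :func:`load_dataset` reads back."""
    meta_to_frame(meta).to_csv(meta_path, index=False)
    records_to_frame(records).to_csv(records_path, index=False)


def meta_to_frame(meta: Sequence[CatchmentMeta]) -> pd.DataFrame:
    rows = [{c: getattr(m, c) for c in META_COLUMNS} for m in meta]
    return pd.DataFrame(rows, columns=META_COLUMNS)


def records_to_frame(records: Sequence[AnnualRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {c: getattr(r, c) for c in ANNUAL_COLUMNS}
        row["q_c_mm"] = "" if r.q_c_mm is None else r.q_c_mm
        row["felling_after"] = bool(r.felling_after)
        rows.append(row)
    return pd.DataFrame(rows, columns=ANNUAL_COLUMNS)


def frame_to_meta(df: pd.DataFrame) -> list[CatchmentMeta]:
    out = []
    for _, row in df.iterrows():
        out.append(
            CatchmentMeta(
                catchment_id=str(row["catchment_id"]),
                country=str(row.get("country") or ""),
                area_km2=float(row["area_km2"]),
                map_mm=float(row["map_mm"]),
                mean_pet_mm=float(row["mean_pet_mm"]),
                fc_s=float(row["fc_s"]),
                historical_forest=str(row["historical_forest"]),
                prior_land_use=str(row["prior_land_use"]),
                prior_land_cover=str(row["prior_land_cover"]),
                forest_type=str(row["forest_type"]),
                establishment=str(row["establishment"]),
                design=str(row["design"]),
            )
        )
    return out


def _parse_bool(value) -> bool:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return False
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    return str(value).strip().lower() in ("true", "1", "yes")


def frame_to_records(df: pd.DataFrame) -> list[AnnualRecord]:
    out = []
    for _, row in df.iterrows():
        q_c = row.get("q_c_mm")
        if q_c is not None and not (isinstance(q_c, float) and np.isnan(q_c)):
            q_c = float(q_c)
        else:
            q_c = None
        out.append(
            AnnualRecord(
                catchment_id=str(row["catchment_id"]),
                hydro_year=int(row["hydro_year"]),
                age_years=float(row["age_years"]),
                q_f_mm=float(row["q_f_mm"]),
                q_c_mm=q_c,
                p_mm=float(row["p_mm"]),
                pet_mm=float(row["pet_mm"]),
                forest_cover_pct=float(row["forest_cover_pct"]),
                q_c_source=str(row.get("q_c_source") or "measured"),
                felling_after=_parse_bool(row.get("felling_after")),
            )
        )
    return out


@dataclass(frozen=True)
class ValidationIssue:
    catchment_id: str
    kind: str  # duplicate_year | decreasing_cover | nonmonotone_year | felling_truncation
    message: str


@dataclass
class ValidationReport:
    """Report-only dataset diagnostics; nothing here raises."""

    per_catchment: pd.DataFrame = field(default_factory=pd.DataFrame)
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not self.issues


def validate_dataset(
    meta: Sequence[CatchmentMeta], records: Sequence[AnnualRecord]
) -> ValidationReport:
    """Summarise series lengths and flag auditable anomalies.

    Flags duplicate (catchment, year) rows, decreasing forest cover without
    a ``felling_after`` flag (possible unreported felling), and reports the
    per-catchment year/age coverage.
    """
    report = ValidationReport()
    df = records_to_frame(records)
    if df.empty:
        return report
    rows = []
    for cid, grp in df.groupby("catchment_id", sort=True):
        grp = grp.sort_values("hydro_year")
        years = grp["hydro_year"].to_numpy()
        dup_years = sorted(set(years[pd.Series(years).duplicated().to_numpy()]))
        for y in dup_years:
            report.issues.append(
                ValidationIssue(cid, "duplicate_year", f"duplicate rows for year {y}")
            )
        cover = pd.to_numeric(grp["forest_cover_pct"]).to_numpy(dtype=float)
        felling = grp["felling_after"].astype(bool).to_numpy()
        drops = np.flatnonzero(np.diff(cover) < 0)
        for i in drops:
            # a cover decrease is expected only downstream of a felling flag
            if not felling[: i + 1].any():
                report.issues.append(
                    ValidationIssue(
                        cid,
                        "decreasing_cover",
                        f"forest cover decreases at year {years[i + 1]} "
                        "with no felling_after flag",
                    )
                )
        if felling.any():
            first = int(years[np.flatnonzero(felling)[0]])
            report.issues.append(
                ValidationIssue(
                    cid,
                    "felling_truncation",
                    f"records after year {first} excluded by felling flag",
                )
            )
        ages = pd.to_numeric(grp["age_years"]).to_numpy(dtype=float)
        rows.append(
            {
                "catchment_id": cid,
                "n_years": len(grp),
                "age_min": float(ages.min()),
                "age_max": float(ages.max()),
                "cover_non_decreasing": bool((np.diff(cover) >= 0).all()),
                "n_duplicate_years": len(dup_years),
            }
        )
    report.per_catchment = pd.DataFrame(rows)
    return report


def apply_felling_truncation(records: Sequence[AnnualRecord]) -> list[AnnualRecord]:
    """Drop all records *after* the first ``felling_after`` year per catchment.

    The flagged year itself is retained; exclusions are driven by the flag
    column so that they remain auditable in the source CSV.
    """
    by_catchment: dict[str, list[AnnualRecord]] = {}
    for r in records:
        by_catchment.setdefault(r.catchment_id, []).append(r)
    out: list[AnnualRecord] = []
    for cid, recs in by_catchment.items():
        recs = sorted(recs, key=lambda r: r.hydro_year)
        cut = None
        for r in recs:
            if r.felling_after:
                cut = r.hydro_year
                break
        for r in recs:
            if cut is None or r.hydro_year <= cut:
                out.append(r)
    return out
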