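"""Response computation, area-weighted forest age and climate decomposition.

The flow response of a catchment-year is the forested-minus-control annual
flow, ``q = q_f - q_c`` (mm; negative = reduction).  Annual precipitation,
PET and forest cover are split into a between-catchment mean (MAP, mean
PET, FC_S) and a within-catchment anomaly (P_T, PET_T, FC_T), which
separates spatial climate variation from temporal variation around it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import AnnualRecord, ResponseRecord

__all__ = [
    "AgeClassSummary",
    "compute_response",
    "compute_responses",
    "area_weighted_age",
    "ages_from_planting",
    "planting_history_from_cover",
    "decompose_climate",
    "aridity_index",
    "age_class_summary",
    "responses_to_frame",
]


def compute_response(record: AnnualRecord) -> float | None:
    """Flow response q = q_f - q_c for one record; None if no control flow."""
    if record.q_c_mm is None:
        warnings.warn(
            f"{record.catchment_id}/{record.hydro_year}: no control flow; skipped",
            stacklevel=2,
        )
        return None
    return record.q_f_mm - record.q_c_mm


def aridity_index(map_mm: float, mean_pet_mm: float) -> float:
    """Aridity index MAP / mean PET (dimensionless; higher = wetter)."""
    if mean_pet_mm <= 0:
        raise ValueError("mean PET must be positive")
    return map_mm / mean_pet_mm


def area_weighted_age(
    planting_history: Sequence[tuple[float, float]], eval_year: float
) -> float:
    """Area-weighted mean forest age for staggered plantings.

    ``planting_history`` is ``[(year, area_planted_that_year)]`` — actual
    per-year increments, in any area unit.  When only forest-cover *levels*
    are reported, convert them first with
    :func:`planting_history_from_cover`, which assumes a constant expansion
    rate between reports.
    """
    if len(planting_history) == 0:
        raise ValueError("empty planting history")
    hist = sorted(planting_history)
    years = np.array([h[0] for h in hist], dtype=float)
    areas = np.array([h[1] for h in hist], dtype=float)
    if (areas < 0).any():
        raise ValueError("area fractions must be non-negative")
    if (years > eval_year).any():
        raise ValueError("planting years must not exceed eval_year")
    keep = areas > 0
    years, areas = years[keep], areas[keep]
    if areas.sum() <= 0:
        raise ValueError("total planted area must be positive")
    ages = eval_year - years
    return float((areas * ages).sum() / areas.sum())


def planting_history_from_cover(
    cover_reports: Sequence[tuple[float, float]]
) -> list[tuple[float, float]]:
    """Yearly planted-area increments from sparse cover reports.

    Gaps between reported cover levels are filled by linear interpolation
    of cumulative area (the expansion rate is assumed constant), yielding
    one increment per intervening year.
    """
    if len(cover_reports) == 0:
        raise ValueError("empty cover reports")
    reports = sorted(cover_reports)
    years = [reports[0][0]]
    increments = [reports[0][1]]
    for (y0, c0), (y1, c1) in zip(reports, reports[1:]):
        gap = int(round(y1 - y0))
        if c1 < c0:
            raise ValueError("cover levels must be non-decreasing")
        if gap <= 0:
            raise ValueError("cover report years must be strictly increasing")
        step = (c1 - c0) / gap
        for k in range(1, gap + 1):
            years.append(y0 + k)
            increments.append(step)
    return [(y, a) for y, a in zip(years, increments) if a > 0]


def ages_from_planting(
    planting: pd.DataFrame, records: Sequence[AnnualRecord]
) -> list[AnnualRecord]:
    """Fill in area-weighted ages from a planting-history table.

    ``planting`` has columns ``catchment_id, hydro_year, area_planted_frac``
    (per-year planted-area increments).  Each record's ``age_years`` is
    replaced by the area-weighted mean age of the forest standing in its
    hydrological year; years before the first planting get age 0.
    """
    from dataclasses import replace

    by_catchment = {
        str(cid): list(zip(grp["hydro_year"].astype(int), grp["area_planted_frac"].astype(float)))
        for cid, grp in planting.groupby("catchment_id")
    }
    out = []
    for r in records:
        history = by_catchment.get(r.catchment_id)
        if not history:
            out.append(r)
            continue
        usable = [(y, a) for y, a in history if y <= r.hydro_year and a > 0]
        age = area_weighted_age(usable, r.hydro_year) if usable else 0.0
        out.append(replace(r, age_years=age))
    return out


def decompose_climate(
    records: Sequence[AnnualRecord],
    responses: Sequence[float | None] | None = None,
) -> list[ResponseRecord]:
    """Centre climate and cover within one catchment and attach responses.

    ``p_t = p - mean(p)`` etc.; the catchment means play the role of MAP,
    mean PET and FC_S where the metadata lacks them.  Records without a
    response (no control flow) are dropped.
    """
    if len(records) == 0:
        raise ValueError("need at least one record")
    if responses is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            responses = [compute_response(r) for r in records]
    keep = [i for i, q in enumerate(responses) if q is not None]
    recs = [records[i] for i in keep]
    qs = [responses[i] for i in keep]
    p = np.array([r.p_mm for r in recs], dtype=float)
    pet = np.array([r.pet_mm for r in recs], dtype=float)
    fc = np.array([r.forest_cover_pct for r in recs], dtype=float)
    p_t = p - p.mean()
    pet_t = pet - pet.mean()
    fc_t = fc - fc.mean()
    out = []
    for r, q, pt, pett, fct in zip(recs, qs, p_t, pet_t, fc_t):
        out.append(
            ResponseRecord(
                catchment_id=r.catchment_id,
                hydro_year=r.hydro_year,
                age_years=r.age_years,
                q_f_mm=r.q_f_mm,
                q_c_mm=float(r.q_c_mm),
                p_mm=r.p_mm,
                pet_mm=r.pet_mm,
                forest_cover_pct=r.forest_cover_pct,
                q_mm=float(q),
                p_t_mm=float(pt),
                pet_t_mm=float(pett),
                fc_t_pct=float(fct),
                q_c_source=r.q_c_source,
                zero_forested_flow=(r.q_f_mm == 0.0),
            )
        )
    return out


def compute_responses(
    meta: Sequence, records: Sequence[AnnualRecord], post_only: bool = True
) -> list[ResponseRecord]:
    """Pipeline step: responses + anomalies for every catchment.

    Pre-forestation rows (age 0) are excluded from the analysis series by
    default; anomalies are centred over the analysed rows only.
    """
    by_catchment: dict[str, list[AnnualRecord]] = {}
    for r in records:
        if post_only and r.age_years == 0.0:
            continue
        by_catchment.setdefault(r.catchment_id, []).append(r)
    out: list[ResponseRecord] = []
    for cid in sorted(by_catchment):
        recs = sorted(by_catchment[cid], key=lambda r: r.hydro_year)
        usable = [r for r in recs if r.q_c_mm is not None]
        if not usable:
            continue
        out.extend(decompose_climate(usable))
    return out


RESPONSE_COLUMNS = [
    "catchment_id", "hydro_year", "age_years", "q_f_mm", "q_c_mm", "p_mm",
    "pet_mm", "forest_cover_pct", "q_mm", "p_t_mm", "pet_t_mm", "fc_t_pct",
    "q_c_source", "zero_forested_flow",
]


def responses_to_frame(responses: Sequence[ResponseRecord]) -> pd.DataFrame:
    rows = [{c: getattr(r, c) for c in RESPONSE_COLUMNS} for r in responses]
    return pd.DataFrame(rows, columns=RESPONSE_COLUMNS)


@dataclass(frozen=True)
class AgeClassSummary:
    """Across-catchment summary of the flow response at one focal age."""

    focal_age: float
    mean_q: float | None
    sd_q: float | None
    n: int
    stratum: str = "all"
    pct_of_control: float | None = None


def _select_one_per_catchment(
    grp: pd.DataFrame, focal: float, window: float
) -> pd.DataFrame:
    """At most one record per catchment within +/-window of the focal age
    (nearest; ties broken toward the earlier hydrological year)."""
    cand = grp[(grp["age_years"] - focal).abs() <= window + 1e-12]
    if cand.empty:
        return cand
    picks = []
    for _, sub in cand.groupby("catchment_id", sort=True):
        sub = sub.assign(_dist=(sub["age_years"] - focal).abs())
        sub = sub.sort_values(["_dist", "hydro_year"], kind="stable")
        picks.append(sub.iloc[[0]].drop(columns="_dist"))
    return pd.concat(picks, ignore_index=True)


def age_class_summary(
    responses: Sequence[ResponseRecord] | pd.DataFrame,
    step: float = 5.0,
    window: float = 0.5,
    strata: Mapping[str, str] | None = None,
    max_age: float | None = None,
) -> list[AgeClassSummary]:
    """Mean flow response per 5-year forest-age class.

    Each class uses at most one record per catchment, the one nearest the
    focal age within +/-0.5 years.  SD is the sample (n-1) standard
    deviation, reported only for n >= 2.  ``strata`` optionally maps
    catchment_id to a stratum label (e.g. a biome) for stratified rows; the
    overall row has stratum "all".  ``pct_of_control`` is the headline
    percent change, mean(q) / mean(q_c) within the class.
    """
    df = responses if isinstance(responses, pd.DataFrame) else responses_to_frame(responses)
    if df.empty:
        return []
    top = max_age if max_age is not None else float(df["age_years"].max())
    focals = np.arange(step, top + window + 1e-9, step)
    labels = ["all"] + (sorted(set(strata.values())) if strata else [])
    out: list[AgeClassSummary] = []
    for focal in focals:
        sel = _select_one_per_catchment(df, float(focal), window)
        for label in labels:
            if label == "all":
                sub = sel
            else:
                ids = {cid for cid, s in strata.items() if s == label}
                sub = sel[sel["catchment_id"].isin(ids)]
            n = len(sub)
            if n == 0:
                out.append(AgeClassSummary(float(focal), None, None, 0, label))
                continue
            q = sub["q_mm"].to_numpy(dtype=float)
            qc = sub["q_c_mm"].to_numpy(dtype=float)
            mean_qc = float(qc.mean())
            pct = 100.0 * float(q.mean()) / mean_qc if mean_qc != 0 else None
            out.append(
                AgeClassSummary(
                    focal_age=float(focal),
                    mean_q=float(q.mean()),
                    sd_q=float(q.std(ddof=1)) if n >= 2 else None,
                    n=n,
                    stratum=label,
                    pct_of_control=pct,
                )
            )
    return out
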