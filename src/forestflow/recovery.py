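"""Detection and quantification of partial river-flow recovery.

A catchment shows a recovery signal when its selected response curve is a
polynomial in forest age with a < 0 and b > 0: flow declines after
forestation, reaches a minimum at age -a/(2b), then rebounds toward (not
necessarily reaching) control levels.  Evidence is graded by whether the
95% confidence intervals of the modelled response at the minimum and at
the final observed age are disjoint, rates are standardised as the modelled
change over the 5 years after the minimum, and apparent recoveries are
screened for climate confounding (precipitation or PET trending with age
during the recovery phase).  Years in which the forested catchment carried
no flow at all are excluded beforehand: while the forested flow is pinned
at zero, variation in the response reflects the control series only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catchment_models import CatchmentModelFit, fit_all_catchments

__all__ = [
    "RecoveryResult",
    "drop_zero_forested_flow",
    "minimum_age",
    "recovery_evidence",
    "confounded_recovery",
    "fisher_exact_rxc",
    "response_group_tests",
    "analyze_recovery",
]

CONFOUNDING_R = 0.7


@dataclass
class RecoveryResult:
    """Recovery diagnostics for one catchment."""

    catchment_id: str
    age_min: float | None = None
    q_at_min: float | None = None
    q_at_min_ci: tuple[float, float] | None = None
    q_at_final: float | None = None
    q_at_final_ci: tuple[float, float] | None = None
    strong_evidence: bool | None = None
    recovery_5yr: float | None = None
    confounded_precip: bool | None = None
    confounded_pet: bool | None = None
    zero_flow_points_removed: int = 0
    classification: str | None = None


def drop_zero_forested_flow(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Remove records whose forested annual flow is exactly zero."""
    mask = df["q_f_mm"].to_numpy(dtype=float) == 0.0
    return df.loc[~mask].copy(), int(mask.sum())


def minimum_age(a: float, b: float) -> float | None:
    """Forest age of minimum flow response, -a/(2b); defined for a<0, b>0."""
    if b <= 0 or a >= 0:
        return None
    return -a / (2.0 * b)


def _poly_prediction_ci(
    fit: CatchmentModelFit, age: float, level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Point prediction and CI of the age curve at zero climate anomalies.

    Delta-method variance of x*a + x^2*b from the coefficient covariance;
    t quantile with the fit's residual degrees of freedom.
    """
    a = fit.coefs["age"]
    b = fit.coefs["age_sq"]
    pred = a * age + b * age**2
    x = np.zeros(len(fit.vcov_terms))
    x[fit.vcov_terms.index("age")] = age
    x[fit.vcov_terms.index("age_sq")] = age**2
    var = float(x @ fit.vcov @ x)
    dof = max(fit.n - len(fit.vcov_terms), 1)
    tq = stats.t.ppf(0.5 + level / 2.0, dof)
    half = tq * math.sqrt(max(var, 0.0))
    return pred, (pred - half, pred + half)


def recovery_evidence(
    fit: CatchmentModelFit, ages: Sequence[float]
) -> RecoveryResult:
    """Grade the recovery signal of a polynomial fit.

    Strong evidence requires disjoint 95% CIs for the modelled response at
    the flow minimum and at the final observed age; the comparison is only
    made when the minimum falls inside the observed series.  The 5-year
    recovery rate is the modelled change q(age_min + 5) - q(age_min)
    (positive = recovery toward control), taken from the curve rather than
    raw data.
    """
    result = RecoveryResult(catchment_id=fit.catchment_id, classification=fit.classification)
    if fit.form != "polynomial":
        return result
    a = fit.coefs.get("age")
    b = fit.coefs.get("age_sq")
    if a is None or b is None:
        return result
    age_min = minimum_age(a, b)
    if age_min is None:
        return result
    result.age_min = age_min
    max_age = float(np.max(ages))
    if age_min > max_age:
        return result  # minimum beyond the data: evidence not evaluated
    q_min, ci_min = _poly_prediction_ci(fit, age_min)
    q_fin, ci_fin = _poly_prediction_ci(fit, max_age)
    result.q_at_min, result.q_at_min_ci = q_min, ci_min
    result.q_at_final, result.q_at_final_ci = q_fin, ci_fin
    result.strong_evidence = bool(ci_min[1] < ci_fin[0] or ci_fin[1] < ci_min[0])
    q5 = a * (age_min + 5.0) + b * (age_min + 5.0) ** 2
    result.recovery_5yr = q5 - q_min
    return result


def confounded_recovery(
    recovery_records: pd.DataFrame, climate: str
) -> bool | None:
    """Is a climate variable confounded with age over the recovery phase?

    True iff |Pearson r| between forest age and the climate series
    (``climate`` is "p" or "pet") strictly exceeds .7.  Returns None with
    fewer than 3 recovery-phase records.
    """
    col = {"p": "p_mm", "pet": "pet_mm"}[climate]
    if len(recovery_records) < 3:
        return None
    age = recovery_records["age_years"].to_numpy(dtype=float)
    x = recovery_records[col].to_numpy(dtype=float)
    if np.std(age) == 0 or np.std(x) == 0:
        return False
    r = float(np.corrcoef(age, x)[0, 1])
    return bool(abs(r) > CONFOUNDING_R)


def fisher_exact_rxc(table: np.ndarray) -> float:
    """Fisher's exact test p-value for an r x 2 contingency table.

    Enumerates all tables with the observed margins and sums the
    probabilities of those no more probable than the observed table
    (the standard two-sided definition).  Exact for the small
    catchment-count tables this analysis produces.
    """
    table = np.asarray(table, dtype=int)
    if table.ndim != 2 or table.shape[1] != 2:
        raise ValueError("expected an r x 2 table")
    rows = table.sum(axis=1)
    col1 = int(table[:, 0].sum())
    n = int(table.sum())

    def log_fact(k: int) -> float:
        return math.lgamma(k + 1)

    log_margin = (
        sum(log_fact(r) for r in rows)
        + log_fact(col1)
        + log_fact(n - col1)
        - log_fact(n)
    )

    def log_prob(xs: Sequence[int]) -> float:
        lp = log_margin
        for x, r in zip(xs, rows):
            lp -= log_fact(x) + log_fact(r - x)
        return lp

    obs_lp = log_prob(table[:, 0])
    total = 0.0

    def recurse(i: int, remaining: int, xs: list[int]) -> None:
        nonlocal total
        if i == len(rows) - 1:
            if 0 <= remaining <= rows[i]:
                lp = log_prob(xs + [remaining])
                if lp <= obs_lp + 1e-9:
                    total += math.exp(lp)
            return
        tail_cap = int(rows[i + 1 :].sum())
        lo = max(0, remaining - tail_cap)
        hi = min(rows[i], remaining)
        for x in range(lo, hi + 1):
            recurse(i + 1, remaining - x, xs + [x])

    recurse(0, col1, [])
    return min(total, 1.0)


def response_group_tests(
    fits: Sequence[CatchmentModelFit],
    age_structure: Mapping[str, str] | None = None,
    species_richness: Mapping[str, str] | None = None,
    durations: Mapping[str, float] | None = None,
) -> dict:
    """Group-difference tests of the response classification.

    Fisher's exact test of response class against forest age structure
    (uniform / non-uniform) and species richness (monospecific /
    polyspecific), and a Kruskal-Wallis test of time-series duration across
    response classes.  Class levels with no catchments are dropped (noted).
    """
    classes = {f.catchment_id: (f.classification or "none") for f in fits}
    out: dict = {"notes": []}

    def fisher_for(mapping: Mapping[str, str], name: str, levels: tuple[str, str]) -> None:
        ids = [cid for cid in classes if cid in mapping]
        if not ids:
            out[name] = None
            out["notes"].append(f"{name}: no catchments annotated")
            return
        cls_levels = sorted({classes[cid] for cid in ids})
        tbl = np.array(
            [
                [sum(1 for cid in ids if classes[cid] == cl and mapping[cid] == lv) for lv in levels]
                for cl in cls_levels
            ]
        )
        keep = tbl.sum(axis=1) > 0
        if (~keep).any():
            out["notes"].append(f"{name}: dropped empty class level(s)")
        tbl = tbl[keep]
        out[name] = {
            "table": tbl.tolist(),
            "class_levels": [cl for cl, k in zip(cls_levels, keep) if k],
            "group_levels": list(levels),
            "p": fisher_exact_rxc(tbl) if len(tbl) >= 2 else None,
        }

    if age_structure is not None:
        fisher_for(age_structure, "age_structure_fisher", ("uniform", "non_uniform"))
    if species_richness is not None:
        fisher_for(species_richness, "species_richness_fisher", ("monospecific", "polyspecific"))

    if durations is None:
        durations = {f.catchment_id: float(f.n) for f in fits}
    groups: dict[str, list[float]] = {}
    for cid, cl in classes.items():
        if cid in durations:
            groups.setdefault(cl, []).append(durations[cid])
    samples = [v for v in groups.values() if len(v) > 0]
    if len(samples) >= 2:
        flat = np.concatenate([np.asarray(s, dtype=float) for s in samples])
        if np.ptp(flat) == 0.0:
            out["duration_kruskal"] = {"statistic": 0.0, "p": 1.0}
        else:
            kw = stats.kruskal(*samples)
            out["duration_kruskal"] = {"statistic": float(kw.statistic), "p": float(kw.pvalue)}
    else:
        out["duration_kruskal"] = None
        out["notes"].append("duration_kruskal: fewer than 2 response classes")
    return out


def analyze_recovery(
    responses: pd.DataFrame,
    fits: Sequence[CatchmentModelFit] | None = None,
) -> list[RecoveryResult]:
    """Full recovery screen: zero-flow exclusion, refit, evidence, confounding.

    Zero-forested-flow years are removed per catchment before (re)fitting,
    so recovery signals cannot be artefacts of a dry forested channel.
    """
    results: list[RecoveryResult] = []
    clean_frames: dict[str, pd.DataFrame] = {}
    removed: dict[str, int] = {}
    for cid, grp in responses.groupby("catchment_id", sort=True):
        clean, n_rm = drop_zero_forested_flow(grp.sort_values("hydro_year"))
        clean_frames[str(cid)] = clean
        removed[str(cid)] = n_rm
    if fits is None:
        usable = [f for f in clean_frames.values() if len(f) >= 3]
        fits = fit_all_catchments(pd.concat(usable)) if usable else []
    for fit in fits:
        df = clean_frames.get(fit.catchment_id)
        if df is None or df.empty:
            results.append(RecoveryResult(catchment_id=fit.catchment_id))
            continue
        res = recovery_evidence(fit, df["age_years"].to_numpy(dtype=float))
        res.zero_flow_points_removed = removed.get(fit.catchment_id, 0)
        if res.age_min is not None:
            phase = df[df["age_years"] >= res.age_min]
            res.confounded_precip = confounded_recovery(phase, "p")
            res.confounded_pet = confounded_recovery(phase, "pet")
        results.append(res)
    return results
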