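"""Control-flow calibration for designs lacking a prior calibration.

Where a study never calibrated its control series, the control flow is
reconstructed from a pre-forestation ("historic") period: a least-squares
regression of historic flow on either historic precipitation (single
catchment designs) or the twin catchment's historic flow (paired designs
with pre-forestation data).  A calibration is accepted only if the slope is
significant (p < .05), adjusted R^2 exceeds .5 and the residuals pass a
normality check; predictions are never issued outside the predictor range
seen during calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationFit",
    "CalibrationError",
    "InsufficientDataError",
    "DegenerateDataError",
    "UnacceptableFitError",
    "fit_calibration",
    "predict_control",
    "choose_paired_calibration",
    "calibrate_dataset",
]

# acceptance gates (strict inequalities on R^2 and slope p)
R2_ADJ_MIN = 0.5
SLOPE_P_MAX = 0.05
NORMALITY_P_MIN = 0.05


class CalibrationError(ValueError):
    pass


class InsufficientDataError(CalibrationError):
    pass


class DegenerateDataError(CalibrationError):
    pass


class UnacceptableFitError(CalibrationError):
    """The calibration failed its gates, so the study cannot be corrected."""


@dataclass(frozen=True)
class CalibrationFit:
    """An OLS calibration line Q = alpha + beta * x with its quality gates."""

    alpha: float
    beta: float
    r2_adj: float
    slope_p: float
    normality_p: float
    predictor_min: float
    predictor_max: float
    n: int
    predictor_kind: str  # "precipitation" | "paired_flow"

    @property
    def acceptable(self) -> bool:
        return (
            self.slope_p < SLOPE_P_MAX
            and self.r2_adj > R2_ADJ_MIN
            and self.normality_p >= NORMALITY_P_MIN
        )


def _residual_normality_p(resid: np.ndarray, scale: float) -> float:
    """Shapiro-Wilk p on residuals; an exact fit trivially passes."""
    if np.allclose(resid, 0.0, atol=1e-9 * max(scale, 1.0)):
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.shapiro(resid).pvalue)


def fit_calibration(
    predictor: Sequence[float],
    response: Sequence[float],
    predictor_kind: str = "precipitation",
) -> CalibrationFit:
    """OLS fit of historic flow on its calibration predictor.

    The slope test is the marginal F-test of the simple regression (for a
    single predictor this equals the squared t-test, and coincides with a
    type-2 ANCOVA slope test).
    """
    x = np.asarray(predictor, dtype=float)
    y = np.asarray(response, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise CalibrationError("predictor and response must be equal-length 1-d series")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise CalibrationError("calibration series must be finite")
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"calibration needs n >= 3, got {n}")
    if np.ptp(x) == 0.0 or np.var(x) < 1e-12 * max(1.0, float(np.mean(x)) ** 2):
        raise DegenerateDataError("predictor has (near-)zero variance")

    X = np.column_stack([np.ones(n), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    alpha, beta = float(coef[0]), float(coef[1])
    fitted = X @ coef
    resid = y - fitted
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    if tss <= 0.0:
        r2_adj = 0.0 if rss > 0 else 1.0
    else:
        r2 = 1.0 - rss / tss
        r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    # marginal F test of the slope
    if rss <= 1e-12 * max(tss, 1.0):
        slope_p = 0.0
    else:
        sigma2 = rss / (n - 2)
        se_beta = np.sqrt(sigma2 / float(((x - x.mean()) ** 2).sum()))
        f_stat = (beta / se_beta) ** 2
        slope_p = float(stats.f.sf(f_stat, 1, n - 2))
    normality_p = _residual_normality_p(resid, scale=float(np.std(y) or 1.0))
    return CalibrationFit(
        alpha=alpha,
        beta=beta,
        r2_adj=float(r2_adj),
        slope_p=slope_p,
        normality_p=normality_p,
        predictor_min=float(x.min()),
        predictor_max=float(x.max()),
        n=int(n),
        predictor_kind=predictor_kind,
    )


def predict_control(
    fit: CalibrationFit, predictor_new: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Predict control flow for new predictor values.

    Returns ``(q_hat, in_range)``; years outside the calibration predictor
    range are flagged ``in_range=False`` and must not be corrected
    downstream.  Refuses to predict from an unacceptable fit.
    """
    if not fit.acceptable:
        raise UnacceptableFitError(
            "calibration fit failed its acceptance gates "
            f"(r2_adj={fit.r2_adj:.3f}, slope_p={fit.slope_p:.3g}, "
            f"normality_p={fit.normality_p:.3g}); study excluded"
        )
    x = np.asarray(predictor_new, dtype=float)
    q_hat = fit.alpha + fit.beta * x
    in_range = (x >= fit.predictor_min) & (x <= fit.predictor_max)
    return q_hat, in_range


def choose_paired_calibration(
    q_hf: Sequence[float], q_hc: Sequence[float], p_hf: Sequence[float]
) -> CalibrationFit:
    """Pick the better pre-forestation calibration for a paired design.

    Fits historic forested flow against (a) the twin control catchment's
    historic flow and (b) historic precipitation, and returns the acceptable
    fit with the higher adjusted R^2.  Ties prefer the paired-flow
    calibration, which also absorbs non-precipitation hydrological
    similarity between the twins.
    """
    candidates: list[CalibrationFit] = []
    for pred, kind in ((q_hc, "paired_flow"), (p_hf, "precipitation")):
        try:
            fit = fit_calibration(pred, q_hf, predictor_kind=kind)
        except CalibrationError:
            continue
        if fit.acceptable:
            candidates.append(fit)
    if not candidates:
        raise UnacceptableFitError("neither paired-flow nor precipitation calibration is acceptable")
    # stable sort keeps paired_flow first on exact ties
    return max(candidates, key=lambda f: (f.r2_adj, f.predictor_kind == "paired_flow"))


def calibrate_dataset(meta, records) -> tuple[list, pd.DataFrame]:
    """Fill in calibrated control flow where the design requires it.

    For each catchment with post-forestation rows lacking ``q_c_mm``:

    * ``single`` design: regress pre-forestation flow on pre-forestation
      precipitation, then predict control flow from each forested year's
      precipitation.
    * ``quasi_paired``: choose between the paired-flow and precipitation
      calibrations on the pre-forestation period.
    * ``paired``: the measured twin series is taken as already calibrated.

    Out-of-range years keep ``q_c_mm`` empty (they are dropped when
    responses are computed).  Returns the updated records plus a log frame
    (one row per calibrated catchment: coefficients, gates, decision).
    """
    from .data_model import AnnualRecord  # local import to avoid cycle

    meta_by_id = {m.catchment_id: m for m in meta}
    by_catchment: dict[str, list] = {}
    for r in records:
        by_catchment.setdefault(r.catchment_id, []).append(r)

    out: list[AnnualRecord] = []
    log_rows = []
    for cid, recs in sorted(by_catchment.items()):
        recs = sorted(recs, key=lambda r: r.hydro_year)
        m = meta_by_id[cid]
        pre = [r for r in recs if r.age_years == 0.0]
        post = [r for r in recs if r.age_years > 0.0]
        # quasi-paired twins were never calibrated against each other, so
        # their control series always needs correction; otherwise correct
        # only catchments with missing control flow
        needs_any = m.design == "quasi_paired" or any(r.q_c_mm is None for r in post)
        if not needs_any or m.design == "paired":
            out.extend(recs)
            continue
        if len(pre) < 3:
            raise InsufficientDataError(
                f"{cid}: calibration required but only {len(pre)} pre-forestation years"
            )
        q_hf = [r.q_f_mm for r in pre]
        p_hf = [r.p_mm for r in pre]
        if m.design == "quasi_paired":
            q_hc = [r.q_c_mm for r in pre]
            if any(v is None for v in q_hc):
                fit = fit_calibration(p_hf, q_hf, "precipitation")
            else:
                fit = choose_paired_calibration(q_hf, q_hc, p_hf)
        else:  # single
            fit = fit_calibration(p_hf, q_hf, "precipitation")
        if not fit.acceptable:
            raise UnacceptableFitError(
                f"{cid}: calibration failed gates; study must be excluded"
            )
        if fit.predictor_kind == "precipitation":
            x_new = np.array([r.p_mm for r in post], dtype=float)
        else:
            x_new = np.array(
                [np.nan if r.q_c_mm is None else r.q_c_mm for r in post], dtype=float
            )
        q_hat, in_range = predict_control(fit, x_new)
        out.extend(pre)
        n_corrected = 0
        for r, qh, ok in zip(post, q_hat, in_range):
            correctable = r.q_c_mm is None or m.design == "quasi_paired"
            if correctable and ok and np.isfinite(qh):
                out.append(replace(r, q_c_mm=float(qh), q_c_source="calibrated"))
                n_corrected += 1
            elif correctable:
                # outside the calibration range: no correction is made and
                # the year is unusable downstream
                out.append(replace(r, q_c_mm=None))
            else:
                out.append(r)
        log_rows.append(
            {
                "catchment_id": cid,
                "predictor_kind": fit.predictor_kind,
                "alpha": fit.alpha,
                "beta": fit.beta,
                "r2_adj": fit.r2_adj,
                "slope_p": fit.slope_p,
                "normality_p": fit.normality_p,
                "n_calibration": fit.n,
                "n_corrected": n_corrected,
                "n_out_of_range": int((~in_range).sum()),
            }
        )
    out.sort(key=lambda r: (r.catchment_id, r.hydro_year))
    return out, pd.DataFrame(log_rows)
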