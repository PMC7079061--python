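"""Per-catchment river-flow-response curves and AIC model selection.

For each catchment the flow response Q (mm) is regressed, through the
origin, on a function of forest age plus within-catchment climate/cover
anomalies:

* linear:      Q = a*Age + climate terms
* polynomial:  Q = a*Age + b*Age^2 + climate terms
* asymptotic:  Q = h*(1 - exp(-exp(k)*Age)) + climate terms

Climate terms are P_T, P_T^2, PET_T, PET_T^2 and FC_T (quadratics only
ever enter together with their linear term).  The origin constraint encodes
that in the year before forestation the forested and control flows are
equal up to measurement error.

Model selection minimises AIC with backward elimination of climate terms,
never co-includes variables whose pairwise |Pearson r| exceeds .7 (each is
tried separately and the lower-AIC variant kept), and prefers the
asymptotic form whenever it comes within 2 AIC units of the best age form
(simpler mechanistic assumption: a stable end state rather than a reversal).
A catchment whose best model retains no age term is classed "none".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "CatchmentModelFit",
    "fit_form",
    "select_catchment_model",
    "classify_response",
    "fit_all_catchments",
    "aic_ls",
    "AGE_TERMS",
    "CLIMATE_TERMS",
]

COLLINEARITY_R = 0.7
ASYM_PREFERENCE_DAIC = 2.0

AGE_TERMS = {
    "linear": ("age",),
    "polynomial": ("age", "age_sq"),
    "asymptotic": ("asym",),  # the (h, k) pair
    "none": (),
}
CLIMATE_TERMS = ("p_t", "p_t_sq", "pet_t", "pet_t_sq", "fc_t")
# base variables for the collinearity screen; quadratics follow their linear term
_VARIABLE_OF_TERM = {
    "age": "age", "age_sq": "age", "asym": "age",
    "p_t": "p_t", "p_t_sq": "p_t",
    "pet_t": "pet_t", "pet_t_sq": "pet_t",
    "fc_t": "fc_t",
}


@dataclass
class CatchmentModelFit:
    """A selected-and-fitted response curve for one catchment.

    ``coefs`` maps term names to estimates: ``age`` (a, mm/yr), ``age_sq``
    (b, mm/yr^2), ``asym_scale`` (h, mm), ``asym_lograte`` (k, log 1/yr)
    and the climate terms.  ``vcov``/``vcov_terms`` give the coefficient
    covariance in the stated order.  No intercept is ever present.
    """

    catchment_id: str
    form: str  # linear | polynomial | asymptotic | none
    coefs: dict[str, float]
    aic: float
    r2_adj: float
    n: int
    dropped_terms: list[tuple[str, str]] = field(default_factory=list)
    vcov: np.ndarray | None = None
    vcov_terms: tuple[str, ...] = ()
    rss: float = float("nan")
    classification: str | None = None

    def predict_age_curve(self, ages: np.ndarray) -> np.ndarray:
        """Predicted response at given ages with zero climate anomalies."""
        ages = np.asarray(ages, dtype=float)
        if self.form == "asymptotic":
            h = self.coefs["asym_scale"]
            k = self.coefs["asym_lograte"]
            return h * (1.0 - np.exp(-np.exp(k) * ages))
        q = np.zeros_like(ages)
        if "age" in self.coefs:
            q = q + self.coefs["age"] * ages
        if "age_sq" in self.coefs:
            q = q + self.coefs["age_sq"] * ages**2
        return q


def _snap_exact(rss: float, y: np.ndarray) -> float:
    """Treat rounding-level residuals as an exact fit.

    Without this, two exact fits would be ranked by machine noise in their
    RSS (amplified by n*log(RSS)), instead of by parameter count.
    """
    tss = float(y @ y)
    return 0.0 if rss < 1e-18 * max(tss, 1e-12) else rss


def aic_ls(rss: float, n: int, n_mean_params: int) -> float:
    """Gaussian profile-likelihood AIC, counting the error variance.

    AIC = n*log(RSS/n) + 2*(p+1); the same convention is applied to linear
    and nonlinear fits so the forms are comparable.
    """
    rss = max(float(rss), 1e-300)
    return n * np.log(rss / n) + 2.0 * (n_mean_params + 1)


def _columns(df: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    cols = []
    for t in terms:
        if t == "age":
            cols.append(df["age_years"].to_numpy(dtype=float))
        elif t == "age_sq":
            cols.append(df["age_years"].to_numpy(dtype=float) ** 2)
        elif t == "p_t":
            cols.append(df["p_t_mm"].to_numpy(dtype=float))
        elif t == "p_t_sq":
            cols.append(df["p_t_mm"].to_numpy(dtype=float) ** 2)
        elif t == "pet_t":
            cols.append(df["pet_t_mm"].to_numpy(dtype=float))
        elif t == "pet_t_sq":
            cols.append(df["pet_t_mm"].to_numpy(dtype=float) ** 2)
        elif t == "fc_t":
            cols.append(df["fc_t_pct"].to_numpy(dtype=float))
        else:
            raise ValueError(f"unknown term {t!r}")
    if not cols:
        return np.empty((len(df), 0))
    return np.column_stack(cols)


def _r2_adj_origin(y: np.ndarray, rss: float, p: int) -> float:
    """Adjusted R^2 with uncentred total SS, the standard convention for
    through-origin least squares."""
    n = y.size
    tss = float(y @ y)
    if tss <= 0:
        return 1.0 if rss <= 0 else 0.0
    r2 = 1.0 - rss / tss
    if n - p <= 0:
        return float("nan")
    return 1.0 - (1.0 - r2) * n / (n - p)


def fit_form(
    df: pd.DataFrame,
    form: str,
    included_terms: Sequence[str] = CLIMATE_TERMS,
    catchment_id: str | None = None,
) -> CatchmentModelFit:
    """Least-squares fit of one functional form through the origin.

    ``included_terms`` are the climate terms to include alongside the age
    terms implied by ``form``.  Raises ``ValueError`` when the residual
    degrees of freedom would be non-positive.
    """
    cid = catchment_id if catchment_id is not None else str(df["catchment_id"].iloc[0])
    y = df["q_mm"].to_numpy(dtype=float)
    n = y.size
    climate = [t for t in included_terms if t in CLIMATE_TERMS]
    # marginality: a quadratic climate term only with its linear term
    climate = [
        t for t in climate
        if not (t.endswith("_sq") and t[:-3] not in climate)
    ]
    if form in ("linear", "polynomial", "none"):
        terms = list(AGE_TERMS[form]) + climate
        p = len(terms)
        if n - p < 1:
            raise ValueError(f"{cid}: insufficient degrees of freedom for {form} ({n} obs, {p} terms)")
        X = _columns(df, terms)
        if p == 0:
            coefs_vec = np.empty(0)
            resid = y
        else:
            coefs_vec, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ coefs_vec
        rss = _snap_exact(float(resid @ resid), y)
        sigma2 = rss / max(n - p, 1)
        if p:
            xtx_inv = np.linalg.pinv(X.T @ X)
            vcov = sigma2 * xtx_inv
        else:
            vcov = np.empty((0, 0))
        coefs = {t: float(c) for t, c in zip(terms, coefs_vec)}
        return CatchmentModelFit(
            catchment_id=cid, form=form, coefs=coefs,
            aic=aic_ls(rss, n, p), r2_adj=_r2_adj_origin(y, rss, p), n=n,
            vcov=vcov, vcov_terms=tuple(terms), rss=rss,
        )
    if form != "asymptotic":
        raise ValueError(f"unknown form {form!r}")

    # asymptotic: h*(1-exp(-exp(k)*age)) + C@gamma; h and gamma are linear
    # given k, so profile k by grid search plus bounded refinement
    age = df["age_years"].to_numpy(dtype=float)
    C = _columns(df, climate)
    p = 2 + C.shape[1]
    if n - p < 1:
        raise ValueError(f"{cid}: insufficient degrees of freedom for asymptotic ({n} obs, {p} params)")
    max_age = float(np.max(age)) if np.max(age) > 0 else 1.0

    def rss_of_k(k: float) -> tuple[float, np.ndarray, np.ndarray]:
        g = 1.0 - np.exp(-np.exp(k) * age)
        X = np.column_stack([g, C]) if C.size else g[:, None]
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r), beta, X

    k_grid = np.linspace(np.log(0.02 / max_age) , np.log(20.0 / max_age), 80)
    rss_grid = np.array([rss_of_k(k)[0] for k in k_grid])
    i = int(np.argmin(rss_grid))
    lo = k_grid[max(i - 1, 0)]
    hi = k_grid[min(i + 1, len(k_grid) - 1)]
    res = optimize.minimize_scalar(
        lambda k: rss_of_k(k)[0], bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    k_hat = float(res.x)
    rss, beta, X = rss_of_k(k_hat)
    rss = _snap_exact(rss, y)
    h_hat = float(beta[0])
    gamma = beta[1:]
    # Gauss-Newton covariance at the optimum, params ordered (h, k, climate)
    g = 1.0 - np.exp(-np.exp(k_hat) * age)
    dg_dk = h_hat * np.exp(k_hat) * age * np.exp(-np.exp(k_hat) * age)
    J = np.column_stack([g, dg_dk] + ([C[:, j] for j in range(C.shape[1])] if C.size else []))
    sigma2 = rss / max(n - p, 1)
    vcov = sigma2 * np.linalg.pinv(J.T @ J)
    terms = ("asym_scale", "asym_lograte") + tuple(climate)
    coefs = {"asym_scale": h_hat, "asym_lograte": k_hat}
    coefs.update({t: float(c) for t, c in zip(climate, gamma)})
    return CatchmentModelFit(
        catchment_id=cid, form="asymptotic", coefs=coefs,
        aic=aic_ls(rss, n, p), r2_adj=_r2_adj_origin(y, rss, p), n=n,
        vcov=vcov, vcov_terms=terms, rss=rss,
    )


def _backward_eliminate(
    df: pd.DataFrame, form: str, climate_terms: list[str], cid: str
) -> CatchmentModelFit | None:
    """Drop climate terms one at a time while AIC falls (marginality kept)."""
    n = len(df)
    terms = list(climate_terms)
    # shrink the starting set if df are insufficient, quadratics first
    drop_priority = ["pet_t_sq", "p_t_sq", "fc_t", "pet_t", "p_t"]
    n_age = 2 if form in ("polynomial", "asymptotic") else (1 if form == "linear" else 0)
    while terms and n - (n_age + len(terms)) < 1:
        for t in drop_priority:
            if t in terms:
                terms.remove(t)
                break
    try:
        best = fit_form(df, form, terms, cid)
    except ValueError:
        return None
    dropped: list[tuple[str, str]] = []
    improved = True
    while improved and terms:
        improved = False
        candidates = [
            t for t in terms
            if not (t in ("p_t", "pet_t") and f"{t}_sq" in terms)  # marginality
        ]
        trial_best = None
        for t in candidates:
            trial_terms = [u for u in terms if u != t]
            try:
                fit = fit_form(df, form, trial_terms, cid)
            except ValueError:
                continue
            if fit.aic < best.aic and (trial_best is None or fit.aic < trial_best[0].aic):
                trial_best = (fit, t, trial_terms)
        if trial_best is not None:
            best, t, terms = trial_best
            dropped.append((t, "AIC fell when dropped"))
            improved = True
    best.dropped_terms = dropped
    return best


def _conflict_free_subsets(df: pd.DataFrame, variables: list[str]) -> list[set[str]]:
    """Maximal subsets of base variables with no pairwise |r| > .7."""
    series = {
        "age": df["age_years"], "p_t": df["p_t_mm"],
        "pet_t": df["pet_t_mm"], "fc_t": df["fc_t_pct"],
    }
    conflicts = set()
    for u, v in combinations(variables, 2):
        a = series[u].to_numpy(dtype=float)
        b = series[v].to_numpy(dtype=float)
        if np.std(a) == 0 or np.std(b) == 0:
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        if abs(r) > COLLINEARITY_R:
            conflicts.add((u, v))
    if not conflicts:
        return [set(variables)]
    subsets: list[set[str]] = []
    for size in range(len(variables), 0, -1):
        for combo in combinations(variables, size):
            s = set(combo)
            if any(u in s and v in s for u, v in conflicts):
                continue
            if any(s <= t for t in subsets):
                continue
            subsets.append(s)
    return subsets


def select_catchment_model(
    df: pd.DataFrame, catchment_id: str | None = None
) -> CatchmentModelFit:
    """Select and fit the best response curve for one catchment.

    Implements the full protocol: per-form backward elimination on AIC,
    the |r| > .7 collinearity rule (alternatives fitted separately, lower
    AIC kept), asymptotic preference within 2 AIC units among age forms,
    and a final comparison against the best climate-only model; if the
    climate-only model wins, ``form="none"``.
    """
    cid = catchment_id if catchment_id is not None else str(df["catchment_id"].iloc[0])
    if len(df) < 3:
        raise ValueError(f"{cid}: need at least 3 records, got {len(df)}")
    variables = ["age", "p_t", "pet_t"]
    if df["fc_t_pct"].std() > 0:
        variables.append("fc_t")
    subsets = _conflict_free_subsets(df, variables)

    def climate_terms_for(subset: set[str]) -> list[str]:
        terms = []
        for v in ("p_t", "pet_t"):
            if v in subset:
                terms += [v, f"{v}_sq"]
        if "fc_t" in subset:
            terms.append("fc_t")
        return terms

    best_by_form: dict[str, CatchmentModelFit] = {}
    for subset in subsets:
        climate = climate_terms_for(subset)
        forms = (["linear", "polynomial", "asymptotic"] if "age" in subset else []) + ["none"]
        for form in forms:
            fit = _backward_eliminate(df, form, list(climate), cid)
            if fit is None:
                continue
            if form not in best_by_form or fit.aic < best_by_form[form].aic:
                best_by_form[form] = fit

    age_fits = {f: m for f, m in best_by_form.items() if f != "none"}
    winner: CatchmentModelFit | None = None
    if age_fits:
        best_aic = min(m.aic for m in age_fits.values())
        asym = age_fits.get("asymptotic")
        if asym is not None and asym.aic - best_aic < ASYM_PREFERENCE_DAIC:
            winner = asym
        else:
            winner = min(age_fits.values(), key=lambda m: m.aic)
    none_fit = best_by_form.get("none")
    if winner is None or (none_fit is not None and none_fit.aic <= winner.aic):
        if none_fit is None:
            raise ValueError(f"{cid}: no model form could be fitted")
        none_fit.form = "none"
        none_fit.classification = "none"
        return none_fit
    winner.classification = classify_response(winner, float(df["age_years"].max()))
    return winner


def classify_response(fit: CatchmentModelFit, max_age: float) -> str:
    """Classify the age response: negative, recovering_negative, positive, none.

    A recovering-negative catchment has a polynomial fit with a < 0, b > 0
    and the modelled flow minimum (-a/2b) not after the observed series.
    """
    if fit.form == "none":
        return "none"
    if fit.form == "asymptotic":
        return "negative" if fit.coefs["asym_scale"] < 0 else "positive"
    a = fit.coefs.get("age", 0.0)
    b = fit.coefs.get("age_sq")
    if fit.form == "polynomial" and b is not None:
        if a < 0 and b > 0 and (-a / (2 * b)) <= max_age:
            return "recovering_negative"
        return "negative" if a < 0 else "positive"
    return "negative" if a < 0 else "positive"


def fit_all_catchments(responses: pd.DataFrame) -> list[CatchmentModelFit]:
    """Run model selection for every catchment in a responses frame."""
    fits = []
    for cid, grp in responses.groupby("catchment_id", sort=True):
        grp = grp.sort_values("hydro_year")
        try:
            fits.append(select_catchment_model(grp, str(cid)))
        except ValueError:
            fits.append(
                CatchmentModelFit(
                    catchment_id=str(cid), form="none", coefs={},
                    aic=float("nan"), r2_adj=float("nan"), n=len(grp),
                    dropped_terms=[("all", "insufficient data")],
                    classification="none",
                )
            )
    return fits
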