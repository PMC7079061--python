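"""Hierarchical mixed model for river-flow response across catchments.

Every catchment-year response is modelled as

    Q_i = a_j*Age_i + b_j*Age_i^2 + c_j*P_Ti + d_j*PET_Ti + eps_i

where j indexes catchments.  The four slopes are catchment-level random
coefficients whose means are structured by catchment covariates:

    a_j ~ N(e + f*MAP + g*FC_S + h*MAP*FC_S + k_HF + l_PLU, sigma1^2)
    b_j ~ N(m,                                              sigma2^2)
    c_j ~ N(n + o*Aridity,                                  sigma3^2)
    d_j ~ N(r + s*Aridity,                                  sigma4^2)

with a freely correlated 4x4 random-effect covariance Psi, and the
within-catchment errors eps following an AR(3) process (three
autoregressive parameters, catchment-level grouping).  There is no global
intercept: at age zero with zero anomalies the expected response is zero.

Estimation maximises the (restricted) profile likelihood: for given
variance parameters the fixed effects are profiled out by generalised
least squares and the residual variance in closed form, leaving an
unconstrained optimisation over a log-Cholesky factor of Psi/sigma^2 and a
partial-autocorrelation transform of the AR coefficients.  The marginal
covariance of catchment j is V_j = Z_j Psi Z_j' + sigma^2 R_j(phi), with
R_j the stationary AR(3) correlation matrix evaluated at the integer lags
of the actual (possibly gapped) year sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.linalg import LinAlgError
from scipy import linalg, optimize, stats

__all__ = [
    "FixedEffects",
    "RandomStructure",
    "HierarchicalFit",
    "DesignBundle",
    "GroupDesign",
    "build_design",
    "marginal_loglik",
    "fit_hierarchical",
    "marginal_anova",
    "predict_mean_response",
    "pacf_to_ar",
    "ar_to_pacf",
    "ar_correlations",
]

VARIANTS = ("base", "ft_for_fcs", "plc_for_plu", "pet_for_map", "aridity_for_map")
RANDOM_TERMS = ("age", "age_sq", "p_t", "pet_t")


# ---------------------------------------------------------------------------
# AR(3) machinery


def pacf_to_ar(pacf: Sequence[float]) -> np.ndarray:
    """Levinson-Durbin map from partial autocorrelations to AR coefficients.

    Any pacf vector in (-1, 1)^p yields a stationary AR(p) model, which is
    what makes this the natural unconstrained parameterisation.
    """
    pacf = np.asarray(pacf, dtype=float)
    phi = np.empty(0)
    for k, a in enumerate(pacf):
        if k == 0:
            phi = np.array([a])
        else:
            phi = np.concatenate([phi - a * phi[::-1], [a]])
    return phi


def ar_to_pacf(phi: Sequence[float]) -> np.ndarray:
    """Inverse of :func:`pacf_to_ar` (reverse Levinson-Durbin recursion)."""
    work = np.asarray(phi, dtype=float).copy()
    p = work.size
    pacf = np.empty(p)
    for k in range(p - 1, -1, -1):
        a = work[k]
        pacf[k] = a
        if k > 0:
            if abs(1.0 - a * a) < 1e-14:
                raise ValueError("AR coefficients on the stationarity boundary")
            work = (work[:k] + a * work[:k][::-1]) / (1.0 - a * a)
    return pacf


def ar_is_stationary(phi: Sequence[float]) -> bool:
    phi = np.asarray(phi, dtype=float)
    if phi.size == 0 or not np.any(phi):
        return True
    roots = np.roots(np.concatenate([[1.0], -phi]))
    return bool(np.all(np.abs(roots) < 1.0))  # companion roots inside unit circle


def ar_correlations(phi: Sequence[float], max_lag: int) -> np.ndarray:
    """Stationary autocorrelations rho(0..max_lag) of an AR(p) process.

    rho(1..p) solve the Yule-Walker system; later lags follow the AR
    recursion rho(h) = sum_k phi_k rho(h-k).
    """
    phi = np.asarray(phi, dtype=float)
    p = phi.size
    rho = np.zeros(max_lag + 1)
    rho[0] = 1.0
    if p == 0 or not np.any(phi):
        return rho
    if not ar_is_stationary(phi):
        raise ValueError("AR coefficients are not stationary")
    # linear system for rho(1..p): rho_m = sum_k phi_k rho_{|m-k|}
    A = np.zeros((p, p))
    b = np.zeros(p)
    for m in range(1, p + 1):
        A[m - 1, m - 1] += 1.0
        for k in range(1, p + 1):
            lag = abs(m - k)
            if lag == 0:
                b[m - 1] += phi[k - 1]
            else:
                A[m - 1, lag - 1] -= phi[k - 1]
    head = np.linalg.solve(A, b)
    rho[1 : min(p, max_lag) + 1] = head[: min(p, max_lag)]
    for h in range(p + 1, max_lag + 1):
        rho[h] = sum(phi[k] * rho[h - k - 1] for k in range(p))
    return rho


def ar_correlation_matrix(phi: Sequence[float], years: Sequence[int]) -> np.ndarray:
    """AR correlation matrix over an integer year sequence with gaps.

    Missing years contribute nothing; the correlation between two observed
    years is rho(|year difference|), so gapped series are handled exactly.
    """
    years = np.asarray(years, dtype=int)
    lags = np.abs(years[:, None] - years[None, :])
    rho = ar_correlations(phi, int(lags.max()) if lags.size else 0)
    return rho[lags]


# ---------------------------------------------------------------------------
# Parameter containers


@dataclass
class FixedEffects:
    """Fixed-effect coefficients in the model's standard letters.

    ``e`` age-slope intercept (mm/yr); ``f`` per mm MAP; ``g`` per % FC_S;
    ``h`` per mm*% (MAP x FC_S interaction); ``k_levels`` historical-forest
    contrasts (reference ``absent`` = 0); ``l_levels`` prior-land-use
    contrasts (reference ``agriculture`` = 0); ``m`` age^2 coefficient
    (mm/yr^2); ``n``/``o`` precipitation-sensitivity intercept / per-unit
    aridity slope; ``r``/``s`` the same for PET sensitivity.
    """

    e: float = -5.3
    f: float = -0.00036
    g: float = 0.13
    h: float = -0.00015
    k_levels: dict = field(default_factory=lambda: {"present": 0.0, "unknown": 0.0})
    l_levels: dict = field(default_factory=lambda: {"idle": -2.8, "other": 0.8})
    m: float = 0.18
    n: float = 0.015
    o: float = -0.07
    r: float = -0.05
    s: float = 0.0

    def age_slope(self, map_mm: float, fc_s: float, hf: str, plu: str) -> float:
        return (
            self.e + self.f * map_mm + self.g * fc_s + self.h * map_mm * fc_s
            + self.k_levels.get(hf, 0.0) + self.l_levels.get(plu, 0.0)
        )

    def precip_slope(self, aridity: float) -> float:
        return self.n + self.o * aridity

    def pet_slope(self, aridity: float) -> float:
        return self.r + self.s * aridity


@dataclass
class RandomStructure:
    """Random-effect SDs/correlations, AR coefficients and residual SD."""

    sds: np.ndarray  # (4,) SDs for the age, age^2, P_T, PET_T slopes
    corr: np.ndarray  # (4, 4) correlation matrix
    phi: np.ndarray  # AR coefficients, jointly stationary
    sigma: float  # residual SD, mm

    def __post_init__(self) -> None:
        self.sds = np.asarray(self.sds, dtype=float)
        self.corr = np.asarray(self.corr, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if (self.sds < 0).any() or self.sigma < 0:
            raise ValueError("random-effect SDs and sigma must be >= 0")
        if not np.allclose(self.corr, self.corr.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.corr), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(self.corr).min() < -1e-8:
            raise ValueError("correlation matrix must be positive semidefinite")
        if not ar_is_stationary(self.phi):
            raise ValueError("AR coefficients must be stationary")

    @property
    def psi(self) -> np.ndarray:
        """Random-effect covariance matrix Psi = D * corr * D."""
        d = np.diag(self.sds)
        return d @ self.corr @ d


@dataclass
class HierarchicalFit:
    """A converged hierarchical fit."""

    beta: np.ndarray
    beta_names: list[str]
    fixed_vcov: np.ndarray
    random: RandomStructure
    loglik: float
    aic: float
    method: str
    n_obs: int
    n_catchments: int
    term_groups: dict[str, list[int]]
    term_level: dict[str, str]
    converged: bool = True
    boundary_terms: list[str] = field(default_factory=list)
    variant: str = "base"

    @property
    def coefficients(self) -> dict[str, float]:
        return dict(zip(self.beta_names, self.beta))

    def fixed_effects(self) -> FixedEffects:
        """Map the fitted coefficient vector back to the lettered structure.

        Only meaningful for the base variant.
        """
        c = self.coefficients
        k_levels = {
            name.split("[")[1][:-1]: v
            for name, v in c.items()
            if name.startswith("age:hf[")
        }
        l_levels = {
            name.split("[")[1][:-1]: v
            for name, v in c.items()
            if name.startswith("age:plu[")
        }
        return FixedEffects(
            e=c.get("age", 0.0), f=c.get("age:map", 0.0), g=c.get("age:fc_s", 0.0),
            h=c.get("age:map:fc_s", 0.0), k_levels=k_levels, l_levels=l_levels,
            m=c.get("age_sq", 0.0), n=c.get("p_t", 0.0), o=c.get("p_t:aridity", 0.0),
            r=c.get("pet_t", 0.0), s=c.get("pet_t:aridity", 0.0),
        )


# ---------------------------------------------------------------------------
# Design construction


@dataclass
class GroupDesign:
    catchment_id: str
    X: np.ndarray  # fixed design, n_j x p
    Z: np.ndarray  # random design, n_j x q
    y: np.ndarray
    years: np.ndarray


@dataclass
class DesignBundle:
    groups: list[GroupDesign]
    x_names: list[str]
    term_groups: dict[str, list[int]]
    term_level: dict[str, str]  # "catchment" | "observation"
    variant: str

    @property
    def n_obs(self) -> int:
        return sum(g.y.size for g in self.groups)

    @property
    def p(self) -> int:
        return len(self.x_names)


def _contrast_columns(level: str, levels: Sequence[str], reference: str) -> list[float]:
    return [1.0 if level == lv else 0.0 for lv in levels if lv != reference]


def build_design(
    meta: Sequence, responses: pd.DataFrame, structure_variant: str = "base"
) -> DesignBundle:
    """Assemble per-catchment fixed/random design matrices.

    Fixed columns (base variant): Age, Age*MAP, Age*FC_S, Age*MAP*FC_S,
    Age x historical-forest contrasts (ref ``absent``), Age x prior-land-use
    contrasts (ref ``agriculture``), Age^2, P_T, P_T*Aridity, PET_T,
    PET_T*Aridity; no global intercept.  Random columns per catchment:
    [Age, Age^2, P_T, PET_T].  Alternate variants swap the catchment
    covariate structuring the age slope (forest type for FC_S, prior land
    cover for prior land use, mean PET or aridity for MAP).
    """
    variant = structure_variant.lower()
    if variant not in VARIANTS:
        raise ValueError(f"unknown structure variant {structure_variant!r}")
    meta_by_id = {m.catchment_id: m for m in meta}

    hf_levels = ("absent", "present", "unknown")
    plu_levels = ("agriculture", "idle", "other")
    plc_levels = ("grassland", "shrubland", "other")
    ft_levels = ("coniferous", "broadleaf", "mixed", "unknown")

    groups: list[GroupDesign] = []
    x_names: list[str] | None = None
    term_groups: dict[str, list[int]] | None = None
    term_level: dict[str, str] | None = None

    for cid, grp in responses.groupby("catchment_id", sort=True):
        grp = grp.sort_values("hydro_year")
        m = meta_by_id[str(cid)]
        age = grp["age_years"].to_numpy(dtype=float)
        p_t = grp["p_t_mm"].to_numpy(dtype=float)
        pet_t = grp["pet_t_mm"].to_numpy(dtype=float)
        y = grp["q_mm"].to_numpy(dtype=float)
        years = grp["hydro_year"].to_numpy(dtype=int)
        aridity = m.aridity
        scale_cov = m.map_mm
        if variant == "pet_for_map":
            scale_cov = m.mean_pet_mm
        elif variant == "aridity_for_map":
            scale_cov = aridity

        cols: list[tuple[str, str, np.ndarray]] = []  # (term, name, column)
        cols.append(("age", "age", age))
        cols.append(("age:map", "age:map", age * scale_cov))
        if variant == "ft_for_fcs":
            for lv, v in zip(
                [l for l in ft_levels if l != "coniferous"],
                _contrast_columns(m.forest_type, ft_levels, "coniferous"),
            ):
                cols.append(("age:ft", f"age:ft[{lv}]", age * v))
        else:
            cols.append(("age:fc_s", "age:fc_s", age * m.fc_s))
            cols.append(("age:map:fc_s", "age:map:fc_s", age * scale_cov * m.fc_s))
        for lv, v in zip(
            [l for l in hf_levels if l != "absent"],
            _contrast_columns(m.historical_forest, hf_levels, "absent"),
        ):
            cols.append(("age:hf", f"age:hf[{lv}]", age * v))
        if variant == "plc_for_plu":
            src, levels, ref = m.prior_land_cover, plc_levels, "grassland"
            tname = "age:plc"
        else:
            src, levels, ref = m.prior_land_use, plu_levels, "agriculture"
            tname = "age:plu"
        for lv, v in zip([l for l in levels if l != ref], _contrast_columns(src, levels, ref)):
            cols.append((tname, f"{tname}[{lv}]", age * v))
        cols.append(("age_sq", "age_sq", age**2))
        cols.append(("p_t", "p_t", p_t))
        cols.append(("p_t:aridity", "p_t:aridity", p_t * aridity))
        cols.append(("pet_t", "pet_t", pet_t))
        cols.append(("pet_t:aridity", "pet_t:aridity", pet_t * aridity))

        if x_names is None:
            x_names = [name for _, name, _ in cols]
            term_groups = {}
            for i, (term, _, _) in enumerate(cols):
                term_groups.setdefault(term, []).append(i)
            observation_terms = {"age", "age_sq", "p_t", "pet_t"}
            term_level = {
                t: ("observation" if t in observation_terms else "catchment")
                for t in term_groups
            }
        X = np.column_stack([c for _, _, c in cols])
        Z = np.column_stack([age, age**2, p_t, pet_t])
        groups.append(GroupDesign(str(cid), X, Z, y, years))

    if x_names is None:
        raise ValueError("no catchments in responses")
    # drop identically-zero columns (e.g. contrast levels absent from the
    # data), which would otherwise make the GLS system singular
    norms = np.zeros(len(x_names))
    for g in groups:
        norms += (g.X**2).sum(axis=0)
    keep = np.flatnonzero(norms > 0.0)
    if len(keep) < len(x_names):
        for g in groups:
            g.X = g.X[:, keep]
        kept_names = [x_names[i] for i in keep]
        new_groups: dict[str, list[int]] = {}
        old_terms = {}
        for term, idx in term_groups.items():
            for i in idx:
                old_terms[i] = term
        for new_i, old_i in enumerate(keep):
            new_groups.setdefault(old_terms[old_i], []).append(new_i)
        term_groups = new_groups
        term_level = {t: term_level[t] for t in term_groups}
        x_names = kept_names
    return DesignBundle(groups, x_names, term_groups, term_level, variant)


# ---------------------------------------------------------------------------
# Likelihood


def marginal_loglik(
    design: DesignBundle, beta: Sequence[float], random: RandomStructure
) -> float:
    """Exact Gaussian marginal log-likelihood at given parameters.

    Sums, over catchments, the multivariate-normal log-density of
    ``y_j - X_j beta`` under ``V_j = Z_j Psi Z_j' + sigma^2 R_j(phi)``.
    """
    beta = np.asarray(beta, dtype=float)
    psi = random.psi
    total = 0.0
    for g in design.groups:
        resid = g.y - g.X @ beta
        R = ar_correlation_matrix(random.phi, g.years)
        V = g.Z @ psi @ g.Z.T + random.sigma**2 * R
        try:
            c, low = linalg.cho_factor(V, lower=True)
        except LinAlgError:
            return -np.inf
        alpha = linalg.cho_solve((c, low), resid)
        logdet = 2.0 * np.log(np.diag(c)).sum()
        total += -0.5 * (resid.size * np.log(2.0 * np.pi) + logdet + resid @ alpha)
    return float(total)


def _unpack_lower(vec: np.ndarray, q: int) -> np.ndarray:
    """Log-Cholesky vector -> lower-triangular factor (diag exponentiated)."""
    L = np.zeros((q, q))
    idx = 0
    for i in range(q):
        for j in range(i + 1):
            if i == j:
                L[i, j] = np.exp(np.clip(vec[idx], -40.0, 40.0))
            else:
                L[i, j] = vec[idx]
            idx += 1
    return L


def _pack_lower(L: np.ndarray) -> np.ndarray:
    q = L.shape[0]
    out = []
    for i in range(q):
        for j in range(i + 1):
            out.append(np.log(max(L[i, j], 1e-18)) if i == j else L[i, j])
    return np.array(out)


class _ProfiledObjective:
    """-2 x profiled (restricted) log-likelihood over (log-chol G, pacf z).

    G = Psi / sigma^2; per catchment U_j = R_j + Z_j G Z_j'.  Fixed effects
    and sigma^2 are solved in closed form at each evaluation.  Fixed-design
    columns are standardised to unit norm internally for conditioning; the
    returned beta/vcov are on the natural scale.
    """

    def __init__(self, design: DesignBundle, method: str, ar_order: int = 3):
        self.design = design
        self.method = method.lower()
        if self.method not in ("ml", "reml"):
            raise ValueError("method must be 'ml' or 'reml'")
        self.ar_order = ar_order
        self.q = design.groups[0].Z.shape[1]
        self.nL = self.q * (self.q + 1) // 2
        self.n = design.n_obs
        self.p = design.p
        norms = np.zeros(self.p)
        for g in design.groups:
            norms += (g.X**2).sum(axis=0)
        self.x_scale = np.sqrt(np.maximum(norms, 1e-300))
        # batch catchments sharing a year pattern: same R, stackable algebra
        batches: dict[tuple, list[int]] = {}
        for i, g in enumerate(design.groups):
            batches.setdefault(tuple(int(v) for v in g.years), []).append(i)
        self.batches = []
        for pat, idx in batches.items():
            Z = np.stack([design.groups[i].Z for i in idx])  # (m, T, q)
            Xs = np.stack([design.groups[i].X / self.x_scale for i in idx])
            y = np.stack([design.groups[i].y for i in idx])  # (m, T)
            self.batches.append((np.array(pat), Z, Xs, y))

    def split(self, params: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        L = _unpack_lower(params[: self.nL], self.q)
        z = params[self.nL : self.nL + self.ar_order]
        phi = pacf_to_ar(np.tanh(z)) if self.ar_order else np.empty(0)
        return L, phi

    def components(self, params: np.ndarray):
        """Return (neg2ll, beta_scaled, Sxx_scaled, rss, logdet_sum, sigma2)."""
        L, phi = self.split(params)
        p, n, q = self.p, self.n, self.q
        Sxx = np.zeros((p, p))
        Sxy = np.zeros(p)
        Syy = 0.0
        logdet_sum = 0.0
        for years, Z, Xs, y in self.batches:
            m, T, _ = Z.shape
            try:
                R = ar_correlation_matrix(phi, years)
                cR = linalg.cholesky(R, lower=True)
            except (ValueError, LinAlgError):
                return None
            # whiten by chol(R): U = R + Z G Z' -> I + Zt (LL') Zt'
            stacked = np.concatenate([Z @ L, Xs, y[:, :, None]], axis=2)  # (m,T,q+p+1)
            B = linalg.solve_triangular(
                cR, stacked.transpose(1, 0, 2).reshape(T, -1), lower=True
            ).reshape(T, m, q + p + 1).transpose(1, 0, 2)
            ZL = B[:, :, :q]
            Xt = B[:, :, q : q + p]
            yt = B[:, :, -1]
            M = np.eye(q) + np.einsum("mti,mtj->mij", ZL, ZL)
            try:
                cM = np.linalg.cholesky(M)  # batched
            except LinAlgError:
                return None
            logdet_sum += 2.0 * m * np.log(np.diag(cR)).sum()
            logdet_sum += 2.0 * np.log(
                np.diagonal(cM, axis1=1, axis2=2)
            ).sum()
            # Woodbury: Ut^{-1} = I - ZL M^{-1} ZL'
            ZtB = np.einsum("mti,mtk->mik", ZL, B[:, :, q:])  # (m, q, p+1)
            W = np.linalg.solve(M, ZtB)
            Sxx += np.einsum("mti,mtj->ij", Xt, Xt) - np.einsum(
                "mki,mkj->ij", ZtB[:, :, :p], W[:, :, :p]
            )
            Sxy += np.einsum("mti,mt->i", Xt, yt) - np.einsum(
                "mki,mk->i", ZtB[:, :, :p], W[:, :, -1]
            )
            Syy += float(np.einsum("mt,mt->", yt, yt)) - float(
                np.einsum("mk,mk->", ZtB[:, :, -1], W[:, :, -1])
            )
        try:
            cS = linalg.cholesky(Sxx, lower=True)
        except LinAlgError:
            return None
        beta_s = linalg.cho_solve((cS, True), Sxy)
        rss = max(float(Syy - Sxy @ beta_s), 1e-300)
        if self.method == "ml":
            sigma2 = rss / n
            neg2 = n * np.log(2.0 * np.pi * sigma2) + logdet_sum + n
        else:
            dof = n - p
            sigma2 = rss / dof
            logdet_sxx = 2.0 * np.log(np.diag(cS)).sum()
            neg2 = dof * np.log(2.0 * np.pi * sigma2) + logdet_sum + logdet_sxx + dof
        return neg2, beta_s, Sxx, rss, logdet_sum, sigma2

    def __call__(self, params: np.ndarray) -> float:
        out = self.components(params)
        if out is None:
            return 1e12
        return out[0]


def _starting_values(design: DesignBundle, obj: _ProfiledObjective) -> np.ndarray:
    """Moment-based start: covariance of per-catchment OLS random slopes."""
    q = obj.q
    coefs = []
    rss_tot, n_tot = 0.0, 0
    for g in design.groups:
        if g.y.size >= q + 2 and np.linalg.matrix_rank(g.Z) == q:
            b, res, *_ = np.linalg.lstsq(g.Z, g.y, rcond=None)
            coefs.append(b)
            r = g.y - g.Z @ b
            rss_tot += float(r @ r)
            n_tot += g.y.size - q
    sigma2 = rss_tot / max(n_tot, 1) if n_tot else float(np.var(
        np.concatenate([g.y for g in design.groups])) or 1.0)
    sigma2 = max(sigma2, 1e-6)
    if len(coefs) >= q + 1:
        G0 = np.cov(np.array(coefs).T) / sigma2
        w, V = np.linalg.eigh((G0 + G0.T) / 2.0)
        G0 = (V * np.maximum(w, 1e-4)) @ V.T
    else:
        G0 = np.eye(q) * 0.1
    L0 = np.linalg.cholesky(G0 + 1e-8 * np.eye(q))
    return np.concatenate([_pack_lower(L0), np.zeros(obj.ar_order)])


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, best_params=None, best_value=None):
        super().__init__(message)
        self.best_params = best_params
        self.best_value = best_value


def fit_hierarchical(
    design: DesignBundle,
    method: str = "reml",
    start: np.ndarray | None = None,
    ar_order: int = 3,
    maxiter: int = 3000,
) -> HierarchicalFit:
    """Fit the hierarchical model by profiled (RE)ML.

    Variance, correlation and AR parameters are estimated by numerical
    maximisation (Nelder-Mead exploration then quasi-Newton polish) of the
    profiled likelihood; fixed effects by GLS at the optimum.  REML is the
    default for variance components.
    """
    if len(design.groups) < 2:
        raise ValueError("hierarchical fit requires at least 2 catchments")
    obj = _ProfiledObjective(design, method, ar_order)
    x0 = start if start is not None else _starting_values(design, obj)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # derivative-free exploration, then a quasi-Newton polish; the
        # profiled surface is smooth but ill-conditioned near strongly
        # correlated random effects, where line-search Powell is the most
        # reliable of scipy's unconstrained methods
        res_df = optimize.minimize(
            obj, x0, method="Powell",
            options={"maxfev": 2 * maxiter, "ftol": 1e-9, "xtol": 1e-7},
        )
        res = optimize.minimize(
            obj, res_df.x, method="L-BFGS-B",
            options={"maxiter": 100, "ftol": 1e-13, "gtol": 1e-8},
        )
    best = res if res.fun <= res_df.fun else res_df
    comp = obj.components(best.x)
    if comp is None:
        raise ConvergenceError("optimizer ended in an infeasible region",
                               best_params=best.x, best_value=float(best.fun))
    neg2, beta_s, Sxx_s, rss, logdet_sum, sigma2 = comp

    L, phi = obj.split(best.x)
    sigma = float(np.sqrt(sigma2))
    psi = sigma2 * (L @ L.T)
    sds = np.sqrt(np.maximum(np.diag(psi), 0.0))
    denom = np.outer(sds, sds)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, psi / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(corr, 1.0)
    boundary = [RANDOM_TERMS[i] for i in range(obj.q) if sds[i] < 1e-6 * sigma]

    beta = beta_s / obj.x_scale
    Sxx_inv_s = np.linalg.inv(Sxx_s)
    fixed_vcov = sigma2 * Sxx_inv_s / np.outer(obj.x_scale, obj.x_scale)

    # report the restricted likelihood in the textbook convention on the
    # natural covariate scale: the internal criterion uses unit-norm design
    # columns, which shifts log|X'V^-1 X| by -2*sum(log scale)
    if method.lower() == "reml":
        neg2_natural = neg2 + 2.0 * np.log(obj.x_scale).sum()
    else:
        neg2_natural = neg2
    loglik = -0.5 * float(neg2_natural)
    n_params = design.p + obj.nL + ar_order + 1
    aic = -2.0 * loglik + 2.0 * n_params

    random = RandomStructure(sds=sds, corr=corr, phi=phi, sigma=sigma)
    return HierarchicalFit(
        beta=beta, beta_names=list(design.x_names), fixed_vcov=fixed_vcov,
        random=random, loglik=loglik, aic=aic, method=method.lower(),
        n_obs=design.n_obs, n_catchments=len(design.groups),
        term_groups=design.term_groups, term_level=design.term_level,
        converged=bool(best.success or res_df.success),
        boundary_terms=boundary, variant=design.variant,
    )


def marginal_anova(fit: HierarchicalFit) -> pd.DataFrame:
    """Marginal (type-2/3 style) F-tests of each fixed term.

    Each term is tested with all other terms retained, via the Wald
    statistic on its coefficient block.  Denominator degrees of freedom
    follow a containment heuristic: terms structured by catchment
    covariates test against ``n_catchments - rank of the catchment-level
    design``; within-catchment terms against ``n_obs - total rank``.
    """
    rows = []
    n_cat_cols = sum(
        len(ix) for t, ix in fit.term_groups.items() if fit.term_level[t] == "catchment"
    )
    df_catchment = max(fit.n_catchments - n_cat_cols, 1)
    df_observation = max(fit.n_obs - len(fit.beta), 1)
    for term, idx in fit.term_groups.items():
        b = fit.beta[idx]
        V = fit.fixed_vcov[np.ix_(idx, idx)]
        qd = len(idx)
        try:
            F = float(b @ np.linalg.solve(V, b)) / qd
        except LinAlgError:
            F = float("nan")
        df_den = df_catchment if fit.term_level[term] == "catchment" else df_observation
        p = float(stats.f.sf(F, qd, df_den)) if np.isfinite(F) else float("nan")
        rows.append({"term": term, "F": F, "df_num": qd, "df_den": df_den, "p": p})
    return pd.DataFrame(rows)


def predict_mean_response(
    fixed: FixedEffects | HierarchicalFit,
    *,
    map_mm: float,
    fc_s: float,
    hf: str = "absent",
    plu: str = "agriculture",
    aridity: float = 1.0,
    age: float = 0.0,
    p_t: float = 0.0,
    pet_t: float = 0.0,
) -> float:
    """Population-level predicted flow response (mm) at given covariates.

    Assembles the catchment-mean slopes from the covariate structure and
    evaluates a*age + m*age^2 + c*p_t + d*pet_t.
    """
    fe = fixed.fixed_effects() if isinstance(fixed, HierarchicalFit) else fixed
    a = fe.age_slope(map_mm, fc_s, hf, plu)
    c = fe.precip_slope(aridity)
    d = fe.pet_slope(aridity)
    return a * age + fe.m * age**2 + c * p_t + d * pet_t
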