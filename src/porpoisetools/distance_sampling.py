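"""Conventional line-transect distance sampling (CDS).

Fits detection functions g(y) (key + series adjustments) to perpendicular
sighting distances by maximising the conditional likelihood
prod g(y_i)/mu with mu = int_0^W g, selects among candidates by AIC,
corrects group size for size bias by regressing log group size on detection
probability, forms stratified density/abundance estimates with a
multiplicative availability correction g(0), and attaches uncertainty by a
within-stratum nonparametric bootstrap over transects.

The density estimator is the standard CDS form

    D = n * E[s] / (2 * L * mu * g0),      N = D * A

with n sightings, E[s] expected group size, L effort (km), mu the effective
strip width (km), g0 the availability probability and A the stratum area
(km^2). Internal units are km and km^2 throughout; input distances in
metres are converted on read.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from numpy.polynomial import hermite as nph
from scipy import integrate, optimize

__all__ = [
    "KEY_ORDER",
    "DEFAULT_ADJUSTMENT_ORDERS",
    "DEFAULT_CANDIDATES",
    "DetectionModel",
    "GroupSizeEstimate",
    "StratumEstimate",
    "CombinedEstimate",
    "BootstrapResult",
    "SurveyAnalysis",
    "FitError",
    "distance_from_declination",
    "fit_detection_function",
    "select_model",
    "effective_strip_width",
    "expected_group_size",
    "estimate_density",
    "combine_strata",
    "apply_g0",
    "bootstrap_estimates",
    "analyze_survey",
    "abundance_from_density",
]

KEY_ORDER = ("uniform", "half-normal", "hazard-rate")

#: Series-adjustment orders tried (greedy, forward, AIC-guided) per
#: key/adjustment combination — standard CDS conventions.
DEFAULT_ADJUSTMENT_ORDERS: dict[tuple[str, str], tuple[int, ...]] = {
    ("uniform", "cosine"): (1, 2, 3),
    ("half-normal", "cosine"): (2, 3),
    ("half-normal", "hermite"): (4, 6),
    ("hazard-rate", "simple-polynomial"): (4, 6),
}

#: The four key/adjustment combinations routinely compared for aerial
#: cetacean surveys.
DEFAULT_CANDIDATES: tuple[tuple[str, str], ...] = (
    ("uniform", "cosine"),
    ("half-normal", "cosine"),
    ("half-normal", "hermite"),
    ("hazard-rate", "simple-polynomial"),
)


class FitError(RuntimeError):
    """Raised when a detection-function fit fails to converge."""


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def distance_from_declination(declination_deg, altitude_m):
    """Perpendicular distance (m) from a clinometer declination angle and
    the aircraft altitude: altitude / tan(declination). 90 degrees is
    directly beneath the aircraft (distance 0)."""
    dec = np.asarray(declination_deg, dtype=float)
    alt = np.asarray(altitude_m, dtype=float)
    if np.any(dec <= 0) or np.any(dec > 90):
        raise ValueError("declination must be in (0, 90] degrees")
    if np.any(alt <= 0):
        raise ValueError("altitude must be positive")
    with np.errstate(divide="ignore"):
        d = np.where(dec == 90.0, 0.0, alt / np.tan(np.radians(dec)))
    return d if d.ndim else float(d)


# ---------------------------------------------------------------------------
# detection functions
# ---------------------------------------------------------------------------


def _key_value(y: np.ndarray, key: str, params: Mapping[str, float]) -> np.ndarray:
    if key == "uniform":
        return np.ones_like(y)
    if key == "half-normal":
        s = params["sigma"]
        return np.exp(-(y**2) / (2 * s**2))
    if key == "hazard-rate":
        s, b = params["sigma"], params["shape"]
        with np.errstate(divide="ignore", over="ignore"):
            v = 1.0 - np.exp(-((np.where(y > 0, y, np.inf) / s) ** (-b)))
        return np.where(y == 0, 1.0, v)
    raise ValueError(f"unknown key {key!r}")


def _adjustment_basis(z: np.ndarray, adjustment: str, order: int) -> np.ndarray:
    if adjustment == "cosine":
        return np.cos(order * np.pi * z)
    if adjustment == "hermite":
        coef = np.zeros(order + 1)
        coef[order] = 1.0
        return nph.hermval(z, coef)
    if adjustment == "simple-polynomial":
        return z**order
    raise ValueError(f"unknown adjustment {adjustment!r}")


def _g_unnormalized(
    y: np.ndarray, key: str, params: Mapping[str, float], adjustment: str,
    orders: Sequence[int], coefs: Sequence[float], w: float,
) -> np.ndarray:
    g = _key_value(y, key, params)
    if orders:
        series = np.ones_like(y)
        z = y / w
        for order, a in zip(orders, coefs):
            series = series + a * _adjustment_basis(z, adjustment, order)
        g = g * series
    return g


@dataclass
class DetectionModel:
    """A fitted key + adjustment detection function, normalised to g(0)=1."""

    key: str
    adjustment: str
    orders: tuple[int, ...]
    key_params: dict[str, float]
    adj_coefficients: tuple[float, ...]
    truncation_w: float
    loglik: float
    n_params: int
    aic: float
    esw: float
    n_obs: int
    flags: dict[str, bool] = field(default_factory=dict)

    def detection_probability(self, y) -> np.ndarray:
        """g(y) on [0, W]; 0 beyond the truncation distance."""
        y = np.asarray(y, dtype=float)
        g0 = _g_unnormalized(
            np.zeros(1), self.key, self.key_params, self.adjustment,
            self.orders, self.adj_coefficients, self.truncation_w,
        )[0]
        g = _g_unnormalized(
            y, self.key, self.key_params, self.adjustment,
            self.orders, self.adj_coefficients, self.truncation_w,
        ) / g0
        return np.where((y >= 0) & (y <= self.truncation_w), g, 0.0)

    def pdf(self, y) -> np.ndarray:
        """Probability density of observed distances, g(y)/mu."""
        return self.detection_probability(y) / self.esw


_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(96)


def _quad_esw(key, params, adjustment, orders, coefs, w) -> float:
    """Gauss-Legendre integral of the normalised g over [0, W]."""
    x = 0.5 * w * (_GL_NODES + 1.0)
    g0 = _g_unnormalized(np.zeros(1), key, params, adjustment, orders, coefs, w)[0]
    g = _g_unnormalized(x, key, params, adjustment, orders, coefs, w) / g0
    return float(0.5 * w * np.sum(_GL_WEIGHTS * g))


def effective_strip_width(model: DetectionModel) -> float:
    """mu = int_0^W g(y) dy by adaptive quadrature."""
    mu, _ = integrate.quad(lambda y: float(model.detection_probability(y)), 0.0, model.truncation_w, limit=200)
    return mu


def _pack_params(key: str, orders: Sequence[int]):
    """Number of key parameters and transforms for the optimizer vector."""
    n_key = {"uniform": 0, "half-normal": 1, "hazard-rate": 2}[key]
    return n_key, n_key + len(orders)


def _unpack(theta: np.ndarray, key: str, orders: Sequence[int]):
    # exponent arguments clipped so optimizer excursions cannot overflow
    if key == "uniform":
        params = {}
        coefs = tuple(theta)
    elif key == "half-normal":
        params = {"sigma": math.exp(min(max(theta[0], -60.0), 60.0))}
        coefs = tuple(theta[1:])
    else:
        params = {
            "sigma": math.exp(min(max(theta[0], -60.0), 60.0)),
            "shape": 1.0 + math.exp(min(max(theta[1], -60.0), 30.0)),
        }
        coefs = tuple(theta[2:])
    return params, coefs


def _neg_loglik(theta, y, key, adjustment, orders, w):
    params, coefs = _unpack(np.asarray(theta, dtype=float), key, orders)
    g0 = _g_unnormalized(np.zeros(1), key, params, adjustment, orders, coefs, w)[0]
    if not np.isfinite(g0) or g0 <= 0:
        return 1e10
    g = _g_unnormalized(y, key, params, adjustment, orders, coefs, w) / g0
    if np.any(~np.isfinite(g)) or np.any(g <= 0):
        return 1e10
    mu = _quad_esw(key, params, adjustment, orders, coefs, w)
    if not np.isfinite(mu) or mu <= 0:
        return 1e10
    return -(float(np.sum(np.log(g))) - len(y) * math.log(mu))


_LOG_SIGMA_LB = math.log(1e-4)


def _fit_hn_closed_form(y: np.ndarray, w: float):
    """Fast path: half-normal key, no adjustments. The truncated-likelihood
    MLE of sigma is found by bounded 1-D search on log sigma using the
    closed-form mu = sigma*sqrt(pi/2)*erf(W/(sigma*sqrt(2)))."""
    ssq = float(np.sum(y**2))
    n = len(y)

    def nll(log_s):
        s = math.exp(log_s)
        mu = s * math.sqrt(math.pi / 2) * math.erf(w / (s * math.sqrt(2)))
        if mu <= 0:
            return 1e10
        return ssq / (2 * s**2) + n * math.log(mu)

    res = optimize.minimize_scalar(nll, bounds=(_LOG_SIGMA_LB, math.log(10 * w)), method="bounded",
                                   options={"xatol": 1e-10})
    return float(res.x), -float(res.fun)


def _fit_once(y, key, adjustment, orders, w, x0=None):
    """Fit one configuration; returns (theta, loglik)."""
    n_key, n_total = _pack_params(key, orders)
    if n_total == 0:  # uniform, no adjustments: parameter-free
        return np.zeros(0), -len(y) * math.log(w)
    if key == "half-normal" and not orders:
        log_s, ll = _fit_hn_closed_form(y, w)
        return np.array([log_s]), ll
    if x0 is None:
        x0 = np.zeros(n_total)
        sd = float(np.std(y)) or 0.25 * w
        if key == "half-normal":
            x0[0] = math.log(max(sd, 1e-3))
        elif key == "hazard-rate":
            x0[0] = math.log(max(0.7 * sd, 1e-3))
            x0[1] = math.log(1.5)  # shape = 2.5
    res = optimize.minimize(
        _neg_loglik, x0, args=(y, key, adjustment, tuple(orders), w),
        method="Nelder-Mead",
        options={"maxiter": 2000 * n_total, "xatol": 1e-8, "fatol": 1e-9},
    )
    if not np.isfinite(res.fun) or res.fun >= 1e9:
        raise FitError(f"detection fit did not converge for {key}+{adjustment} orders {orders}")
    return np.asarray(res.x), -float(res.fun)


def _violates_shape(key, params, adjustment, orders, coefs, w) -> bool:
    """g(y) (normalised to g(0)=1) must stay within [0, 1] on [0, W]."""
    yy = np.linspace(0.0, w, 201)
    g = _g_unnormalized(yy, key, params, adjustment, orders, coefs, w)
    g0 = _g_unnormalized(np.zeros(1), key, params, adjustment, orders, coefs, w)[0]
    if not np.isfinite(g0) or g0 <= 0:
        return True
    g = g / g0
    return bool(np.any(g < 0) or np.any(g > 1.0 + 1e-6))


def fit_detection_function(
    distances,
    key: str = "half-normal",
    adjustment: str = "cosine",
    truncation_w: float | None = None,
    max_adjust_terms: int = 3,
    orders: Sequence[int] | None = None,
) -> DetectionModel:
    """Maximum-likelihood fit of a detection function to perpendicular
    distances (km).

    Adjustment terms are added greedily in the order configured for the
    key/adjustment combination while the AIC improves, up to
    ``max_adjust_terms``. If the fitted g(y) goes negative anywhere on
    [0, W], the last term is dropped and the refit flagged
    (``adjustment_reduced``). A scale parameter pinned at its lower
    optimisation bound flags the fit ``degenerate``.
    """
    y = np.sort(np.asarray(distances, dtype=float))
    if np.any(y < 0):
        raise ValueError("distances must be non-negative")
    w = float(truncation_w) if truncation_w is not None else float(np.max(y)) if len(y) else 0.0
    if w <= 0:
        # all-zero distances: adopt a nominal strip so the degenerate fit is expressible
        w = 1e-3
    y = y[y <= w]
    if len(y) < 2:
        raise ValueError("need at least 2 distances within (0, W]")
    if orders is None:
        orders = DEFAULT_ADJUSTMENT_ORDERS.get(
            (key, adjustment),
            {"cosine": (1, 2, 3), "hermite": (4, 6), "simple-polynomial": (4, 6)}[adjustment],
        )
    orders = tuple(orders)[:max_adjust_terms]

    def build(theta, used_orders, ll, flags):
        params, coefs = _unpack(theta, key, used_orders)
        k = len(theta)
        mu = _quad_esw(key, params, adjustment, used_orders, coefs, w)
        model = DetectionModel(
            key=key, adjustment=adjustment, orders=tuple(used_orders),
            key_params=params, adj_coefficients=tuple(coefs), truncation_w=w,
            loglik=ll, n_params=k, aic=2 * k - 2 * ll, esw=mu, n_obs=len(y), flags=dict(flags),
        )
        return model

    # greedy forward selection on the adjustment terms
    flags: dict[str, bool] = {}
    theta, ll = _fit_once(y, key, adjustment, (), w)
    best = (theta, (), ll, 2 * len(theta) - 2 * ll)
    for t in range(1, len(orders) + 1):
        used = orders[:t]
        x0 = np.concatenate([best[0], [0.0]]) if len(best[1]) == t - 1 else None
        try:
            theta_t, ll_t = _fit_once(y, key, adjustment, used, w, x0=x0)
        except FitError:
            break
        aic_t = 2 * len(theta_t) - 2 * ll_t
        if aic_t < best[3]:
            best = (theta_t, used, ll_t, aic_t)
        else:
            break

    theta, used, ll, _ = best
    params, coefs = _unpack(theta, key, used)
    while used and _violates_shape(key, params, adjustment, used, coefs, w):
        used = used[:-1]
        theta, ll = _fit_once(y, key, adjustment, used, w)
        params, coefs = _unpack(theta, key, used)
        flags["adjustment_reduced"] = True

    if "sigma" in params and math.log(params["sigma"]) <= _LOG_SIGMA_LB + 0.05:
        flags["degenerate"] = True

    model = build(theta, used, ll, flags)
    gg = model.detection_probability(np.linspace(0.0, w, 201))
    if np.any(np.diff(gg) > 1e-6):
        model.flags["nonmonotonic"] = True
    return model


def select_model(candidates: Sequence[DetectionModel]) -> DetectionModel:
    """Minimum-AIC candidate; ties broken by fewer parameters, then by the
    conventional key order (uniform, half-normal, hazard-rate)."""
    if not candidates:
        raise ValueError("no candidate models to select from")
    return min(candidates, key=lambda m: (m.aic, m.n_params, KEY_ORDER.index(m.key)))


# ---------------------------------------------------------------------------
# group size
# ---------------------------------------------------------------------------


@dataclass
class GroupSizeEstimate:
    """Observed and size-bias-corrected mean group size.

    ``expected_mean`` is the regression prediction at detection probability
    1 with the log-normal back-transform correction exp(resid_var/2); it is
    used (``used_expected``) when the regression slope is significant at
    the configured alpha.
    """

    observed_mean: float
    expected_mean: float
    slope: float
    slope_p: float
    used_expected: bool
    cv_percent: float
    n: int

    @property
    def estimate(self) -> float:
        return self.expected_mean if self.used_expected else self.observed_mean


def expected_group_size(sightings: pd.DataFrame, model: DetectionModel, alpha: float = 0.15) -> GroupSizeEstimate:
    """Size-bias correction: OLS of ln(group size) on fitted detection
    probability; predict at g = 1 when the slope is significant
    (two-sided p <= alpha), otherwise keep the observed mean."""
    s = sightings["group_size"].to_numpy(dtype=float)
    y = sightings["perp_distance_km"].to_numpy(dtype=float)
    n = len(s)
    if n < 3:
        raise ValueError("need at least 3 sightings for the size-bias regression")
    obs_mean = float(np.mean(s))
    obs_cv = float(np.std(s, ddof=1) / math.sqrt(n) / obs_mean * 100.0) if obs_mean > 0 else 0.0

    ls = np.log(s)
    p = model.detection_probability(y)
    if np.std(ls) == 0 or np.std(p) == 0:
        return GroupSizeEstimate(
            observed_mean=obs_mean, expected_mean=obs_mean, slope=0.0, slope_p=1.0,
            used_expected=False, cv_percent=obs_cv, n=n,
        )
    X = sm.add_constant(p)
    fit = sm.OLS(ls, X).fit()
    a, b = fit.params
    p_slope = float(fit.pvalues[1])
    s2 = float(fit.mse_resid)
    pred = a + b
    expected = max(float(math.exp(pred + s2 / 2.0)), 1.0)
    if p_slope <= alpha:
        x0 = np.array([1.0, 1.0])
        var_pred = float(x0 @ fit.cov_params() @ x0)
        cv = math.sqrt(var_pred) * 100.0  # delta method on the log scale
        return GroupSizeEstimate(
            observed_mean=obs_mean, expected_mean=expected, slope=float(b), slope_p=p_slope,
            used_expected=True, cv_percent=cv, n=n,
        )
    return GroupSizeEstimate(
        observed_mean=obs_mean, expected_mean=expected, slope=float(b), slope_p=p_slope,
        used_expected=False, cv_percent=obs_cv, n=n,
    )


# ---------------------------------------------------------------------------
# stratified estimates
# ---------------------------------------------------------------------------


@dataclass
class StratumEstimate:
    stratum: str
    n_sightings: int
    n_individuals: int
    effort_km: float
    area_km2: float
    esw_km: float
    group_size: float
    density: float
    abundance: float
    g0_used: float
    cv_percent: float = math.nan
    ci_low: float = math.nan  # density scale
    ci_high: float = math.nan


@dataclass
class CombinedEstimate:
    strata: list[StratumEstimate]
    density: float
    abundance: float
    total_area_km2: float
    rule: str = "effort-weighted"
    cv_percent: float = math.nan
    ci_low: float = math.nan
    ci_high: float = math.nan


def _esw_of(model_or_esw) -> float:
    return float(getattr(model_or_esw, "esw", model_or_esw))


def _group_size_of(group_size) -> float:
    return float(getattr(group_size, "estimate", group_size))


def estimate_density(
    sightings: pd.DataFrame,
    effort_km: float,
    area_km2: float,
    model,
    group_size,
    g0: float = 1.0,
    stratum: str = "all",
) -> StratumEstimate:
    """CDS stratum estimate D = n E[s] / (2 L mu g0), N = D A.

    ``model`` may be a fitted :class:`DetectionModel` or a bare ESW in km;
    ``group_size`` a :class:`GroupSizeEstimate` or a bare mean.
    """
    if not (0 < g0 <= 1):
        raise ValueError("g0 must be in (0, 1]")
    if effort_km <= 0:
        raise ValueError("effort must be positive")
    mu = _esw_of(model)
    es = _group_size_of(group_size)
    n = int(len(sightings))
    density = n * es / (2.0 * effort_km * mu * g0)
    return StratumEstimate(
        stratum=str(stratum),
        n_sightings=n,
        n_individuals=int(sightings["group_size"].sum()) if n else 0,
        effort_km=float(effort_km),
        area_km2=float(area_km2),
        esw_km=mu,
        group_size=es,
        density=density,
        abundance=density * area_km2,
        g0_used=float(g0),
    )


def combine_strata(estimates: Sequence[StratumEstimate], total_area_km2: float | None = None) -> CombinedEstimate:
    """Overall density as the effort-weighted mean of stratum densities;
    overall abundance = density x total area."""
    if not estimates:
        raise ValueError("at least one stratum estimate required")
    efforts = np.array([e.effort_km for e in estimates])
    if efforts.sum() <= 0:
        raise ValueError("total effort is zero")
    dens = np.array([e.density for e in estimates])
    d = float(np.sum(dens * efforts) / np.sum(efforts))
    area = float(total_area_km2) if total_area_km2 is not None else float(sum(e.area_km2 for e in estimates))
    return CombinedEstimate(strata=list(estimates), density=d, abundance=d * area, total_area_km2=area)


def apply_g0(estimate, g0: float):
    """Divide density and abundance (and their CI bounds) by g0; the CV is
    unchanged. Works on stratum and combined estimates."""
    if not (0 < g0 <= 1):
        raise ValueError("g0 must be in (0, 1]")
    fields = dict(
        density=estimate.density / g0,
        abundance=estimate.abundance / g0,
        ci_low=estimate.ci_low / g0,
        ci_high=estimate.ci_high / g0,
    )
    if isinstance(estimate, StratumEstimate):
        fields["g0_used"] = estimate.g0_used * g0
    return dataclasses.replace(estimate, **fields)


def abundance_from_density(density: float, area_km2: float) -> int:
    """Reported abundance: density x area, rounded to the nearest animal."""
    return int(round(density * area_km2))


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


@dataclass
class BootstrapResult:
    B: int
    seed: int
    strata: list[str]
    replicates: pd.DataFrame  # columns: one per stratum plus "overall" (density scale)
    cv_percent: dict[str, float]
    ci: dict[str, tuple[float, float]]  # density-scale percentile CIs


def _prepare_stratum_data(sightings: pd.DataFrame, effort: pd.DataFrame):
    """Index the survey by stratum and transect for fast resampling."""
    data: dict[str, dict] = {}
    for stratum, eff in effort.groupby("stratum", sort=True):
        per_t = {}
        for tid, length in zip(eff["transect_id"], eff["length_km"]):
            per_t[tid] = {"length": float(length), "dist": np.zeros(0), "sizes": np.zeros(0, dtype=int)}
        sub = sightings[sightings["stratum"] == stratum]
        for tid, rows in sub.groupby("transect_id"):
            if tid not in per_t:
                raise ValueError(f"sighting on unknown transect {tid!r} in stratum {stratum!r}")
            per_t[tid]["dist"] = rows["perp_distance_km"].to_numpy(dtype=float)
            per_t[tid]["sizes"] = rows["group_size"].to_numpy(dtype=int)
        data[str(stratum)] = {"tids": list(per_t), "transects": per_t}
    return data


def bootstrap_estimates(
    sightings: pd.DataFrame,
    effort: pd.DataFrame,
    areas: Mapping[str, float],
    model_spec: Mapping,
    g0: float = 1.0,
    B: int = 999,
    seed: int = 0,
    alpha: float = 0.15,
    total_area_km2: float | None = None,
    fallback_model: DetectionModel | None = None,
) -> BootstrapResult:
    """Nonparametric bootstrap: resample transects with replacement within
    each stratum, refit the pooled detection function per replicate
    (``model_spec``: kwargs for :func:`fit_detection_function`), recompute
    the per-stratum expected group size and density and the effort-weighted
    overall density. CV = SD/mean x 100; CIs are the 2.5th/97.5th
    percentiles. A replicate with no sightings contributes density 0.
    Deterministic given the seed.
    """
    data = _prepare_stratum_data(sightings, effort)
    strata = list(data)
    for st in strata:
        if len(data[st]["tids"]) < 2:
            raise ValueError(f"stratum {st!r} has fewer than 2 transects")
        if st not in areas:
            raise ValueError(f"no area supplied for stratum {st!r}")
    rng = np.random.default_rng(seed)
    spec = dict(model_spec)
    rows = np.zeros((B, len(strata) + 1))
    for b in range(B):
        pooled_dist = []
        per_stratum: list[tuple[str, np.ndarray, np.ndarray, float]] = []
        for st in strata:
            tids = data[st]["tids"]
            pick = rng.integers(0, len(tids), size=len(tids))
            trs = [data[st]["transects"][tids[i]] for i in pick]
            eff = sum(t["length"] for t in trs)
            dist = np.concatenate([t["dist"] for t in trs]) if trs else np.zeros(0)
            sizes = np.concatenate([t["sizes"] for t in trs]) if trs else np.zeros(0, dtype=int)
            pooled_dist.append(dist)
            per_stratum.append((st, dist, sizes, eff))
        pooled = np.concatenate(pooled_dist)
        model: DetectionModel | None = None
        if len(pooled) >= 2 and np.max(pooled) > 0:
            try:
                model = fit_detection_function(pooled, **spec)
            except (FitError, ValueError):
                model = None
        if model is None:
            model = fallback_model
        ests = []
        for st, dist, sizes, eff in per_stratum:
            if model is None or len(dist) == 0:
                d = 0.0
            else:
                df = pd.DataFrame({"perp_distance_km": dist, "group_size": sizes})
                if len(dist) >= 3:
                    gs = expected_group_size(df, model, alpha=alpha)
                else:
                    gs = float(np.mean(sizes))
                d = estimate_density(df, eff, areas[st], model, gs, g0=g0, stratum=st).density
            ests.append((d, eff))
        dens = np.array([d for d, _ in ests])
        effs = np.array([e for _, e in ests])
        rows[b, : len(strata)] = dens
        rows[b, -1] = float(np.sum(dens * effs) / np.sum(effs))
    rep = pd.DataFrame(rows, columns=strata + ["overall"])
    cv = {}
    ci = {}
    for col in rep.columns:
        vals = rep[col].to_numpy()
        m = vals.mean()
        cv[col] = float(vals.std(ddof=1) / m * 100.0) if m > 0 else 0.0
        lo, hi = np.percentile(vals, [2.5, 97.5])
        ci[col] = (float(lo), float(hi))
    return BootstrapResult(B=B, seed=seed, strata=strata, replicates=rep, cv_percent=cv, ci=ci)


# ---------------------------------------------------------------------------
# full survey analysis
# ---------------------------------------------------------------------------


@dataclass
class SurveyAnalysis:
    model: DetectionModel
    candidates: list[DetectionModel]
    strata: list[StratumEstimate]
    combined: CombinedEstimate
    bootstrap: BootstrapResult | None
    g0: float
    seed: int
    _effort: pd.DataFrame | None = None

    def aic_table(self) -> pd.DataFrame:
        rows = [
            {
                "key": m.key, "adjustment": m.adjustment, "orders": list(m.orders),
                "n_params": m.n_params, "loglik": m.loglik, "aic": m.aic, "esw_km": m.esw,
            }
            for m in self.candidates
        ]
        return pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)

    def report_table(self) -> pd.DataFrame:
        """Stratum/overall summary with report rounding: densities to 3
        decimals, abundances to the nearest individual."""
        rows = []
        for e in self.strata + [None]:
            if e is None:
                c = self.combined
                rows.append(
                    {
                        "stratum": "total",
                        "transects": self._n_transects(None),
                        "distance_km": round(sum(s.effort_km for s in self.strata), 1),
                        "sightings": sum(s.n_sightings for s in self.strata),
                        "individuals": sum(s.n_individuals for s in self.strata),
                        "expected_group_size": round(float(np.mean([s.group_size for s in self.strata])), 2),
                        "density": round(c.density, 3),
                        "density_ci_low": round(c.ci_low, 3),
                        "density_ci_high": round(c.ci_high, 3),
                        # abundance derives from the printed density so the
                        # reported table is internally consistent
                        "abundance": abundance_from_density(round(c.density, 3), c.total_area_km2),
                        "abundance_ci_low": abundance_from_density(round(c.ci_low, 3), c.total_area_km2) if np.isfinite(c.ci_low) else np.nan,
                        "abundance_ci_high": abundance_from_density(round(c.ci_high, 3), c.total_area_km2) if np.isfinite(c.ci_high) else np.nan,
                        "cv_percent": round(c.cv_percent, 2),
                    }
                )
            else:
                rows.append(
                    {
                        "stratum": e.stratum,
                        "transects": self._n_transects(e.stratum),
                        "distance_km": round(e.effort_km, 1),
                        "sightings": e.n_sightings,
                        "individuals": e.n_individuals,
                        "expected_group_size": round(e.group_size, 2),
                        "density": round(e.density, 3),
                        "density_ci_low": round(e.ci_low, 3),
                        "density_ci_high": round(e.ci_high, 3),
                        "abundance": abundance_from_density(round(e.density, 3), e.area_km2),
                        "abundance_ci_low": abundance_from_density(round(e.ci_low, 3), e.area_km2) if np.isfinite(e.ci_low) else np.nan,
                        "abundance_ci_high": abundance_from_density(round(e.ci_high, 3), e.area_km2) if np.isfinite(e.ci_high) else np.nan,
                        "cv_percent": round(e.cv_percent, 2),
                    }
                )
        return pd.DataFrame(rows)

    def _n_transects(self, stratum: str | None) -> int:
        if self._effort is None:
            return 0
        if stratum is None:
            return int(len(self._effort))
        return int((self._effort["stratum"].astype(str) == stratum).sum())

    def to_manifest(self) -> dict:
        best = self.model
        return {
            "selected_model": {
                "key": best.key, "adjustment": best.adjustment, "orders": list(best.orders),
                "aic": best.aic, "esw_km": best.esw, "n_params": best.n_params,
                "flags": best.flags,
            },
            "aic_table": self.aic_table().to_dict(orient="records"),
            "g0": self.g0,
            "seed": self.seed,
            "bootstrap_B": self.bootstrap.B if self.bootstrap else 0,
        }


def analyze_survey(
    sightings: pd.DataFrame,
    effort: pd.DataFrame,
    areas: Mapping[str, float],
    candidates: Sequence[tuple[str, str]] = DEFAULT_CANDIDATES,
    g0: float = 0.364,
    truncation_w: float | None = None,
    alpha: float = 0.15,
    B: int = 999,
    seed: int = 0,
    total_area_km2: float | None = None,
    max_adjust_terms: int = 3,
) -> SurveyAnalysis:
    """End-to-end CDS analysis: pooled detection function fitted per
    candidate and AIC-selected, per-stratum size-bias-corrected estimates
    with the g(0) correction, and (optionally, B > 0) bootstrap CVs/CIs."""
    sightings = sightings.copy()
    sightings["stratum"] = sightings["stratum"].astype(str)
    effort = effort.copy()
    effort["stratum"] = effort["stratum"].astype(str)
    if "perp_distance_km" not in sightings and "perp_distance_m" in sightings:
        sightings["perp_distance_km"] = sightings["perp_distance_m"] / 1000.0
    dist = sightings["perp_distance_km"].to_numpy(dtype=float)

    fitted: list[DetectionModel] = []
    for key, adjustment in candidates:
        try:
            fitted.append(
                fit_detection_function(
                    dist, key=key, adjustment=adjustment,
                    truncation_w=truncation_w, max_adjust_terms=max_adjust_terms,
                )
            )
        except (FitError, ValueError) as err:  # pragma: no cover - diagnostic path
            warnings.warn(f"candidate {key}+{adjustment} failed: {err}")
    best = select_model(fitted)
    w = best.truncation_w
    sightings = sightings[sightings["perp_distance_km"] <= w]

    strata_names = sorted(effort["stratum"].unique())
    estimates = []
    for st in strata_names:
        sub = sightings[sightings["stratum"] == st]
        eff = float(effort.loc[effort["stratum"] == st, "length_km"].sum())
        if len(sub) >= 3:
            gs = expected_group_size(sub, best, alpha=alpha)
        else:
            gs = float(sub["group_size"].mean()) if len(sub) else 1.0
        estimates.append(estimate_density(sub, eff, areas[st], best, gs, g0=g0, stratum=st))
    combined = combine_strata(estimates, total_area_km2=total_area_km2)

    boot = None
    if B > 0:
        # refit the selected model form (key + chosen orders), as DISTANCE does
        spec = {
            "key": best.key, "adjustment": best.adjustment,
            "truncation_w": w, "orders": best.orders,
            "max_adjust_terms": len(best.orders),
        }
        boot = bootstrap_estimates(
            sightings, effort, areas, spec, g0=g0, B=B, seed=seed, alpha=alpha,
            total_area_km2=total_area_km2, fallback_model=best,
        )
        for e in estimates:
            e.cv_percent = boot.cv_percent[e.stratum]
            e.ci_low, e.ci_high = boot.ci[e.stratum]
        combined.cv_percent = boot.cv_percent["overall"]
        combined.ci_low, combined.ci_high = boot.ci["overall"]

    analysis = SurveyAnalysis(
        model=best, candidates=fitted, strata=estimates, combined=combined,
        bootstrap=boot, g0=g0, seed=seed,
    )
    analysis._effort = effort
    return analysis
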