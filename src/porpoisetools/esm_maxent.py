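"""Ensembles of small models (ESM) with a MaxEnt base learner.

For each survey year, every unordered pair of eco-geographical variables
(EGVs) is fitted as a small presence/background MaxEnt model (penalized
Gibbs likelihood, linear + quadratic features), evaluated on random 80/20
splits by Somers' D, and the runs with D >= 0.5 are averaged with
D-proportional weights into a habitat-suitability index (HSI) map in
[0, 1]. Model calibration is validated with the Continuous Boyce Index
(CBI) and summarised by per-EGV contribution percentages and multi-year
mean/CV maps.

The MaxEnt model maximises, over feature weights beta,

    mean_p eta(x)  -  log mean_b exp(eta(x))  -  sum_j lambda_j |beta_j|

where eta = X beta on standardized features, presences (p) and background
(b) enter with equal total weight (prevalence 0.5), and
lambda_j = reg_multiplier / sqrt(n_presence). Predictions use the
complementary log-log transform 1 - exp(-exp(eta - logZ + H)) with H the
entropy of the fitted distribution over the training background.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import rankdata, spearmanr

from .env_preprocessing import EGVStack

__all__ = [
    "BackgroundSet",
    "MaxentModel",
    "BivariateRun",
    "EnsembleModel",
    "BoyceResult",
    "ESMResult",
    "ConvergenceError",
    "enumerate_pairs",
    "sample_background",
    "fit_maxent",
    "somers_d",
    "cross_validate",
    "build_ensemble",
    "boyce_index",
    "variable_contribution",
    "annual_mean_and_cv",
    "predict_map",
    "run_esm",
]


class ConvergenceError(RuntimeError):
    pass


def enumerate_pairs(names: Sequence[str]) -> list[tuple[str, str]]:
    """All C(k, 2) unordered EGV pairs in stable input order."""
    names = list(names)
    if len(names) < 2:
        raise ValueError("need at least two EGVs to form bivariate models")
    return list(itertools.combinations(names, 2))


@dataclass
class BackgroundSet:
    """One replicate of uniform random background cells from the sea mask."""

    replicate_id: int
    rows: np.ndarray
    cols: np.ndarray
    values: pd.DataFrame  # one column per EGV layer
    seed: int


def sample_background(
    stack: EGVStack,
    n: int = 10000,
    replicates: int = 10,
    seed: int = 0,
    with_replacement: bool = False,
) -> list[BackgroundSet]:
    """Uniform random sea cells, independent across replicates,
    deterministic given the seed."""
    sea = stack.sea_mask
    idx = np.flatnonzero(sea.ravel())
    if len(idx) == 0:
        raise ValueError("stack has no sea cells")
    if n > len(idx) and not with_replacement:
        raise ValueError(f"cannot draw {n} background cells from {len(idx)} sea cells without replacement")
    rng = np.random.default_rng(seed)
    ny, nx = stack.grid.shape
    out = []
    flat = {name: np.asarray(layer).ravel() for name, layer in stack.layers.items()}
    for rep in range(1, replicates + 1):
        pick = rng.choice(idx, size=n, replace=with_replacement)
        rows, cols = np.divmod(pick, nx)
        values = pd.DataFrame({name: flat[name][pick] for name in stack.layers})
        out.append(BackgroundSet(replicate_id=rep, rows=rows, cols=cols, values=values, seed=seed))
    return out


# ---------------------------------------------------------------------------
# MaxEnt core
# ---------------------------------------------------------------------------


def _design(values: np.ndarray, features: str) -> np.ndarray:
    cols = [values[:, 0], values[:, 1]]
    if "q" in features:
        cols += [values[:, 0] ** 2, values[:, 1] ** 2]
    return np.column_stack(cols)


@dataclass
class MaxentModel:
    """A fitted bivariate MaxEnt model."""

    pair: tuple[str, str]
    features: str
    beta: np.ndarray
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    train_min: np.ndarray  # per raw EGV, for range clamping at prediction
    train_max: np.ndarray
    log_z: float  # logsumexp of eta over training background
    entropy: float  # of the fitted distribution over training background
    n_presence: int
    n_background: int
    converged: bool = True

    def linear_predictor(self, values: np.ndarray, clamp: bool = True) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        if v.ndim == 1:
            v = v[None, :]
        if clamp:
            v = np.clip(v, self.train_min, self.train_max)
        X = (_design(v, self.features) - self.feature_mean) / self.feature_sd
        return X @ self.beta

    def predict(self, values: np.ndarray, output: str = "cloglog", clamp: bool = True) -> np.ndarray:
        """Suitability in [0, 1] for raw EGV value rows (one column per
        pair member). Features outside the training range are clamped to
        the range boundary first."""
        eta = self.linear_predictor(values, clamp=clamp)
        z = eta - self.log_z + self.entropy
        if output == "cloglog":
            return 1.0 - np.exp(-np.exp(np.minimum(z, 30.0)))
        if output == "logistic":
            return 1.0 / (1.0 + np.exp(-z))
        if output == "raw":
            return np.exp(eta - self.log_z)
        raise ValueError(f"unknown output {output!r}")


def _gibbs_objective(beta, Xp, Xb, lam):
    eta_b = Xb @ beta
    f = -float(Xp.mean(axis=0) @ beta) + float(logsumexp(eta_b) - math.log(len(Xb)))
    return f + float(np.sum(lam * np.abs(beta)))


def _smooth_part(beta, Xp, Xb):
    eta_b = Xb @ beta
    lse = logsumexp(eta_b)
    p = np.exp(eta_b - lse)
    f = -float(Xp.mean(axis=0) @ beta) + float(lse - math.log(len(Xb)))
    grad = -Xp.mean(axis=0) + p @ Xb
    return f, grad


def fit_maxent(
    presence_values: np.ndarray,
    background_values: np.ndarray,
    pair: tuple[str, str] = ("v1", "v2"),
    features: str = "lq",
    reg_multiplier: float = 1.0,
    max_iter: int = 2000,
    tol: float = 1e-7,
) -> MaxentModel:
    """Fit the penalized presence/background Gibbs likelihood.

    The L1 penalty is handled exactly by the positive/negative weight
    split, leaving a smooth convex bound-constrained problem solved with
    L-BFGS-B. Presences are added to the normalizing background (the
    standard MaxEnt convention). ``reg_multiplier = 0`` gives the
    unpenalized MLE. Constant features are dropped (zero weight) with a
    warning.
    """
    P = np.asarray(presence_values, dtype=float)
    Bg = np.asarray(background_values, dtype=float)
    P = P[np.all(np.isfinite(P), axis=1)]
    Bg = Bg[np.all(np.isfinite(Bg), axis=1)]
    if len(P) < 5:
        raise ValueError("need at least 5 presence records")
    if len(Bg) < 2 * len(P):
        raise ValueError("background sample must be at least twice the presence sample")

    Xp_raw = _design(P, features)
    Xb_raw = _design(Bg, features)
    allX = np.vstack([Xp_raw, Xb_raw])
    mean = allX.mean(axis=0)
    sd = allX.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn("constant feature dropped from MaxEnt design")
        sd = np.where(keep, sd, 1.0)
    Xp = (Xp_raw - mean) / sd
    Xb = (Xb_raw - mean) / sd
    Xp[:, ~keep] = 0.0
    Xb[:, ~keep] = 0.0

    # presences are included in the normalizing background (the standard
    # MaxEnt convention), which also keeps the Gibbs objective bounded when
    # presences fall outside the background's feature hull
    Xn = np.vstack([Xb, Xp])

    k = Xp.shape[1]
    lam = np.full(k, reg_multiplier / math.sqrt(len(P)))
    lam[~keep] = 0.0

    # L1 handled exactly by the positive/negative split: beta = u - v with
    # u, v >= 0 turns the penalized problem into a smooth bound-constrained
    # one, solved by L-BFGS-B (convex, tiny dimension).
    def split_obj(uv):
        u, v = uv[:k], uv[k:]
        b = u - v
        f, grad = _smooth_part(b, Xp, Xn)
        f += float(lam @ (u + v))
        return f, np.concatenate([grad + lam, -grad + lam])

    from scipy import optimize as _opt

    res = _opt.minimize(
        split_obj, np.zeros(2 * k), jac=True, method="L-BFGS-B",
        bounds=[(0.0, None)] * (2 * k),
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-8},
    )
    if not res.success and res.status != 1:  # status 1 = maxiter
        raise ConvergenceError(f"MaxEnt optimisation failed: {res.message}")
    if res.status == 1:
        raise ConvergenceError(f"MaxEnt did not converge within {max_iter} iterations")
    beta = res.x[:k] - res.x[k:]
    beta[~keep] = 0.0
    converged = True

    eta_b = Xn @ beta
    log_z = float(logsumexp(eta_b))
    p = np.exp(eta_b - log_z)
    entropy = float(-np.sum(p * np.log(np.maximum(p, 1e-300))))
    return MaxentModel(
        pair=tuple(pair), features=features, beta=beta,
        feature_mean=mean, feature_sd=sd,
        train_min=np.minimum(P.min(axis=0), Bg.min(axis=0)),
        train_max=np.maximum(P.max(axis=0), Bg.max(axis=0)),
        log_z=log_z, entropy=entropy,
        n_presence=len(P), n_background=len(Bg), converged=converged,
    )


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def somers_d(presence_scores, background_scores) -> float:
    """D = 2*AUC - 1 with AUC by rank comparison, ties counted 1/2."""
    a = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([a, b]))
    r1 = ranks[: len(a)].sum()
    u = r1 - len(a) * (len(a) + 1) / 2.0
    auc = u / (len(a) * len(b))
    return float(2.0 * auc - 1.0)


@dataclass
class BivariateRun:
    """One cross-validation run of one bivariate model on one background
    replicate, with its held-out Somers' D."""

    pair: tuple[str, str]
    background_id: int
    run_id: int
    model: MaxentModel
    somers_d: float
    train_somers_d: float = float("nan")


def cross_validate(
    presence_values: np.ndarray,
    background_values: np.ndarray,
    pair: tuple[str, str],
    background_id: int = 1,
    splits: int = 10,
    train_frac: float = 0.8,
    seed: int = 0,
    reg_multiplier: float = 1.0,
) -> list[BivariateRun]:
    """Random 80/20 presence splits (background split alike); one fitted
    model and one held-out Somers' D per run. Runs whose test split has
    fewer than 2 presences are skipped with a warning."""
    P = np.asarray(presence_values, dtype=float)
    Bg = np.asarray(background_values, dtype=float)
    if len(P) < 5:
        raise ValueError("need at least 5 presences to cross-validate")
    rng = np.random.default_rng(seed)
    n_p, n_b = len(P), len(Bg)
    n_p_train = int(round(train_frac * n_p))
    n_b_train = int(round(train_frac * n_b))
    runs: list[BivariateRun] = []
    for run_id in range(1, splits + 1):
        perm_p = rng.permutation(n_p)
        perm_b = rng.permutation(n_b)
        tr_p, te_p = perm_p[:n_p_train], perm_p[n_p_train:]
        tr_b, te_b = perm_b[:n_b_train], perm_b[n_b_train:]
        if len(te_p) < 2:
            warnings.warn(f"run {run_id}: test split has fewer than 2 presences; skipped")
            continue
        model = fit_maxent(P[tr_p], Bg[tr_b], pair=pair, reg_multiplier=reg_multiplier)
        d = somers_d(model.predict(P[te_p]), model.predict(Bg[te_b]))
        d_train = somers_d(model.predict(P[tr_p]), model.predict(Bg[tr_b]))
        runs.append(BivariateRun(pair=tuple(pair), background_id=background_id, run_id=run_id,
                                 model=model, somers_d=d, train_somers_d=d_train))
    return runs


# ---------------------------------------------------------------------------
# ensemble
# ---------------------------------------------------------------------------


@dataclass
class EnsembleModel:
    """Somers'-D-weighted average of the retained bivariate runs."""

    runs: list[BivariateRun]
    weights: np.ndarray
    d_threshold: float = 0.5

    def predict_values(self, values: Mapping[str, np.ndarray]) -> np.ndarray:
        """Weighted-average prediction for named EGV value arrays."""
        out = None
        for run, wgt in zip(self.runs, self.weights):
            v = np.column_stack([values[run.pair[0]], values[run.pair[1]]])
            p = run.model.predict(v)
            out = wgt * p if out is None else out + wgt * p
        return out


def build_ensemble(runs: Sequence[BivariateRun], d_threshold: float = 0.5) -> EnsembleModel:
    """Discard runs with D < threshold; weight the rest by D / sum(D)."""
    if not runs:
        raise ValueError("at least one run required")
    kept = [r for r in runs if r.somers_d >= d_threshold]
    if not kept:
        raise ValueError("no skillful models: every run scored below the Somers' D threshold")
    d = np.array([r.somers_d for r in kept], dtype=float)
    return EnsembleModel(runs=list(kept), weights=d / d.sum(), d_threshold=d_threshold)


def predict_map(ensemble: EnsembleModel, stack: EGVStack) -> np.ndarray:
    """Per-cell ensemble HSI on the stack grid; cells missing any layer
    value are NaN. Feature values beyond each run's training range are
    clamped to the boundary."""
    needed = sorted({name for r in ensemble.runs for name in r.pair})
    missing = [n for n in needed if n not in stack.layers]
    if missing:
        raise ValueError(f"stack is missing layers required by the ensemble: {missing}")
    sea = stack.sea_mask
    flat_idx = np.flatnonzero(sea.ravel())
    values = {n: np.asarray(stack.layers[n]).ravel()[flat_idx] for n in needed}
    pred = ensemble.predict_values(values)
    out = np.full(stack.grid.shape, np.nan).ravel()
    out[flat_idx] = pred
    return out.reshape(stack.grid.shape)


# ---------------------------------------------------------------------------
# Boyce index, contributions, multi-year summaries
# ---------------------------------------------------------------------------


@dataclass
class BoyceResult:
    cbi: float
    degenerate: bool
    table: pd.DataFrame | None = None

    def __float__(self) -> float:
        return self.cbi


def boyce_index(
    hsi_map: np.ndarray,
    presence_hsi: np.ndarray,
    n_classes: int = 101,
    window_frac: float = 0.1,
) -> BoyceResult:
    """Continuous Boyce Index: Spearman rank correlation between the
    predicted-to-expected presence ratio P/E in a moving suitability window
    and the window midpoint. Windows span the mapped HSI range with
    ``n_classes`` midpoints and width ``window_frac`` x range."""
    cells = np.asarray(hsi_map, dtype=float).ravel()
    cells = cells[np.isfinite(cells)]
    pres = np.asarray(presence_hsi, dtype=float)
    pres = pres[np.isfinite(pres)]
    if len(pres) < 5:
        raise ValueError("need at least 5 presences on mapped cells")
    lo, hi = float(cells.min()), float(cells.max())
    if hi - lo <= 0:
        return BoyceResult(cbi=0.0, degenerate=True)
    half = window_frac * (hi - lo) / 2.0
    mids = np.linspace(lo, hi, n_classes)
    P = np.empty(n_classes)
    E = np.empty(n_classes)
    for i, m in enumerate(mids):
        a, b = m - half, m + half
        P[i] = np.mean((pres >= a) & (pres <= b))
        E[i] = np.mean((cells >= a) & (cells <= b))
    ok = E > 0
    ratio = P[ok] / E[ok]
    mids_ok = mids[ok]
    table = pd.DataFrame({"midpoint": mids_ok, "predicted": P[ok], "expected": E[ok], "pe_ratio": ratio})
    # drop duplicated P/E values (keeping first occurrences) so runs of tied
    # windows do not dilute the rank correlation — the method's convention
    _, first = np.unique(ratio, return_index=True)
    keep = np.zeros(len(ratio), dtype=bool)
    keep[first] = True
    ratio_u = ratio[keep]
    mids_u = mids_ok[keep]
    if len(ratio_u) < 3 or np.all(ratio_u == ratio_u[0]):
        return BoyceResult(cbi=0.0, degenerate=True, table=table)
    rho, _ = spearmanr(mids_u, ratio_u)
    return BoyceResult(cbi=float(rho), degenerate=False, table=table)


def variable_contribution(
    runs: Sequence[BivariateRun],
    egv_names: Sequence[str] | None = None,
    d_threshold: float = 0.0,
) -> pd.Series:
    """Per-EGV contribution percentages.

    Each variable scores the mean ensemble weight (Somers' D) over *all*
    runs whose pair contains it, where a run below the retention threshold
    contributes weight 0; scores are normalised to sum to 100. Passing
    already-filtered runs with the default ``d_threshold = 0`` averages
    their D directly. Variables appearing in no positive-weight run
    contribute 0."""
    if not runs:
        raise ValueError("at least one run required")
    if egv_names is None:
        egv_names = sorted({n for r in runs for n in r.pair})
    scores = {}
    for name in egv_names:
        ds = [
            r.somers_d if r.somers_d >= d_threshold and r.somers_d > 0 else 0.0
            for r in runs
            if name in r.pair
        ]
        scores[name] = float(np.mean(ds)) if ds else 0.0
    total = sum(scores.values())
    if total <= 0:
        return pd.Series({n: 0.0 for n in egv_names})
    return pd.Series({n: 100.0 * v / total for n, v in scores.items()})


def annual_mean_and_cv(maps: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Cell-wise mean and coefficient of variation (sample SD / mean) of
    annual HSI maps on one grid. Cells with mean 0 get CV NaN."""
    if len(maps) < 2:
        raise ValueError("need at least two annual maps")
    shape = np.asarray(maps[0]).shape
    for m in maps[1:]:
        if np.asarray(m).shape != shape:
            raise ValueError("annual maps are on mismatched grids")
    stack = np.stack([np.asarray(m, dtype=float) for m in maps])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    return mean, cv


# ---------------------------------------------------------------------------
# full ESM stage
# ---------------------------------------------------------------------------


@dataclass
class ESMResult:
    years: list
    ensembles: dict
    hsi_maps: dict
    cbi: dict
    contributions: pd.DataFrame  # one row per year, one column per EGV
    runs_ledger: pd.DataFrame
    mean_map: np.ndarray | None
    cv_map: np.ndarray | None
    seed: int


def run_esm(
    presences: pd.DataFrame,
    stacks: Mapping,
    n_background: int = 10000,
    replicates: int = 10,
    splits: int = 10,
    d_threshold: float = 0.5,
    reg_multiplier: float = 1.0,
    seed: int = 0,
    with_replacement: bool = False,
) -> ESMResult:
    """The whole ESM stage for a multi-year presence table.

    ``presences`` needs columns ``x_km, y_km, year``; ``stacks`` maps year
    to its (already screened) :class:`EGVStack`. Per year: background
    replicates are drawn, every EGV pair is cross-validated on every
    replicate, the pooled retained runs form the weighted ensemble, the
    annual HSI map is predicted, and the CBI is evaluated on that year's
    presences. Years with fewer than 5 on-sea presences are skipped.
    Deterministic given (seed, config).
    """
    years = sorted(stacks)
    ensembles: dict = {}
    hsi_maps: dict = {}
    cbi: dict = {}
    contrib_rows = {}
    ledger_rows = []
    for yi, year in enumerate(years):
        stack = stacks[year]
        sub = presences[presences["year"] == year]
        vals = stack.values_at(sub["x_km"].to_numpy(), sub["y_km"].to_numpy())
        on_sea = np.all(np.isfinite(vals.to_numpy()), axis=1)
        vals = vals[on_sea].reset_index(drop=True)
        if len(vals) < 5:
            warnings.warn(f"year {year}: fewer than 5 on-sea presences; skipped")
            continue
        pairs = enumerate_pairs(stack.names)
        bgs = sample_background(
            stack, n=n_background, replicates=replicates,
            seed=seed * 1000 + 17 * yi + 1, with_replacement=with_replacement,
        )
        runs: list[BivariateRun] = []
        for bg in bgs:
            for pi, pair in enumerate(pairs):
                pv = vals[list(pair)].to_numpy()
                bv = bg.values[list(pair)].to_numpy()
                runs.extend(
                    cross_validate(
                        pv, bv, pair=pair, background_id=bg.replicate_id,
                        splits=splits,
                        seed=seed * 1000 + 100_000 * yi + 1000 * bg.replicate_id + pi,
                        reg_multiplier=reg_multiplier,
                    )
                )
        ensemble = build_ensemble(runs, d_threshold=d_threshold)
        hsi = predict_map(ensemble, stack)
        pres_hsi = ensemble.predict_values({n: vals[n].to_numpy() for n in vals.columns})
        cbi[year] = boyce_index(hsi, pres_hsi)
        contrib_rows[year] = variable_contribution(runs, egv_names=stack.names, d_threshold=d_threshold)
        ensembles[year] = ensemble
        hsi_maps[year] = hsi
        for r in runs:
            ledger_rows.append(
                {
                    "year": year, "pair": "+".join(r.pair), "background_id": r.background_id,
                    "run_id": r.run_id, "somers_d": r.somers_d,
                    "retained": r.somers_d >= d_threshold,
                }
            )
    contributions = pd.DataFrame(contrib_rows).T if contrib_rows else pd.DataFrame()
    mean_map = cv_map = None
    if len(hsi_maps) >= 2:
        mean_map, cv_map = annual_mean_and_cv(list(hsi_maps.values()))
    return ESMResult(
        years=list(hsi_maps), ensembles=ensembles, hsi_maps=hsi_maps, cbi=cbi,
        contributions=contributions, runs_ledger=pd.DataFrame(ledger_rows),
        mean_map=mean_map, cv_map=cv_map, seed=seed,
    )
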