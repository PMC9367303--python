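import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import logsumexp

from porpoisetools import GridSpec, env_preprocessing as ep, esm_maxent as esm


def brute_force_somers_d(pres, bg):
    """O(n*m) pairwise comparison with ties counted 1/2."""
    wins = sum((p > b) + 0.5 * (p == b) for p in pres for b in bg)
    auc = wins / (len(pres) * len(bg))
    return 2 * auc - 1


# ---------------------------------------------------------------------------
# pairs and background
# ---------------------------------------------------------------------------


def test_enumerate_pairs():
    names = ["bathymetry", "slope", "sst", "chla", "ammonium"]
    pairs = esm.enumerate_pairs(names)
    assert len(pairs) == 10  # C(5, 2)
    assert len(esm.enumerate_pairs(names[:2])) == 1
    assert len(set(map(frozenset, pairs))) == 10  # no duplicates
    assert all(a != b for a, b in pairs)  # no self-pairs
    with pytest.raises(ValueError):
        esm.enumerate_pairs(["only"])


@pytest.fixture(scope="module")
def tiny_stack():
    grid = GridSpec(nx=20, ny=20)
    rng = np.random.default_rng(13)
    layers = {
        "chla": rng.lognormal(0.5, 0.5, grid.shape),
        "sst": rng.normal(17, 1.5, grid.shape),
        "bathymetry": rng.uniform(5, 150, grid.shape),
    }
    layers["chla"][0, :3] = np.nan  # a little land
    layers["sst"][0, :3] = np.nan
    layers["bathymetry"][0, :3] = np.nan
    return ep.EGVStack(grid=grid, layers=layers)


def test_background_sampling_determinism_and_errors(tiny_stack):
    a = esm.sample_background(tiny_stack, n=50, replicates=3, seed=4)
    b = esm.sample_background(tiny_stack, n=50, replicates=3, seed=4)
    for x, y in zip(a, b):
        pd.testing.assert_frame_equal(x.values, y.values)
    # replicate sets differ pairwise
    assert not a[0].values.equals(a[1].values)
    assert not a[1].values.equals(a[2].values)
    with pytest.raises(ValueError):
        esm.sample_background(tiny_stack, n=10_000, replicates=1, seed=0)
    oversample = esm.sample_background(tiny_stack, n=1000, replicates=1, seed=0, with_replacement=True)
    assert len(oversample[0].values) == 1000


# ---------------------------------------------------------------------------
# Somers' D
# ---------------------------------------------------------------------------


def test_somers_d_worked_examples():
    assert esm.somers_d([0.9, 0.8], [0.1, 0.2]) == pytest.approx(1.0)
    assert esm.somers_d([0.5, 0.5], [0.5, 0.5]) == pytest.approx(0.0)
    # presence {0.9, 0.4}, background {0.4, 0.1}: AUC 0.875, D 0.75
    assert esm.somers_d([0.9, 0.4], [0.4, 0.1]) == pytest.approx(0.75)


def test_somers_d_matches_brute_force_pair_counting():
    rng = np.random.default_rng(8)
    for _ in range(5):
        pres = np.round(rng.uniform(0, 1, 23), 2)  # rounding creates ties
        bg = np.round(rng.uniform(0, 1, 37), 2)
        assert esm.somers_d(pres, bg) == pytest.approx(brute_force_somers_d(pres, bg))
    with pytest.raises(ValueError):
        esm.somers_d([], [0.1])


# ---------------------------------------------------------------------------
# MaxEnt fitting
# ---------------------------------------------------------------------------


def test_maxent_null_discrimination_near_zero():
    """Presences drawn from the background distribution give D ~ 0."""
    ds_list = []
    for seed in range(20):
        rng = np.random.default_rng(100 + seed)
        pres = rng.normal(0, 1, (60, 2))
        bg = rng.normal(0, 1, (600, 2))
        runs = esm.cross_validate(pres, bg, pair=("a", "b"), splits=2, seed=seed)
        ds_list.extend(r.somers_d for r in runs)
    assert abs(np.mean(ds_list)) < 0.15


def test_maxent_monotone_response_when_presences_at_high_values():
    rng = np.random.default_rng(3)
    bg = np.column_stack([rng.uniform(0, 10, 800), rng.normal(0, 1, 800)])
    pres = np.column_stack([rng.uniform(7, 10, 80), rng.normal(0, 1, 80)])
    model = esm.fit_maxent(pres, bg, pair=("v1", "v2"))
    v1 = np.linspace(1, 9.5, 9)
    pred = model.predict(np.column_stack([v1, np.zeros_like(v1)]))
    assert np.all(np.diff(pred) >= -1e-9)
    assert pred[-1] > pred[0]


def test_maxent_tiny_unpenalized_matches_brute_force():
    """10 presences, 50 background, linear features, no penalty: the fit
    agrees with direct numerical maximization of the same objective."""
    rng = np.random.default_rng(17)
    pres = rng.normal(1.0, 1.0, (10, 2))
    bg = rng.normal(0.0, 1.0, (50, 2))
    model = esm.fit_maxent(pres, bg, features="l", reg_multiplier=0.0)

    # independent implementation of the Gibbs objective (presences join the
    # normalizing background, features standardized the same way)
    Xp = pres.copy()
    Xb = bg.copy()
    allx = np.vstack([Xp, Xb])
    mu, sdv = allx.mean(0), allx.std(0)
    Zp, Zb = (Xp - mu) / sdv, (Xb - mu) / sdv
    Zn = np.vstack([Zb, Zp])

    def neg_ll(beta):
        return -float(Zp.mean(0) @ beta) + float(logsumexp(Zn @ beta) - math.log(len(Zn)))

    res = minimize(neg_ll, np.zeros(2), method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
    np.testing.assert_allclose(model.beta, res.x, rtol=0.01)  # 2 significant figures


def test_maxent_constant_feature_dropped_with_warning():
    rng = np.random.default_rng(5)
    pres = np.column_stack([rng.normal(1, 1, 20), np.full(20, 3.0)])
    bg = np.column_stack([rng.normal(0, 1, 100), np.full(100, 3.0)])
    with pytest.warns(UserWarning, match="constant feature"):
        model = esm.fit_maxent(pres, bg)
    assert model.beta[1] == 0.0 and model.beta[3] == 0.0


def test_maxent_input_validation():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError):
        esm.fit_maxent(rng.normal(size=(3, 2)), rng.normal(size=(50, 2)))
    with pytest.raises(ValueError):
        esm.fit_maxent(rng.normal(size=(10, 2)), rng.normal(size=(15, 2)))


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def test_cross_validate_split_sizes_and_determinism():
    rng = np.random.default_rng(12)
    pres = rng.normal(1, 1, (10, 2))
    bg = rng.normal(0, 1, (200, 2))
    runs = esm.cross_validate(pres, bg, pair=("a", "b"), splits=4, seed=3)
    assert len(runs) == 4
    for r in runs:
        assert r.model.n_presence == 8  # 80% of 10 trained; 2 held out
    again = esm.cross_validate(pres, bg, pair=("a", "b"), splits=4, seed=3)
    assert [r.somers_d for r in runs] == [r.somers_d for r in again]


def test_cross_validate_no_anti_overfitting_anomaly():
    """Held-out D does not systematically exceed training D."""
    gaps = []
    for seed in range(20):
        rng = np.random.default_rng(200 + seed)
        pres = np.column_stack([rng.normal(1.2, 1, 40), rng.normal(0, 1, 40)])
        bg = np.column_stack([rng.normal(0, 1, 400), rng.normal(0, 1, 400)])
        runs = esm.cross_validate(pres, bg, pair=("a", "b"), splits=2, seed=seed)
        gaps.extend(r.train_somers_d - r.somers_d for r in runs)
    assert np.mean(gaps) > -0.02


# ---------------------------------------------------------------------------
# ensemble
# ---------------------------------------------------------------------------


@dataclass
class _StubModel:
    value: float

    def predict(self, values):
        return np.full(len(np.atleast_2d(values)), self.value)


def _stub_run(d, value, pair=("a", "b")):
    return esm.BivariateRun(pair=pair, background_id=1, run_id=1, model=_StubModel(value), somers_d=d)


def test_build_ensemble_weighted_average_hand_arithmetic():
    # D = {0.6, 0.9}, predictions {0.2, 0.7} -> (0.6*0.2 + 0.9*0.7)/1.5 = 0.50
    ensemble = esm.build_ensemble([_stub_run(0.6, 0.2), _stub_run(0.9, 0.7)])
    out = ensemble.predict_values({"a": np.zeros(3), "b": np.zeros(3)})
    np.testing.assert_allclose(out, 0.50)
    single = esm.build_ensemble([_stub_run(0.8, 0.33)])
    np.testing.assert_allclose(single.predict_values({"a": np.zeros(2), "b": np.zeros(2)}), 0.33)


def test_build_ensemble_threshold_rules():
    kept = esm.build_ensemble([_stub_run(0.49, 0.1), _stub_run(0.52, 0.9)])
    assert len(kept.runs) == 1 and kept.runs[0].somers_d == 0.52
    with pytest.raises(ValueError, match="no skillful"):
        esm.build_ensemble([_stub_run(0.4, 0.1)])
    with pytest.raises(ValueError):
        esm.build_ensemble([])


def test_ensemble_prediction_in_convex_hull_of_members():
    rng = np.random.default_rng(6)
    runs = [_stub_run(d, v) for d, v in zip(rng.uniform(0.5, 1, 5), rng.uniform(0, 1, 5))]
    ens = esm.build_ensemble(runs)
    out = ens.predict_values({"a": np.zeros(1), "b": np.zeros(1)})
    values = [r.model.value for r in runs]
    assert min(values) - 1e-12 <= out[0] <= max(values) + 1e-12
    assert ens.weights.sum() == pytest.approx(1.0)
    assert np.all(ens.weights >= 0)


def test_predict_map_clamping_missing_layers_and_nodata(tiny_stack):
    pres_idx = np.flatnonzero(tiny_stack.sea_mask.ravel())[:40]
    ny, nx = tiny_stack.grid.shape
    rows, cols = np.divmod(pres_idx, nx)
    pv = np.column_stack([tiny_stack.layers["chla"][rows, cols], tiny_stack.layers["sst"][rows, cols]])
    bg = esm.sample_background(tiny_stack, n=300, replicates=1, seed=2)[0]
    model = esm.fit_maxent(pv, bg.values[["chla", "sst"]].to_numpy(), pair=("chla", "sst"))
    run = esm.BivariateRun(pair=("chla", "sst"), background_id=1, run_id=1, model=model, somers_d=0.9)
    ens = esm.EnsembleModel(runs=[run], weights=np.array([1.0]))
    hsi = esm.predict_map(ens, tiny_stack)
    assert np.isnan(hsi[0, 0])  # land stays nodata
    finite = hsi[np.isfinite(hsi)]
    assert np.all((finite >= 0) & (finite <= 1))
    # a cell 10x beyond the training range predicts like a boundary cell
    hi = model.train_max
    beyond = model.predict(np.array([[hi[0] * 10, hi[1] * 10]]))
    at_edge = model.predict(np.array([hi]))
    assert beyond[0] == pytest.approx(at_edge[0])
    with pytest.raises(ValueError, match="missing"):
        esm.predict_map(ens, tiny_stack.subset(["chla"]))


# ---------------------------------------------------------------------------
# Boyce index
# ---------------------------------------------------------------------------


def test_boyce_index_top_decile_presences():
    hsi = np.linspace(0, 1, 200).reshape(10, 20)
    presences = np.linspace(0.91, 0.99, 12)  # only in the top decile
    res = esm.boyce_index(hsi, presences)
    assert res.cbi >= 0.9 and not res.degenerate


def test_boyce_index_null_and_antisymmetry():
    hsi = np.linspace(0, 1, 400)
    cbis = []
    for seed in range(20):
        rng = np.random.default_rng(300 + seed)
        pres = rng.choice(hsi, size=40)
        cbis.append(esm.boyce_index(hsi, pres).cbi)
    assert abs(np.mean(cbis)) < 0.3
    rng = np.random.default_rng(1)
    # graded presence density over the full range; reversing the map flips
    # the sign (exact up to the tie-deduplication of P/E windows)
    pres = np.concatenate([np.linspace(0.01, 0.99, 80), rng.beta(3, 1, 120)])
    fwd = esm.boyce_index(hsi, pres).cbi
    rev = esm.boyce_index(1.0 - hsi, 1.0 - pres).cbi
    assert fwd > 0.9
    assert rev == pytest.approx(-fwd, abs=0.01)


def test_boyce_index_constant_map_degenerate():
    res = esm.boyce_index(np.full(100, 0.5), np.full(8, 0.5))
    assert res.cbi == 0.0 and res.degenerate


# ---------------------------------------------------------------------------
# contributions and multi-year summaries
# ---------------------------------------------------------------------------


def test_variable_contribution_symmetry_and_toy_example():
    # balanced pairs with equal D -> 20% each for 5 EGVs
    names = ["a", "b", "c", "d", "e"]
    runs = [_stub_run(0.8, 0.5, pair=p) for p in itertools.combinations(names, 2)]
    contrib = esm.variable_contribution(runs)
    assert np.allclose(contrib.to_numpy(), 20.0)
    assert contrib.sum() == pytest.approx(100.0)
    # {AB: 0.8, AC: 0.4} -> scores {A: 0.6, B: 0.8, C: 0.4} -> {33.3, 44.4, 22.2}
    toy = [_stub_run(0.8, 0.5, pair=("A", "B")), _stub_run(0.4, 0.5, pair=("A", "C"))]
    c = esm.variable_contribution(toy)
    assert c["A"] == pytest.approx(100 * 0.6 / 1.8, abs=0.01)
    assert c["B"] == pytest.approx(100 * 0.8 / 1.8, abs=0.01)
    assert c["C"] == pytest.approx(100 * 0.4 / 1.8, abs=0.01)


def test_variable_contribution_threshold_zeroes_unskillful_runs():
    runs = [_stub_run(0.8, 0.5, pair=("A", "B")), _stub_run(0.4, 0.5, pair=("A", "C"))]
    c = esm.variable_contribution(runs, d_threshold=0.5)
    assert c["C"] == 0.0
    assert c.sum() == pytest.approx(100.0)


def test_annual_mean_and_cv():
    a = np.full((4, 4), 0.2)
    b = np.full((4, 4), 0.4)
    mean, cv = esm.annual_mean_and_cv([a, b])
    assert np.allclose(mean, 0.3)
    assert np.allclose(cv, np.std([0.2, 0.4], ddof=1) / 0.3)
    assert cv[0, 0] == pytest.approx(0.4714, abs=1e-4)
    same, cv0 = esm.annual_mean_and_cv([a, a])
    assert np.allclose(cv0, 0.0)
    assert np.all(mean >= np.minimum(a, b)) and np.all(mean <= np.maximum(a, b))
    with pytest.raises(ValueError):
        esm.annual_mean_and_cv([a, np.zeros((3, 3))])


def test_run_esm_deterministic(tiny_stack):
    # presences at the highest-chla sea cells so some runs pass the D filter
    chla = np.where(tiny_stack.sea_mask, tiny_stack.layers["chla"], -np.inf)
    pick = np.argsort(chla.ravel())[-30:]
    ny, nx = tiny_stack.grid.shape
    rows, cols = np.divmod(pick, nx)
    x, y = tiny_stack.grid.cell_center(rows, cols)
    pres = pd.DataFrame({"x_km": x, "y_km": y, "year": 2011})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r1 = esm.run_esm(pres, {2011: tiny_stack}, n_background=200, replicates=2, splits=2, seed=5)
        r2 = esm.run_esm(pres, {2011: tiny_stack}, n_background=200, replicates=2, splits=2, seed=5)
    pd.testing.assert_frame_equal(r1.runs_ledger, r2.runs_ledger)
    np.testing.assert_array_equal(r1.hsi_maps[2011], r2.hsi_maps[2011])
    assert r1.contributions.loc[2011].sum() == pytest.approx(100.0)


# ---------------------------------------------------------------------------
# property-based checks
# ---------------------------------------------------------------------------

from hypothesis import given, settings, strategies as st

scores = st.lists(st.integers(0, 5).map(lambda v: v / 5.0), min_size=1, max_size=15)


@settings(deadline=None, derandomize=True, max_examples=60)
@given(pres=scores, bg=scores)
def test_somers_d_properties(pres, bg):
    """D matches brute-force pair counting, is antisymmetric under swapping
    the score sets, and stays within [-1, 1] — including heavy ties."""
    d = esm.somers_d(pres, bg)
    assert d == pytest.approx(brute_force_somers_d(pres, bg))
    assert esm.somers_d(bg, pres) == pytest.approx(-d)
    assert -1.0 <= d <= 1.0
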