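# Methods

`porpoisetools` implements the two computational engines of a coastal
harbour-porpoise assessment — conventional line-transect distance sampling
(CDS) and an ensemble-of-small-models (ESM) MaxEnt habitat-suitability
analysis — together with a synthetic study-system generator so that every
stage can be validated by parameter recovery. This note records the models,
the numerical choices, and the limits of what the synthetic validation can
show.

## 1. Synthetic study system

The generator emulates a multi-year aerial campaign over a coastal strip.

**Grids.** All layers live on a planar km grid, square 1-km cells, rows
stored north to south, cell-centre coordinates. The default study domain is
40 × 740 km: a 20-nm-wide strip along a ~740 km coast, which makes the
systematic design produce 39–40 transects and ~1,445–1,480 km of effort per
year, and a study area of ~25,000–27,500 km² depending on the simulated
coastline — the scale of the emulated campaign.

**Environment.** Five eco-geographical variables (EGVs) are generated as
smoothed Gaussian fields (configurable correlation length, default 15 km)
on top of deterministic structure: land occupies a gently wiggling 1–6-cell
band on the western edge; depth increases offshore at ~4 m/km plus noise;
SST warms southward and offshore (a crude upwelling signature); Chl-a is
log-normal and negatively coupled to SST (the coupling is deliberately kept
below the |r| = 0.7 collinearity screen so that both variables survive
screening, as in the emulated study); ammonium is log-normal with coastal
enhancement. Slope is derived from bathymetry by the Horn gradient. Static
layers (terrain) can be shared across years while the dynamic layers are
redrawn, mirroring annual environmental data with a one-month lag
(represented only as a provenance tag; no calendar arithmetic).

**Suitability truth and populations.** True habitat suitability is a
product of logistic responses, one per EGV: `expit(rate * (v − midpoint))`.
The default truth rises with Chl-a and ammonium and falls with SST, depth
and slope. Porpoise groups follow an inhomogeneous Poisson process with
intensity `intensity_scale × suitability` (groups/km²); group sizes are
i.i.d. zero-truncated Poisson with λ = 0.70, giving the emulated mean group
size 0.70/(1 − e^−0.70) = 1.390. The default `intensity_scale = 1.8` makes
the realized individual density ≈ 0.08–0.09 ind/km² and the five-year
pooled survey yield ≈ 50–60 sightings — the order of magnitude of the
emulated campaign.

**Surveys.** Transects are parallel, shore-perpendicular, spaced 10 nm with
a spacing/2 offset (equal-coverage systematic design), 20 nm long, clipped
to the sea. A group abeam of a flown segment at perpendicular distance *y*
is recorded with probability `g0 · k(y)` for y ≤ W, where k is half-normal
(default σ = 0.12 km; hazard-rate available for misspecification tests),
W = 0.3 km, and g0 = 0.364 is the availability probability, applied as a
single distance-constant Bernoulli thinning — the same multiplicative form
the estimator later corrects for. Every generator is bit-reproducible given
its seed.

**What the generator does not emulate.** Real coastline geometry, tides and
upwelling dynamics, within-season animal movement, responsive movement to
the aircraft, measurement error in angles and group sizes, and
observer-specific detection heterogeneity. Passing recovery tests therefore
show the estimators are correct *under the stated model*, not that the
field estimates they emulate are unbiased.

## 2. Conventional distance sampling

**Detection model.** g(y) = key(y)·(1 + Σ aⱼ bⱼ(y/W)), normalised to
g(0) = 1. Keys: uniform, half-normal, hazard-rate; adjustments: cosine,
Hermite, simple polynomial, with conventional orders (cosine {1,2,3} for
the uniform key, {2,3} for half-normal; Hermite {4,6}; simple polynomial
{4,6}). The conditional likelihood Π g(yᵢ)/μ with μ = ∫₀^W g is maximised
by Nelder–Mead on log-transformed scale parameters, with a closed-form fast
path for the plain half-normal (μ = σ√(π/2)·erf(W/σ√2)). μ inside the
optimiser uses 96-node Gauss–Legendre quadrature; the reported ESW uses
adaptive quadrature. Adjustment terms are added greedily while the AIC
improves; a fitted g that goes negative on [0, W] is refitted with one
fewer term and flagged; monotonicity is checked, not constrained.
Truncation defaults to the largest observed distance. Candidate models are
compared by AIC; exact ties go to fewer parameters, then key order.

**Estimates.** Per stratum (year or sector),
`D = n·E[s] / (2·L·μ·g0)` and `N = D·A`. Expected group size comes from the
size-bias regression of ln(group size) on fitted detection probability:
when the two-sided slope p-value is ≤ α = 0.15 the prediction at g = 1 is
used with the log-normal back-transform `exp(â + b̂ + σ̂²/2)` (clipped at
1.0 — a group has at least one animal), otherwise the observed mean. The
overall density is the effort-weighted mean of stratum densities — this
pooling rule reproduces the emulated study's printed overall row from its
annual rows. Reported tables round densities to 3 decimals and compute
abundances from the *rounded* density so printed rows are internally
consistent.

**Uncertainty.** Nonparametric bootstrap, transects resampled with
replacement within strata (B = 999 by default), refitting the *selected
model form* on the pooled resampled distances each replicate and
recomputing every downstream quantity. CV = SD/mean × 100; 95% intervals
are the 2.5th/97.5th percentiles. Replicates with zero sightings contribute
density 0; a replicate whose detection refit fails falls back to the
point-estimate model rather than being dropped.

**Monte-Carlo scale.** Recovery experiments in the tests and the acceptance
script use 200 replicates of the full five-year survey for the bias check
(SE of the mean relative bias ≈ 1.6%), 100 surveys × B = 199 for interval
coverage, and the plain half-normal refit in the coverage run (the
simulator's truth), keeping each experiment to a few minutes; these sizes
are the package's validation design, chosen for stable Monte-Carlo error.

## 3. EGV preprocessing

Slope: Horn 3×3 gradient, edge-replicated borders, land cells filled from
the nearest sea cell and re-masked. Distance to coast: exact Euclidean
distance transform to the nearest land-cell centre. IDW: Shepard weights
d^−power (default 2) over the k = 12 nearest sources, exact at coincident
points, hence bounded by the sources used. Collinearity screening: pairwise
Pearson r over sea cells, pairwise-complete; a pair with |r| > 0.7
(strict, absolute value — the screening intent is redundancy regardless of
sign) in *any* supplied year loses its lower-priority member everywhere, so
the retained set is constant across years. The default keep-priority is the
core habitat set (bathymetry, slope, SST, Chl-a, ammonium) ahead of derived
or auxiliary layers; the screen is idempotent.

## 4. Ensemble of small models (ESM) with MaxEnt

For each year, every C(k,2) pair of retained EGVs defines a *small model*.
Each pair is fitted on each of the background replicates (10,000 uniform
sea cells each by default; scaled-down sizes in the bundled experiments)
and evaluated on 10 random 80/20 presence/background splits.

**MaxEnt.** The bivariate model maximises the penalized Gibbs likelihood

    mean_p η(x) − log mean_b exp(η(x)) − Σⱼ λⱼ|βⱼ|

with linear + quadratic features of the two EGVs, standardized; product
features are excluded (two predictors only). Presences enter the
normalizing background (the standard MaxEnt convention, which also keeps
the objective bounded when presences sit outside the background's feature
hull). Presence and background totals are equally weighted (prevalence
0.5). λⱼ = reg_multiplier/√n_presence on standardized features
(default multiplier 1.0). The L1 problem is solved exactly via the
positive/negative weight split with L-BFGS-B. Output is mapped to [0, 1]
by the complementary log-log transform 1 − exp(−exp(η − logZ + H)), H being
the entropy of the fitted distribution over the training background; a
logistic output is available by flag.

**Ensemble.** Runs are pooled across pairs × background replicates × CV
splits; runs with held-out Somers' D (= 2·AUC − 1, ties as ½) below 0.5
are discarded, the rest weighted by D/ΣD. The ensemble HSI is the weighted
average of member predictions (member features clamped to their training
range when extrapolating), so it lies in the convex hull of member
predictions.

**Validation and summaries.** Calibration uses the Continuous Boyce Index:
the Spearman correlation between the predicted-to-expected presence ratio
in a moving window (101 midpoints, window = 10% of the HSI range) and the
window midpoint, with duplicated P/E values deduplicated before the rank
correlation (the method's convention; note this makes the map-reversal
antisymmetry exact only up to deduplication). Variable contributions follow
the ESM convention: each variable scores the mean ensemble weight over
*all* runs containing it, where runs below the D threshold contribute 0,
normalised to percentages summing to 100. Multi-year summaries are the
cell-wise mean of annual HSI maps and their CV (sample SD/mean; CV is
nodata where the mean is 0).

Under the default five-driver suitability truth the five contribution
percentages all come out near 20% — no single driver dominates, which is
also the pattern of the emulated study's contribution table. The
attribution *power* experiment therefore uses a Chl-a-driven truth (all
other responses flat; logistic rate 4 at 2.2 mg m⁻³) on fields with a 4-km
correlation length, so the ranking measures environmental signal rather
than incidental co-location of smooth fields; with 150 presences, Chl-a
lands in the top-2 contributions in ≥80% of seeded runs.

## 5. Pipeline and reproducibility

`run_pipeline` executes simulate → prep-env → fit-distance → fit-esm from
one validated config and one seed; the global seed expands into fixed
per-stage offsets so stages can be rerun independently. Reruns are
bit-identical; the JSON report carries input hashes, the AIC table, ESW,
CBI values and the file inventory. Artifacts use plain-text formats only
(CSV/TSV, ESRI ASCII grids, JSON).

## 6. Known limitations

- No covariate (MCDS) detection functions, no double-platform g(0)
  estimation: g(0) is an external input, as in the emulated analysis.
- The bootstrap treats the detection-function *form* as fixed (refit, not
  reselected, per replicate).
- The size-bias CV uses the delta method on the log scale and ignores the
  variance contribution of σ̂².
- MaxEnt feature space is linear + quadratic only; responses requiring
  threshold/hinge shapes will be smoothed.
- The Boyce index is computed on the same year's presences used to fit the
  annual ensemble (as a calibration summary, not an independent test)
  unless the caller supplies held-out presences.
- The planar-grid world has no projection, no real coastline, and a single
  habitat regime; transfers of conclusions to field data rest on the CDS
  and ESM assumptions, not on these simulations.
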