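# porpoisetools

Line-transect distance sampling and ensemble-of-small-models (ESM) habitat
suitability analysis for coastal harbour porpoise (*Phocoena phocoena*)
surveys — with a synthetic study-system generator so the whole pipeline can
be validated end to end by parameter recovery.

The package is aimed at marine-mammal survey analysts who need, in one
place: aerial line-transect abundance estimation with an availability
correction, presence-background habitat modelling suited to very small
sample sizes, and a simulation harness that tells them whether the whole
chain actually recovers known truth.

## The statistics at the core

**Conventional distance sampling (CDS).** Perpendicular sighting distances
*y* are modelled with a detection function g(y) (uniform, half-normal or
hazard-rate key with cosine/Hermite/polynomial series adjustments, g(0)=1),
fitted by maximising the conditional likelihood ∏ g(yᵢ)/μ where
μ = ∫₀^W g(y) dy is the effective strip width (ESW). Candidates are
compared by AIC. Density and abundance per stratum are

    D = n · E[s] / (2 · L · μ · g(0)),     N = D · A

with effort L, size-bias-corrected expected group size E[s] (regression of
ln s on detection probability, used when significant at α = 0.15), and an
external availability probability g(0) (default 0.364, aerial
good-conditions estimate for this species). CVs and 95% CIs come from a
within-stratum bootstrap over transects (999 replicates by default); the
overall density is the effort-weighted mean of stratum densities.

**ESM MaxEnt.** Every pair of screened eco-geographical variables (EGVs)
is fitted as a bivariate MaxEnt model — the penalized presence/background
Gibbs likelihood with linear+quadratic features and prevalence 0.5 —
evaluated on 80/20 splits by Somers' D = 2·AUC − 1, and the runs with
D ≥ 0.5 are averaged with D-proportional weights into a habitat
suitability index (HSI ∈ [0, 1]). Calibration is checked with the
Continuous Boyce Index; per-EGV contribution percentages and multi-year
mean/CV maps summarise the ensembles.

## Worked example

Simulate a small two-year study and analyse it end to end (the demo study
uses a short 220-km coast and a boosted population so it runs in seconds):

```python
from porpoisetools.pipeline import RunConfig, run_pipeline

config = RunConfig(nx=40, ny=220, years=(2011, 2012), intensity_scale=6.0,
                   bootstrap_B=99, n_background=400, background_replicates=1,
                   cv_splits=2, seed=3)
report = run_pipeline(config, "demo_out")
print(report.estimate_table.to_string(index=False))
```

prints

```
stratum  transects  distance_km  sightings  individuals  expected_group_size  density  density_ci_low  density_ci_high  abundance  abundance_ci_low  abundance_ci_high  cv_percent
   2011         12        437.2         16           21                 1.31    0.372           0.159            0.576       3028              1294               4688       28.63
   2012         12        437.2          2            2                 1.00    0.035           0.000            0.072        285                 0                586       60.48
  total         24        874.3         18           23                 1.16    0.204           0.084            0.302       1660               684               2458       26.83
```

Each row is one survey year (stratum): effort flown, sightings and
individuals, the size-bias-corrected expected group size, and the
g(0)-corrected density (ind/km²) and abundance with bootstrap percentile
CIs and CVs; the total row pools the years with effort weighting, and every
abundance equals the printed density × area rounded to the nearest animal.
The AIC table for the pooled detection function in the same run,

```
        key        adjustment orders  n_params    loglik        aic   esw_km
    uniform            cosine     []         0 31.141126 -62.282251 0.177273
half-normal            cosine     []         1 31.442349 -60.884697 0.145633
half-normal           hermite     []         1 31.442349 -60.884697 0.145633
hazard-rate simple-polynomial     []         2 31.670021 -59.340041 0.142695
```

selects the uniform key (lowest AIC) with an ESW of 0.177 km. The ESM stage
of the report adds the annual Boyce index (0.866 for 2011 here; 2012 had
too few presences and is skipped) and the EGV contribution percentages,
which sum to 100 per year.

The same stages are available from the shell:

```bash
porpoise-pipeline run --config run.yaml --out demo_out/
porpoise-pipeline simulate --seed 1 --out sim/
porpoise-pipeline fit-distance --sightings sim/sightings.csv --effort sim/effort.csv \
    --area 25052.52 --g0 0.364 --bootstrap 999 --seed 1 --out cds/
porpoise-pipeline recover --reps 200 --seed 1
```

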