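# savannagrad

Census-to-inference pipeline for the diversity and biomass of savanna
ungulates along a protected-area / pastoral-land gradient.

Fine-scale ground censuses of African savanna ungulates are collected on
1 km-by-1 km blocks, each nested into nine 333 m sub-blocks, spanning a
reserve boundary into adjacent pastoral land, in contrasting rainfall years
(a drought year and a normal year).  This package implements every stage
needed to go from such sub-block count tables to the questions ecologists ask
of them — *where along the human-use gradient do ungulate diversity and
biomass peak, and how does drought shift them?* — together with a synthetic
census generator that reproduces the statistical structure of the data, so
the whole chain is verifiable without the field archive.  It is written for
quantitative ecologists and biostatisticians who work with block-census or
transect count data.

## What it computes

**Block aggregation with missing-sub-block correction.**  Blocks sometimes
hold fewer than nine censused sub-blocks; the expected block total for
species *u* in block *i* is

    c_ui = ( Σ_j d_uij ) · 9 / Q_i

with `Q_i` the number of censused sub-blocks and `d_uij` the sub-block
counts.  Metric covariates are averaged across sub-blocks, presence flags
are OR-ed.

**Spatial imputation.**  Vegetation attributes observed only on the planned
plot subset (grass in every third sub-block, shrubs/trees in the central one)
are imputed by ordinary kriging with automated variogram fitting
(spherical/exponential/gaussian candidates, pair-count-weighted least
squares).

**Diversity profiles.**  Per block, the effective number of species
(Hill number) of order *q*,

    ^qD = ( Σ_u p_u^q )^(1/(1−q)) ,   ^1D = exp(−Σ p_u ln p_u) ,

at orders 0, 1 (Shannon), 2 (Simpson), 10 (evenness) and ∞ (reciprocal
Berger–Parker, undefined on ties), bias-adjusted for unseen species with a
Burnham–Overton jackknife whose order is chosen by sequential tests, plus raw
richness.  **Biomass** is Σ_u c_ui·w_u with per-species unit weights, split
into migratory (wildebeest, zebra) and resident components.

**Boosted distributional regression.**  Responses are modeled with
GAMLSS-type families — negative binomial (raw richness, log link),
zero-truncated negative binomial (bias-adjusted richness), and zero-adjusted
gamma (biomass; diversity orders after subtracting 1) with a logit-linked
zero probability ν and log-linked mean μ — fitted by non-cyclical
component-wise gradient boosting: P-spline base learners for metric
predictors and linear learners for flags, separate learners per land-use ×
census-year cell ("variable coefficients"), early stopping by subsampled
cross-validation, and complementary-pairs **stability selection** with a 70 %
selection-frequency threshold and the PFER bound q²/((2π−1)p).

**Gradient prediction.**  Fitted models are evaluated along the signed
distance to the reserve boundary (negative inside the reserve) with all other
covariates at their medians and flags at zero, yielding the diversity and
biomass curves, their peak locations, and drought-vs-normal percent change.

## Worked example

```python
import numpy as np
from savannagrad import (ScenarioConfig, simulate_landscape, aggregate_grid,
                         diversity_profile, block_biomass, family_from_name)
from savannagrad.pipeline import fit_response_model
from savannagrad.gradients import (conditioning_record, default_distance_grid,
                                   gradient_curve)

cfg = ScenarioConfig(seed=1)          # 30 x 30 blocks, drought 1999 / normal 2002
grid = simulate_landscape(cfg)
print(f"sub-block rows: {len(grid)}")
for year in grid.years:
    print(f"  {year}: zero fraction {grid.zero_fraction(year):.3f}")

blocks = aggregate_grid(grid)
cm = grid.colmap
row = blocks.iloc[700]
prof = diversity_profile(row[list(cm.species)].to_numpy(dtype=float))
bio = block_biomass({s: float(row[s]) for s in cm.species})
print(f"block {row[cm.block_id]} / {row[cm.year]}: S={prof.richness_raw}, "
      f"^0D={prof.d0:.2f}, ^1D={prof.d1:.2f}, ^2D={prof.d2:.2f}, "
      f"biomass={bio.total_kg:.0f} kg (migratory {bio.migratory_kg:.0f})")

blocks["richness_raw"] = (blocks[list(cm.species)].to_numpy() > 0).sum(axis=1)
metric = [cm.dist_boundary, "grass_color", "dist_water_km", "elevation_m", "slope_deg"]
binary = ["sheep_goats", "fire_scar"]
model, data = fit_response_model(blocks, "richness_raw", family_from_name("nb"), cm,
                                 grouping=("year",), metric_predictors=metric,
                                 binary_predictors=binary, n_iter=300, seed=1)
cond = conditioning_record(data, metric, binary, cm.dist_boundary)
dgrid = default_distance_grid(data, cm.dist_boundary, 0.5)
obs = (data[cm.dist_boundary].min(), data[cm.dist_boundary].max())
for year in grid.years:
    c = gradient_curve(model, dgrid, cond, cm.dist_boundary,
                       extra={cm.year: year}, observed_range=obs)
    print(f"richness peak {year}: {c.peak_distance:+.1f} km "
          f"(predicted {c.peak_value:.1f} species)")
```

prints

```
sub-block rows: 15353
  1999: zero fraction 0.733
  2002: zero fraction 0.639
block B011_020 / 1999: S=8, ^0D=12.72, ^1D=9.48, ^2D=6.67, biomass=2084 kg (migratory 984)
richness peak 1999: +4.5 km (predicted 9.8 species)
richness peak 2002: +4.5 km (predicted 13.4 species)
```

The zero fractions match the generator's calibration targets (73 % in the
drought year, 63 % in the normal year); the bias-adjusted richness `^0D`
exceeds the eight observed species because rare species were likely missed;
and the fitted richness gradient peaks a few kilometres onto the pastoral
side of the boundary in both years, lower in the drought year — the
generating truth places the diversity peak at +5 km.

The same stages are available as a command line tool:

```bash
savannagrad simulate --seed 1 --out sub.csv
savannagrad aggregate sub.csv --out blocks.csv
savannagrad diversity blocks.csv --out metrics.csv
savannagrad fit metrics.csv --response richness_raw --family nb --out model.json
savannagrad predict-gradient model.json metrics.csv --out curves.csv
savannagrad run --seed 1 --out artifacts/      # full chained pipeline + manifest
```

## Layout

```
src/savannagrad/
  synthetic.py    # scenario config + two-year census generator (+ truth table)
  censusio.py     # ColumnMap, sub-block/block CSV readers and writers
  kriging.py      # variograms, ordinary kriging, covariate imputation
  aggregate.py    # 9/Q expected totals, covariate means, flag ORs
  metrics.py      # Hill numbers, jackknife richness, diversity profiles, biomass
  families.py     # NB, truncated NB, zero-adjusted gamma, Gaussian + gradients
  boost.py        # base learners, non-cyclical boosting, CV early stopping
  stabsel.py      # complementary-pairs stability selection, PFER bound
  gradients.py    # conditioning records, distance curves, relative change
  pipeline.py     # chained stages with one global seed and a run manifest
  cli.py          # click entry point (`savannagrad`)
docs/methods.md   # model and generator assumptions, defaults, limitations
```
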