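# rxaccess

Tract-level spatial access to pharmacies, measured as the
**population-weighted mean shortest road-network distance (PWMSD)**, and the
sociodemographic disparities in it.

The package is for health-geography and epidemiology analysts who want a
reproducible version of the block-to-pharmacy distance pipeline: given a road
network, pharmacy locations and census blocks nested in tracts, it computes
for every block the shortest network distance to the nearest in-scope
pharmacy, aggregates it to tracts, applies standard exclusion rules, and
quantifies disparities across quartiles of tract covariates with
log-linear models and heteroskedasticity-robust standard errors.  A
synthetic-region generator with known ground truth makes every stage testable
without any external downloads.

## The statistic and the model

For tract *t* with blocks *b*, block population `pop_b` and block-centroid
network distance `d_b` to the nearest in-scope pharmacy:

```
PWMSD_t = Σ_b pop_b · d_b / Σ_b pop_b
```

Distances are pure network path lengths between points snapped
(perpendicular projection) onto the nearest road edge; the off-network snap
gap is reported for QC but never added.  Pharmacies across a state border
count as destinations (`in_scope = 1`); pharmacies across an international
border do not (`in_scope = 0`).

Tracts are excluded in order: water-only (no land area), then total
population < 10, then tracts with an unreachable populated block.  For each
covariate *x* (% poverty, % higher education, % Black/AA, % Hispanic/Latino)
tracts are split into quartiles Q1–Q4 of the *x* distribution and a separate
Gaussian GLM (≡ OLS) is fitted:

```
ln(PWMSD_t) = β0 + β2·I(Q2) + β3·I(Q3) + β4·I(Q4) [+ γ·density]  ,
```

with sandwich (HC3 by default) coefficient covariance and normal-reference
Wald inference.  Each βk is reported as a percent difference in distance,
`(e^βk − 1)·100`, with the 95% CI transformed from `βk ± 1.96·SE`; negative
values mean *shorter* distances, i.e. greater access, in that quartile
relative to Q1.

## Worked example

```python
import rxaccess

scenario = rxaccess.generate_scenario(seed=7)        # synthetic region
out = rxaccess.run_scenario_analysis(scenario)       # full pipeline
s = out["summary"]
print(out["exclusion_log"]["n_retained"], "tracts analysed")
print(f"mean PWMSD {s['mean_km']:.2f} km, median {s['median_km']:.2f} km")
print(out["results"].summary())
```

prints (abridged):

```
97 tracts analysed
mean PWMSD 1.42 km, median 1.23 km

Quartile disparity analysis of ln(PWMSD)
  n tracts: 97   robust covariance: HC3

covariate       level         pct diff                95% CI         p
pct_poverty     Q1            referent
                Q2              -13.7%         (-39.8, 23.8)    0.4238
                Q3              -20.2%         (-43.1, 12.0)    0.1925
                Q4              -36.5%         (-57.6, -5.0)    0.0271
...
```

The poverty Q4 row reads: tracts in the highest-poverty quartile have a
36.5% shorter population-weighted distance to a pharmacy than the
lowest-poverty quartile — the generator sites pharmacies proportionally to
population, which concentrates them in the dense urban core where synthetic
poverty is highest, so higher-poverty tracts end up with *greater* spatial
access.

The same analysis runs from the shell, stage by stage or in one shot:

```sh
rxaccess --seed 7 --outdir out run-all
# or: simulate / distances / pwmsd / analyze on the documented CSV schemas
```

## Analysing real tract data

A tract table that already carries a computed PWMSD column (for example a
published state-wide dataset) skips the geometric stages entirely:

```python
from rxaccess import io, QuartileDisparityModel
records = io.load_deposited_tracts("data/nys_deposited_tracts.csv")
print(QuartileDisparityModel.from_dataframe(records).fit().summary())
```

or `rxaccess analyze --records records.csv`.  Column names are adapted via
`io.DEPOSITED_COLUMN_MAP` / the `column_map` argument.

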