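# Data dictionary

## Analysis table (`analysis_table.csv`, one row per child)

| column | level | type | meaning |
|---|---|---|---|
| `child_id` | child | int | unique child identifier |
| `household_id` | household | int/str | household identifier; each household belongs to exactly one cluster |
| `cluster_id` | cluster | int/str | survey-cluster identifier |
| `urban` | cluster | 0/1 | 1 if the cluster is urban |
| `diarrhea` | child | 0/1 | 1 if the child had diarrheal disease in the two-week recall window |
| `age` | child | int 0–59 | age in months |
| `wealth_high` | household | 0/1 | household wealth in the top two quintiles |
| `edu_secondary` | household | 0/1 | mother has secondary education or higher |
| `improved_sanitation` | household | 0/1 | WHO/JMP improved sanitation facility |
| `improved_water` | household | 0/1 | WHO/JMP improved drinking-water source |
| `precip_lag_z` | cluster | float | one-month-lag long-term monthly precipitation, z-scored over the pooled sample |
| `precip_change` | cluster | float | survey-month minus previous-month precipitation, z-scored |
| `temp_lag_z` | cluster | float | one-month-lag long-term monthly temperature, z-scored |
| `temp_change` | cluster | float | survey-month minus previous-month temperature, z-scored |
| `human_index` | cluster | % 0–100 | share of accumulated water that fell as rain on upstream human/livestock-impacted land, averaged over the 10 km window |
| `tree_index` | cluster | % 0–100 | share of accumulated water that fell as rain on upstream tree-covered land, averaged over the 10 km window |

## Cluster tables

`clusters.csv`: `cluster_id`, `true_x`, `true_y`, `reported_x`,
`reported_y` (meters; reported = anonymization-displaced), `urban`,
`row`, `col` (grid cell of the true location).

`cluster_indices.csv`: `cluster_id`, `human_index`, `tree_index`,
`total_water` (mm·m², accumulated volume), `n_cells` (cells in the
aggregation window).

`cluster_environment.csv`: `cluster_id` plus the six cluster-level model
covariates listed above.

## Landscape rasters (`landscape/*.asc`, ESRI ASCII grid)

`elevation` (m), `precip` (mm/month), `aet` (mm/month, actual
evapotranspiration), `tree_frac` (0–1), `pasture_frac` (0–1),
`population` (persons/cell), `cattle` (head/cell).

## Fit JSON (`fit_*.json`)

`names` (intercept first), `beta`, `se`, `cov_beta` (fixed-effect
covariance), `sigma_cluster`, `sigma_household` (random-intercept SDs),
`loglik`, sample sizes, convergence flags, `x_mean` (covariate sample
means used for at-means effects).

## Policy tables (`policy_*.csv` / `.json`)

One row per binary policy variable and per tree-cover scenario:
`variable`, `baseline_probability` (at-means), `delta_probability`,
`percent_reduction` (100·|delta|/baseline), `ci_low`, `ci_high`
(delta-method 95%), `scenario_size` (percentage points; empty for
binary variables). Rows sorted by |delta|, largest first.
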