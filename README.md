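# watershed-health

Does the condition of the land upstream of where children live predict
their risk of diarrheal disease (DD)? Analyses that ask this question
join georeferenced household-survey data (child outcomes, wealth,
education, water and sanitation access) to hydrologically routed
environmental indices: the percentage of the water reaching a survey
cluster that fell as rain on upstream land impacted by people and
livestock, or on upstream tree cover. This package implements that whole
analysis chain at desk scale — on synthetic landscapes and surveys with
known generating parameters — so every stage is testable against ground
truth without any restricted data.

It is aimed at quantitative epidemiologists and ecosystem-services
researchers who want a validated, inspectable reference implementation
of the method: the routing metric, the clustered-survey structure, the
hierarchical model, and the policy-effect calculations.

## What it computes

**Upstream water-source indices.** On a raster with a D8 drainage
network, each cell contributes runoff = max(P − AET, 0). A fraction of
each cell's runoff is tagged — human activity (a 3.65 m² contaminated
ground footprint per person, plus all pasture whenever cattle are
present, capped at the full cell) or tree cover — and accumulated
downstream. The index at a cell is `100 × tagged / total` percent (0
where there is no water). A brute-force upstream-enumeration oracle
verifies the accumulation exactly.

**Three-level mixed logit.** For child *i* in household *j* in cluster
*k*:

    logit P(y_ijk = 1) = x_ijk'β + v_k + u_jk,
    v_k ~ N(0, σ_k²),  u_jk ~ N(0, σ_jk²),

with the fixed effects: age, household wealth (top two quintiles),
maternal secondary education, improved sanitation, improved water
(WHO/JMP recodes), one-month-lag precipitation and temperature z-scores
with month-over-month change terms, and the two upstream indices.
Estimation is by nested adaptive Gauss–Hermite quadrature (Laplace
available); intra-class correlations use the latent π²/3 convention.
Subgroup fits (urban/rural, improved/unimproved water, high/low upstream
human activity) and an age-band/tree-quartile variant specification are
built in.

**Marginal effects at means.** Discrete 0→1 probability changes for the
binary policy variables and instantaneous-rate scenario effects for
10/20/30-point increases in upstream tree cover, with delta-method 95%
intervals, collected into a sortable policy table.

## Worked example

```python
from watershed_health import pipeline, model_fit as mf
import pandas as pd

report = pipeline.run_pipeline(pipeline.RunConfig(seed=7), "out")
print("children:", report.summary["n_children"],
      "| prevalence: %.4f" % report.summary["prevalence"])
print("ICC cluster: %.4f | ICC household (cumulative): %.4f" % (
    report.summary["icc_cluster"], report.summary["icc_household_cumulative"]))

fit = mf.FitResult.from_json(report.paths["fit_rural"])
print(fit.odds_ratios().loc[["improved_water", "human_index", "tree_index"]].round(4))
```

prints (numbers from this exact run):

```
children: 5000 | prevalence: 0.0778
ICC cluster: 0.0279 | ICC household (cumulative): 0.2156
                  coef      se  odds_ratio  or_low  or_high
term
improved_water -0.1636  0.1839      0.8491  0.5922   1.2175
human_index    -0.0032  0.0063      0.9968  0.9846   1.0092
tree_index     -0.0142  0.0042      0.9859  0.9779   0.9940
```

Reading it: in this synthetic rural subsample each additional percentage
point of upstream tree-cover water share multiplies the odds of DD by
0.986 (interval excluding 1), while the improved-water and
human-activity intervals straddle 1 at this sample size — the synthetic
truth gives tree cover a protective coefficient, and 5,000 children is
enough to resolve it but not every smaller effect. The corresponding
policy table (`policy_rural.csv`) ranks effects by magnitude:

```
           variable  scenario_size  delta_probability  percent_reduction
      edu_secondary            NaN            -0.0235            48.4523
         tree_index           30.0            -0.0196            40.5163
        wealth_high            NaN            -0.0163            33.7070
         tree_index           20.0            -0.0131            27.0109
     improved_water            NaN            -0.0072            14.9368
         tree_index           10.0            -0.0065            13.5054
improved_sanitation            NaN            -0.0041             8.4964
```

i.e. a 30-point increase in the upstream tree-cover share lowers the
at-means probability of DD by about 2 percentage points in this
simulation, comparable to the wealth effect and larger than improved
sanitation.

The same stages are available as a CLI:

```bash
watershed-health run --seed 7 --out out/          # full pipeline
watershed-health generate --seed 3 --out work/    # landscape + clusters
watershed-health route --grid work/landscape --clusters work/clusters.csv \
    --window-km 10 --out work/indices.csv
watershed-health validate --config config.yaml
```

## Layout

```
src/watershed_health/
  synthetic_data.py      landscapes, clusters, DHS-style displacement, surveys
  hydro_routing.py       D8 networks, water balance, tagging, indices, oracle
  covariate_assembly.py  WHO/JMP recodes, climate z-scores, table build
  model_fit.py           three-level logit (nested AGQ / Laplace), ICC, subgroups
  marginal_effects.py    at-means effects, delta-method intervals, policy table
  pipeline.py, cli.py    orchestration, config, command line
docs/methods.md          model, assumptions, defaults, numerical choices
```
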