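# Methods

This package implements, at desk scale, an analysis linking upstream
watershed condition to childhood diarrheal disease (DD): construction of
spatially routed upstream water-source indices, assembly of a clustered
child-level covariate table, a three-level random-intercept logistic
model, and marginal-effect comparison of policy options. Everything runs
on synthetic landscapes and surveys with known generating parameters, so
every stage can be validated against ground truth.

## Upstream water-source indices

Each raster cell contributes monthly runoff

    runoff = max(precipitation − actual evapotranspiration, 0)   [mm]

to a single-downstream-neighbor (D8) drainage network: every cell drains
to its steepest-descent 8-neighbor (drop divided by center distance),
with ties broken by a fixed neighbor precedence (E, SE, S, SW, W, NW, N,
NE). Edge cells with no lower neighbor are outlets. The network requires
pit-free elevation; the generator guarantees this (below), and
`derive_flow_network` refuses pits with an instruction to fill them.

A fraction of each cell's runoff is *tagged*:

* **Human activity.** Each person is assumed to contaminate 3.65 m² of
  ground per year, so the human part of the tag is
  `min(1, population × 3.65 / cell_area)`. All pasture counts as
  polluted whenever the cell's cattle headcount is positive. The two
  parts add and are capped at the full cell. The rules are stated
  separately in the underlying analysis framework; the capped sum is
  this package's combination choice.
* **Tree cover.** The cell's tree-cover fraction.

Tagged and total water are accumulated downstream in topological order
(cells sorted by descending elevation are a valid order because flow is
strictly descending). The index at a cell is

    index = 100 × tagged / total   [%],   defined as 0 where total = 0,

so 100 means all water at the cell fell as rain on tagged land and 0
means no tagged upstream land *or* no water (the dry-cell clause is an
explicit definition, since 0/0 is otherwise undefined). The footprint is
applied as a static fractional land tag, not accumulated over years: the
indices are long-term averages.

Cluster-level values average the index over all cells whose centers fall
in a square window (default 10 km side, one aggregation cell) centered
on the cluster's *reported* (displaced) coordinates; a square is chosen
over a circle for exactness on the raster. Averaging at this scale is
also what absorbs the anonymization displacement of the coordinates.

An independent oracle (`upstream_oracle`) recomputes any cell's index by
explicitly enumerating its entire upstream set; the accumulation pass is
tested against it cell-by-cell at 1e-9 relative tolerance, along with
mass conservation at outlets and monotonicity/dilution properties.

## Synthetic landscapes and surveys

The landscape generator emulates the gridded environmental layers a real
analysis would assemble from global products, on a default 50×50 grid of
10 km cells:

* **Elevation**: Gaussian-smoothed noise (correlation length 3 cells,
  relief SD 300 m) plus a deterministic tilt toward the south edge, then
  priority-flood pit filling with an epsilon gradient. This guarantees a
  strictly descending path from every cell to an edge, hence a valid D8
  network (real drainage products are likewise pit-resolved).
* **Climate**: monthly precipitation (mean 100 mm, spatial SD 30) and
  actual evapotranspiration (mean 60 mm, SD 20) as smoothed fields,
  clipped at zero. A per-cluster monthly climatology adds a sinusoidal
  seasonal cycle with cluster-specific phase; each cluster gets a survey
  month.
* **Land cover and pressure**: tree fraction from a logit-normal smoothed
  field (mean 0.35); pasture on part of the non-tree remainder; lognormal
  population with 30% of cells uninhabited; cattle Poisson on pasture at
  5 head per km².

Surveys follow the two-stage cluster design of DHS-style household
surveys. Clusters sit at distinct cell centers; urban flags are Bernoulli
(default urban fraction 0.35) and urban clusters are drawn
population-weighted. Published coordinates are displaced like the DHS
anonymization rule: direction uniform, distance uniform up to 2 km
(urban) or 5 km (rural), with 1% of rural clusters drawn up to 10 km; a
bounding-box clip (the analog of staying inside the survey's
administrative area) never increases the displacement. Note that under a
uniform distance draw, the marginal share of rural displacements beyond
5 km is 0.5% (half of the 1% far draws).

Child outcomes follow the three-level logit below with all covariates
drawn per configured distributions: household covariates are Bernoulli
with urban/rural-specific probabilities (improved water 63%/22%,
matching the urban/rural access contrast the analysis emphasizes; wealth
65%/25%; secondary education 45%/15%; improved sanitation 50%/25% —
the last three chosen once as plausible for multi-country survey data),
and child age is uniform on 0–59 months (all children are under five).
Default coefficients give ~8–10% outcome prevalence with protective
wealth, education, water/sanitation, lagged precipitation and upstream
tree cover, and adverse temperature and upstream human activity. Default
random-intercept SDs (0.4479 cluster, 0.7222 household) are obtained by
inverting latent-scale intra-class correlations of 0.05 (cluster) and
0.18 (cumulative household) under the logistic residual variance π²/3.

A designed-simulation hook (`GeneratingParams.interactions`) adds
product terms to the linear predictor — e.g. a tree-cover effect
confined to rural households without improved water — so subgroup
machinery can be validated on data where the qualitative pattern is true
by construction.

All randomness flows from one root seed through named substreams
(landscape, clusters, displacement, climate, survey), so each stage is
reproducible in isolation.

What the generator does *not* emulate: survey sampling weights,
multi-country stratification, asset-based wealth-index construction
(quintile membership is generated directly), spatial correlation between
covariates and the drainage network beyond what the smoothed fields
induce, and reporting behavior (recall error) in the outcome. Passing
tests therefore demonstrate the correctness of the estimation machinery
under the stated model, not the realism of any particular coefficient
for real populations.

## Covariate assembly

Water-source and sanitation categories are dichotomized improved/
unimproved following the WHO/JMP classification; the mapping ships as an
editable table (config-overridable YAML) with the standard categories.
Climate enters as the survey month's one-month-lag climatology value and
the month-over-month change (January wraps to December), each
standardized to z-scores over the pooled analysis sample — pooled rather
than per-stratum scaling matches a single pooled model; standardized
columns are checked to mean < 1e-10 and |SD−1| < 1e-10. Missing-data
handling is listwise deletion with a logged count. Referential integrity
(child → household → cluster, one cluster per household, environment for
every cluster) is enforced at assembly.

## The three-level model

For child *i* in household *j* in cluster *k*:

    logit P(y_ijk = 1) = β0 + β1 Age_ijk + β2 Wealth_jk + β3 Education_jk
                       + β4 ImprovedSanitation_jk + β5 ImprovedWater_jk
                       + β6 Precip_{t−1,k} + β7 ΔPrecip_k
                       + β8 Temp_{t−1,k} + β9 ΔTemp_k
                       + β10 HumanActivityUpstream_k + β11 TreeCoverUpstream_k
                       + v_k + u_jk,

    v_k ~ N(0, σ_k²),  u_jk ~ N(0, σ_jk²)  independent.

No country-level random effect is included. Estimation maximizes an
approximated marginal likelihood:

* **Laplace** (`method="laplace"`): joint Laplace approximation at the
  mode of all random effects. The penalized-likelihood Hessian has an
  arrow structure (each household belongs to one cluster) whose cluster
  Schur complement is diagonal, so the inner Newton solve and the
  log-determinant are O(n) vectorized operations.
* **Nested adaptive Gauss–Hermite quadrature** (`method="agq"`, the
  default, 5 nodes per level by default): the household integral is done
  by adaptive quadrature inside every cluster-level quadrature node, with
  centers and scales taken from the joint Laplace mode and its Schur
  curvature. On small reference problems the quadrature log-likelihood
  agrees with dense 80-node brute-force integration to within 5e-3
  (5 nodes, the default), 1e-3 (7 nodes) and 1e-7 (21 nodes), with the
  error shrinking monotonically in the node count (asserted in the
  suite).

AGQ is the default because the Laplace objective misbehaves in exactly
this package's design regime: with two-child households at ~10%
prevalence, the Laplace surface can favor a degenerate solution with a
very large household variance (it overestimates the integral there; the
quadrature objective at the same point is hundreds of log-likelihood
units lower). Adaptive quadrature also removes the well-known Laplace
shrinkage of the household variance at small household sizes, matching
what the standard mixed-logit routines compute.

The outer optimization is L-BFGS-B over (β, σ_k, σ_jk) with σ ≥ 0, on an
internally centered/scaled design (estimates and covariance are mapped
back), with an analytic score for the quadrature objective
(posterior-weighted residual sums; the dependence of the adaptive
centers on the parameters enters only at the order of the quadrature
error and is ignored). Standard errors come from the numerically
differentiated observed information at the optimum, so fixed-effect
standard errors reflect variance-component uncertainty; 95% intervals
are Wald on the coefficient scale, exponentiated to odds-ratio bounds
exp(β ± 1.96 SE). Complete separation raises an explicit error, as does
optimizer non-convergence (with diagnostics).

Intra-class correlations use the latent-response convention,
σ²-shares of σ_k² + σ_jk² + π²/3. The household figure is reported
cumulatively (the correlation of two children in the same household,
(σ_k² + σ_jk²)/total) by default — this is the convention under which a
household ICC exceeds the cluster ICC — with the non-cumulative variance
share available via `icc(fit, cumulative=False)`.

Finite-sample behavior worth knowing: at the default study size (500
clusters × 5 households × 2 children) the household variance is
recovered essentially unbiasedly by AGQ, while the *cluster* variance —
a small component (ICC 0.05) identified from only ~10 children per
cluster — shows the usual downward skew of a near-boundary variance MLE:
the mean ICC estimate falls below the generating 0.05, while the
generating value stays well inside the central 95% of the estimate
distribution (both asserted by the recovery study in the suite). This was
verified to be a property of the exact marginal likelihood, not of the
approximation: the quadrature matches brute-force integration, is
insensitive to node count, and matches `lme4::glmer` at high quadrature
order on single-level designs.

### Subgroups and the variant specification

Subgroup fits apply the identical specification to both halves of a
split: urban/rural, improved/unimproved water within rural, and
high/low upstream human activity within rural (split at the *subset*
sample mean; the pooled full-sample z-scaling of covariates is retained
within subgroups). The variant specification replaces age in months
with year-of-age dummies (reference: first year) and the continuous
tree-cover index with quartile dummies (reference: below the 25th
percentile; half-open, lower-inclusive bins at the empirical quartiles).

## Marginal effects at means

Policy comparisons convert coefficients into probability changes with
all covariates at their sample means (binary covariates at their
proportions) and random effects at zero, the median of their
distribution:

* binary variables: delta = p(x_v=1, rest at means) − p(x_v=0, rest at
  means), an exact difference of two inverse-logit evaluations;
* continuous tree cover: the instantaneous rate at means scaled by a
  scenario-sized increase, delta = β_v p̄(1−p̄) × Δ for Δ ∈ {10, 20, 30}
  percentage points of the index (the index is itself a percentage, so
  "10/20/30% increases" are read as additive percentage points; a
  relative-increase reading can be obtained by passing Δ = 0.1 × the
  index mean etc.). The approximation is exactly linear in Δ.

Confidence intervals are delta-method on the probability scale via the
fitted coefficient covariance; a zero-variance coefficient degenerates
to a point interval, and the delta-method SE was checked against
simulation from the coefficient sampling distribution. Reported
`percent_reduction` is 100·|delta| divided by the at-means baseline
probability. For synthetic runs the pipeline reports both the at-means
baseline and the raw prevalence (the two need not coincide in a
nonlinear model).

## Pipeline, sizes and numerical choices

`run_pipeline` executes generate → route → climate → survey → assemble →
fit (full, urban/rural, water split, human-activity split, quartile
variant) → effects, writing plain CSV/JSON/ASCII-grid outputs plus the
resolved config; identical config and seed give byte-identical tables.
Default problem sizes — 50×50 grid, 500 clusters, 5,000 children — keep
a full run in seconds and the 200-replicate recovery study in minutes on
one CPU, while matching the nesting structure (many small households)
that makes the estimation problem statistically interesting.

Numerical parameters: inner Newton tolerance 1e-11–2e-9 on the gradient
sup-norm with step damping; priority-flood epsilon 1e-3 m; quadrature
nodes 5 (configurable); L-BFGS-B ftol 1e-11; variance components bounded
in [0, 10]; degenerate inputs (zero variance components, dry cells,
constant covariates, single-class outcomes, separation) are handled by
explicit branches or explicit errors rather than by numerical fallback.

## Known limitations

* The tagged-share index follows the verbal description of the
  water-source metric ("percent of water that fell as rain on a defined
  land cover"); exact equivalence with any particular platform's
  implementation of it cannot be asserted.
* Single static AET layer; no sub-monthly dynamics; no multi-direction
  flow; no stream burning or sink carving beyond pit filling.
* Population-averaged (integrated-over-random-effects) marginal effects
  are out of scope; effects are conditional at the random-effect median.
* No survey weights, no imputation, no Bayesian estimation.
* The Laplace method is retained for speed and as the quadrature's
  adaptive center but should not be used for final variance-component
  estimates in designs with very small households (see above).
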