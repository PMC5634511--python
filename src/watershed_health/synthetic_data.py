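"""Synthetic landscapes and DHS-style clustered surveys with known truth.

This module stands in for the data a field analysis would assemble from
global rasters (climate, tree cover, population, livestock) and from a
two-stage cluster household survey. Everything is generated from explicit
parameters so that routing, covariate assembly, model fitting and
marginal-effect calculations downstream can be validated against known
ground truth.

Children are nested in households, households in survey clusters. The
binary diarrhea outcome is drawn from a three-level logistic model with
independent Normal random intercepts at the household and cluster levels:

    logit P(y_ijk = 1) = x_ijk' beta + v_k + u_jk,
    v_k ~ N(0, sigma_cluster^2),  u_jk ~ N(0, sigma_household^2).

Cluster coordinates are randomly displaced the way the DHS program
anonymizes its published GPS positions: up to 2 km for urban clusters, up
to 5 km for rural clusters, with 1% of rural clusters displaced up to
10 km.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from ._random import substream
from .errors import ConfigurationError
from .schema import MODEL_TERMS

__all__ = [
    "LandscapeConfig",
    "LandscapeGrid",
    "ClusterRecord",
    "GeneratingParams",
    "generate_landscape",
    "place_clusters",
    "displace_coordinates",
    "displace_all",
    "generate_cluster_climate",
    "simulate_survey",
    "priority_flood_fill",
]

# DHS anonymization caps, meters.
URBAN_CAP_M = 2000.0
RURAL_CAP_M = 5000.0
RURAL_FAR_CAP_M = 10000.0
RURAL_FAR_FRACTION = 0.01


# ---------------------------------------------------------------------------
# Landscape


@dataclass
class LandscapeConfig:
    """Settings for the gridded landscape generator.

    Cells default to 10 km on a side, the resolution at which the
    environmental layers are aggregated. Climate fields are monthly
    long-term means in millimeters; setting a *_sd to zero yields a
    spatially constant layer.
    """

    n_rows: int = 50
    n_cols: int = 50
    cell_size: float = 10_000.0  # meters per cell edge
    corr_cells: float = 3.0  # Gaussian correlation length, in cells
    relief: float = 300.0  # SD of the smoothed elevation field, meters
    tilt: float = 2.0  # deterministic drop per row toward the south edge, m
    precip_mean: float = 100.0  # mm / month
    precip_sd: float = 30.0
    aet_mean: float = 60.0  # actual evapotranspiration, mm / month
    aet_sd: float = 20.0
    tree_cover_mean: float = 0.35  # mean tree fraction
    tree_cover_spread: float = 1.5  # SD of the latent logit field
    pasture_scale: float = 0.5  # max share of non-tree land in pasture
    pop_log_mean: float = 7.6  # log persons per inhabited cell
    pop_log_sd: float = 1.5
    uninhabited_fraction: float = 0.3  # share of cells with zero population
    cattle_density: float = 5.0  # head per km^2 of pasture

    def validate(self) -> list[str]:
        findings = []
        if self.n_rows < 2 or self.n_cols < 2:
            findings.append(f"grid must be at least 2x2, got {self.n_rows}x{self.n_cols}")
        if self.cell_size <= 0:
            findings.append("cell_size must be positive")
        for name in ("precip_mean", "precip_sd", "aet_mean", "aet_sd"):
            if getattr(self, name) < 0:
                findings.append(f"{name} must be nonnegative")
        if not 0.0 <= self.tree_cover_mean <= 1.0:
            findings.append("tree_cover_mean must be in [0, 1]")
        if not 0.0 <= self.pasture_scale <= 1.0:
            findings.append("pasture_scale must be in [0, 1]")
        if not 0.0 <= self.uninhabited_fraction <= 1.0:
            findings.append("uninhabited_fraction must be in [0, 1]")
        return findings


@dataclass
class LandscapeGrid:
    """Per-cell environmental state on a square raster.

    All layers are (n_rows, n_cols) arrays. ``elevation`` is pit-free:
    every cell has a monotone strictly descending 8-neighbor path to the
    grid edge, so the single-direction drainage network is well defined.
    """

    cell_size: float
    elevation: np.ndarray  # m
    precip: np.ndarray  # mm / month
    aet: np.ndarray  # mm / month
    tree_frac: np.ndarray  # [0, 1]
    pasture_frac: np.ndarray  # [0, 1]
    population: np.ndarray  # persons per cell
    cattle: np.ndarray  # head per cell

    @property
    def n_rows(self) -> int:
        return self.elevation.shape[0]

    @property
    def n_cols(self) -> int:
        return self.elevation.shape[1]

    @property
    def cell_area(self) -> float:
        """Cell area in square meters."""
        return self.cell_size**2

    def layers(self) -> dict[str, np.ndarray]:
        return {
            "elevation": self.elevation,
            "precip": self.precip,
            "aet": self.aet,
            "tree_frac": self.tree_frac,
            "pasture_frac": self.pasture_frac,
            "population": self.population,
            "cattle": self.cattle,
        }

    def validate(self) -> None:
        shape = self.elevation.shape
        for name, layer in self.layers().items():
            if layer.shape != shape:
                raise ConfigurationError(f"layer {name} has shape {layer.shape}, expected {shape}")
        if np.any(self.precip < 0) or np.any(self.aet < 0):
            raise ConfigurationError("precip and aet must be nonnegative")
        if np.any((self.tree_frac < 0) | (self.tree_frac > 1)):
            raise ConfigurationError("tree_frac must lie in [0, 1]")
        if np.any((self.pasture_frac < 0) | (self.pasture_frac > 1)):
            raise ConfigurationError("pasture_frac must lie in [0, 1]")
        if np.any(self.tree_frac + self.pasture_frac > 1 + 1e-12):
            raise ConfigurationError("tree_frac + pasture_frac must not exceed 1")
        if np.any(self.population < 0) or np.any(self.cattle < 0):
            raise ConfigurationError("population and cattle must be nonnegative")

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(x, y) of a cell center; x runs along columns, y along rows."""
        return ((col + 0.5) * self.cell_size, (row + 0.5) * self.cell_size)


def priority_flood_fill(elevation: np.ndarray, epsilon: float = 1e-3) -> np.ndarray:
    """Raise enclosed depressions so every cell drains strictly to an edge.

    Standard priority-flood with an epsilon gradient: cells are popped from
    a min-heap seeded with the grid boundary; any neighbor lower than the
    popped cell is raised to popped + epsilon, which also resolves flats
    into strictly descending staircases.
    """
    z = np.asarray(elevation, dtype=float).copy()
    n_rows, n_cols = z.shape
    seen = np.zeros(z.shape, dtype=bool)
    heap: list[tuple[float, int, int, int]] = []
    tick = 0  # heap tie-break for determinism
    for r in range(n_rows):
        for c in (0, n_cols - 1):
            heapq.heappush(heap, (z[r, c], tick, r, c))
            seen[r, c] = True
            tick += 1
    for c in range(1, n_cols - 1):
        for r in (0, n_rows - 1):
            heapq.heappush(heap, (z[r, c], tick, r, c))
            seen[r, c] = True
            tick += 1
    while heap:
        zc, _, r, c = heapq.heappop(heap)
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < n_rows and 0 <= cc < n_cols and not seen[rr, cc]:
                    seen[rr, cc] = True
                    if z[rr, cc] <= zc:
                        z[rr, cc] = zc + epsilon
                    heapq.heappush(heap, (z[rr, cc], tick, rr, cc))
                    tick += 1
    return z


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], corr: float) -> np.ndarray:
    """Unit-variance spatially correlated Gaussian field."""
    raw = rng.standard_normal(shape)
    if corr <= 0:
        return raw
    sm = gaussian_filter(raw, sigma=corr, mode="reflect")
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def generate_landscape(config: LandscapeConfig | None = None, seed: int = 0) -> LandscapeGrid:
    """Generate a pit-free landscape with correlated environmental layers.

    The elevation field is Gaussian-smoothed noise plus a deterministic
    tilt toward the south edge, then priority-flood filled, which
    guarantees a valid single-downstream-neighbor drainage network.
    Identical seed and config yield identical grids.
    """
    config = config or LandscapeConfig()
    findings = config.validate()
    if findings:
        raise ConfigurationError("; ".join(findings))
    rng = substream(seed, "landscape")
    shape = (config.n_rows, config.n_cols)

    rows = np.arange(config.n_rows, dtype=float)[:, None]
    elev = config.relief * _smooth_field(rng, shape, config.corr_cells)
    elev = elev + config.tilt * (config.n_rows - 1 - rows)  # north high, south low
    elev = priority_flood_fill(elev)

    precip = np.clip(config.precip_mean + config.precip_sd * _smooth_field(rng, shape, config.corr_cells), 0.0, None)
    aet = np.clip(config.aet_mean + config.aet_sd * _smooth_field(rng, shape, config.corr_cells), 0.0, None)

    tree_latent = _smooth_field(rng, shape, config.corr_cells)
    mean_logit = np.log(config.tree_cover_mean / (1 - config.tree_cover_mean)) if 0 < config.tree_cover_mean < 1 else 0.0
    tree = expit(mean_logit + config.tree_cover_spread * tree_latent)
    if config.tree_cover_mean == 0.0:
        tree = np.zeros(shape)
    elif config.tree_cover_mean == 1.0:
        tree = np.ones(shape)

    pasture = (1.0 - tree) * config.pasture_scale * expit(1.5 * _smooth_field(rng, shape, config.corr_cells))

    pop_latent = _smooth_field(rng, shape, config.corr_cells)
    population = np.round(np.exp(config.pop_log_mean + config.pop_log_sd * pop_latent))
    if config.uninhabited_fraction > 0:
        cutoff = np.quantile(pop_latent, config.uninhabited_fraction)
        population = np.where(pop_latent < cutoff, 0.0, population)

    area_km2 = (config.cell_size / 1000.0) ** 2
    cattle = rng.poisson(config.cattle_density * pasture * area_km2).astype(float)

    grid = LandscapeGrid(
        cell_size=config.cell_size,
        elevation=elev,
        precip=precip,
        aet=aet,
        tree_frac=tree,
        pasture_frac=pasture,
        population=population,
        cattle=cattle,
    )
    grid.validate()
    return grid


# ---------------------------------------------------------------------------
# Survey clusters


@dataclass
class ClusterRecord:
    """A DHS-style survey cluster located at a grid-cell center."""

    cluster_id: int
    true_coords: tuple[float, float]  # meters (x, y)
    urban: bool
    reported_coords: tuple[float, float] | None = None
    row: int = -1
    col: int = -1


def place_clusters(
    grid: LandscapeGrid,
    n_clusters: int,
    urban_fraction: float,
    seed: int = 0,
) -> list[ClusterRecord]:
    """Place survey clusters at distinct cell centers.

    Urban flags are iid Bernoulli(urban_fraction); urban clusters are
    sampled without replacement with probability proportional to cell
    population (so urban clusters sit in populous cells in expectation),
    rural clusters uniformly over the remaining cells.
    """
    if n_clusters < 1:
        raise ConfigurationError("n_clusters must be at least 1")
    n_cells = grid.n_rows * grid.n_cols
    if n_clusters > n_cells:
        raise ConfigurationError(f"n_clusters={n_clusters} exceeds the {n_cells} available cells")
    if not 0.0 <= urban_fraction <= 1.0:
        raise ConfigurationError("urban_fraction must be in [0, 1]")

    rng = substream(seed, "clusters")
    urban = rng.random(n_clusters) < urban_fraction
    n_urban = int(urban.sum())

    weights = grid.population.ravel() + 1.0
    all_cells = np.arange(n_cells)
    urban_cells = rng.choice(all_cells, size=n_urban, replace=False, p=weights / weights.sum())
    remaining = np.setdiff1d(all_cells, urban_cells)
    rural_cells = rng.choice(remaining, size=n_clusters - n_urban, replace=False)

    cells = np.empty(n_clusters, dtype=int)
    cells[urban] = urban_cells
    cells[~urban] = rural_cells

    records = []
    for cid, (cell, is_urban) in enumerate(zip(cells, urban)):
        r, c = divmod(int(cell), grid.n_cols)
        records.append(
            ClusterRecord(
                cluster_id=cid,
                true_coords=grid.cell_center(r, c),
                urban=bool(is_urban),
                row=r,
                col=c,
            )
        )
    return records


def displace_coordinates(
    cluster: ClusterRecord,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    bounds: tuple[float, float] | None = None,
) -> ClusterRecord:
    """Apply the DHS anonymization displacement to one cluster.

    Direction is uniform on the circle; distance is uniform on [0, cap]
    with cap 2 km for urban clusters and 5 km for rural, except that 1% of
    rural clusters draw their distance from [0, 10 km]. If ``bounds``
    (x_max, y_max) is given, reported coordinates are clipped into
    [0, x_max] x [0, y_max] — the analog of DHS keeping displaced points
    inside the survey's administrative area. Clipping projects onto a box
    that contains the true location, so it never increases the
    displacement distance and the caps continue to hold.
    """
    if rng is None:
        rng = substream(0 if seed is None else seed, "displacement")
    if cluster.urban:
        cap = URBAN_CAP_M
    elif rng.random() < RURAL_FAR_FRACTION:
        cap = RURAL_FAR_CAP_M
    else:
        cap = RURAL_CAP_M
    radius = cap * rng.random()
    angle = 2 * np.pi * rng.random()
    x, y = cluster.true_coords
    rx, ry = x + radius * np.cos(angle), y + radius * np.sin(angle)
    if bounds is not None:
        rx = float(np.clip(rx, 0.0, bounds[0]))
        ry = float(np.clip(ry, 0.0, bounds[1]))
    return replace(cluster, reported_coords=(rx, ry))


def displace_all(
    clusters: list[ClusterRecord],
    seed: int = 0,
    bounds: tuple[float, float] | None = None,
) -> list[ClusterRecord]:
    """Displace every cluster using one shared displacement stream."""
    rng = substream(seed, "displacement")
    return [displace_coordinates(c, rng=rng, bounds=bounds) for c in clusters]


def generate_cluster_climate(
    clusters: list[ClusterRecord],
    grid: LandscapeGrid,
    seed: int = 0,
    temp_mean: float = 25.0,
    temp_amplitude: float = 4.0,
    precip_amplitude_frac: float = 0.6,
) -> tuple[pd.DataFrame, pd.Series]:
    """Long-term monthly climatology per cluster plus a survey month.

    Monthly precipitation follows a sinusoidal seasonal cycle around the
    landscape's local monthly mean (with a cluster-specific phase), and
    temperature a similar cycle in degrees Celsius. Returns a long-format
    frame with columns (cluster_id, month, precip, temp) and a Series of
    survey months indexed by cluster_id.
    """
    rng = substream(seed, "climate")
    months = np.arange(1, 13)
    rows = []
    survey_months = {}
    for cl in clusters:
        base_p = float(grid.precip[cl.row, cl.col]) if cl.row >= 0 else 100.0
        phase = rng.uniform(0, 2 * np.pi)
        amp_p = precip_amplitude_frac * base_p
        amp_t = temp_amplitude * (0.5 + rng.random())
        t_off = rng.normal(0, 2.0)
        for m in months:
            ang = 2 * np.pi * (m - 1) / 12.0
            rows.append(
                {
                    "cluster_id": cl.cluster_id,
                    "month": int(m),
                    "precip": max(0.0, base_p + amp_p * np.sin(ang + phase) + rng.normal(0, 2.0)),
                    "temp": temp_mean + t_off + amp_t * np.cos(ang + phase) + rng.normal(0, 0.3),
                }
            )
        survey_months[cl.cluster_id] = int(rng.integers(1, 13))
    climatology = pd.DataFrame(rows)
    survey = pd.Series(survey_months, name="survey_month").rename_axis("cluster_id")
    return climatology, survey


# ---------------------------------------------------------------------------
# Survey simulation


def _default_beta() -> dict[str, float]:
    # Signs mirror the direction of each association in the field: wealth,
    # education, improved water/sanitation, upstream tree cover and lagged
    # precipitation protective; temperature and upstream human activity
    # adverse. Intercept set for ~10% baseline prevalence.
    return {
        "intercept": -2.2,
        "age": -0.012,  # per month
        "wealth_high": -0.32,
        "edu_secondary": -0.35,
        "improved_sanitation": -0.10,
        "improved_water": -0.22,
        "precip_lag_z": -0.08,
        "precip_change": 0.04,
        "temp_lag_z": 0.10,
        "temp_change": 0.03,
        "human_index": 0.006,  # per percentage point
        "tree_index": -0.005,  # per percentage point
    }


@dataclass
class GeneratingParams:
    """True parameters of the three-level outcome model and the survey design.

    ``beta`` holds the intercept plus the 11 fixed effects on the logit
    scale, keyed by term name. The default random-intercept SDs correspond
    to latent-scale intra-class correlations of 0.05 at the cluster level
    and 0.18 cumulatively at the household level. The default improved-water
    probabilities encode the strong urban/rural contrast in access (63% vs
    22%).

    ``interactions`` lets designed simulations add product terms to the
    linear predictor: each entry is (columns, coefficient), where columns
    name model covariates or the derived indicators "rural"
    (1 - urban) and "unimproved_water" (1 - improved_water). E.g.
    ``((("tree_index", "rural", "unimproved_water"), -0.02),)`` gives
    upstream tree cover an effect only in rural households without
    improved water.
    """

    beta: dict[str, float] = field(default_factory=_default_beta)
    sigma_cluster: float = 0.4479
    sigma_household: float = 0.7222
    n_clusters: int = 500
    households_per_cluster: int = 5
    children_per_household: int = 2
    urban_fraction: float = 0.35
    wealth_high_p: dict[str, float] = field(default_factory=lambda: {"urban": 0.65, "rural": 0.25})
    edu_secondary_p: dict[str, float] = field(default_factory=lambda: {"urban": 0.45, "rural": 0.15})
    improved_water_p: dict[str, float] = field(default_factory=lambda: {"urban": 0.63, "rural": 0.22})
    improved_sanitation_p: dict[str, float] = field(default_factory=lambda: {"urban": 0.50, "rural": 0.25})
    age_range: tuple[int, int] = (0, 59)  # months, inclusive
    interactions: tuple[tuple[tuple[str, ...], float], ...] = ()

    def validate(self) -> list[str]:
        findings = []
        if self.sigma_cluster < 0:
            findings.append(f"sigma_cluster must be nonnegative, got {self.sigma_cluster}")
        if self.sigma_household < 0:
            findings.append(f"sigma_household must be nonnegative, got {self.sigma_household}")
        for name in ("n_clusters", "households_per_cluster", "children_per_household"):
            if getattr(self, name) < 1:
                findings.append(f"{name} must be at least 1")
        if not 0.0 <= self.urban_fraction <= 1.0:
            findings.append(f"urban_fraction must be in [0, 1], got {self.urban_fraction}")
        for name in ("wealth_high_p", "edu_secondary_p", "improved_water_p", "improved_sanitation_p"):
            probs = getattr(self, name)
            for stratum in ("urban", "rural"):
                p = probs.get(stratum)
                if p is None or not 0.0 <= p <= 1.0:
                    findings.append(f"{name}[{stratum!r}] must be a probability in [0, 1]")
        missing = {"intercept", *MODEL_TERMS} - set(self.beta)
        if missing:
            findings.append(f"beta is missing terms: {sorted(missing)}")
        lo, hi = self.age_range
        if not (0 <= lo <= hi <= 59):
            findings.append(f"age_range must satisfy 0 <= lo <= hi <= 59, got {self.age_range}")
        return findings

    @property
    def n_children(self) -> int:
        return self.n_clusters * self.households_per_cluster * self.children_per_household


def simulate_survey(
    clusters: list[ClusterRecord],
    params: GeneratingParams,
    environment: pd.DataFrame,
    seed: int = 0,
    return_prob: bool = False,
) -> pd.DataFrame:
    """Simulate child-level outcomes from the three-level logit.

    ``environment`` must contain one row per cluster (indexed by, or with a
    column, ``cluster_id``) holding the cluster-level model covariates:
    human_index, tree_index, precip_lag_z, precip_change, temp_lag_z,
    temp_change. Household covariates are drawn with urban/rural-specific
    probabilities; ages are uniform over ``params.age_range``.

    Returns one row per child with identifiers, the binary outcome, and
    child/household covariates. Cluster environment columns are joined on
    later by the covariate-assembly stage. With ``return_prob`` the table
    additionally carries the true outcome probability per child (column
    ``p``), conditional on the drawn random effects.
    """
    findings = params.validate()
    if findings:
        raise ConfigurationError("; ".join(findings))
    if len(clusters) != params.n_clusters:
        raise ConfigurationError(
            f"got {len(clusters)} clusters but params.n_clusters={params.n_clusters}"
        )
    env = environment.set_index("cluster_id") if "cluster_id" in environment.columns else environment
    needed = ["human_index", "tree_index", "precip_lag_z", "precip_change", "temp_lag_z", "temp_change"]
    for cl in clusters:
        if cl.cluster_id not in env.index:
            raise KeyError(f"no environment values for cluster {cl.cluster_id}")
    missing_cols = [c for c in needed if c not in env.columns]
    if missing_cols:
        raise KeyError(f"environment is missing columns: {missing_cols}")

    rng = substream(seed, "survey")
    K = params.n_clusters
    H = params.households_per_cluster
    C = params.children_per_household
    n = K * H * C

    cluster_ids = np.array([cl.cluster_id for cl in clusters])
    urban = np.array([cl.urban for cl in clusters], dtype=bool)
    env_vals = env.loc[cluster_ids, needed].to_numpy(dtype=float)  # (K, 6)

    # index maps child -> cluster / household
    child_cl = np.repeat(np.arange(K), H * C)
    child_hh = np.repeat(np.arange(K * H), C)
    hh_cl = np.repeat(np.arange(K), H)

    v = params.sigma_cluster * rng.standard_normal(K)
    u = params.sigma_household * rng.standard_normal(K * H)

    def hh_draw(probs: dict[str, float]) -> np.ndarray:
        p = np.where(urban[hh_cl], probs["urban"], probs["rural"])
        return (rng.random(K * H) < p).astype(int)

    wealth = hh_draw(params.wealth_high_p)
    edu = hh_draw(params.edu_secondary_p)
    water = hh_draw(params.improved_water_p)
    sanitation = hh_draw(params.improved_sanitation_p)
    lo, hi = params.age_range
    age = rng.integers(lo, hi + 1, size=n)

    b = params.beta
    eta = (
        b["intercept"]
        + b["age"] * age
        + b["wealth_high"] * wealth[child_hh]
        + b["edu_secondary"] * edu[child_hh]
        + b["improved_sanitation"] * sanitation[child_hh]
        + b["improved_water"] * water[child_hh]
        + b["precip_lag_z"] * env_vals[child_cl, 2]
        + b["precip_change"] * env_vals[child_cl, 3]
        + b["temp_lag_z"] * env_vals[child_cl, 4]
        + b["temp_change"] * env_vals[child_cl, 5]
        + b["human_index"] * env_vals[child_cl, 0]
        + b["tree_index"] * env_vals[child_cl, 1]
        + v[child_cl]
        + u[child_hh]
    )
    if params.interactions:
        columns = {
            "age": age,
            "wealth_high": wealth[child_hh],
            "edu_secondary": edu[child_hh],
            "improved_sanitation": sanitation[child_hh],
            "improved_water": water[child_hh],
            "urban": urban[child_cl].astype(float),
            "rural": 1.0 - urban[child_cl],
            "unimproved_water": 1.0 - water[child_hh],
            "human_index": env_vals[child_cl, 0],
            "tree_index": env_vals[child_cl, 1],
            "precip_lag_z": env_vals[child_cl, 2],
            "precip_change": env_vals[child_cl, 3],
            "temp_lag_z": env_vals[child_cl, 4],
            "temp_change": env_vals[child_cl, 5],
        }
        for cols, coef in params.interactions:
            term = np.full(n, coef)
            for c in cols:
                if c not in columns:
                    raise ConfigurationError(f"unknown interaction column {c!r}")
                term = term * columns[c]
            eta = eta + term
    prob = expit(eta)
    y = (rng.random(n) < prob).astype(int)

    table = pd.DataFrame(
        {
            "child_id": np.arange(n),
            "household_id": child_hh,
            "cluster_id": cluster_ids[child_cl],
            "urban": urban[child_cl].astype(int),
            "diarrhea": y,
            "age": age,
            "wealth_high": wealth[child_hh],
            "edu_secondary": edu[child_hh],
            "improved_sanitation": sanitation[child_hh],
            "improved_water": water[child_hh],
        }
    )
    if return_prob:
        table["p"] = prob
    return table
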