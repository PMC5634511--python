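import numpy as np
import pytest
from hypothesis import settings

from watershed_health import covariate_assembly as ca
from watershed_health import hydro_routing as hr
from watershed_health import synthetic_data as sd

settings.register_profile("suite", derandomize=True, max_examples=30, deadline=None)
settings.load_profile("suite")


def build_study_table(seed: int, params: sd.GeneratingParams | None = None):
    """Full synthetic study: landscape -> routing -> climate -> survey -> table."""
    params = params or sd.GeneratingParams()
    grid = sd.generate_landscape(sd.LandscapeConfig(), seed=seed)
    clusters = sd.place_clusters(grid, params.n_clusters, params.urban_fraction, seed=seed)
    extent = (grid.n_cols * grid.cell_size, grid.n_rows * grid.cell_size)
    clusters = sd.displace_all(clusters, seed=seed, bounds=extent)
    indices = hr.route_indices(grid)
    index_table = hr.cluster_index_table(indices, clusters, grid.cell_size)
    climatology, survey_month = sd.generate_cluster_climate(clusters, grid, seed=seed)
    env = index_table[["human_index", "tree_index"]].join(
        ca.standardize_climate(climatology, survey_month)
    )
    survey = sd.simulate_survey(clusters, params, env, seed=seed)
    return ca.build_table(survey, env), env, clusters, grid


@pytest.fixture(scope="session")
def study():
    """One survey generated under the default study conditions."""
    table, env, clusters, grid = build_study_table(seed=11)
    return {"table": table, "env": env, "clusters": clusters, "grid": grid}


@pytest.fixture(scope="session")
def study_fit(study):
    """The three-level fit of the default synthetic study."""
    from watershed_health import model_fit as mf

    return mf.fit_three_level_logit(study["table"])


@pytest.fixture
def small_grid():
    return sd.generate_landscape(sd.LandscapeConfig(n_rows=20, n_cols=20), seed=5)


def descent_reaches_edge(elevation: np.ndarray, start: tuple[int, int]) -> bool:
    """Brute-force oracle: follow any strictly lower neighbor to the edge."""
    n_rows, n_cols = elevation.shape
    r, c = start
    for _ in range(n_rows * n_cols + 1):
        if r in (0, n_rows - 1) or c in (0, n_cols - 1):
            return True
        best = None
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if elevation[rr, cc] < elevation[r, c]:
                    if best is None or elevation[rr, cc] < elevation[best]:
                        best = (rr, cc)
        if best is None:
            return False  # enclosed pit
        r, c = best
    return False
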