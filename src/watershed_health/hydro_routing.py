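"""Flow routing and upstream water-source indices on a raster drainage net.

Each cell contributes monthly runoff (precipitation minus actual
evapotranspiration, floored at zero) to a single-downstream-neighbor (D8)
drainage network. A fraction of each cell's runoff is tagged — as having
fallen on land impacted by people or livestock, or on tree-covered land —
and both tagged and total water are accumulated downstream. The index at a
cell is the tagged share of accumulated water, in percent:

    index = 100 * tagged / total   (0 when total water is 0).

A value of 100 means all water at the cell fell as rain on tagged land; 0
means no tagged upstream land, or no water at all.

The human-activity tag combines a per-person ground-contamination
footprint of 3.65 m^2 per year with a pasture rule: all pasture in a cell
counts as polluted whenever the cell's cattle headcount is positive. The
two parts add and are capped at the full cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import RoutingError
from .synthetic_data import ClusterRecord, LandscapeGrid

__all__ = [
    "FlowNetwork",
    "RoutedIndices",
    "HUMAN_FOOTPRINT_M2",
    "water_balance",
    "contaminated_fraction",
    "derive_flow_network",
    "accumulate",
    "index_from_accumulation",
    "route_indices",
    "aggregate_at_cluster",
    "upstream_oracle",
]

#: Ground area assumed contaminated per person, m^2 per year.
HUMAN_FOOTPRINT_M2 = 3.65

# D8 neighbor offsets in fixed precedence order (ties in steepest descent
# resolve to the earliest entry): E, SE, S, SW, W, NW, N, NE.
_D8_OFFSETS = ((0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1))


@dataclass
class FlowNetwork:
    """Single-downstream-neighbor drainage graph over grid cells.

    ``downstream`` maps each flat cell index to the flat index of its
    steepest-descent neighbor, or -1 for an outlet. ``topo_order`` lists
    every cell before its downstream neighbor.
    """

    shape: tuple[int, int]
    downstream: np.ndarray  # (n_cells,) int, -1 = outlet
    topo_order: np.ndarray  # (n_cells,) int permutation

    @property
    def n_cells(self) -> int:
        return self.shape[0] * self.shape[1]

    def validate(self) -> None:
        n = self.n_cells
        if self.downstream.shape != (n,) or self.topo_order.shape != (n,):
            raise RoutingError("downstream and topo_order must have one entry per cell")
        if sorted(self.topo_order.tolist()) != list(range(n)):
            raise RoutingError("topo_order is not a permutation of the cells")
        # one pass: every cell must appear before the cell it drains to
        position = np.empty(n, dtype=int)
        position[self.topo_order] = np.arange(n)
        has_down = self.downstream >= 0
        src = np.arange(n)[has_down]
        dst = self.downstream[has_down]
        if np.any(position[src] >= position[dst]):
            raise RoutingError("topo_order inconsistent with downstream pointers (cycle?)")


@dataclass
class RoutedIndices:
    """Accumulated water and upstream source-share indices per cell."""

    total_water: np.ndarray  # mm * m^2 (volume units)
    human_index: np.ndarray  # percent [0, 100]
    tree_index: np.ndarray  # percent [0, 100]


def water_balance(precip: np.ndarray, aet: np.ndarray) -> np.ndarray:
    """Monthly runoff: rainfall minus actual evapotranspiration, floored at 0."""
    precip = np.asarray(precip, dtype=float)
    aet = np.asarray(aet, dtype=float)
    if np.any(precip < 0) or np.any(aet < 0):
        raise ValueError("precip and aet must be nonnegative")
    return np.maximum(precip - aet, 0.0)


def contaminated_fraction(
    population: np.ndarray | float,
    cattle: np.ndarray | float,
    pasture_frac: np.ndarray | float,
    cell_area: float,
) -> np.ndarray:
    """Fraction of a cell's ground tagged as human/livestock-impacted.

    Human part: population * 3.65 m^2 footprint / cell area, capped at 1.
    Pasture part: the full pasture fraction whenever cattle are present.
    The parts add, capped at the full cell.
    """
    if cell_area <= 0:
        raise ValueError(f"cell_area must be positive, got {cell_area}")
    population = np.asarray(population, dtype=float)
    cattle = np.asarray(cattle, dtype=float)
    pasture_frac = np.asarray(pasture_frac, dtype=float)
    if np.any(population < 0) or np.any(cattle < 0) or np.any(pasture_frac < 0):
        raise ValueError("population, cattle and pasture_frac must be nonnegative")
    human = np.minimum(1.0, population * HUMAN_FOOTPRINT_M2 / cell_area)
    pasture = np.where(cattle > 0, pasture_frac, 0.0)
    return np.minimum(1.0, human + pasture)


def derive_flow_network(grid: LandscapeGrid) -> FlowNetwork:
    """Build the D8 network: each cell drains to its steepest-descent neighbor.

    Requires pit-free elevation. Edge cells with no strictly lower neighbor
    are outlets; an interior cell with no strictly lower neighbor is a pit
    and raises, instructing pit-filling. Ties in steepest descent resolve by
    the fixed neighbor precedence E, SE, S, SW, W, NW, N, NE.
    """
    z = np.asarray(grid.elevation, dtype=float)
    n_rows, n_cols = z.shape
    n = n_rows * n_cols

    best_slope = np.full((n_rows, n_cols), -np.inf)
    best_nb = np.full((n_rows, n_cols), -1, dtype=int)
    for dr, dc in _D8_OFFSETS:
        dist = np.hypot(dr, dc)
        r0, r1 = max(0, -dr), min(n_rows, n_rows - dr)
        c0, c1 = max(0, -dc), min(n_cols, n_cols - dc)
        slope = np.full((n_rows, n_cols), -np.inf)
        slope[r0:r1, c0:c1] = (z[r0:r1, c0:c1] - z[r0 + dr : r1 + dr, c0 + dc : c1 + dc]) / dist
        take = slope > best_slope  # strict: earlier offsets win ties
        best_slope = np.where(take, slope, best_slope)
        rows, cols = np.nonzero(take)
        best_nb[rows, cols] = (rows + dr) * n_cols + (cols + dc)

    downstream = np.where(best_slope.ravel() > 0, best_nb.ravel(), -1)

    interior = np.ones((n_rows, n_cols), dtype=bool)
    interior[0, :] = interior[-1, :] = interior[:, 0] = interior[:, -1] = False
    pits = (best_slope <= 0) & interior
    if pits.any():
        r, c = np.argwhere(pits)[0]
        raise RoutingError(
            f"pit at cell ({r}, {c}): no strictly lower neighbor; run priority_flood_fill first"
        )

    # downstream cells are strictly lower, so descending elevation is a
    # valid topological order
    topo = np.argsort(-z.ravel(), kind="stable")
    net = FlowNetwork(shape=(n_rows, n_cols), downstream=downstream, topo_order=topo)
    net.validate()
    return net


def accumulate(
    network: FlowNetwork,
    runoff: np.ndarray,
    source_frac: np.ndarray,
    cell_area: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Route runoff downstream, tracking total and source-tagged water.

    In topological order, each cell passes its own runoff volume (runoff *
    cell area, of which ``source_frac`` is tagged) plus everything received
    from upstream to its single downstream neighbor. Returns flat arrays
    (total, tagged); tagged <= total everywhere.
    """
    network.validate()
    runoff = np.asarray(runoff, dtype=float).ravel()
    source_frac = np.asarray(source_frac, dtype=float).ravel()
    if np.any(runoff < 0):
        raise ValueError("runoff must be nonnegative")
    if np.any((source_frac < 0) | (source_frac > 1)):
        raise ValueError("source_frac must lie in [0, 1]")

    total = runoff * cell_area
    tagged = total * source_frac
    down = network.downstream
    for c in network.topo_order:
        d = down[c]
        if d >= 0:
            total[d] += total[c]
            tagged[d] += tagged[c]
    return total, tagged


def index_from_accumulation(tagged: np.ndarray, total: np.ndarray) -> np.ndarray:
    """Tagged share of accumulated water, percent; 0 where there is no water."""
    tagged = np.asarray(tagged, dtype=float)
    total = np.asarray(total, dtype=float)
    if np.any(tagged > total * (1 + 1e-12) + 1e-300):
        raise ValueError("tagged water exceeds total water")
    with np.errstate(invalid="ignore", divide="ignore"):
        index = np.where(total > 0, 100.0 * tagged / total, 0.0)
    return np.clip(index, 0.0, 100.0)


def route_indices(grid: LandscapeGrid, network: FlowNetwork | None = None) -> RoutedIndices:
    """Full routing pipeline for a landscape: runoff, tagging, accumulation.

    Computes both the upstream human-activity index (footprint + pasture
    tagging) and the upstream tree-cover index (tree-fraction tagging).
    """
    if network is None:
        network = derive_flow_network(grid)
    runoff = water_balance(grid.precip, grid.aet)
    human_frac = contaminated_fraction(grid.population, grid.cattle, grid.pasture_frac, grid.cell_area)
    total, tagged_h = accumulate(network, runoff, human_frac, grid.cell_area)
    _, tagged_t = accumulate(network, runoff, grid.tree_frac, grid.cell_area)
    shape = (grid.n_rows, grid.n_cols)
    return RoutedIndices(
        total_water=total.reshape(shape),
        human_index=index_from_accumulation(tagged_h, total).reshape(shape),
        tree_index=index_from_accumulation(tagged_t, total).reshape(shape),
    )


def aggregate_at_cluster(
    indices: RoutedIndices,
    coords: tuple[float, float],
    cell_size: float,
    window: float = 10_000.0,
) -> dict[str, float]:
    """Average each index over cells whose centers fall in a square window.

    The window (default 10 km on a side, one aggregation cell of the
    environmental layers) is centered on the cluster's reported
    coordinates; averaging over it absorbs the anonymization displacement.
    """
    n_rows, n_cols = indices.human_index.shape
    x, y = coords
    half = window / 2.0
    cols = np.arange(n_cols)
    rows = np.arange(n_rows)
    cx = (cols + 0.5) * cell_size
    cy = (rows + 0.5) * cell_size
    in_x = np.abs(cx - x) <= half
    in_y = np.abs(cy - y) <= half
    if not in_x.any() or not in_y.any():
        raise ValueError(f"window of {window} m at {coords} contains no cell centers")
    mask = np.ix_(in_y, in_x)
    return {
        "human_index": float(indices.human_index[mask].mean()),
        "tree_index": float(indices.tree_index[mask].mean()),
        "total_water": float(indices.total_water[mask].mean()),
        "n_cells": int(in_x.sum() * in_y.sum()),
    }


def cluster_index_table(
    indices: RoutedIndices,
    clusters: list[ClusterRecord],
    cell_size: float,
    window: float = 10_000.0,
) -> pd.DataFrame:
    """Per-cluster aggregated indices as a DataFrame keyed by cluster_id."""
    rows = []
    for cl in clusters:
        coords = cl.reported_coords if cl.reported_coords is not None else cl.true_coords
        agg = aggregate_at_cluster(indices, coords, cell_size, window)
        rows.append({"cluster_id": cl.cluster_id, **agg})
    return pd.DataFrame(rows).set_index("cluster_id")


def flow_network_to_frame(network: FlowNetwork) -> pd.DataFrame:
    """Two-column cell -> downstream-cell table (-1 marks outlets)."""
    return pd.DataFrame(
        {"cell": np.arange(network.n_cells), "downstream": network.downstream}
    )


def flow_network_from_frame(df: pd.DataFrame, shape: tuple[int, int]) -> FlowNetwork:
    """Rebuild a network from its two-column export; recomputes a valid order."""
    down = np.full(shape[0] * shape[1], -1, dtype=int)
    down[df["cell"].to_numpy()] = df["downstream"].to_numpy()
    # Kahn's algorithm for a topological order
    n = len(down)
    indegree = np.zeros(n, dtype=int)
    for d in down:
        if d >= 0:
            indegree[d] += 1
    queue = [c for c in range(n) if indegree[c] == 0]
    order = []
    while queue:
        c = queue.pop()
        order.append(c)
        d = down[c]
        if d >= 0:
            indegree[d] -= 1
            if indegree[d] == 0:
                queue.append(d)
    if len(order) != n:
        raise RoutingError("cycle in imported flow network")
    net = FlowNetwork(shape=shape, downstream=down, topo_order=np.array(order))
    net.validate()
    return net


def upstream_oracle(
    network: FlowNetwork,
    runoff: np.ndarray,
    source_frac: np.ndarray,
    cell: int,
    cell_area: float = 1.0,
) -> float:
    """Index at one cell by explicit enumeration of its full upstream set.

    Independent of the accumulation pass: walks the reversed drainage graph
    from the cell, collects every upstream contributor, and sums runoff and
    tagged runoff directly. Intended for small grids.
    """
    runoff = np.asarray(runoff, dtype=float).ravel()
    source_frac = np.asarray(source_frac, dtype=float).ravel()
    n = network.n_cells
    upstream_of: list[list[int]] = [[] for _ in range(n)]
    for c, d in enumerate(network.downstream):
        if d >= 0:
            upstream_of[d].append(c)
    members = set()
    stack = [int(cell)]
    while stack:
        c = stack.pop()
        if c in members:
            continue
        members.add(c)
        stack.extend(upstream_of[c])
    total = sum(runoff[c] * cell_area for c in members)
    tagged = sum(runoff[c] * cell_area * source_frac[c] for c in members)
    return 100.0 * tagged / total if total > 0 else 0.0
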