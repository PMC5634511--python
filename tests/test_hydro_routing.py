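"""Water routing: balance, tagging, D8 networks, accumulation, indices.

The central correctness check compares the linear-time accumulation pass
against a brute-force oracle that enumerates every cell's full upstream
set explicitly.
"""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from watershed_health import hydro_routing as hr
from watershed_health import synthetic_data as sd
from watershed_health.errors import RoutingError


def random_grid(seed, n=30):
    return sd.generate_landscape(sd.LandscapeConfig(n_rows=n, n_cols=n), seed=seed)


def chain_network(n=3):
    """n cells in a row, each draining to the next, last is the outlet."""
    down = np.r_[np.arange(1, n), -1]
    return hr.FlowNetwork(shape=(1, n), downstream=down, topo_order=np.arange(n))


class TestWaterBalance:
    @pytest.mark.parametrize("p,a,expected", [(100.0, 40.0, 60.0), (30.0, 50.0, 0.0)])
    def test_examples(self, p, a, expected):
        assert hr.water_balance(np.array([p]), np.array([a]))[0] == expected

    def test_matches_elementwise_loop(self):
        rng = np.random.default_rng(0)
        p, a = rng.uniform(0, 200, (10, 10)), rng.uniform(0, 120, (10, 10))
        out = hr.water_balance(p, a)
        for i in range(10):
            for j in range(10):
                assert out[i, j] == max(p[i, j] - a[i, j], 0.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            hr.water_balance(np.array([-1.0]), np.array([0.0]))


class TestContaminatedFraction:
    def test_no_sources_gives_zero(self):
        assert hr.contaminated_fraction(0, 0, 0.9, 100.0) == 0.0

    def test_footprint_of_one_person(self):
        assert hr.contaminated_fraction(1, 0, 0.0, 100.0) == pytest.approx(0.0365)

    def test_people_plus_pasture(self):
        # 10 people on 100 m^2 -> 0.365; cattle present -> pasture 0.5 counts
        assert hr.contaminated_fraction(10, 5, 0.5, 100.0) == pytest.approx(0.865)

    def test_pasture_ignored_without_cattle(self):
        assert hr.contaminated_fraction(0, 0, 0.5, 100.0) == 0.0
        assert hr.contaminated_fraction(0, 1, 0.5, 100.0) == 0.5

    def test_capped_at_one(self):
        assert hr.contaminated_fraction(1000, 1, 1.0, 100.0) == 1.0

    def test_bad_area_rejected(self):
        with pytest.raises(ValueError):
            hr.contaminated_fraction(1, 0, 0.0, 0.0)

    @given(
        pop=st.floats(0, 1e6),
        cattle=st.floats(0, 1e4),
        pasture=st.floats(0, 1),
        area=st.floats(1.0, 1e8),
    )
    def test_always_a_fraction(self, pop, cattle, pasture, area):
        f = hr.contaminated_fraction(pop, cattle, pasture, area)
        assert 0.0 <= f <= 1.0


class TestAccumulate:
    def test_three_cell_chain_headwater_tagged(self):
        net = chain_network(3)
        total, tagged = hr.accumulate(net, np.ones(3), np.array([1.0, 0.0, 0.0]))
        assert total[-1] == pytest.approx(3.0)
        assert tagged[-1] / total[-1] == pytest.approx(1 / 3)

    def test_full_tagging_means_tagged_equals_total(self):
        net = chain_network(5)
        total, tagged = hr.accumulate(net, np.arange(1.0, 6.0), np.ones(5))
        np.testing.assert_allclose(tagged, total)

    def test_no_water_everywhere(self):
        net = chain_network(4)
        total, tagged = hr.accumulate(net, np.zeros(4), np.ones(4))
        assert (total == 0).all() and (tagged == 0).all()

    def test_cyclic_network_rejected(self):
        net = hr.FlowNetwork(
            shape=(1, 2), downstream=np.array([1, 0]), topo_order=np.array([0, 1])
        )
        with pytest.raises(RoutingError):
            hr.accumulate(net, np.ones(2), np.zeros(2))

    def test_tagged_never_exceeds_total(self):
        grid = random_grid(4)
        net = hr.derive_flow_network(grid)
        runoff = hr.water_balance(grid.precip, grid.aet)
        total, tagged = hr.accumulate(net, runoff, grid.tree_frac, grid.cell_area)
        assert (tagged <= total * (1 + 1e-12)).all()


class TestIndex:
    def test_fully_tagged_is_100(self):
        assert hr.index_from_accumulation(np.array([5.0]), np.array([5.0]))[0] == 100.0

    def test_no_water_is_0(self):
        assert hr.index_from_accumulation(np.array([0.0]), np.array([0.0]))[0] == 0.0

    def test_one_third(self):
        out = hr.index_from_accumulation(np.array([1.0]), np.array([3.0]))
        assert out[0] == pytest.approx(33.3333333333)

    def test_tagged_above_total_rejected(self):
        with pytest.raises(ValueError):
            hr.index_from_accumulation(np.array([2.0]), np.array([1.0]))


class TestFlowNetwork:
    def test_tilted_plane_flows_downslope(self):
        grid = sd.generate_landscape(
            sd.LandscapeConfig(n_rows=8, n_cols=8, relief=0.0, tilt=5.0), seed=0
        )
        net = hr.derive_flow_network(grid)
        down = net.downstream.reshape(8, 8)
        # south edge cells are outlets; everyone else points due south
        assert (down[-1, :] == -1).all()
        for r in range(7):
            for c in range(8):
                assert down[r, c] == (r + 1) * 8 + c

    def test_cone_drains_to_single_outlet(self):
        rr, cc = np.meshgrid(np.arange(9), np.arange(9), indexing="ij")
        elev = np.hypot(rr - 0, cc - 0)  # outlet at corner (0, 0)
        grid = sd.generate_landscape(sd.LandscapeConfig(n_rows=9, n_cols=9), seed=0)
        grid.elevation = elev
        net = hr.derive_flow_network(grid)
        for cell in range(81):
            c, steps = cell, 0
            while net.downstream[c] >= 0:
                c = net.downstream[c]
                steps += 1
                assert steps <= 81
            assert c == 0

    def test_pit_raises_with_instruction(self):
        grid = sd.generate_landscape(sd.LandscapeConfig(n_rows=7, n_cols=7), seed=0)
        z = np.full((7, 7), 5.0)
        z[3, 3] = 0.0
        grid.elevation = z
        with pytest.raises(RoutingError, match="pit"):
            hr.derive_flow_network(grid)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_random_grid_acyclic_by_traversal(self, seed):
        grid = random_grid(seed)
        net = hr.derive_flow_network(grid)
        n = net.n_cells
        for start in range(n):
            c, steps = start, 0
            while net.downstream[c] >= 0:
                c = net.downstream[c]
                steps += 1
                assert steps <= n, "cycle detected"

    def test_inconsistent_topo_order_rejected(self):
        net = chain_network(3)
        net.topo_order = np.array([2, 1, 0])  # outlet first: invalid
        with pytest.raises(RoutingError):
            net.validate()


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [10, 11])
    def test_pipeline_equals_upstream_enumeration(self, seed):
        grid = random_grid(seed, n=25)
        net = hr.derive_flow_network(grid)
        runoff = hr.water_balance(grid.precip, grid.aet)
        frac = hr.contaminated_fraction(
            grid.population, grid.cattle, grid.pasture_frac, grid.cell_area
        )
        total, tagged = hr.accumulate(net, runoff, frac, grid.cell_area)
        index = hr.index_from_accumulation(tagged, total)
        for cell in range(net.n_cells):
            oracle = hr.upstream_oracle(net, runoff, frac, cell, grid.cell_area)
            assert index[cell] == pytest.approx(oracle, rel=1e-9, abs=1e-9)

    def test_mass_conservation_at_outlets(self):
        grid = random_grid(12)
        net = hr.derive_flow_network(grid)
        runoff = hr.water_balance(grid.precip, grid.aet)
        total, _ = hr.accumulate(net, runoff, np.zeros(net.n_cells), grid.cell_area)
        outlets = np.flatnonzero(net.downstream < 0)
        assert total[outlets].sum() == pytest.approx(
            runoff.sum() * grid.cell_area, rel=1e-9
        )


class TestRoutingProperties:
    @pytest.mark.parametrize("seed", [21, 22, 23])
    def test_indices_bounded(self, seed):
        grid = random_grid(seed, n=20)
        idx = hr.route_indices(grid)
        for layer in (idx.human_index, idx.tree_index):
            assert (layer >= 0).all() and (layer <= 100).all()

    def test_more_upstream_tree_cover_never_lowers_downstream_index(self):
        grid = random_grid(31, n=15)
        net = hr.derive_flow_network(grid)
        runoff = hr.water_balance(grid.precip, grid.aet)
        base_total, base_tagged = hr.accumulate(net, runoff, grid.tree_frac, grid.cell_area)
        base_idx = hr.index_from_accumulation(base_tagged, base_total)
        rng = np.random.default_rng(0)
        for cell in rng.choice(net.n_cells, 10, replace=False):
            frac = grid.tree_frac.ravel().copy()
            frac[cell] = min(1.0, frac[cell] + 0.3)
            total, tagged = hr.accumulate(net, runoff, frac, grid.cell_area)
            idx = hr.index_from_accumulation(tagged, total)
            # walk downstream from the perturbed cell
            c = cell
            while c >= 0:
                assert idx[c] >= base_idx[c] - 1e-12
                c = net.downstream[c]

    def test_untagged_runoff_upstream_dilutes_downstream_index(self):
        grid = random_grid(32, n=15)
        net = hr.derive_flow_network(grid)
        runoff = hr.water_balance(grid.precip, grid.aet).ravel()
        frac = grid.tree_frac.ravel().copy()
        rng = np.random.default_rng(1)
        base_total, base_tagged = hr.accumulate(net, runoff, frac, grid.cell_area)
        base_idx = hr.index_from_accumulation(base_tagged, base_total)
        for cell in rng.choice(net.n_cells, 10, replace=False):
            runoff2 = runoff.copy()
            runoff2[cell] += 50.0
            frac2 = frac.copy()
            frac2[cell] = 0.0  # the extra water is untagged
            total, tagged = hr.accumulate(net, runoff2, frac2, grid.cell_area)
            idx = hr.index_from_accumulation(tagged, total)
            c = net.downstream[cell]
            while c >= 0:
                assert idx[c] <= base_idx[c] + 1e-12
                c = net.downstream[c]


class TestAggregation:
    def _indices(self, values):
        arr = np.asarray(values, dtype=float)
        return hr.RoutedIndices(total_water=np.ones_like(arr), human_index=arr, tree_index=arr)

    def test_single_cell_window(self):
        idx = self._indices(np.arange(9.0).reshape(3, 3))
        out = hr.aggregate_at_cluster(idx, coords=(1500.0, 1500.0), cell_size=1000.0, window=900.0)
        assert out["human_index"] == 4.0 and out["n_cells"] == 1

    def test_uniform_field_window_invariant(self):
        idx = self._indices(np.full((5, 5), 7.0))
        for window in (900.0, 2500.0, 4900.0):
            out = hr.aggregate_at_cluster(idx, (2500.0, 2500.0), 1000.0, window)
            assert out["tree_index"] == pytest.approx(7.0)

    def test_three_by_three_mean(self):
        vals = np.arange(25.0).reshape(5, 5)
        idx = self._indices(vals)
        out = hr.aggregate_at_cluster(idx, (2500.0, 2500.0), 1000.0, 2500.0)
        assert out["n_cells"] == 9
        assert out["human_index"] == pytest.approx(vals[1:4, 1:4].mean())

    def test_empty_window_rejected(self):
        idx = self._indices(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            hr.aggregate_at_cluster(idx, (50_000.0, 50_000.0), 1000.0, 900.0)


class TestNetworkExport:
    def test_round_trip_preserves_routing(self, small_grid):
        net = hr.derive_flow_network(small_grid)
        back = hr.flow_network_from_frame(hr.flow_network_to_frame(net), net.shape)
        np.testing.assert_array_equal(back.downstream, net.downstream)
        runoff = hr.water_balance(small_grid.precip, small_grid.aet)
        t1, _ = hr.accumulate(net, runoff, small_grid.tree_frac, small_grid.cell_area)
        t2, _ = hr.accumulate(back, runoff, small_grid.tree_frac, small_grid.cell_area)
        np.testing.assert_allclose(t1, t2)

    def test_cycle_rejected_on_import(self):
        df = hr.flow_network_to_frame(chain_network(3))
        df.loc[2, "downstream"] = 0  # outlet now points back: cycle
        with pytest.raises(RoutingError, match="cycle"):
            hr.flow_network_from_frame(df, (1, 3))


class TestUpstreamOracleBoundaries:
    def test_outlet_of_fully_tagged_grid_is_100(self):
        net = chain_network(4)
        assert hr.upstream_oracle(net, np.ones(4), np.ones(4), 3) == pytest.approx(100.0)

    def test_untagged_headwater_is_0(self):
        net = chain_network(4)
        assert hr.upstream_oracle(net, np.ones(4), np.zeros(4), 0) == 0.0
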