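import heapq

import numpy as np
import pytest

from ecopattern.grid import CategoricalRaster, Raster, VectorSet, class_area_table
from ecopattern.security import (
    RESISTANCE_TABLE,
    SECURITY_LEVELS,
    cost_distance,
    ecological_nodes,
    identify_sources,
    least_cost_corridors,
    least_cost_path,
    resistance_surface,
    ridge_valley_lines,
    river_corridors,
    security_index,
)
from ecopattern.synth import LANDUSE_CLASSES


def dijkstra_oracle(res, cell_size, src, dst=None):
    """Textbook heap Dijkstra over the 8-neighbor grid graph."""
    nr, nc = res.shape
    dist = np.full((nr, nc), np.inf)
    dist[src] = 0.0
    heap = [(0.0, src)]
    while heap:
        d, (r, c) = heapq.heappop(heap)
        if d > dist[r, c]:
            continue
        if dst is not None and (r, c) == dst:
            return d
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < nr and 0 <= cc < nc:
                    step = cell_size * (np.sqrt(2) if dr and dc else 1.0)
                    w = 0.5 * (res[r, c] + res[rr, cc]) * step
                    if d + w < dist[rr, cc]:
                        dist[rr, cc] = d + w
                        heapq.heappush(heap, (d + w, (rr, cc)))
    return dist


def five_level(codes):
    return CategoricalRaster(SECURITY_LEVELS, np.asarray(codes, dtype=int))


class TestSecurityIndex:
    def test_best_case_scores_one(self):
        sec = security_index(five_level([[4]]), five_level([[0]]),
                             five_level([[4]]))
        assert sec.score.values[0, 0] == pytest.approx(1.0)
        assert sec.classes.labels[sec.classes.values[0, 0]] == "highest"

    def test_sensitivity_polarity(self):
        # flipping the sensitivity rank r -> 4 - r and negating the
        # polarity inside the formula returns identical scores
        a = security_index(five_level([[2]]), five_level([[1]]),
                           five_level([[3]]))
        manual = (1 / 3) * (2 / 4) + (1 / 3) * (1 - 1 / 4) + (1 / 3) * (3 / 4)
        assert a.score.values[0, 0] == pytest.approx(manual)

    def test_weighted_sum_oracle(self, rng):
        imp = five_level(rng.integers(0, 5, (10, 10)))
        sen = five_level(rng.integers(0, 5, (10, 10)))
        con = five_level(rng.integers(0, 5, (10, 10)))
        w = (0.5, 0.2, 0.3)
        sec = security_index(imp, sen, con, w)
        for r in range(10):
            for c in range(10):
                expected = (w[0] * imp.values[r, c] / 4
                            + w[1] * (1 - sen.values[r, c] / 4)
                            + w[2] * con.values[r, c] / 4)
                assert sec.score.values[r, c] == pytest.approx(expected)

    def test_bad_weights(self):
        with pytest.raises(ValueError):
            security_index(five_level([[0]]), five_level([[0]]),
                           five_level([[0]]), weights=(1.0, 1.0, 1.0))


class TestIdentifySources:
    def block_security(self):
        codes = np.zeros((12, 12), dtype=int)
        codes[2:7, 2:7] = 4  # 25-cell highest block
        codes[8:11, 8:11] = 3  # 9-cell higher block
        return five_level(codes)

    def test_single_block_centroid(self):
        sources = identify_sources(self.block_security(), min_area=1.0)
        assert len(sources.primary) == 1
        assert len(sources.secondary) == 1
        patch = sources.primary[0]
        assert patch.area == pytest.approx(25.0)
        template = self.block_security().to_raster()
        assert patch.point == pytest.approx(template.cell_center(4, 4))

    def test_threshold_above_everything_raises(self):
        with pytest.raises(ValueError):
            identify_sources(self.block_security(), min_area=1000.0)

    def test_patch_count_monotone_in_threshold(self, rng):
        codes = (rng.random((40, 40)) < 0.35).astype(int) * 4
        sec = five_level(codes)
        counts = []
        for threshold in (0.0, 2.0, 5.0, 10.0, 20.0):
            try:
                s = identify_sources(sec, min_area=threshold)
                counts.append(len(s.all_patches))
            except ValueError:
                counts.append(0)
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_share_arithmetic(self):
        sources = identify_sources(self.block_security(), min_area=1.0)
        total = 144.0
        table = class_area_table(
            labels=["primary", "secondary"],
            areas=[sum(p.area for p in sources.primary),
                   sum(p.area for p in sources.secondary)],
            total_area=total)
        assert table["share_pct"][0] == pytest.approx(100 * 25 / 144)
        assert table["share_pct"][1] == pytest.approx(100 * 9 / 144)


class TestResistanceSurface:
    def make_layers(self, nl_values=None, dem_values=None):
        codes = np.array([[0, 1], [2, 5]])  # forest, grass, farm, constr
        lu = CategoricalRaster(LANDUSE_CLASSES, codes)
        nl = Raster(np.ones((2, 2)) if nl_values is None
                    else np.asarray(nl_values, dtype=float))
        dem = Raster(np.ones((2, 2)) if dem_values is None
                     else np.asarray(dem_values, dtype=float))
        return lu, nl, dem

    def test_base_table_lookup(self):
        lu, nl, dem = self.make_layers()
        rs = resistance_surface(lu, nl, dem)
        assert rs.base.values[0, 0] == 1.0  # forest
        assert rs.base.values[1, 1] == 500.0  # construction

    def test_identity_fixed_point(self):
        # NL_i = NL_a and DEM_i = DEM_a everywhere -> R_j = R
        lu, nl, dem = self.make_layers()
        rs = resistance_surface(lu, nl, dem)
        np.testing.assert_allclose(rs.elevation_corrected.values,
                                   rs.base.values)

    def test_nightlight_doubling(self):
        # two farmland cells, one at twice the class-mean nightlight
        codes = np.full((1, 2), LANDUSE_CLASSES.index("farmland"))
        lu = CategoricalRaster(LANDUSE_CLASSES, codes)
        nl = Raster(np.array([[2.0, 1.0]]))  # mean 1.5; cell0 = 2x mean of 1?
        dem = Raster(np.ones((1, 2)))
        rs = resistance_surface(lu, nl, dem)
        # R_i = NL_i / NL_a * R with NL_a = 1.5
        assert rs.nightlight_corrected.values[0, 0] == pytest.approx(
            2.0 / 1.5 * 30.0)
        # a cell at exactly 2x the class mean gives R_i = 60 for farmland
        nl2 = Raster(np.array([[4.0, 0.0]]))  # mean 2.0, cell0 = 2x mean
        rs2 = resistance_surface(lu, nl2, dem)
        assert rs2.nightlight_corrected.values[0, 0] == pytest.approx(60.0)

    def test_zero_mean_nightlight_falls_back(self):
        lu, _, dem = self.make_layers()
        nl = Raster(np.zeros((2, 2)))
        rs = resistance_surface(lu, nl, dem)
        np.testing.assert_allclose(rs.nightlight_corrected.values,
                                   rs.base.values)

    def test_missing_class_raises(self):
        lu, nl, dem = self.make_layers()
        with pytest.raises(KeyError):
            resistance_surface(lu, nl, dem, table={"forest": 1.0})


class TestCostDistance:
    def test_uniform_grid_closed_form(self):
        res = Raster(np.full((9, 9), 3.0), cell_size=0.5)
        cells, cost = least_cost_path(res, (4, 0), (4, 4))
        assert cost == pytest.approx(4 * 3.0 * 0.5)
        assert len(cells) == 5

    @pytest.mark.parametrize("seed", range(10))
    def test_against_dijkstra_oracle(self, seed):
        rng = np.random.default_rng(seed)
        res_vals = rng.random((10, 10)) * 10 + 0.1
        res = Raster(res_vals, cell_size=0.3)
        a = tuple(rng.integers(0, 10, 2))
        b = tuple(rng.integers(0, 10, 2))
        _, cost = least_cost_path(res, a, b)
        assert cost == pytest.approx(
            dijkstra_oracle(res_vals, 0.3, a, b), rel=1e-12)

    def test_wall_with_gap(self):
        vals = np.ones((11, 11))
        vals[:, 5] = 1000.0
        vals[5, 5] = 1.0  # the gap
        res = Raster(vals, cell_size=1.0)
        cells, _ = least_cost_path(res, (0, 0), (0, 10))
        assert (5, 5) in cells

    def test_metric_properties(self, rng):
        vals = rng.random((8, 8)) * 5 + 0.5
        res = Raster(vals, cell_size=1.0)
        src = [(0, 0), (7, 7)]
        cd = cost_distance(res, src)
        assert cd.values[0, 0] == 0.0
        assert cd.values[7, 7] == 0.0
        assert np.all(cd.values >= 0)
        # triangle inequality on sampled triples via single-pair costs
        for _ in range(5):
            pts = [tuple(rng.integers(0, 8, 2)) for _ in range(3)]
            d01 = least_cost_path(res, pts[0], pts[1])[1]
            d12 = least_cost_path(res, pts[1], pts[2])[1]
            d02 = least_cost_path(res, pts[0], pts[2])[1]
            assert d02 <= d01 + d12 + 1e-9

    def test_endpoint_symmetry(self, rng):
        vals = rng.random((9, 9)) * 3 + 0.2
        res = Raster(vals, cell_size=0.7)
        a, b = (1, 2), (7, 6)
        assert least_cost_path(res, a, b)[1] == pytest.approx(
            least_cost_path(res, b, a)[1])

    def test_lowering_resistance_never_raises_cost(self, rng):
        vals = rng.random((7, 7)) * 4 + 0.5
        res = Raster(vals.copy(), cell_size=1.0)
        base_cost = least_cost_path(res, (0, 0), (6, 6))[1]
        for _ in range(10):
            r, c = rng.integers(0, 7, 2)
            lowered = vals.copy()
            lowered[r, c] *= 0.5
            new_cost = least_cost_path(Raster(lowered, cell_size=1.0),
                                       (0, 0), (6, 6))[1]
            assert new_cost <= base_cost + 1e-9

    def test_nonpositive_resistance_raises(self):
        res = Raster(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            cost_distance(res, [(0, 0)])

    def test_empty_sources_raise(self):
        res = Raster(np.ones((3, 3)))
        with pytest.raises(ValueError):
            cost_distance(res, [])


class TestCorridors:
    def block_sources(self):
        codes = np.zeros((20, 20), dtype=int)
        codes[1:4, 1:4] = 4
        codes[1:4, 16:19] = 4
        codes[16:19, 1:4] = 3
        sec = five_level(codes)
        return identify_sources(sec, min_area=1.0)

    def test_corridor_cost_matches_cost_distance(self):
        sources = self.block_sources()
        res = Raster(np.ones((20, 20)) + 0.0, cell_size=1.0)
        corridors = least_cost_corridors(res, sources)
        for cor in corridors.corridors:
            a = next(p for p in sources.all_patches if p.id == cor.endpoints[0])
            b = next(p for p in sources.all_patches if p.id == cor.endpoints[1])
            _, cost = least_cost_path(res, res.cell_of(*a.point),
                                      res.cell_of(*b.point))
            assert cor.cost == pytest.approx(cost)

    def test_levels_assigned(self):
        sources = self.block_sources()
        res = Raster(np.ones((20, 20)), cell_size=1.0)
        corridors = least_cost_corridors(res, sources)
        levels = {c.level for c in corridors.corridors}
        assert "primary" in levels
        assert all(c.level in {"primary", "secondary"}
                   for c in corridors.corridors)

    def test_length_equals_step_sum(self):
        sources = self.block_sources()
        res = Raster(np.ones((20, 20)), cell_size=0.5)
        corridors = least_cost_corridors(res, sources)
        for cor in corridors.corridors:
            steps = 0.0
            for (r0, c0), (r1, c1) in zip(cor.cells[:-1], cor.cells[1:]):
                steps += 0.5 * (np.sqrt(2) if r0 != r1 and c0 != c1 else 1.0)
            assert cor.length == pytest.approx(steps)


class TestRidgeValley:
    def test_tent_ridge(self):
        profile = np.concatenate([np.arange(6), np.arange(4, -1, -1)])
        vals = np.tile(profile, (5, 1)).astype(float)
        ridge, _ = ridge_valley_lines(Raster(vals))
        assert ridge[:, 5].all()
        assert not ridge[:, 0].any()

    def test_inverted_tent_valley(self):
        profile = np.concatenate([np.arange(6), np.arange(4, -1, -1)])
        vals = -np.tile(profile, (5, 1)).astype(float)
        _, valley = ridge_valley_lines(Raster(vals))
        assert valley[2, 5]

    def test_ridge_cells_locally_high(self, rng):
        from scipy import ndimage

        vals = ndimage.gaussian_filter(rng.random((30, 30)), 3)
        ridge, _ = ridge_valley_lines(Raster(vals))
        interior = ridge[1:-1, 1:-1]
        rr, cc = np.where(interior)
        for r, c in zip(rr[:20] + 1, cc[:20] + 1):
            neighborhood = vals[r - 1:r + 2, c - 1:c + 2]
            assert vals[r, c] >= np.median(neighborhood) - 1e-12


class TestNodes:
    def corridor_set(self):
        from ecopattern.security import Corridor, CorridorSet

        cells = [(5, c) for c in range(20)]
        return CorridorSet([Corridor(1, (1, 2), "primary", cells,
                                     10.0, 19.0)])

    def test_single_road_crossing(self):
        template = Raster(np.zeros((20, 20)), cell_size=1.0)
        x = template.cell_center(0, 10)[0]
        road = VectorSet("polylines",
                         [np.array([[x, 0.5], [x, 19.5]])])
        nodes = ecological_nodes(self.corridor_set(),
                                 np.zeros((20, 20), dtype=bool),
                                 np.zeros((20, 20), dtype=bool),
                                 road, None, template)
        assert len(nodes.by_type("breaking")) == 1
        assert len(nodes) == 1

    def test_disjoint_masks_empty(self):
        template = Raster(np.zeros((20, 20)))
        nodes = ecological_nodes(self.corridor_set(),
                                 np.zeros((20, 20), dtype=bool),
                                 np.zeros((20, 20), dtype=bool),
                                 None, None, template)
        assert len(nodes) == 0

    def test_k_crossings_merge_to_k_nodes(self, rng):
        template = Raster(np.zeros((20, 20)), cell_size=1.0)
        xs = [3.5, 9.5, 15.5]
        roads = VectorSet("polylines", [
            np.array([[x, 0.5], [x, 19.5]]) for x in xs])
        nodes = ecological_nodes(self.corridor_set(),
                                 np.zeros((20, 20), dtype=bool),
                                 np.zeros((20, 20), dtype=bool),
                                 roads, None, template)
        assert len(nodes.by_type("breaking")) == len(xs)

    def test_nodes_lie_on_corridors(self):
        template = Raster(np.zeros((20, 20)), cell_size=1.0)
        ridge = np.zeros((20, 20), dtype=bool)
        ridge[5, 7] = True
        ridge[3, 2] = True  # off-corridor: must not produce a node
        nodes = ecological_nodes(self.corridor_set(), ridge,
                                 np.zeros((20, 20), dtype=bool),
                                 None, None, template)
        corridor_cells = set(self.corridor_set().corridors[0].cells)
        assert all(n.cell in corridor_cells for n in nodes.nodes)
        assert len(nodes.by_type("strategic")) == 1


class TestRiverCorridors:
    def test_lengths_from_geometry(self):
        template = Raster(np.zeros((10, 10)), cell_size=1.0)
        line = np.array([[0.5, 0.5], [3.5, 4.5]])
        rivers = VectorSet("polylines", [line])
        cors = river_corridors(rivers, template)
        assert len(cors) == 1
        assert cors.corridors[0].level == "river"
        assert cors.corridors[0].length == pytest.approx(5.0)
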