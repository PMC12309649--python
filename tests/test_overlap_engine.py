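import numpy as np
import pytest
import shapely

from aoh_gapscan.frames import Frame, FrameError
from aoh_gapscan.geometry_prep import repair_geometries
from aoh_gapscan.overlap_engine import (InputError, build_matrix, combination_count,
                                        mask_area, summarize_map, summarize_maps)
from conftest import make_map, make_site


def ray_cast_inside(poly_coords, x, y):
    """Independent even-odd point-in-polygon (no shapely)."""
    inside = False
    n = len(poly_coords)
    for i in range(n):
        x1, y1 = poly_coords[i]
        x2, y2 = poly_coords[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xin = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xin:
                inside = not inside
    return inside


class TestMaskArea:
    def test_polygon_covering_two_of_four_cell_centers(self):
        # cells (9,0),(9,1),(9,2),(9,3) on a 10x10 unit grid have centers at
        # y = 0.5, x = 0.5..3.5; a box over x in [0, 2] covers two centers
        m = make_map([(9, 0), (9, 1), (9, 2), (9, 3)])
        assert mask_area(m, shapely.box(0, 0, 2, 1)) == pytest.approx(2.0)

    def test_disjoint_polygon_gives_zero(self):
        m = make_map([(9, 0), (9, 1)])
        assert mask_area(m, shapely.box(50, 50, 60, 60)) == 0.0

    def test_matches_exhaustive_point_in_polygon_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            side = int(rng.integers(20, 101))
            n_cells = int(rng.integers(1, 201))
            flat = rng.choice(side * side, size=n_cells, replace=False)
            cells = [(int(f // side), int(f % side)) for f in flat]
            m = make_map(cells, shape=(side, side))
            pts = rng.uniform(0, side, size=(6, 2))
            hull = shapely.convex_hull(shapely.MultiPoint(pts))
            coords = list(hull.exterior.coords)[:-1]
            x, y = m.centers()
            expected = sum(ray_cast_inside(coords, xi, yi) for xi, yi in zip(x, y))
            assert mask_area(m, hull) == pytest.approx(expected * 1.0)

    def test_frame_mismatch_is_an_error(self):
        m = make_map([(0, 0)])
        with pytest.raises(FrameError):
            mask_area(m, shapely.box(0, 0, 1, 1), polygon_frame=None)
        with pytest.raises(FrameError):
            mask_area(m, shapely.box(0, 0, 1, 1), polygon_frame=Frame("other", c=5.0))


class TestBuildMatrix:
    def test_cross_product_accounting_at_global_scale(self):
        # counting path only; no records materialized
        assert combination_count(11_985, 16_012, 9) == 191_795_955

    def test_three_maps_by_two_sites(self):
        maps = [make_map([(9, 0)], map_id=f"m{i}", species_id=f"s{i}") for i in range(3)]
        ss = repair_geometries([make_site("a", shapely.box(0, 0, 5, 5)),
                                make_site("b", shapely.box(6, 6, 9, 9))])
        mat = build_matrix(maps, ss)
        assert mat.combination_count == 6

    def test_map_nested_in_one_site_of_disjoint_pair(self):
        m = make_map([(9, 0), (9, 1), (8, 0)])
        ss = repair_geometries([make_site("in", shapely.box(0, 0, 3, 3)),
                                make_site("out", shapely.box(6, 6, 9, 9))])
        mat = build_matrix([m], ss)
        assert mat.percent("m1", "in") == pytest.approx(100.0)
        assert mat.percent("m1", "out") == 0.0

    def test_duplicate_map_ids_rejected(self):
        maps = [make_map([(0, 0)], map_id="dup"), make_map([(1, 1)], map_id="dup")]
        ss = repair_geometries([make_site("a", shapely.box(0, 0, 5, 5))])
        with pytest.raises(InputError):
            build_matrix(maps, ss)

    def test_dropped_sites_shrink_the_cross_product(self):
        collapsed = shapely.Polygon([(0, 0), (1, 0), (2, 0), (1, 0)])
        ss = repair_geometries([make_site("ok", shapely.box(0, 0, 2, 2)),
                                make_site("bad", collapsed)])
        mat = build_matrix([make_map([(9, 0)])], ss)
        assert mat.n_sites == 1 and mat.combination_count == 1


class TestSummarize:
    def test_map_fully_inside_union(self):
        m = make_map([(9, 0), (9, 1)])
        assert summarize_map(m, shapely.box(0, 0, 5, 5))["pct_in_union"] == 100.0

    def test_map_disjoint_from_union(self):
        m = make_map([(9, 0)])
        assert summarize_map(m, shapely.box(5, 5, 9, 9))["pct_in_union"] == 0.0

    def test_two_sites_covering_same_half_are_not_double_counted(self):
        # both sites cover the SAME half of the map; the dissolved union gives
        # 50% while summing per-site percents would claim 100%
        m = make_map([(9, 0), (9, 1), (9, 2), (9, 3)])
        site_a = shapely.box(0, 0, 2, 1)
        site_b = shapely.box(0, 0, 2, 1)
        ss = repair_geometries([make_site("a", site_a), make_site("b", site_b)])
        union = ss.dissolve()
        pct_union = summarize_map(m, union)["pct_in_union"]
        per_site = [100 * mask_area(m, g) / m.total_area_km2
                    for g in ss.records.geometry]
        assert pct_union == pytest.approx(50.0)
        assert sum(per_site) == pytest.approx(100.0)
        assert pct_union < sum(per_site)

    def test_zero_area_map_flagged_unusable(self):
        m = make_map([])
        out = summarize_map(m, shapely.box(0, 0, 5, 5))
        assert out["unusable"] and np.isnan(out["pct_in_union"])


class TestOverlapProperties:
    """Union-bound, split-invariance, monotonicity on random scenes."""

    @staticmethod
    def random_scene(rng):
        side = 40
        n_cells = int(rng.integers(5, 120))
        flat = rng.choice(side * side, size=n_cells, replace=False)
        m = make_map([(int(f // side), int(f % side)) for f in flat],
                     shape=(side, side))
        boxes = []
        for _ in range(int(rng.integers(2, 8))):
            x, y = rng.uniform(0, side - 1, 2)
            w, h = rng.uniform(1, 12, 2)
            boxes.append(shapely.box(x, y, x + w, y + h))
        return m, boxes

    def test_union_bound_and_monotonicity_on_random_scenes(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            m, boxes = self.random_scene(rng)
            union = shapely.union_all(boxes)
            pct_union = 100 * mask_area(m, union) / m.total_area_km2
            per_site = sum(100 * mask_area(m, b) / m.total_area_km2 for b in boxes)
            assert pct_union <= per_site + 1e-9
            # monotonicity: adding one more site never lowers union percent
            extra = shapely.box(*rng.uniform(0, 30, 2), 39, 39)
            bigger = shapely.union_all(boxes + [extra])
            pct_bigger = 100 * mask_area(m, bigger) / m.total_area_km2
            assert pct_bigger >= pct_union - 1e-9

    def test_split_invariance(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            m, boxes = self.random_scene(rng)
            box = boxes[0]
            minx, miny, maxx, maxy = box.bounds
            xm = (minx + maxx) / 2
            halves = [shapely.box(minx, miny, xm, maxy), shapely.box(xm, miny, maxx, maxy)]
            u1 = shapely.union_all(boxes)
            u2 = shapely.union_all(halves + boxes[1:])
            a1 = mask_area(m, u1)
            a2 = mask_area(m, u2)
            assert a1 == pytest.approx(a2, abs=1e-9)

    def test_summaries_cover_all_maps(self, small_scenario):
        ss = repair_geometries(small_scenario.sites)
        out = summarize_maps(small_scenario.maps, ss.dissolve(), warn_unusable=False)
        assert len(out) == len(small_scenario.maps)
        ok = out["pct_in_union"].dropna()
        assert ((ok >= 0) & (ok <= 100)).all()
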