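"""Buffer-level covariate extraction against independent geometric oracles."""

import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import LineString, Point, box

from sagersf.covariates import (EnergyIndex, active_wells, class_proportions,
                                classify_roads, distance_to_class,
                                distance_to_features, filter_rare_classes,
                                line_density, mean_within_buffer)
from sagersf.grid import Raster, disc_cell_weights, disc_polygon
from sagersf.synthetic import STUDY_INTERVAL, make_well_registry


def uniform_raster(value=1, n=40, cell=25.0):
    return Raster(np.full((n, n), value, dtype=int), x0=0.0, y0=0.0, cell=cell)


class TestClassProportions:
    def test_homogeneous_landscape(self):
        veg = uniform_raster(1)
        props = class_proportions(500.0, 500.0, 150.0, veg)
        assert props["sagebrush"] == pytest.approx(1.0)

    def test_checkerboard_matches_polygon_clipping_oracle(self):
        cell = 25.0
        n = 40
        vals = (np.indices((n, n)).sum(axis=0) % 2) + 1  # classes 1 and 2
        veg = Raster(vals, x0=0.0, y0=0.0, cell=cell)
        x, y, r = 500.0, 500.0, cell  # radius of one cell
        props = class_proportions(x, y, r, veg)
        # independent oracle: clip every nearby cell square against the 32-gon
        disc = Point(x, y).buffer(r, quad_segs=8)
        areas = {1: 0.0, 2: 0.0}
        for row in range(n):
            for col in range(n):
                cx = col * cell + cell / 2
                cy = (n - row - 1) * cell + cell / 2
                if abs(cx - x) > r + cell or abs(cy - y) > r + cell:
                    continue
                inter = box(cx - cell / 2, cy - cell / 2, cx + cell / 2, cy + cell / 2
                            ).intersection(disc).area
                areas[int(vals[row, col])] += inter
        total = sum(areas.values())
        assert props["sagebrush"] == pytest.approx(areas[1] / total, abs=1e-6)
        assert props["grassland"] == pytest.approx(areas[2] / total, abs=1e-6)
        assert props["sagebrush"] == pytest.approx(0.5, abs=0.1)

    def test_proportions_partition_the_disc(self, landscape, rng):
        xmin, ymin, xmax, ymax = landscape.extent.bounds
        for _ in range(100):
            x = rng.uniform(xmin + 200, xmax - 200)
            y = rng.uniform(ymin + 200, ymax - 200)
            props = class_proportions(x, y, 150.8, landscape.vegetation)
            assert sum(props.values()) == pytest.approx(1.0, abs=1e-9)

    def test_buffer_outside_raster_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            class_proportions(-5000.0, -5000.0, 100.0, uniform_raster())


class TestDistanceToClass:
    def test_zero_when_class_inside_buffer(self):
        assert distance_to_class(500.0, 500.0, 150.0, uniform_raster(1), code=1) == 0.0

    def test_unit_conversion(self):
        vals = np.full((40, 40), 2, dtype=int)
        vals[20, 30] = 1  # one sagebrush cell
        veg = Raster(vals, x0=0.0, y0=0.0, cell=25.0)
        cx, cy = veg.cell_center(20, 30)
        x, y = cx - 500.0, cy
        d = distance_to_class(x, y, 100.0, veg, code=1)
        assert d == pytest.approx(0.5)

    def test_matches_bruteforce_nearest_cell(self, landscape, rng):
        veg = landscape.vegetation
        rows, cols = np.nonzero(veg.values == 4)  # riparian (sparse)
        cx, cy = veg.cell_center(rows, cols)
        xmin, ymin, xmax, ymax = landscape.extent.bounds
        for _ in range(50):
            x = rng.uniform(xmin + 200, xmax - 200)
            y = rng.uniform(ymin + 200, ymax - 200)
            d = distance_to_class(x, y, 80.0, veg, code=4)
            props = class_proportions(x, y, 80.0, veg)
            brute = np.hypot(cx - x, cy - y).min() / 1000.0
            if props["riparian"] > 0:
                assert d == 0.0
            else:
                assert d == pytest.approx(brute, abs=1e-9)

    def test_zero_iff_positive_proportion(self, landscape, rng):
        veg = landscape.vegetation
        xmin, ymin, xmax, ymax = landscape.extent.bounds
        for _ in range(50):
            x = rng.uniform(xmin + 200, xmax - 200)
            y = rng.uniform(ymin + 200, ymax - 200)
            d = distance_to_class(x, y, 150.8, veg, code=1)
            props = class_proportions(x, y, 150.8, veg)
            assert (d == 0.0) == (props["sagebrush"] > 0)


class TestDistanceToFeatures:
    def test_zero_if_feature_within_radius(self):
        line = LineString([(0, 100), (1000, 100)])
        assert distance_to_features(500.0, 200.0, 150.0, [line]) == 0.0

    def test_kilometers(self):
        line = LineString([(0, 0), (0, 1000)])
        assert distance_to_features(500.0, 500.0, 100.0, [line]) == pytest.approx(0.5)

    def test_empty_layer_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            distance_to_features(0, 0, 10, [])

    def test_matches_bruteforce_over_vertices(self, rng):
        for _ in range(50):
            pts = rng.uniform(0, 2000, (6, 2))
            lines = [LineString(pts[:3]), LineString(pts[3:])]
            x, y = rng.uniform(0, 2000, 2)
            d = distance_to_features(x, y, 10.0, lines)
            brute = min(line.distance(Point(x, y)) for line in lines) / 1000.0
            assert d == pytest.approx(brute if brute > 0.01 else 0.0, abs=1e-9)


class TestLineDensity:
    def test_unit_definition(self):
        window = box(0, 0, 1000, 1000)  # 1 km^2
        assert line_density(window, [LineString([(0, 500), (1000, 500)])]) \
            == pytest.approx(1.0)

    def test_no_lines(self):
        assert line_density(box(0, 0, 100, 100), []) == 0.0

    def test_matches_clip_and_sum_oracle(self, rng):
        window = disc_polygon(500.0, 500.0, 200.0)
        for _ in range(30):
            segs = [LineString(rng.uniform(0, 1000, (2, 2))) for _ in range(5)]
            d = line_density(window, segs)
            clipped = sum(s.intersection(window).length for s in segs) / 1000.0
            assert d == pytest.approx(clipped / (window.area / 1e6), abs=1e-9)


class TestMeanWithinBuffer:
    def test_constant_field(self):
        r = Raster(np.full((40, 40), 7.5), x0=0.0, y0=0.0, cell=25.0)
        assert mean_within_buffer(500.0, 500.0, 120.0, r) == pytest.approx(7.5)

    def test_linear_ramp_equals_centroid_value(self):
        n, cell = 60, 25.0
        cols = np.arange(n) * cell + cell / 2
        vals = np.tile(2.0 * cols + 10.0, (n, 1))
        r = Raster(vals, x0=0.0, y0=0.0, cell=cell)
        x, y = 740.0, 800.0
        got = mean_within_buffer(x, y, 150.0, r)
        assert got == pytest.approx(2.0 * x + 10.0, abs=0.5)

    def test_matches_cell_enumeration_oracle(self, landscape, rng):
        elev = landscape.elevation
        xmin, ymin, xmax, ymax = landscape.extent.bounds
        for _ in range(100):
            x = rng.uniform(xmin + 200, xmax - 200)
            y = rng.uniform(ymin + 200, ymax - 200)
            rows, cols, w = disc_cell_weights(elev, x, y, 83.1)
            brute = float(np.sum(elev.values[rows, cols] * w) / w.sum())
            assert mean_within_buffer(x, y, 83.1, elev) == pytest.approx(brute, abs=1e-9)


class TestFilterRareClasses:
    def make_tables(self, shares, used_zero=()):
        rng = np.random.default_rng(0)
        n = 200
        df = pd.DataFrame({"response": [1] * 50 + [0] * 150})
        for name, share in shares.items():
            col = np.full(n, share)
            if name in used_zero:
                col[:50] = 0.0
            df[name] = col
        return {"breeding": df}

    def test_below_threshold_dropped(self):
        tabs = self.make_tables({"sagebrush": 0.9, "riparian": 0.0005})
        retained, audit = filter_rare_classes(tabs, 0.001,
                                              class_names=["sagebrush", "riparian"])["breeding"]
        assert retained == ["sagebrush"]
        assert audit[0]["reason"] == "rare"

    def test_exactly_at_threshold_retained(self):
        tabs = self.make_tables({"grassland": 0.001})
        retained, _ = filter_rare_classes(tabs, 0.001, class_names=["grassland"])["breeding"]
        assert retained == ["grassland"]

    def test_separation_guard(self):
        tabs = self.make_tables({"sagebrush": 0.5, "agriculture": 0.2},
                                used_zero=("agriculture",))
        retained, audit = filter_rare_classes(
            tabs, 0.001, class_names=["sagebrush", "agriculture"])["breeding"]
        assert retained == ["sagebrush"]
        assert audit[0]["reason"] == "separation guard"


class TestClassifyRoads:
    wells = pd.DataFrame({"x": [1000.0], "y": [1000.0]})

    def test_road_ending_near_well_is_oil_gas(self):
        roads = pd.DataFrame({"geometry": [LineString([(0, 0), (1000, 970)])],
                              "road_class": ["unclassified"]})
        tagged = classify_roads(roads, self.wells, [])
        assert tagged["tag"].iloc[0] == "oil_gas"

    def test_protected_class_stays_other(self):
        field = box(500, 500, 1500, 1500)
        roads = pd.DataFrame({"geometry": [LineString([(600, 600), (1400, 1400)])],
                              "road_class": ["county"]})
        tagged = classify_roads(roads, self.wells, [field])
        assert tagged["tag"].iloc[0] == "other"

    def test_far_road_is_other(self):
        roads = pd.DataFrame({"geometry": [LineString([(5000, 5000), (6000, 6000)])],
                              "road_class": ["unclassified"]})
        tagged = classify_roads(roads, self.wells, [])
        assert tagged["tag"].iloc[0] == "other"

    def test_road_in_field_is_oil_gas(self):
        field = box(500, 500, 1500, 1500)
        roads = pd.DataFrame({"geometry": [LineString([(600, 600), (1400, 1400)])],
                              "road_class": ["unclassified"]})
        tagged = classify_roads(roads, self.wells, [field])
        assert tagged["tag"].iloc[0] == "oil_gas"


class TestActiveWells:
    def test_no_overlap_excluded(self):
        w = pd.DataFrame([{"well_id": "a", "x": 0, "y": 0, "status": "active",
                           "spud": "1990-01-01", "completion": "1990-03-01",
                           "first_production": "1990-04-01",
                           "last_production": "2005-01-01", "expiration": "2005-01-01"}])
        assert len(active_wells(w, STUDY_INTERVAL)) == 0

    def test_full_overlap_included(self):
        w = pd.DataFrame([{"well_id": "a", "x": 0, "y": 0, "status": "active",
                           "spud": "2000-01-01", "completion": "2000-03-01",
                           "first_production": "2000-04-01",
                           "last_production": "2015-01-01", "expiration": None}])
        assert len(active_wells(w, STUDY_INTERVAL)) == 1

    def test_registry_matches_bruteforce_interval_scan(self):
        reg = make_well_registry(n_wells=677, n_active=181, seed=5)
        got = active_wells(reg, STUDY_INTERVAL)
        start, end = STUDY_INTERVAL
        expected = []
        for _, r in reg.iterrows():
            if str(r["status"]).lower() != "active":
                continue
            begins = [pd.Timestamp(r[c]) for c in ("spud", "completion", "first_production")
                      if pd.notna(r[c])]
            if not begins:
                continue
            w_start = min(begins)
            ends = [pd.Timestamp(r[c]) for c in ("last_production", "expiration")
                    if pd.notna(r[c])]
            w_end = max(ends) if ends else pd.Timestamp.max
            if w_start <= pd.Timestamp(end) and w_end >= pd.Timestamp(start):
                expected.append(r["well_id"])
        assert list(got["well_id"]) == expected
        assert len(got) == 181


class TestEnergyIndex:
    def test_empty_development_is_zero(self):
        template = uniform_raster(1, n=50)
        idx = EnergyIndex.build(template, pd.DataFrame(columns=["x", "y"]), [])
        assert np.all(idx.index.values == 0.0)
        assert idx.at(600.0, 600.0) == 0.0

    def test_cell_attaining_both_maxima_scores_two(self):
        template = uniform_raster(1, n=50)
        wells = pd.DataFrame({"x": [625.0], "y": [625.0]})
        roads = [LineString([(125, 625), (1125, 625)])]
        idx = EnergyIndex.build(template, wells, roads)
        assert idx.index.values.max() == pytest.approx(2.0)

    def test_at_matches_independent_recomputation(self, rng):
        template = uniform_raster(1, n=50)
        wells = pd.DataFrame({"x": rng.uniform(100, 1100, 8),
                              "y": rng.uniform(100, 1100, 8)})
        roads = [LineString(rng.uniform(0, 1250, (3, 2))) for _ in range(4)]
        idx = EnergyIndex.build(template, wells, roads)
        union = shapely.union_all(roads)
        for _ in range(20):
            x, y = rng.uniform(200, 1000, 2)
            win = box(x - 500, y - 500, x + 500, y + 500)
            wd = np.sum((np.abs(wells.x - x) <= 500) & (np.abs(wells.y - y) <= 500))
            rd = union.intersection(win).length / 1000.0
            wlo, whi = idx.wd_range
            rlo, rhi = idx.rd_range
            expect = ((wd - wlo) / (whi - wlo) if whi > wlo else 0.0) \
                + ((rd - rlo) / (rhi - rlo) if rhi > rlo else 0.0)
            assert idx.at(x, y) == pytest.approx(expect, abs=1e-9)
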