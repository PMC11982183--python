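"""Threat overlays, risk index construction and categorization."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

import enmrisk as er


def full_map(grid):
    return er.BinaryMap(grid, np.ones(grid.shape, np.uint8))


class TestHfpOverlap:
    def test_strict_comparison_and_counting(self, grid20):
        bm = full_map(grid20)
        hfp = np.full(grid20.shape, 10.0)
        assert er.hfp_overlap(bm, hfp, cut=10)[0] == 0.0  # strict >
        hfp2 = np.zeros(grid20.shape)
        hfp2.ravel()[:7] = 11.0
        g = er.GridSpec(10, 10)
        bm100 = full_map(g)
        h = np.zeros((10, 10))
        h.ravel()[:7] = 11.0
        prop, area_ = er.hfp_overlap(bm100, h, cut=10)
        assert prop == pytest.approx(0.07)
        assert area_ == 7.0

    def test_empty_range_flagged(self, grid20):
        empty = er.BinaryMap(grid20, np.zeros(grid20.shape, np.uint8))
        with pytest.warns(UserWarning):
            prop, _ = er.hfp_overlap(empty, np.zeros(grid20.shape))
        assert np.isnan(prop)


class TestPaOverlap:
    def test_whole_grid_polygon(self, grid20):
        bm = full_map(grid20)
        poly = box(*grid20.extent)
        assert er.pa_overlap(bm, [poly]) == 1.0

    def test_overlapping_squares_dissolved(self):
        g = er.GridSpec(10, 10)
        bm = full_map(g)
        # two 4x4 squares overlapping on a 2x4 block: union covers
        # 16 + 16 - 8 = 24 cell centers
        a = box(0, 0, 4, 4)
        b = box(2, 0, 6, 4)
        assert er.pa_overlap(bm, [a, b]) == pytest.approx(24 / 100)
        raster = er.rasterize_polygons([a, b], g)
        assert raster.sum() == 24

    def test_invalid_geometry_reported_with_index(self, grid20):
        from shapely.geometry import Polygon
        bowtie = Polygon([(0, 0), (2, 2), (2, 0), (0, 2)])
        with pytest.raises(ValueError, match="index 1"):
            er.pa_overlap(full_map(grid20), [box(0, 0, 1, 1), bowtie])


class TestContactZone:
    def test_trivial_and_counted_cases(self):
        g = er.GridSpec(10, 10)
        a = np.zeros((10, 10), np.uint8)
        a.ravel()[:50] = 1
        b = np.zeros((10, 10), np.uint8)
        b.ravel()[40:60] = 1  # overlaps a on 10 cells
        amap, bmap = er.BinaryMap(g, a), er.BinaryMap(g, b)
        inter, prop = er.contact_zone(amap, bmap)
        assert prop == pytest.approx(10 / 50)
        assert inter.n_present == 10
        _, p_disjoint = er.contact_zone(
            amap, er.BinaryMap(g, np.zeros((10, 10), np.uint8)))
        assert p_disjoint == 0.0
        _, p_super = er.contact_zone(amap, full_map(g))
        assert p_super == 1.0

    def test_empty_focal_flagged(self, grid20):
        empty = er.BinaryMap(grid20, np.zeros(grid20.shape, np.uint8))
        with pytest.warns(UserWarning):
            _, prop = er.contact_zone(empty, full_map(grid20))
        assert np.isnan(prop)


class TestConsistency:
    def test_counting(self, grid20):
        maps = [full_map(grid20) for _ in range(4)]
        np.testing.assert_array_equal(er.consistency_layer(maps), 4)
        empty = [er.BinaryMap(grid20, np.zeros(grid20.shape, np.uint8))
                 for _ in range(3)]
        np.testing.assert_array_equal(er.consistency_layer(empty), 0)
        two = [full_map(grid20), full_map(grid20)] + empty[:2]
        np.testing.assert_array_equal(er.consistency_layer(two), 2)


class TestRiskIndex:
    def test_weighted_sum_examples(self, grid20):
        a = np.full(grid20.shape, 4)
        b = np.full(grid20.shape, 4)
        rmap = er.risk_index(a, b, grid20, n_scenarios=4)
        assert np.all(rmap.risk == 40)
        rmap2 = er.risk_index(np.zeros(grid20.shape, int),
                              np.ones(grid20.shape, int), grid20, 4)
        assert np.all(rmap2.risk == 3)
        rmap3 = er.risk_index(np.full(grid20.shape, 2),
                              np.full(grid20.shape, 3), grid20, 4)
        assert np.all(rmap3.risk == 23)

    def test_attainable_set(self, grid20):
        rmap = er.risk_index(np.zeros(grid20.shape, int),
                             np.zeros(grid20.shape, int), grid20, 4)
        vals = rmap.attainable_values()
        assert vals.max() == 40
        assert vals[vals > 0].min() == 3
        expect = sorted({7 * a + 3 * b for a in range(5) for b in range(5)})
        np.testing.assert_array_equal(vals, expect)

    def test_negative_counts_rejected(self, grid20):
        with pytest.raises(ValueError):
            er.risk_index(np.full(grid20.shape, -1),
                          np.zeros(grid20.shape, int), grid20, 4)


class TestZeroRisk:
    def make(self, grid, present):
        vals = np.full(grid.shape, 1 if present else 0, np.uint8)
        return er.BinaryMap(grid, vals)

    def test_all_maintained_no_contact(self, grid20):
        zr = er.zero_risk([self.make(grid20, True)] * 4,
                          [self.make(grid20, False)] * 4)
        assert zr.n_present == grid20.n_cells

    def test_all_rule(self, grid20):
        maintained = [self.make(grid20, True)] * 3 + [self.make(grid20, False)]
        zr = er.zero_risk(maintained, [self.make(grid20, False)] * 4)
        assert zr.n_present == 0

    def test_none_rule(self, grid20):
        contact = [self.make(grid20, False)] * 3 + [self.make(grid20, True)]
        zr = er.zero_risk([self.make(grid20, True)] * 4, contact)
        assert zr.n_present == 0

    def test_scenario_mismatch_rejected(self, grid20):
        with pytest.raises(ValueError):
            er.zero_risk([self.make(grid20, True)] * 3,
                         [self.make(grid20, False)] * 4)

    @pytest.mark.parametrize("seed", range(20))
    def test_zero_risk_cells_have_zero_risk(self, grid20, seed):
        rng = np.random.default_rng(seed)
        S = 4
        current = er.BinaryMap(grid20, rng.random(grid20.shape) < 0.6)
        futures = [er.BinaryMap(grid20, rng.random(grid20.shape) < 0.5)
                   for _ in range(S)]
        congener = [er.BinaryMap(grid20, rng.random(grid20.shape) < 0.3)
                    for _ in range(S)]
        maintained = [er.maintained_map(current, f) for f in futures]
        losses = [er.loss_map(current, f) for f in futures]
        contacts = [er.contact_zone(f, c)[0]
                    for f, c in zip(futures, congener)]
        zr = er.zero_risk(maintained, contacts)
        rmap = er.risk_index(er.consistency_layer(losses),
                             er.consistency_layer(contacts), grid20, S,
                             zero_risk_mask=zr.presence)
        assert np.all(rmap.risk[zr.presence] == 0)
        assert np.all(rmap.contact_count[zr.presence] == 0)
        assert np.all(rmap.loss_count[zr.presence] == 0)


class TestClassification:
    def test_category_bounds(self):
        cats = er.RiskCategories()
        assert cats.of(3) == "low"
        assert cats.of(14) == "low"
        assert cats.of(23) == "moderate"
        assert cats.of(28) == "moderate"
        assert cats.of(29) == "high"
        assert cats.of(40) == "high"
        assert cats.of(0) == "none"

    def test_proportions_sum_to_one(self, grid20):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 5, grid20.shape)
        b = rng.integers(0, 5, grid20.shape)
        rmap = er.risk_index(a, b, grid20, 4)
        codes, props = er.classify_risk(rmap)
        assert sum(props.values()) == pytest.approx(1.0, abs=1e-9)

    def test_stray_value_warns(self, grid20):
        rmap = er.risk_index(np.ones(grid20.shape, int),
                             np.zeros(grid20.shape, int), grid20, 4)
        rmap.risk[0, 0] = 5.0  # not representable as 7a + 3b with a,b <= 4
        with pytest.warns(UserWarning, match="attainable"):
            er.classify_risk(rmap)


class TestPaRiskSummary:
    def test_toy_counts(self):
        # 1x3 PA covering risks {0(zero), 3, 30} equally
        g = er.GridSpec(3, 3)
        a = np.array([[0, 0, 3], [0, 0, 0], [0, 0, 0]])
        b = np.array([[0, 1, 3], [0, 0, 0], [0, 0, 0]])  # risks 0, 3, 30
        zero_mask = np.zeros((3, 3), bool)
        zero_mask[0, 0] = True
        rmap = er.risk_index(a, b, g, 4, zero_risk_mask=zero_mask)
        pa = [box(0, 2, 3, 3)]  # top row
        overall, table = er.pa_risk_summary(rmap, pa)
        assert overall["pa_cells_on_risk_surface"] == 3
        assert overall["zero_risk_pct"] == pytest.approx(100 / 3)
        assert overall["low_pct_of_at_risk"] == pytest.approx(50.0)
        assert overall["high_pct_of_at_risk"] == pytest.approx(50.0)

    def test_entirely_zero_risk_pa(self, grid20):
        rmap = er.risk_index(np.zeros(grid20.shape, int),
                             np.zeros(grid20.shape, int), grid20, 4,
                             zero_risk_mask=np.ones(grid20.shape, bool))
        overall, _ = er.pa_risk_summary(rmap, [box(*grid20.extent)])
        assert overall["zero_risk_pct"] == 100.0

    def test_key_pa_filter_rule(self):
        table = pd.DataFrame({
            "pa_index": [0, 1, 2, 3],
            "area": [150.0, 90.0, 200.0, 300.0],
            "overlap_pct": [45.0, 80.0, 30.0, 41.0],
        })
        sel = er.threats.filter_protected_areas(table, 100.0, 40.0)
        assert list(sel["pa_index"]) == [0, 3]
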