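import numpy as np
import pandas as pd
import pytest

from corridorscope.evaluate import (
    TIER_CODES,
    capture_stats,
    equal_sens_spec_threshold,
    identify_patches,
    per_individual_capture,
    tier_map,
)
from corridorscope.lcm import CorridorMask
from corridorscope.migration import MigrationWindow, Track
from corridorscope.pointset import PointSet
from corridorscope.raster import GridSpec, RasterLayer


def binary_mask(cells, shape=(10, 10), cellsize=100.0, **prov):
    vals = np.zeros(shape, dtype=np.int64)
    for r, c in cells:
        vals[r, c] = 1
    spec = GridSpec(*shape, cellsize, origin_y=shape[0] * cellsize)
    layer = RasterLayer(spec, vals, "binary")
    defaults = dict(season="spring", hsm="maxent", method="lcm", threshold=10.0)
    defaults.update(prov)
    return CorridorMask(layer, **defaults)


class TestEqualSensSpec:
    def test_perfectly_separated_lowest_in_gap(self):
        # any threshold in (0.4, 0.6] separates; the lowest candidate wins
        t = equal_sens_spec_threshold([0.9, 0.8, 0.6], [0.4, 0.3, 0.1])
        assert t == 0.6

    def test_identical_distributions_near_median(self):
        rng = np.random.default_rng(1)
        scores = rng.random(1000)
        t = equal_sens_spec_threshold(scores, scores)
        sens = np.mean(scores >= t)
        spec = np.mean(scores < t)
        assert sens == pytest.approx(0.5, abs=0.05)
        assert spec == pytest.approx(0.5, abs=0.05)

    def test_enumeration_oracle(self):
        presence = np.array([0.9, 0.8, 0.3])
        background = np.array([0.7, 0.2, 0.1])
        best_t, best_gap = None, np.inf
        for t in sorted(np.r_[presence, background]):
            gap = abs(np.mean(presence >= t) - np.mean(background < t))
            if gap < best_gap - 1e-12:
                best_gap, best_t = gap, t
        assert equal_sens_spec_threshold(presence, background) == best_t == pytest.approx(0.7)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            equal_sens_spec_threshold([], [0.5])


class TestCaptureStats:
    def test_full_mask(self):
        mask = binary_mask([(r, c) for r in range(10) for c in range(10)])
        pts = PointSet(np.full(10, 550.0), np.full(10, 450.0))
        assert capture_stats(mask, pts, mask.layer.mask) == (100.0, 100.0)

    def test_empty_mask(self):
        mask = binary_mask([])
        pts = PointSet(np.full(10, 550.0), np.full(10, 450.0))
        assert capture_stats(mask, pts, mask.layer.mask) == (0.0, 0.0)

    def test_70_points_25_area_fixture(self):
        # 25-cell mask on a 100-cell grid; 7 of 10 points inside -> exactly (70, 25)
        mask = binary_mask([(r, c) for r in range(5) for c in range(5)])
        spec = mask.layer.spec
        inside = [spec.cell_center(r, c) for r, c in [(0, 0), (1, 1), (2, 2), (3, 3), (4, 4), (0, 4), (4, 0)]]
        outside = [spec.cell_center(r, c) for r, c in [(9, 9), (8, 8), (7, 7)]]
        xy = np.array(inside + outside)
        pct_points, pct_area = capture_stats(mask, PointSet(xy[:, 0], xy[:, 1]), mask.layer.mask)
        assert (pct_points, pct_area) == (70.0, 25.0)

    def test_zero_points_rejected(self):
        mask = binary_mask([(0, 0)])
        with pytest.raises(ValueError):
            capture_stats(mask, PointSet(np.array([]), np.array([])), mask.layer.mask)


class TestPerIndividual:
    def make_track_window(self, ind, cells, spec):
        xy = np.array([spec.cell_center(r, c) for r, c in cells])
        t = np.datetime64("2008-04-01").astype("datetime64[s]") + np.arange(len(cells)) * np.timedelta64(14400, "s")
        track = Track(ind, xy[:, 0], xy[:, 1], t)
        window = MigrationWindow(ind, "spring", 0, len(cells) - 1,
                                 t[0].astype("datetime64[D]"), t[-1].astype("datetime64[D]"))
        return track, window

    def test_fully_inside_and_fully_outside(self):
        mask = binary_mask([(r, c) for r in range(5) for c in range(5)])
        spec = mask.layer.spec
        t_in, w_in = self.make_track_window("in", [(0, 0), (1, 1), (2, 2)], spec)
        t_out, w_out = self.make_track_window("out", [(9, 9), (8, 8), (7, 7)], spec)
        df = per_individual_capture(mask, [t_in, t_out], {"in": w_in, "out": w_out})
        by = df.set_index("individual")
        assert by.loc["in", "fraction_inside"] == 1.0 and bool(by.loc["in", "fully_contained"])
        assert by.loc["out", "fraction_inside"] == 0.0 and not bool(by.loc["out", "fully_contained"])

    def test_fraction_matches_brute_force(self):
        rng = np.random.default_rng(2)
        mask = binary_mask([(r, c) for r in range(10) for c in range(10) if rng.random() < 0.4])
        spec = mask.layer.spec
        cells = [(int(r), int(c)) for r, c in rng.integers(0, 10, (30, 2))]
        track, window = self.make_track_window("x", cells, spec)
        df = per_individual_capture(mask, [track], {"x": window})
        expected = np.mean([mask.cells[r, c] for r, c in cells])
        assert df.loc[0, "fraction_inside"] == pytest.approx(expected)


@pytest.fixture(scope="module")
def blobby():
    spec = GridSpec(30, 30, 100.0, origin_y=3000.0)
    vals = np.full((30, 30), 0.2)
    vals[2:8, 2:8] = 0.9  # north-west blob
    vals[2:8, 20:26] = 0.85  # north-east blob
    vals[22:28, 12:18] = 0.95  # southern blob (source)
    suit = RasterLayer(spec, vals)
    rng = np.random.default_rng(3)
    # presences concentrated in the blobs
    pts = []
    for (r0, c0) in [(24, 14), (4, 4), (4, 22)]:
        pts.append(np.column_stack([
            spec.origin_x + (c0 + rng.uniform(-2, 2, 40)) * 100.0,
            spec.origin_y - (r0 + rng.uniform(-2, 2, 40)) * 100.0,
        ]))
    pts = np.vstack(pts)
    return suit, PointSet(pts[:, 0], pts[:, 1])


class TestIdentifyPatches:
    def box(self, r, c, half=500.0, spec=None):
        x, y = spec.cell_center(r, c)
        return (x - half, y - half, x + half, y + half)

    def test_single_blob_source(self, blobby):
        suit, pts = blobby
        spec = suit.spec
        ps = identify_patches(suit, pts, self.box(25, 15, spec=spec),
                              [self.box(5, 5, spec=spec), self.box(5, 23, spec=spec)])
        src = np.asarray(ps.source_cells())
        assert (src[:, 0] >= 22).all() and (src[:, 0] <= 27).all()

    def test_destination_count_and_ranking(self, blobby):
        suit, pts = blobby
        spec = suit.spec
        ps = identify_patches(suit, pts, self.box(25, 15, spec=spec),
                              [self.box(5, 5, spec=spec), self.box(5, 23, spec=spec)])
        assert len(ps.destinations) == 2
        assert ps.source not in ps.destinations

    def test_hint_without_habitat_raises(self, blobby):
        suit, pts = blobby
        spec = suit.spec
        with pytest.raises(ValueError, match="destination\\[0\\]"):
            identify_patches(suit, pts, self.box(25, 15, spec=spec), [self.box(15, 2, spec=spec)])

    def test_no_cell_above_threshold(self):
        spec = GridSpec(5, 5, 100.0, origin_y=500.0)
        suit = RasterLayer(spec, np.linspace(0, 1, 25).reshape(5, 5))
        pts = PointSet(np.array([50.0]), np.array([450.0]))
        # all presence scores at the bottom: threshold exceeds every cell in the hint box
        with pytest.raises(ValueError):
            identify_patches(suit, pts, (0.0, 400.0, 100.0, 500.0), [])


class TestTierMap:
    def mask_for(self, cells, season, p):
        return binary_mask(cells, season=season, method="lcm", threshold=float(p))

    def grid_cells(self, rows, cols):
        return [(r, c) for r in rows for c in cols]

    def test_identical_seasons_nest(self):
        sets = {1: self.grid_cells(range(2), range(2)),
                5: self.grid_cells(range(4), range(4)),
                10: self.grid_cells(range(6), range(6))}
        corridors = {(s, p): self.mask_for(sets[p], s, p) for s in ("spring", "fall") for p in (1, 5, 10)}
        tiers = tier_map(corridors)
        t1 = tiers.values == TIER_CODES["tier1"]
        t2 = tiers.values == TIER_CODES["tier2"]
        t3 = tiers.values == TIER_CODES["tier3"]
        assert t1.sum() == 4 and (t1 | t2).sum() == 16 and (t1 | t2 | t3).sum() == 36

    def test_disjoint_5pct_gives_empty_tier2(self):
        corridors = {
            ("spring", 1): self.mask_for([], "spring", 1),
            ("fall", 1): self.mask_for([], "fall", 1),
            ("spring", 5): self.mask_for(self.grid_cells(range(3), range(3)), "spring", 5),
            ("fall", 5): self.mask_for(self.grid_cells(range(7, 10), range(7, 10)), "fall", 5),
            ("spring", 10): self.mask_for(self.grid_cells(range(5), range(5)), "spring", 10),
            ("fall", 10): self.mask_for(self.grid_cells(range(5, 10), range(10)), "fall", 10),
        }
        tiers = tier_map(corridors)
        assert (tiers.values == TIER_CODES["tier2"]).sum() == 0

    def test_tier2_subset_tier3_random_masks(self):
        rng = np.random.default_rng(4)
        corridors = {}
        for s in ("spring", "fall"):
            base = rng.random((10, 10))
            # per-season nesting by construction: thresholds on one surface
            for p, q in ((1, 0.1), (5, 0.3), (10, 0.5)):
                cells = [(r, c) for r in range(10) for c in range(10) if base[r, c] < q]
                corridors[(s, p)] = self.mask_for(cells, s, p)
        tiers = tier_map(corridors)
        t2 = np.zeros((10, 10), dtype=bool)
        t3 = np.zeros((10, 10), dtype=bool)
        t2 |= corridors[("spring", 5)].cells & corridors[("fall", 5)].cells
        t3 |= corridors[("spring", 10)].cells & corridors[("fall", 10)].cells
        assert np.all(t3[t2])  # tier2 region nests inside tier3 region

    def test_missing_corridor_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            tier_map({("spring", 1): self.mask_for([], "spring", 1)})
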