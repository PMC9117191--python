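"""Point-pattern generation, orthoimage rendering and tiling."""
import numpy as np
import pytest
import shapely
from shapely.geometry import Polygon

import burrowscape as bc
from burrowscape.detect_eval import DetectionBox
from burrowscape.synthgen import (
    AvoidanceParams,
    GenerationError,
    ImageSpec,
    LandscapeSpec,
    airfield_landscape,
    export_tiles,
    generate_point_patterns,
    render_orthoimage,
)


def small_land(size=100.0):
    return LandscapeSpec(Polygon([(0, 0), (size, 0), (size, size), (0, size)]))


def params(**kw):
    base = dict(
        burrow_count=15,
        mound_base_intensity=250.0,
        avoidance_radius=8.0,
        avoidance_strength=0.5,
        colony_centers=1,
        colony_spread=30.0,
        mole_patches=0,
    )
    base.update(kw)
    return AvoidanceParams(**base)


class TestPointPatterns:
    def test_zero_intensity_gives_no_mounds(self):
        _, mounds = generate_point_patterns(small_land(), params(mound_base_intensity=0.0), seed=1)
        assert len(mounds) == 0

    def test_expected_count_matches_intensity_without_avoidance(self):
        # Monte-Carlo expectation over 200 seeds: mean count within
        # 3 standard errors of intensity x area
        land = small_land(100.0)  # 1 ha
        p = params(avoidance_strength=0.0, mound_base_intensity=300.0)
        counts = [
            len(generate_point_patterns(land, p, seed=s)[1]) for s in range(200)
        ]
        counts = np.asarray(counts, dtype=float)
        expected = 300.0 * land.total_area_ha
        sem = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - expected) < 3 * sem

    def test_complete_thinning_leaves_exclusion_zone_empty(self):
        land = small_land()
        p = params(avoidance_strength=1.0, avoidance_radius=5.0)
        for seed in range(10):
            burrows, mounds = generate_point_patterns(land, p, seed=seed)
            if len(mounds) == 0:
                continue
            d = np.min(
                np.hypot(
                    mounds.x[:, None] - burrows.x[None, :],
                    mounds.y[:, None] - burrows.y[None, :],
                ),
                axis=1,
            )
            assert (d > 5.0).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_all_points_inside_boundary(self, seed):
        land = small_land(120.0)
        burrows, mounds = generate_point_patterns(
            land, params(mole_patches=4, mole_patch_spread=30.0), seed=seed
        )
        for pts in (burrows, mounds):
            assert shapely.contains_xy(land.boundary, pts.x, pts.y).all()

    def test_burrow_inhibition_spacing(self):
        burrows, _ = generate_point_patterns(small_land(), params(), seed=5)
        xy = burrows.xy
        d = np.linalg.norm(xy[:, None] - xy[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 10.0

    def test_presence_near_burrows_decreases_with_strength(self):
        # thinning calibration: empirical presence probability in 10 m^2
        # plots at burrows decreases monotonically in avoidance strength
        land = small_land(150.0)
        means = []
        for s in (0.0, 0.5, 1.0):
            vals = []
            for seed in range(25):
                burrows, mounds = generate_point_patterns(
                    land, params(avoidance_strength=s, mound_base_intensity=400.0), seed=seed
                )
                plots = [
                    bc.SamplePlot(x, y, bc.plot_radius(10.0), bc.Zone.BURROW, 0)
                    for x, y in burrows.xy
                ]
                scored = bc.score_plots(plots, mounds)
                vals.append(np.mean([p.presence for p in scored]))
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_impossible_packing_fails_loudly(self):
        land = small_land(15.0)
        with pytest.raises(GenerationError, match="boundary too small"):
            generate_point_patterns(
                land, params(burrow_count=10, burrow_min_spacing=10.0, colony_spread=0.0), seed=0
            )

    def test_same_seed_is_byte_identical(self):
        land = small_land()
        p = params(mole_patches=3)
        b1, m1 = generate_point_patterns(land, p, seed=77)
        b2, m2 = generate_point_patterns(land, p, seed=77)
        assert b1.xy.tobytes() == b2.xy.tobytes()
        assert m1.xy.tobytes() == m2.xy.tobytes()


class TestRendering:
    def test_truth_box_width_follows_diameter_over_gsd(self):
        land = small_land(4.0)
        pts = bc.PointSet2D(np.array([[2.0, 2.0]]), "mound")
        spec = ImageSpec(
            ground_sample_distance=0.02,
            mound_diameter_range=(0.30, 0.30),
            mound_aspect_range=(1.0, 1.0),
        )
        img = render_orthoimage(pts, land, spec, seed=0)
        (b,) = img.boxes
        assert abs((b.xmax - b.xmin) - 15) <= 1
        assert abs((b.ymax - b.ymin) - 15) <= 1

    def test_no_mounds_yields_background_only(self):
        land = small_land(4.0)
        img = render_orthoimage(bc.PointSet2D(np.empty((0, 2)), "mound"), land, ImageSpec(), seed=0)
        assert img.boxes == []
        assert img.image.shape == (200, 200)

    def test_box_count_conserved(self):
        land = small_land(30.0)
        rng = np.random.default_rng(8)
        pts = bc.PointSet2D(rng.uniform(2, 28, (100, 2)), "mound")
        img = render_orthoimage(pts, land, ImageSpec(ground_sample_distance=0.04), seed=8)
        assert len(img.boxes) == 100

    def test_box_centroids_backproject_to_mound_coordinates(self):
        land = small_land(20.0)
        rng = np.random.default_rng(9)
        xy = rng.uniform(2, 18, (20, 2))
        spec = ImageSpec(ground_sample_distance=0.02)
        img = render_orthoimage(bc.PointSet2D(xy, "mound"), land, spec, seed=9)
        assert len(img.boxes) == 20
        cx = np.array([(b.xmin + b.xmax) / 2 for b in img.boxes])
        cy = np.array([(b.ymin + b.ymax) / 2 for b in img.boxes])
        wx, wy = img.pixel_to_world(cx, cy)
        world = np.sort(np.column_stack([wx, wy]), axis=0)
        target = np.sort(xy, axis=0)
        assert np.abs(world - target).max() <= spec.ground_sample_distance

    def test_peak_brightness_exceeds_background_q99(self):
        land = small_land(10.0)
        pts = bc.PointSet2D(np.array([[5.0, 5.0]]), "mound")
        spec = ImageSpec(ground_sample_distance=0.02, mound_brightness_contrast=0.3)
        img = render_orthoimage(pts, land, spec, seed=2)
        b = img.boxes[0]
        window = img.image[int(b.ymin):int(b.ymax), int(b.xmin):int(b.xmax)]
        assert window.max() >= np.percentile(img.image, 99) + 0.2

    def test_same_seed_is_byte_identical(self):
        land = small_land(8.0)
        pts = bc.PointSet2D(np.array([[3.0, 3.0], [6.0, 5.0]]), "mound")
        a = render_orthoimage(pts, land, ImageSpec(), seed=4)
        b = render_orthoimage(pts, land, ImageSpec(), seed=4)
        assert a.image.tobytes() == b.image.tobytes()

    def test_coarse_gsd_rejected(self):
        with pytest.raises(ValueError, match="3 pixels"):
            ImageSpec(ground_sample_distance=0.10)


class TestTiling:
    def test_four_tiles_from_512(self):
        img = np.zeros((512, 512))
        tiles = export_tiles(img, [], 256, seed=0)
        assert len(tiles) == 4

    def test_box_inside_one_tile_appears_once_translated(self):
        img = np.zeros((512, 512))
        b = DetectionBox(300, 100, 320, 120)
        tiles = export_tiles(img, [b], 256, seed=0)
        hits = [(t, bb) for t in tiles for bb in t.boxes]
        assert len(hits) == 1
        t, bb = hits[0]
        assert t.index == (0, 1)
        assert (bb.xmin, bb.ymin, bb.xmax, bb.ymax) == (44, 100, 64, 120)

    def test_straddling_box_kept_only_in_majority_tile(self):
        # 60/40 split across the x=256 boundary: kept only where 60% lies
        img = np.zeros((256, 512))
        b = DetectionBox(250, 10, 260, 20)  # 6 px in tile 0, 4 px in tile 1
        tiles = export_tiles(img, [b], 256, seed=0)
        holders = [t.index for t in tiles if t.boxes]
        assert holders == [(0, 0)]
        bb = tiles[0].boxes[0]
        assert (bb.xmin, bb.xmax) == (250, 256)

    def test_every_truth_box_appears_at_least_once(self):
        rng = np.random.default_rng(12)
        img = np.zeros((512, 512))
        boxes = [
            DetectionBox(x, y, x + 12, y + 12)
            for x, y in rng.uniform(0, 498, (50, 2))
        ]
        tiles = export_tiles(img, boxes, 256, seed=0)
        assert sum(len(t.boxes) for t in tiles) >= 50

    def test_small_raster_padded_to_single_tile(self):
        img = np.full((100, 120), 0.5)
        tiles = export_tiles(img, [], 256, seed=0)
        assert len(tiles) == 1
        assert tiles[0].image.shape == (256, 256)


class TestLandscape:
    def test_airfield_area(self):
        land = airfield_landscape(105.0)
        assert land.total_area_ha == pytest.approx(105.0, rel=1e-6)

    def test_invalid_polygon_rejected(self):
        bowtie = Polygon([(0, 0), (1, 1), (1, 0), (0, 1)])
        with pytest.raises(ValueError):
            LandscapeSpec(bowtie)
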