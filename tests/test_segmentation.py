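import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungmorph.segmentation import (
    GrayRaster,
    LabeledAirspaceMap,
    SegmentationError,
    SegmentationParams,
    TissueMask,
    WallHullSet,
    binarize_tissue,
    extract_green_channel,
    extract_thick_walls,
    label_lumina,
    remove_vessels,
    segment_section,
    unimodal_threshold,
    wall_convex_hulls,
)
from lungmorph.synthetic import SceneSpec, render_scene


# ---------------------------------------------------------------- green channel
class TestExtractGreenChannel:
    def test_selects_second_channel(self):
        image = np.zeros((2, 2, 3), dtype=np.uint8)
        image[0, 0] = (200, 37, 180)
        gray = extract_green_channel(image, pixel_size_um=0.725)
        assert gray.pixels[0, 0] == 37
        assert gray.pixel_size_um == 0.725

    def test_all_white(self):
        image = np.full((4, 5, 3), 255, dtype=np.uint8)
        assert np.all(extract_green_channel(image, 1.0).pixels == 255)

    def test_shape_contract(self):
        image = np.zeros((7, 9, 3), dtype=np.uint8)
        assert extract_green_channel(image, 1.0).pixels.shape == (7, 9)

    def test_grayscale_input_rejected(self):
        with pytest.raises(ValueError, match="3 channels"):
            extract_green_channel(np.zeros((5, 5), dtype=np.uint8), 1.0)


# ---------------------------------------------------------- unimodal threshold
def brute_force_corner_threshold(hist):
    """Independent oracle: exhaustive point-to-line distance over all bins."""
    hist = np.asarray(hist, dtype=float)
    nz = [i for i, c in enumerate(hist) if c > 0]
    peak = max(range(len(hist)), key=lambda i: (hist[i], -i))
    lo, hi = nz[0], nz[-1]
    tail = hi if (hi - peak) >= (peak - lo) else lo
    if tail == peak:
        return peak
    p = np.array([peak, hist[peak]])
    q = np.array([tail, hist[tail]])
    best, best_i = -1.0, peak
    for i in range(min(peak, tail), max(peak, tail) + 1):
        x = np.array([i, hist[i]])
        v1, v2 = q - p, x - p
        d = abs(v1[0] * v2[1] - v1[1] * v2[0]) / np.linalg.norm(v1)
        if d > best + 1e-12 or (abs(d - best) <= 1e-12 and abs(i - peak) < abs(best_i - peak)):
            best, best_i = max(best, d), i
    return best_i


class TestUnimodalThreshold:
    def test_single_nonzero_bin(self):
        h = np.zeros(256)
        h[93] = 17
        assert unimodal_threshold(h) == 93

    def test_example_histogram_matches_brute_force(self):
        h = np.zeros(256)
        h[:6] = [100, 10, 8, 6, 4, 2]
        t = unimodal_threshold(h)
        assert t == brute_force_corner_threshold(h)
        assert t == 1  # frozen from the exhaustive evaluation

    def test_scale_invariance(self):
        h = np.zeros(256)
        h[:6] = [100, 10, 8, 6, 4, 2]
        assert unimodal_threshold(h) == unimodal_threshold(h * 10)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            unimodal_threshold(np.zeros(256))

    def test_negative_counts_rejected(self):
        h = np.zeros(256)
        h[0], h[1] = 5, -1
        with pytest.raises(ValueError):
            unimodal_threshold(h)

    @given(st.lists(st.integers(min_value=0, max_value=1000), min_size=2, max_size=64))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_on_random_histograms(self, counts):
        h = np.array(counts, dtype=float)
        if not np.any(h > 0):
            h[0] = 1
        assert unimodal_threshold(h) == brute_force_corner_threshold(h)


# ----------------------------------------------------------------- binarize
class TestBinarizeTissue:
    def test_threshold_255_all_true(self):
        gray = GrayRaster(np.arange(9, dtype=np.uint8).reshape(3, 3), 1.0)
        assert np.all(binarize_tissue(gray, 255).pixels)

    def test_threshold_below_minimum_all_false(self):
        gray = GrayRaster(np.full((3, 3), 100, dtype=np.uint8), 1.0)
        assert not np.any(binarize_tissue(gray, 50).pixels)

    def test_scene_mask_equals_rendered_walls(self, five_airspaces_one_vessel):
        spec, image, truth = five_airspaces_one_vessel
        gray = extract_green_channel(image, spec.pixel_size_um)
        mask = binarize_tissue(gray, 128).pixels
        walls = (truth.label_map == 0) & np.any(
            image != spec.background_level, axis=-1
        )
        assert np.array_equal(mask, walls)

    def test_out_of_range_threshold(self):
        gray = GrayRaster(np.zeros((2, 2), dtype=np.uint8), 1.0)
        with pytest.raises(ValueError):
            binarize_tissue(gray, 300)


# -------------------------------------------------------------- label lumina
class TestLabelLumina:
    def test_single_closed_ring(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True
        mask[7:13, 7:13] = False  # enclosed lumen
        result = label_lumina(TissueMask(mask), 1.0)
        assert result.n_regions == 1
        assert result.regions.loc[0, "area_px"] == 36

    def test_all_false_mask_no_regions(self):
        result = label_lumina(TissueMask(np.zeros((10, 10), dtype=bool)), 1.0)
        assert result.n_regions == 0
        assert not np.any(result.label_map)

    def test_scene_region_count(self, five_airspaces_one_vessel):
        spec, image, truth = five_airspaces_one_vessel
        gray = extract_green_channel(image, spec.pixel_size_um)
        tissue = binarize_tissue(gray, 128)
        result = label_lumina(tissue, spec.pixel_size_um)
        assert result.n_regions == truth.true_areas_um2.size == 6

    def test_labels_contiguous_and_centroids_inside_bbox(self, five_airspaces_one_vessel):
        spec, image, _ = five_airspaces_one_vessel
        gray = extract_green_channel(image, spec.pixel_size_um)
        result = label_lumina(binarize_tissue(gray, 128), spec.pixel_size_um)
        assert list(result.regions["label"]) == list(range(1, result.n_regions + 1))
        for row in result.regions.itertuples():
            rows, cols = np.nonzero(result.label_map == row.label)
            assert rows.min() <= row.centroid_row <= rows.max()
            assert cols.min() <= row.centroid_col <= cols.max()

    def test_area_sum_bounded_by_nontissue(self, five_airspaces_one_vessel):
        spec, image, _ = five_airspaces_one_vessel
        gray = extract_green_channel(image, spec.pixel_size_um)
        tissue = binarize_tissue(gray, 128)
        result = label_lumina(tissue, spec.pixel_size_um)
        assert result.regions["area_px"].sum() <= np.count_nonzero(~tissue.pixels)


# -------------------------------------------------------------- thick walls
def brute_force_erosion(mask, size):
    """Naive erosion: a pixel survives iff its full size x size window is set."""
    h, w = mask.shape
    r = size // 2
    out = np.zeros_like(mask)
    for i in range(h):
        for j in range(w):
            i0, i1 = i - r, i + r + 1
            j0, j1 = j - r, j + r + 1
            if i0 < 0 or j0 < 0 or i1 > h or j1 > w:
                continue  # border windows fall outside: not fully covered
            out[i, j] = mask[i0:i1, j0:j1].all()
    return out


class TestExtractThickWalls:
    def test_thin_stripe_removed(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[10:13, :] = True  # 3 px wide
        assert not np.any(extract_thick_walls(TissueMask(mask), 7).pixels)

    def test_block_shrinks_by_se_minus_one(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[5:55, 5:55] = True
        out = extract_thick_walls(TissueMask(mask), 7).pixels
        assert out.sum() == 44 * 44
        assert np.array_equal(out, brute_force_erosion(mask, 7))

    def test_empty_mask(self):
        out = extract_thick_walls(TissueMask(np.zeros((10, 10), dtype=bool)), 7)
        assert not np.any(out.pixels)

    @pytest.mark.parametrize("se_size", [2, 4, 1, 0])
    def test_invalid_se_size(self, se_size):
        with pytest.raises(ValueError):
            extract_thick_walls(TissueMask(np.ones((5, 5), dtype=bool)), se_size)

    def test_disk_element_supported(self):
        mask = np.ones((20, 20), dtype=bool)
        out = extract_thick_walls(TissueMask(mask), 7, se_shape="disk")
        assert out.pixels.sum() > 0

    @given(st.integers(0, 2**30 - 1))
    @settings(max_examples=25, deadline=None)
    def test_erosion_matches_brute_force_and_is_monotone(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((16, 16)) < 0.7
        out3 = extract_thick_walls(TissueMask(mask), 3).pixels
        out5 = extract_thick_walls(TissueMask(mask), 5).pixels
        assert np.array_equal(out3, brute_force_erosion(mask, 3))
        assert np.array_equal(out5, brute_force_erosion(mask, 5))
        assert not np.any(out3 & ~mask)  # subset of input
        assert not np.any(out5 & ~out3)  # growing SE never adds pixels


# ---------------------------------------------------------------- wall hulls
class TestWallConvexHulls:
    def test_square_ring_one_hull(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[8:32, 8:32] = True
        mask[14:26, 14:26] = False
        hulls = wall_convex_hulls(TissueMask(mask), downsample_factor=1)
        assert len(hulls.hulls) == 1
        verts = hulls.hulls[0]
        assert verts[:, 0].min() == 8 and verts[:, 0].max() == 31
        assert verts[:, 1].min() == 8 and verts[:, 1].max() == 31

    def test_two_disjoint_rings_two_hulls(self):
        mask = np.zeros((40, 80), dtype=bool)
        for off in (5, 45):
            mask[5:30, off : off + 25] = True
            mask[12:23, off + 7 : off + 18] = False
        hulls = wall_convex_hulls(TissueMask(mask), downsample_factor=1)
        assert len(hulls.hulls) == 2

    def test_c_shape_hull_closes_opening(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[5:35, 5:35] = True
        mask[12:28, 12:28] = False
        mask[15:25, 28:40] = False  # cut an opening: C-shaped wall
        hulls = wall_convex_hulls(TissueMask(mask), downsample_factor=1)
        assert len(hulls.hulls) == 1
        geom = hulls.geometries()[0]
        from shapely.geometry import Point

        assert geom.intersects(Point(20.0, 20.0))  # cavity center is enclosed

    def test_hull_contains_all_component_pixels(self):
        rng = np.random.default_rng(0)
        mask = np.zeros((30, 30), dtype=bool)
        pts = rng.integers(5, 25, size=(40, 2))
        mask[pts[:, 0], pts[:, 1]] = True
        hulls = wall_convex_hulls(TissueMask(mask), downsample_factor=1)
        from shapely.geometry import Point

        geoms = hulls.geometries()
        for r, c in np.argwhere(mask):
            assert any(g.distance(Point(float(c), float(r))) < 1e-9 for g in geoms)

    def test_empty_input(self):
        hulls = wall_convex_hulls(TissueMask(np.zeros((8, 8), dtype=bool)))
        assert hulls.hulls == []

    def test_or_pooling_preserves_single_pixels(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[3, 3] = True  # would vanish under subsampling at stride 4
        hulls = wall_convex_hulls(TissueMask(mask), downsample_factor=4)
        assert len(hulls.hulls) == 1

    def test_invalid_factor(self):
        with pytest.raises(ValueError):
            wall_convex_hulls(TissueMask(np.zeros((4, 4), dtype=bool)), 0)


# ------------------------------------------------------------- remove vessels
def winding_number_inside(polygon, point):
    """Oracle: winding number, with explicit on-boundary detection."""
    poly = np.asarray(polygon, dtype=float)
    px, py = point
    n = len(poly)
    wn = 0
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        cross = (x2 - x1) * (py - y1) - (px - x1) * (y2 - y1)
        if (
            abs(cross) < 1e-12
            and min(x1, x2) - 1e-12 <= px <= max(x1, x2) + 1e-12
            and min(y1, y2) - 1e-12 <= py <= max(y1, y2) + 1e-12
        ):
            return True  # on an edge
        if y1 <= py:
            if y2 > py and cross > 0:
                wn += 1
        elif y2 <= py and cross < 0:
            wn -= 1
    return wn != 0


def _map_with_centroids(centroids):
    rows = [
        {"label": k, "area_px": 1, "centroid_row": r, "centroid_col": c}
        for k, (r, c) in enumerate(centroids, start=1)
    ]
    label_map = np.zeros((64, 64), dtype=np.int32)
    for k, (r, c) in enumerate(centroids, start=1):
        label_map[int(r), int(c)] = k
    return LabeledAirspaceMap(label_map, pd.DataFrame(rows), 1.0)


class TestRemoveVessels:
    square = np.array([[0.0, 0.0], [0.0, 10.0], [10.0, 10.0], [10.0, 0.0]])

    def test_centroid_inside_removed(self):
        lumina = _map_with_centroids([(5.0, 5.0)])
        hulls = WallHullSet(hulls=[self.square], downsample_factor=1)
        assert remove_vessels(lumina, hulls).n_regions == 0

    def test_centroid_outside_kept(self):
        lumina = _map_with_centroids([(20.0, 20.0)])
        hulls = WallHullSet(hulls=[self.square], downsample_factor=1)
        assert remove_vessels(lumina, hulls).n_regions == 1

    def test_centroid_on_edge_removed(self):
        lumina = _map_with_centroids([(10.0, 5.0)])
        hulls = WallHullSet(hulls=[self.square], downsample_factor=1)
        assert remove_vessels(lumina, hulls).n_regions == 0

    def test_downsample_scaling_applied(self):
        # centroid (20, 20) at full resolution is (5, 5) in hull coordinates
        lumina = _map_with_centroids([(20.0, 20.0)])
        hulls = WallHullSet(hulls=[self.square], downsample_factor=4)
        assert remove_vessels(lumina, hulls).n_regions == 0

    def test_relabeling_contiguous(self):
        lumina = _map_with_centroids([(5.0, 5.0), (20.0, 20.0), (30.0, 40.0)])
        hulls = WallHullSet(hulls=[self.square], downsample_factor=1)
        out = remove_vessels(lumina, hulls)
        assert list(out.regions["label"]) == [1, 2]
        assert set(np.unique(out.label_map)) == {0, 1, 2}

    def test_never_increases_region_count(self, five_airspaces_one_vessel):
        spec, image, _ = five_airspaces_one_vessel
        gray = extract_green_channel(image, spec.pixel_size_um)
        tissue = binarize_tissue(gray, 128)
        lumina = label_lumina(tissue, spec.pixel_size_um)
        hulls = wall_convex_hulls(extract_thick_walls(tissue), 4)
        out = remove_vessels(lumina, hulls)
        assert out.n_regions <= lumina.n_regions

    @given(st.integers(0, 2**30 - 1))
    @settings(max_examples=40, deadline=None)
    def test_hull_membership_matches_winding_number(self, seed):
        rng = np.random.default_rng(seed)
        n_pts = int(rng.integers(3, 21))
        pts = rng.uniform(0, 30, size=(n_pts, 2))
        from shapely.geometry import MultiPoint

        geom = MultiPoint([(c, r) for r, c in pts]).convex_hull
        if geom.geom_type != "Polygon":
            return
        verts = np.asarray(geom.exterior.coords)[:-1, ::-1]
        hulls = WallHullSet(hulls=[verts], downsample_factor=1)
        probes = rng.uniform(-5, 35, size=(10, 2))
        geoms = hulls.geometries()
        for r, c in np.clip(probes, 0, 63):
            expected = winding_number_inside(
                [(x, y) for y, x in verts], (c, r)
            )
            from shapely.geometry import Point

            got = any(g.intersects(Point(c, r)) for g in geoms)
            assert got == expected


# ------------------------------------------------------------ full pipeline
class TestSegmentSection:
    def test_scene_counts(self, five_airspaces_one_vessel):
        spec, image, truth = five_airspaces_one_vessel
        result = segment_section(image, SegmentationParams(pixel_size_um=1.0))
        assert result.n_regions == truth.n_airspaces == 5
        for vl in truth.vessel_labels:
            assert not np.any((result.label_map > 0) & (truth.label_map == vl))

    def test_blank_image(self):
        image = np.full((64, 64, 3), 230, dtype=np.uint8)
        result = segment_section(image, SegmentationParams(pixel_size_um=1.0))
        assert result.n_regions == 0

    def test_vessel_only_scene(self):
        from lungmorph.synthetic import Ellipse

        spec = SceneSpec(
            image_size=(200, 200),
            pixel_size_um=1.0,
            vessels=(Ellipse((100, 100), (30, 30), 0.0, 12.0),),
        )
        image, truth = render_scene(spec)
        assert truth.vessel_labels == {1}
        result = segment_section(image, SegmentationParams(pixel_size_um=1.0))
        assert result.n_regions == 0

    def test_stage_error_identified(self):
        with pytest.raises(SegmentationError) as err:
            segment_section(np.zeros((10, 10), dtype=np.uint8))
        assert err.value.stage == "green_channel"

    def test_accepted_areas_match_truth_noise_free(self, five_airspaces_one_vessel):
        spec, image, truth = five_airspaces_one_vessel
        result = segment_section(image, SegmentationParams(pixel_size_um=1.0))
        for row in result.regions.itertuples():
            region = result.label_map == row.label
            overlap = np.bincount(truth.label_map[region])
            true_label = int(overlap.argmax())
            true_area = np.count_nonzero(truth.label_map == true_label)
            perimeter = 2 * np.pi * np.sqrt(true_area / np.pi)
            assert abs(row.area_px - true_area) <= perimeter

    def test_min_area_filter(self, five_airspaces_one_vessel):
        spec, image, _ = five_airspaces_one_vessel
        params = SegmentationParams(pixel_size_um=1.0, min_airspace_area_px=10**6)
        assert segment_section(image, params).n_regions == 0
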