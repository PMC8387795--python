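"""Density-mapping contracts: merging, detection, binning, smoothing,
Otsu masking, map combination and the center/edge statistic."""

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st
from scipy.spatial import cKDTree

from hhpbone.density_mapping import (
    CellDetections,
    DensityMap,
    SmoothedDensity,
    TrabecularMask,
    center_edge_statistic,
    combine_map,
    compute_density_matrix,
    detect_cells,
    edge_corrected_density,
    estimate_sample_support,
    gaussian_normalize,
    merge_tiles,
    otsu_threshold,
    trabecular_mask,
)
from hhpbone.exceptions import (
    AlignmentError,
    ConfigError,
    DegenerateImageError,
    LayoutError,
    ZoneError,
)
from hhpbone.synthetic import cut_tiles


def make_detections(positions, positive=None):
    positions = np.asarray(positions, dtype=float).reshape(-1, 2)
    n = len(positions)
    if positive is None:
        positive = np.ones(n, dtype=bool)
    return CellDetections(
        positions=positions,
        tunel_positive=np.asarray(positive, dtype=bool),
        dapi_intensity=np.ones(n),
        tunel_intensity=np.ones(n),
        radii=np.full(n, 3.0),
    )


class TestMergeTiles:
    def test_single_tile_identity(self):
        rng = np.random.default_rng(0)
        tile = rng.random((64, 64))
        assert np.array_equal(merge_tiles([tile], (1, 1)), tile)

    def test_constant_tiles_any_overlap(self):
        tiles = [np.full((32, 32), 7.0)] * 4
        merged = merge_tiles(tiles, (2, 2), overlap_px=8)
        assert merged.shape == (56, 56)
        assert np.allclose(merged, 7.0)

    def test_roundtrip_with_overlap(self):
        rng = np.random.default_rng(1)
        img = rng.random((64, 118))
        tiles = cut_tiles(img, (1, 2), overlap_px=10)
        rec = merge_tiles(tiles, (1, 2), overlap_px=10)
        assert np.allclose(rec, img, atol=1e-12)

    def test_layout_errors(self):
        t = np.zeros((8, 8))
        with pytest.raises(LayoutError):
            merge_tiles([t, t, t], (2, 2))
        with pytest.raises(LayoutError):
            merge_tiles([t, np.zeros((8, 9))], (1, 2))


class TestDetectCells:
    def test_blank_images_no_detections(self):
        blank = np.zeros((128, 128))
        assert len(detect_cells(blank, blank)) == 0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ConfigError):
            detect_cells(np.zeros((10, 10)), np.zeros((10, 12)))

    def test_scene_recall_and_precision(self, small_scene):
        """>= 95% of 200 planted nuclei found within 2 px, <= 5% spurious."""
        params, tunel_tiles, dapi_tiles, truth = small_scene
        dapi = merge_tiles(dapi_tiles, params.tile_grid)
        tunel = merge_tiles(tunel_tiles, params.tile_grid)
        dets = detect_cells(dapi, tunel)
        tree = cKDTree(dets.positions)
        d, idx = tree.query(truth.positions)
        recall = np.mean(d <= 2.0)
        spurious = (len(dets) - np.sum(d <= 2.0)) / len(dets)
        assert recall >= 0.95
        assert spurious <= 0.05
        # TUNEL labels agree with the generator truth for matched cells
        ok = d <= 2.0
        agree = dets.tunel_positive[idx[ok]] == truth.tunel_positive[ok]
        assert agree.mean() >= 0.98

    def test_background_tunel_labels_negative(self):
        rng = np.random.default_rng(4)
        dapi = 0.05 + 0.005 * rng.standard_normal((96, 96))
        yy, xx = np.mgrid[0:96, 0:96]
        dapi += 0.6 * np.exp(-((xx - 48.0) ** 2 + (yy - 48.0) ** 2) / (2 * 9.0))
        tunel = np.full((96, 96), 0.02)
        dets = detect_cells(dapi, tunel)
        assert len(dets) == 1
        assert not dets.tunel_positive[0]


class TestDensityMatrix:
    def test_no_positives_zero_matrix(self):
        dets = make_detections(np.empty((0, 2)))
        m = compute_density_matrix(dets, 16, (0, 0, 64, 64))
        assert m.bin_counts.shape == (4, 4)
        assert m.total == 0

    def test_corner_point_assigned_once(self):
        dets = make_detections([(16.0, 16.0)])  # shared corner of 4 bins
        m = compute_density_matrix(dets, 16, (0, 0, 64, 64))
        assert m.total == 1
        assert m.bin_counts[1, 1] == 1  # half-open convention: lower-right bin

    def test_uniform_positions_pass_chi_square(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 256, size=(1000, 2))
        m = compute_density_matrix(make_detections(pts), 32, (0, 0, 256, 256))
        assert m.total == 1000
        from scipy.stats import chisquare

        assert chisquare(m.bin_counts.ravel()).pvalue > 0.01

    def test_region_errors(self):
        dets = make_detections([(1.0, 1.0)])
        with pytest.raises(ConfigError):
            compute_density_matrix(dets, 16, (10, 10, 10, 20))
        with pytest.raises(ConfigError):
            compute_density_matrix(dets, 0.5, (0, 0, 10, 10))


class TestGaussianNormalize:
    def test_sigma_zero_is_identity(self):
        m = compute_density_matrix(
            make_detections([(5.0, 5.0), (20.0, 9.0)]), 8, (0, 0, 32, 32)
        )
        sd = gaussian_normalize(m, 0.0)
        assert np.array_equal(sd.values, m.bin_counts.astype(float))

    def test_point_source_matches_closed_form_kernel(self):
        dets = make_detections([(328.0, 328.0)])
        m = compute_density_matrix(dets, 16, (0, 0, 656, 656))
        sd = gaussian_normalize(m, 2.0)
        sigma = 2.0
        peak = sd.values.max()
        assert peak == pytest.approx(1.0 / (2 * np.pi * sigma**2), rel=0.01)

    def test_total_conserved(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            pts = rng.uniform(0, 200, size=(rng.integers(1, 300), 2))
            m = compute_density_matrix(make_detections(pts), 10, (0, 0, 200, 200))
            sd = gaussian_normalize(m, rng.uniform(0.5, 4.0))
            assert sd.total == pytest.approx(m.total, rel=1e-9)

    def test_negative_sigma_raises(self):
        m = compute_density_matrix(make_detections([(1.0, 1.0)]), 8, (0, 0, 16, 16))
        with pytest.raises(ConfigError):
            gaussian_normalize(m, -1.0)


def brute_force_otsu(img):
    """Independent oracle: exhaustive search over all 256 thresholds."""
    vals = img.ravel().astype(float)
    best_t, best_v = None, -np.inf
    for t in range(256):
        lo, hi = vals[vals <= t], vals[vals > t]
        if len(lo) == 0 or len(hi) == 0:
            continue
        w0, w1 = len(lo) / len(vals), len(hi) / len(vals)
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v + 1e-12:
            best_v, best_t = v, t
    return best_t


class TestOtsu:

    def test_bimodal_delta_histogram(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        img[:, 5:] = 255
        t = otsu_threshold(img)
        assert 0 <= t < 255
        assert np.array_equal(img > t, img == 255)

    def test_matches_brute_force_on_random_images(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            img = rng.integers(0, 256, size=(40, 40), dtype=np.uint8)
            assert otsu_threshold(img) == brute_force_otsu(img)

    def test_constant_image_raises(self):
        with pytest.raises(DegenerateImageError):
            otsu_threshold(np.full((8, 8), 7, dtype=np.uint8))

    @settings(max_examples=25, deadline=None, derandomize=True,
              suppress_health_check=[HealthCheck.too_slow])
    @given(st.integers(0, 2**32 - 1))
    def test_brute_force_agreement_property(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, size=(24, 24), dtype=np.uint8)
        if img.min() == img.max():
            return
        assert otsu_threshold(img) == brute_force_otsu(img)


class TestTrabecularMask:
    def test_scene_fraction_and_jaccard(self):
        from hhpbone.synthetic import HistologySceneParams, generate_histology_scene

        params = HistologySceneParams(
            image_shape=(384, 384),
            tile_grid=(1, 1),
            n_cells=150,
            trabecula_fraction=0.4,
            texture_scale_px=48.0,
            seed=11,
        )
        _, dapi_tiles, truth = generate_histology_scene(params)
        tm = trabecular_mask(dapi_tiles[0])
        truth_frac = truth.trabecular_mask.mean()
        assert abs(tm.area_fraction - truth_frac) <= 0.05
        inter = (tm.mask & truth.trabecular_mask).sum()
        union = (tm.mask | truth.trabecular_mask).sum()
        assert inter / union >= 0.9

    def test_bright_half_exact(self):
        img = np.zeros((20, 20))
        img[:, 10:] = 1.0
        tm = trabecular_mask(img)
        assert np.array_equal(tm.mask, img == 1.0)

    def test_inversion_flag_complements(self):
        img = np.zeros((20, 20))
        img[:, 10:] = 1.0
        normal = trabecular_mask(img).mask
        flipped = trabecular_mask(1.0 - img, invert=True).mask
        assert np.array_equal(normal, flipped)


class TestCombineMap:
    def _sd(self, values, bin_size=16.0):
        return SmoothedDensity(
            values=np.asarray(values, dtype=float),
            sigma_bins=1.0,
            bin_size_px=bin_size,
            origin=(0.0, 0.0),
        )

    def test_all_true_mask_keeps_values(self):
        vals = np.arange(16.0).reshape(4, 4)
        dm = combine_map(self._sd(vals), np.ones((4, 4), dtype=bool))
        assert np.array_equal(dm.map, vals)

    def test_all_false_mask_all_sentinel(self):
        dm = combine_map(self._sd(np.ones((4, 4))), np.zeros((4, 4), dtype=bool))
        assert np.all(np.isnan(dm.map))

    def test_checkerboard_bin_by_bin(self):
        vals = np.arange(36.0).reshape(6, 6)
        mask = (np.indices((6, 6)).sum(axis=0) % 2) == 0
        dm = combine_map(self._sd(vals), mask)
        for i in range(6):
            for j in range(6):
                if mask[i, j]:
                    assert dm.map[i, j] == vals[i, j]
                else:
                    assert np.isnan(dm.map[i, j])

    def test_pixel_mask_majority_downsampling(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[:, :40] = True  # bins 0,1 fully true; bin 2 half (8/16 -> true)
        dm = combine_map(self._sd(np.ones((4, 4))), TrabecularMask(mask, 0.5))
        assert np.array_equal(dm.bin_mask[:, 0], np.ones(4, dtype=bool))
        assert np.array_equal(dm.bin_mask[:, 3], np.zeros(4, dtype=bool))
        assert dm.bin_mask[0, 2]  # exactly half true -> majority rule keeps it

    def test_incompatible_geometry_raises(self):
        with pytest.raises(AlignmentError):
            combine_map(self._sd(np.ones((4, 4))), np.zeros((2, 2), dtype=bool))


class TestCenterEdgeStatistic:
    def _map(self, values, mask=None):
        values = np.asarray(values, dtype=float)
        if mask is None:
            mask = np.ones_like(values, dtype=bool)
        return DensityMap(
            map=np.where(mask, values, np.nan),
            bin_mask=mask,
            sentinel=np.nan,
            bin_size_px=16.0,
            origin=(0.0, 0.0),
        )

    def test_uniform_map_ratio_one(self):
        stat = center_edge_statistic(self._map(np.full((21, 21), 3.0)))
        assert stat.ratio == pytest.approx(1.0)

    def test_inverted_gradient_ratio_below_one_profile_increasing(self):
        yy, xx = np.mgrid[0:41, 0:41]
        r = np.hypot(yy - 20, xx - 20)
        vals = 1.0 + r / r.max() * 3.0  # increasing outward
        stat = center_edge_statistic(self._map(vals))
        assert stat.ratio < 1.0
        prof = stat.radial_profile[~np.isnan(stat.radial_profile)]
        assert np.all(np.diff(prof) > -1e-9)

    def test_empty_zone_raises(self):
        # an annulus: the centroid region holds no masked-in bins
        yy, xx = np.mgrid[0:21, 0:21]
        r = np.hypot(yy - 10, xx - 10)
        mask = (r >= 7) & (r <= 10)
        with pytest.raises(ZoneError):
            center_edge_statistic(self._map(np.ones((21, 21)), mask))

    def test_bad_fractions_raise(self):
        with pytest.raises(ConfigError):
            center_edge_statistic(self._map(np.ones((5, 5))), 0.9, 0.2)


class TestPipelineInvariants:
    def test_translation_invariance(self):
        """Shifting all detections by whole bins shifts the map identically
        (mass kept far enough from the boundary that reflection is inert)."""
        rng = np.random.default_rng(12)
        pts = rng.uniform(160, 288, size=(150, 2))
        shift = 32.0  # 2 bins of 16 px
        m1 = compute_density_matrix(make_detections(pts), 16, (0, 0, 512, 512))
        m2 = compute_density_matrix(make_detections(pts + shift), 16, (0, 0, 512, 512))
        s1 = gaussian_normalize(m1, 1.5).values
        s2 = gaussian_normalize(m2, 1.5).values
        assert np.allclose(np.roll(s2, (-2, -2), axis=(0, 1)), s1, atol=1e-12)

    def test_end_to_end_count_conservation(self, small_scene):
        params, tunel_tiles, dapi_tiles, truth = small_scene
        dapi = merge_tiles(dapi_tiles, params.tile_grid)
        tunel = merge_tiles(tunel_tiles, params.tile_grid)
        dets = detect_cells(dapi, tunel)
        H, W = dapi.shape
        m = compute_density_matrix(dets, 16, (0, 0, W, H))
        sd = gaussian_normalize(m, 2.0)
        assert m.total == dets.n_positive
        assert sd.total == pytest.approx(m.total, rel=1e-9)

    def test_edge_corrected_density_flat_on_uniform_disc(self):
        """Support-normalized smoothing removes the boundary dip a plain
        smooth shows on a uniformly filled disc."""
        rng = np.random.default_rng(5)
        n = 4000
        ang = rng.uniform(0, 2 * np.pi, n)
        rad = 120 * np.sqrt(rng.uniform(size=n))
        pts = np.column_stack([128 + rad * np.cos(ang), 128 + rad * np.sin(ang)])
        dets = make_detections(pts)
        m = compute_density_matrix(dets, 8, (0, 0, 256, 256))
        support = estimate_sample_support(dets, m.bin_counts.shape, 8.0)
        plain = gaussian_normalize(m, 2.0).values
        corrected = edge_corrected_density(m, 2.0, support).values
        yy, xx = np.mgrid[0:32, 0:32]
        rr = np.hypot(yy - 15.5, xx - 15.5)
        interior = rr < 8
        ring = (rr > 13) & (rr < 14.8) & support
        interior_mean = corrected[interior].mean()
        assert corrected[ring].mean() == pytest.approx(interior_mean, rel=0.15)
        assert plain[ring].mean() < 0.9 * interior_mean  # plain smoothing dips
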