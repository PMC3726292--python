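import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import make_image
from filodetect.filopodia import (
    classify_combined,
    count_skeleton_features,
    detect_filopodia,
    disk_footprint,
    disk_structuring_element,
    estimate_filopodium_width,
    extract_candidates,
    fit_region_ellipse,
    measure_length,
    morphological_opening,
    skeletonize_region,
)
from filodetect.records import DetectionParams, PixelRegion
from filodetect.segmentation import segment_cell
from filodetect.synthetic import SyntheticSpec, generate_cell_image
from oracle_utils import bfs_label


def region_of(pixels):
    return PixelRegion.from_pixels(pixels)


class TestStructuringElement:
    def test_half_micron_at_half_micron_pixels_is_plus(self):
        se = disk_structuring_element(0.5, 0.5)
        assert se == {(0, 0), (1, 0), (-1, 0), (0, 1), (0, -1)}

    def test_subpixel_radius_degenerates_with_warning(self):
        with pytest.warns(UserWarning, match="single pixel"):
            se = disk_structuring_element(0.2, 0.5)
        assert se == {(0, 0)}

    def test_point_symmetric(self):
        se = disk_structuring_element(0.7, 0.2)
        assert all((-dr, -dc) in se for dr, dc in se)


class TestOpening:
    def test_identity_element_is_identity(self):
        rng = np.random.default_rng(0)
        mask = rng.random((20, 20)) < 0.4
        assert np.array_equal(morphological_opening(mask, {(0, 0)}), mask)

    def test_thin_line_removed_by_plus_element(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[4, 1:8] = True
        se = {(0, 0), (1, 0), (-1, 0), (0, 1), (0, -1)}
        assert not morphological_opening(mask, se).any()

    @given(st.integers(0, 10_000))
    def test_antiextensive_and_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((24, 24)) < 0.5
        se = disk_footprint(1.5)
        opened = morphological_opening(mask, se)
        assert not (opened & ~mask).any()  # opened is a subset
        assert np.array_equal(morphological_opening(opened, se), opened)


class TestExtractCandidates:
    def test_no_residue_gives_empty_list(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:8, 2:8] = True
        assert extract_candidates(mask, mask) == []

    def test_two_spikes_give_two_regions(self):
        cell = np.zeros((20, 20), dtype=bool)
        cell[5:15, 5:15] = True
        cell[2:5, 7] = True
        cell[2:5, 12] = True
        opened = np.zeros_like(cell)
        opened[5:15, 5:15] = True
        regions = extract_candidates(cell, opened)
        assert len(regions) == 2
        assert sum(r.area for r in regions) == 6

    def test_agrees_with_flood_fill_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            cell = rng.random((30, 30)) < 0.5
            opened = cell & (rng.random((30, 30)) < 0.6)
            regions = extract_candidates(cell, opened)
            labels, n = bfs_label(cell & ~opened, connectivity=8)
            assert len(regions) == n
            got = {frozenset(r.pixels) for r in regions}
            want = {
                frozenset(zip(*np.nonzero(labels == i)))
                for i in range(1, n + 1)
            }
            want = {frozenset((int(a), int(b)) for a, b in s) for s in want}
            assert got == want

    def test_opened_must_be_subset(self):
        cell = np.zeros((5, 5), dtype=bool)
        opened = np.ones((5, 5), dtype=bool)
        with pytest.raises(ValueError, match="subset"):
            extract_candidates(cell, opened)


class TestEllipseFit:
    def test_thin_bar_is_strongly_elongated(self):
        fit = fit_region_ellipse(region_of([(0, c) for c in range(9)]))
        assert fit.axis_ratio > 5

    def test_square_is_round(self):
        fit = fit_region_ellipse(region_of([(r, c) for r in range(3) for c in range(3)]))
        assert fit.major_axis_px == pytest.approx(fit.minor_axis_px)

    def test_rotation_invariance(self):
        pixels = [(r, c) for r in range(2) for c in range(7)]
        rotated = [(c, r) for r, c in pixels]
        f1 = fit_region_ellipse(region_of(pixels))
        f2 = fit_region_ellipse(region_of(rotated))
        assert f1.major_axis_px == pytest.approx(f2.major_axis_px)
        assert f1.minor_axis_px == pytest.approx(f2.minor_axis_px)

    def test_single_pixel_is_unit_circle(self):
        fit = fit_region_ellipse(region_of([(3, 3)]))
        assert fit.major_axis_px == fit.minor_axis_px == 1.0


class TestWidthEstimate:
    def test_mean_minor_axis_of_elongated_bars(self):
        bars = [
            region_of([(r, c) for r in range(2) for c in range(20)]),
            region_of([(r, c) for r in range(4) for c in range(20)]),
        ]
        L = estimate_filopodium_width(bars, DetectionParams(), 0.1)
        minors = [fit_region_ellipse(b).minor_axis_px for b in bars]
        assert L == pytest.approx(np.mean(minors))
        # minor axis of a width-w bar tracks w within a pixel
        assert abs(minors[0] - 2) <= 1 and abs(minors[1] - 4) <= 1

    def test_round_candidates_fall_back_to_opening_radius(self):
        blobs = [region_of([(r, c) for r in range(4) for c in range(4)])]
        with pytest.warns(UserWarning, match="falling back"):
            L = estimate_filopodium_width(blobs, DetectionParams(), 0.1)
        assert L == pytest.approx(0.5 / 0.1)


class TestSkeleton:
    def test_unit_line_is_its_own_skeleton(self):
        pixels = [(5, c) for c in range(3, 13)]
        assert skeletonize_region(region_of(pixels)) == frozenset(pixels)

    def test_bar_thins_to_midline(self):
        n = 20
        region = region_of([(r, c) for r in range(3) for c in range(n)])
        skel = skeletonize_region(region)
        assert n - 2 <= len(skel) <= n + 2

    def test_skeleton_stays_connected(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            # random connected blob: dilate a random walk
            path = [(15, 15)]
            for _ in range(60):
                dr, dc = rng.integers(-1, 2, size=2)
                r = min(max(path[-1][0] + int(dr), 1), 28)
                c = min(max(path[-1][1] + int(dc), 1), 28)
                path.append((r, c))
            pixels = {(r + dr, c + dc) for r, c in path
                      for dr in (0, 1) for dc in (0, 1)}
            skel = skeletonize_region(region_of(pixels))
            mask = np.zeros((32, 32), dtype=bool)
            for r, c in skel:
                mask[r, c] = True
            _, n_comp = bfs_label(mask, connectivity=8)
            assert n_comp == 1


class TestSkeletonFeatures:
    def test_straight_line(self):
        skel = frozenset((0, c) for c in range(10))
        assert count_skeleton_features(skel) == (2, 0)

    def test_h_shape_two_junctions(self):
        # two diagonal V-junctions joined by a vertical bar
        skel = frozenset([
            (0, 0), (1, 1), (0, 4), (1, 3), (2, 2),  # upper V into junction
            (3, 2), (4, 2),                            # stem
            (5, 2), (6, 1), (6, 3), (7, 0), (7, 4),   # lower junction and V
        ])
        assert count_skeleton_features(skel) == (4, 2)

    def test_y_shape(self):
        skel = frozenset([(0, 0), (1, 1), (0, 4), (1, 3), (2, 2), (3, 2), (4, 2)])
        assert count_skeleton_features(skel) == (3, 1)

    def test_isolated_pixel_is_one_endpoint(self):
        assert count_skeleton_features(frozenset([(2, 2)])) == (1, 0)


class TestClassifyCombined:
    @pytest.mark.parametrize("ends,branches,expected", [
        (2, 0, False),
        (4, 2, True),
        (4, 1, False),   # literal conjunction: one branch point is not enough
        (3, 2, False),
        (5, 3, True),
    ])
    def test_literal_conjunctive_rule(self, ends, branches, expected):
        assert classify_combined(ends, branches) is expected


class TestMeasureLength:
    def test_pixel_count_semantics(self):
        skel = frozenset((0, c) for c in range(10))
        assert measure_length(skel, 0.1) == pytest.approx(1.0)
        assert measure_length(frozenset([(0, 0)]), 0.2) == pytest.approx(0.2)

    def test_diagonal_counts_pixels_not_euclidean(self):
        skel = frozenset((i, i) for i in range(10))
        assert measure_length(skel, 0.1) == pytest.approx(1.0)


class TestDetectFilopodia:
    def test_bare_disk_detects_nothing(self, disk_cell_image):
        img, _ = disk_cell_image
        res = detect_filopodia(img)
        assert res.n_total == 0 and res.filopodia == ()

    def test_single_short_stub_below_minimum_is_dropped(self):
        # hand-built cell: disk plus one 3x3 (0.3 um) axis-aligned stub
        yy, xx = np.mgrid[0:128, 0:128]
        disk = np.hypot(yy - 64, xx - 64) <= 40
        disk[63:66, 104:107] = True  # stub sticking out on the right
        img = make_image(np.where(disk, 200, 10).astype(np.uint8))
        res = detect_filopodia(img)
        assert res.n_total == 0

    def test_twelve_separated_filaments_counted_exactly(self):
        spec = SyntheticSpec(n_filopodia=12, seed=42)
        img, gt = generate_cell_image(spec)
        res = detect_filopodia(img)
        assert res.n_total == 12
        assert res.n_single == 12 and res.n_combined == 0

    def test_detections_inside_cell_and_disjoint_from_opened_body(self):
        spec = SyntheticSpec(n_filopodia=15, seed=7)
        img, _ = generate_cell_image(spec)
        cell = segment_cell(img)
        res = detect_filopodia(img, cell=cell)
        assert res.n_total == 15
        for rec in res.filopodia:
            assert rec.length_um >= res.params_used.min_length_um
            for r, c in rec.region.pixels:
                assert cell.mask[r, c]

    def test_pipeline_is_deterministic(self):
        spec = SyntheticSpec(n_filopodia=10, seed=3)
        img, _ = generate_cell_image(spec)
        a = detect_filopodia(img)
        b = detect_filopodia(img)
        assert a == b
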