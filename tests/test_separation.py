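"""Hull merging, boundary tracing, curvature, neck splitting."""

import numpy as np
import pytest

from _oracles import brute_force_hull_vertices
from archseg import separation
from archseg.separation import (
    ClosedContour,
    NoOverlapError,
    convex_hull_merge,
    find_cut_points,
    morphological_prepare,
    second_derivative,
    separate_pipeline,
    smooth_contour,
    split_object,
    trace_boundary,
)
from conftest import make_disc


def circle_contour(radius=50.0, n=100, center=(60.0, 60.0)):
    theta = 2 * np.pi * np.arange(n) / n
    pts = np.stack([center[0] + radius * np.cos(theta), center[1] + radius * np.sin(theta)], axis=1)
    return ClosedContour(points=np.rint(pts).astype(int), smoothed=pts)


class TestConvexHullMerge:
    def test_hull_of_disc_equals_disc_up_to_one_pixel(self):
        disc = make_disc((60, 60), (30, 30), 15)
        hull = convex_hull_merge([disc]).hull_mask
        assert not (disc & ~hull).any()
        from scipy import ndimage as ndi

        extra = hull & ~disc
        assert not (extra & ~ndi.binary_dilation(disc)).any()

    def test_two_points_give_line_segment(self):
        m = np.zeros((5, 20), dtype=bool)
        m[0, 0] = m[0, 10] = True
        hull = convex_hull_merge([m]).hull_mask
        assert hull.sum() == 11
        assert hull[0, :11].all()

    def test_vertices_match_brute_force_hull(self):
        rng = np.random.default_rng(40)
        pts = rng.integers(5, 55, size=(20, 2))
        m = np.zeros((60, 60), dtype=bool)
        m[pts[:, 0], pts[:, 1]] = True
        hull = convex_hull_merge([m]).hull_mask
        vertices = brute_force_hull_vertices(pts)
        for r, c in vertices:  # every brute-force vertex is in the mask
            assert hull[r, c]
        # and the mask stays within the brute-force hull polygon (1-px slack)
        from shapely.geometry import MultiPoint, Point

        poly = MultiPoint([tuple(map(float, v)) for v in vertices]).convex_hull.buffer(1.0)
        for r, c in np.argwhere(hull):
            assert poly.contains(Point(float(r), float(c)))

    def test_hull_grows_monotonically_with_components(self):
        a = make_disc((80, 80), (30, 30), 10)
        b = make_disc((80, 80), (50, 55), 8)
        h1 = convex_hull_merge([a]).hull_mask
        h2 = convex_hull_merge([a, b]).hull_mask
        assert not (h1 & ~h2).any()

    def test_empty_components_rejected(self):
        with pytest.raises(ValueError):
            convex_hull_merge([np.zeros((5, 5), dtype=bool)])


class TestMorphologicalPrepare:
    def test_interior_hole_filled(self):
        disc = make_disc((50, 50), (25, 25), 12).copy()
        disc[25, 25] = False
        out = morphological_prepare(disc)
        assert out[25, 25]

    def test_one_pixel_spur_removed(self):
        sq = np.zeros((30, 30), dtype=bool)
        sq[10:20, 10:20] = True
        sq[15, 20] = True  # spur
        out = morphological_prepare(sq)
        assert not out[15, 20]
        assert out[12:18, 12:18].all()

    def test_largest_component_kept(self):
        m = np.zeros((40, 40), dtype=bool)
        m[5:15, 5:15] = True  # area 100
        m[30:31, 30:33] = True  # area 3
        out = morphological_prepare(m)
        assert out[10, 10] and not out[30, 31]


class TestTraceBoundary:
    def test_three_by_three_square_contour(self):
        m = np.zeros((6, 6), dtype=bool)
        m[2:5, 2:5] = True
        contour = trace_boundary(m)
        pts = {tuple(p) for p in contour.points}
        border = {(r, c) for r in range(2, 5) for c in range(2, 5) if (r, c) != (3, 3)}
        assert pts == border
        # consecutive points are 8-neighbours, cyclically
        p = contour.points
        diffs = np.abs(np.roll(p, -1, axis=0) - p)
        assert diffs.max() <= 1

    def test_disc_contour_length_near_circumference(self):
        m = make_disc((50, 50), (25, 25), 15)
        contour = trace_boundary(m)
        assert len(contour) == pytest.approx(2 * np.pi * 15, rel=0.15)

    def test_translation_equivariance(self):
        m1 = make_disc((60, 60), (20, 20), 10)
        m2 = make_disc((60, 60), (32, 27), 10)
        c1, c2 = trace_boundary(m1), trace_boundary(m2)
        assert np.array_equal(c1.points + [12, 7], c2.points)

    def test_multi_component_mask_rejected(self):
        m = np.zeros((20, 20), dtype=bool)
        m[2, 2] = m[15, 15] = True
        with pytest.raises(ValueError, match="connected"):
            trace_boundary(m)


class TestSmoothAndCurvature:
    def test_window_one_is_identity(self):
        c = trace_boundary(make_disc((40, 40), (20, 20), 10))
        sm = smooth_contour(c, window=1)
        assert np.allclose(sm.smoothed, c.points)

    def test_centroid_preserved(self):
        c = trace_boundary(make_disc((40, 40), (20, 20), 12))
        sm = smooth_contour(c, window=7)
        assert np.allclose(sm.smoothed.mean(axis=0), c.points.mean(axis=0), atol=1e-9)

    def test_square_corners_rounded(self):
        m = np.zeros((40, 40), dtype=bool)
        m[10:30, 10:30] = True
        raw = second_derivative(smooth_contour(trace_boundary(m), window=1))
        smoothed = second_derivative(smooth_contour(trace_boundary(m), window=5))
        assert np.linalg.norm(smoothed.d2, axis=1).max() < np.linalg.norm(raw.d2, axis=1).max()

    def test_straight_line_has_zero_second_derivative(self):
        pts = np.stack([np.arange(10.0), np.arange(10.0)], axis=1)
        c = ClosedContour(points=pts.astype(int), smoothed=pts)
        d2 = second_derivative(c).d2
        assert np.allclose(d2[1:-1], 0.0)

    def test_circle_curvature_points_inward_with_analytic_magnitude(self):
        rho, n = 50.0, 100
        c = second_derivative(circle_contour(rho, n))
        expected = 2 * rho * (1 - np.cos(2 * np.pi / n))
        mags = np.linalg.norm(c.d2, axis=1)
        assert np.allclose(mags, expected, rtol=1e-6)
        # direction toward the centre
        to_center = np.array([60.0, 60.0]) - c.smoothed
        cos = np.sum(c.d2 * to_center, axis=1) / (mags * np.linalg.norm(to_center, axis=1))
        assert np.all(cos > 0.999)

    def test_cyclic_second_differences_sum_to_zero(self):
        c = second_derivative(smooth_contour(trace_boundary(make_disc((50, 50), (25, 25), 14)), 5))
        assert np.allclose(c.d2.sum(axis=0), 0.0, atol=1e-9)

    def test_even_window_rejected(self):
        c = trace_boundary(make_disc((30, 30), (15, 15), 8))
        with pytest.raises(ValueError, match="odd"):
            smooth_contour(c, window=4)


def twin_discs(shape, c1, c2, r1, r2):
    return make_disc(shape, c1, r1) | make_disc(shape, c2, r2)


def analytic_intersections(c1, c2, r1, r2):
    """Closed-form intersection points of two circles."""
    p1, p2 = np.asarray(c1, float), np.asarray(c2, float)
    d = np.linalg.norm(p2 - p1)
    a = (d**2 + r1**2 - r2**2) / (2 * d)
    h = np.sqrt(r1**2 - a**2)
    mid = p1 + a * (p2 - p1) / d
    perp = np.array([-(p2 - p1)[1], (p2 - p1)[0]]) / d
    return mid + h * perp, mid - h * perp


class TestFindCutPoints:
    def test_convex_disc_reports_no_overlap(self):
        m = make_disc((60, 60), (30, 30), 18)
        prepared = morphological_prepare(m)
        c = second_derivative(smooth_contour(trace_boundary(prepared), 9))
        with pytest.raises(NoOverlapError):
            find_cut_points(c, prepared)

    def test_twin_discs_cut_points_near_analytic_intersections(self):
        c1, c2, r = (45, 35), (45, 65), 20
        mask = morphological_prepare(twin_discs((90, 100), c1, c2, r, r))
        contour = second_derivative(smooth_contour(trace_boundary(mask), 9))
        cuts = find_cut_points(contour, mask)
        expected = analytic_intersections(c1, c2, r, r)
        dists = [min(np.linalg.norm(np.array(p) - e) for e in expected) for p in cuts]
        assert max(dists) <= 3.0

    def test_mirror_symmetric_dumbbell_gives_mirror_cut_points(self):
        mask = morphological_prepare(twin_discs((80, 120), (40, 40), (40, 75), 18, 18))
        contour = second_derivative(smooth_contour(trace_boundary(mask), 9))
        (r1, c1), (r2, c2) = find_cut_points(contour, mask)
        assert abs((r1 + r2) / 2 - 40) <= 2.0  # mirror about the neck axis row 40
        assert abs(c1 - c2) <= 2.0


class TestSplitObject:
    def test_twin_discs_split_recovers_sources(self):
        c1, c2, r = (45, 35), (45, 65), 20
        mask = twin_discs((90, 100), c1, c2, r, r)
        cuts = analytic_intersections(c1, c2, r, r)
        result = split_object(mask, [tuple(np.rint(c).astype(int)) for c in cuts])
        for part in result.parts:
            dice = max(
                2 * np.count_nonzero(part & make_disc(mask.shape, c, r))
                / (part.sum() + make_disc(mask.shape, c, r).sum())
                for c in (c1, c2)
            )
            assert dice >= 0.95

    def test_square_cut_along_diagonal_gives_equal_triangles(self):
        m = np.zeros((50, 50), dtype=bool)
        m[5:45, 5:45] = True
        result = split_object(m, [(5, 5), (44, 44)])
        a1, a2 = result.parts[0].sum(), result.parts[1].sum()
        assert abs(a1 - a2) / max(a1, a2) <= 0.01

    def test_pixel_conservation(self):
        mask = twin_discs((90, 100), (45, 35), (45, 65), 20, 20)
        cuts = analytic_intersections((45, 35), (45, 65), 20, 20)
        pts = [tuple(np.rint(c).astype(int)) for c in cuts]
        result = split_object(mask, pts)
        from skimage.draw import line

        rr, cc = line(*pts[0], *pts[1])
        cut_in_mask = mask[rr, cc].sum()
        assert result.parts[0].sum() + result.parts[1].sum() + cut_in_mask == mask.sum()
        assert not (result.parts[0] & result.parts[1]).any()

    def test_identical_cut_points_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            split_object(make_disc((30, 30), (15, 15), 8), [(10, 10), (10, 10)])


class TestSeparatePipeline:
    def test_fragments_of_one_convex_body_merge_to_one_mask(self):
        disc = make_disc((60, 60), (30, 30), 15)
        left = disc & (np.arange(60)[None, :] < 28)
        right = disc & (np.arange(60)[None, :] > 31)
        out = separate_pipeline([left, right])
        assert len(out) == 1
        inter = np.count_nonzero(out[0] & disc)
        assert 2 * inter / (out[0].sum() + disc.sum()) >= 0.9

    def test_two_overlapping_bodies_split_with_high_dice(self):
        c1, c2, r = (45, 33), (45, 67), 20
        mask = twin_discs((90, 100), c1, c2, r, r)
        out = separate_pipeline([mask])
        assert len(out) == 2
        for center in (c1, c2):
            disc = make_disc(mask.shape, center, r)
            dice = max(
                2 * np.count_nonzero(p & disc) / (p.sum() + disc.sum()) for p in out
            )
            assert dice >= 0.9

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            separate_pipeline([])

    def test_separation_sweep_never_exceeds_two_parts(self):
        r1, r2 = 18, 20
        for frac in (1.1, 1.0, 0.95, 0.9, 0.85, 0.8):
            d = frac * (r1 + r2)
            mask1 = make_disc((100, 140), (50, 45), r1)
            mask2 = make_disc((100, 140), (50, 45 + int(round(d))), r2)
            out = separate_pipeline([mask1, mask2])
            assert 1 <= len(out) <= 2
            if frac >= 1.1:
                assert len(out) == 1  # disjoint -> hull -> convex, no neck
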