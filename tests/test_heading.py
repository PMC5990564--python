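"""Species-specific head geometry: angles, projections, both algorithms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from headdir.errors import (
    DegenerateGeometryError,
    EarsNotFoundError,
    InsufficientForegroundError,
    TagNotFoundError,
)
from headdir.evaluate import circular_diff
from headdir.heading import (
    HeadingState,
    apply_deg_th,
    cluster_heading,
    color_tag_bpos,
    head_angle,
    project_head_point,
    tuft_heading,
)
from headdir.imaging import BoundingRect, ContourInfo
from headdir.params import SpeciesParams

points = st.tuples(
    st.integers(-500, 500).map(float), st.integers(-500, 500).map(float)
)


class TestHeadAngle:
    def test_published_worked_example(self):
        # hPos (343, 374), bPos (373, 381) -> 166.87, printed as 167
        angle = head_angle((343, 374), (373, 381))
        assert angle == pytest.approx(166.87, abs=0.01)
        assert round(angle) == 167

    @pytest.mark.parametrize(
        "hpos,bpos,expected",
        [
            ((110, 100), (100, 100), 0.0),  # due image-east
            ((100, 90), (100, 100), 90.0),  # image-up
            ((90, 100), (100, 100), 180.0),
            ((100, 110), (100, 100), -90.0),
        ],
    )
    def test_cardinal_directions(self, hpos, bpos, expected):
        assert head_angle(hpos, bpos) == pytest.approx(expected)

    def test_coincident_points_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            head_angle((5, 5), (5, 5))

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(points, points)
    def test_range_and_antipodal_property(self, p, q):
        if p == q:
            return
        a, b = head_angle(p, q), head_angle(q, p)
        assert -180 < a <= 180 and -180 < b <= 180
        assert abs(a - b) % 360 == pytest.approx(180.0, abs=1e-9)


class TestProjectHeadPoint:
    @pytest.mark.parametrize(
        "d,l,b,expected",
        [
            (0, 50, (100, 100), (150, 100)),
            (90, 50, (100, 100), (100, 50)),
            (135, 10, (0, 0), (-7.0710678, -7.0710678)),
        ],
    )
    def test_projection_formula(self, d, l, b, expected):
        mbr = BoundingRect(0, 0, l, 0)
        got = project_head_point(b, d, mbr)
        assert got == pytest.approx(expected)

    def test_longer_mbr_side_used(self):
        assert project_head_point((0, 0), 0, BoundingRect(0, 0, 10, 30)) == (30, 0)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.floats(-180, 180, allow_nan=False))
    def test_periodicity(self, d):
        mbr = BoundingRect(0, 0, 20, 10)
        a = project_head_point((5, 5), d, mbr)
        b = project_head_point((5, 5), d + 360, mbr)
        assert a == pytest.approx(b, abs=1e-9)


def _params(k):
    return SpeciesParams(
        mexo_iter=0, th_param=0, contour_th=0, motion_th=(0.5, 100),
        deg_th=180, hd_line_len=10, k=k,
    )


class TestClusterHeading:
    def test_hand_traced_two_blob_instance(self):
        # blob A around (10, 10), blob B around (50, 50); previous state
        # points from B toward A, so A must become the head cluster and
        # B's centroid the base point
        mask = np.zeros((64, 64), np.uint8)
        for x, y in [(9, 10), (10, 10), (11, 10), (49, 50), (50, 50), (51, 50)]:
            mask[y, x] = 255
        prev = HeadingState((10, 10), (50, 50), 135.0)
        out = cluster_heading(mask, prev, _params(2), BoundingRect(0, 0, 47, 47))
        assert out.bpos == pytest.approx((50, 50))
        assert out.hpos[1] == 10 and out.hpos[0] in (9, 10, 11)
        assert circular_diff(out.hdir, 135.0) < 3
        assert not out.m_hpos and not out.m_hd

    def test_insufficient_foreground(self):
        mask = np.zeros((20, 20), np.uint8)
        mask[5, 5] = 255
        prev = HeadingState((0, 0), (1, 1), 0.0)
        with pytest.raises(InsufficientForegroundError):
            cluster_heading(mask, prev, _params(2), BoundingRect(0, 0, 5, 5))

    def test_head_cluster_matches_exhaustive_search(self, rng):
        """Nearest-centroid head-cluster choice equals plain enumeration."""
        from sklearn.cluster import KMeans

        from headdir.heading import project_head_point

        for trial in range(25):
            npts = int(rng.integers(6, 30))
            pts = rng.uniform(0, 100, (npts, 2))
            mask = np.zeros((110, 110), np.uint8)
            for x, y in pts.astype(int):
                mask[y, x] = 255
            ys, xs = np.nonzero(mask)
            coords = np.column_stack([xs, ys]).astype(float)
            if len(coords) < 3:
                continue
            prev = HeadingState((20, 20), (50, 50), float(rng.uniform(-180, 180)))
            mbr = BoundingRect(0, 0, 30, 20)
            out = cluster_heading(mask, prev, _params(3), mbr, seed=trial)

            km = KMeans(n_clusters=3, init="k-means++", n_init=1, max_iter=100,
                        random_state=trial).fit(coords)
            hpt = project_head_point(prev.bpos, prev.hdir, mbr)
            # exhaustive nearest-centroid search, no vectorisation
            best, best_d = None, float("inf")
            for ci, (cx, cy) in enumerate(km.cluster_centers_):
                d = math.hypot(cx - hpt[0], cy - hpt[1])
                if d < best_d:
                    best, best_d = ci, d
            head_pts = coords[km.labels_ == best]
            assert any(
                (out.hpos[0], out.hpos[1]) == (px, py) for px, py in head_pts
            )
            neigh, nd = None, float("inf")
            for ci, (cx, cy) in enumerate(km.cluster_centers_):
                if ci == best:
                    continue
                d = math.hypot(*(km.cluster_centers_[best] - (cx, cy)))
                if d < nd:
                    neigh, nd = ci, d
            assert out.bpos == pytest.approx(tuple(km.cluster_centers_[neigh]))


def _contour(cx, cy, half_girth):
    n = half_girth // 2
    pts = np.array([[cx - n // 2 + i, cy] for i in range(max(n, 2))])
    info = ContourInfo(points=pts, center=(float(cx), float(cy)), half_girth=half_girth)
    return info


class TestTuftHeading:
    def test_hand_geometry(self):
        ears = [_contour(100, 100, 20), _contour(120, 100, 20)]
        prev = HeadingState((0, 0), (1, 1), 90.0)
        out = tuft_heading(ears, prev)
        assert out.bpos == pytest.approx((110, 100))
        assert out.hpos == pytest.approx((110, 90))
        assert out.hdir == pytest.approx(90.0)

    def test_previous_heading_disambiguates(self):
        ears = [_contour(100, 100, 20), _contour(120, 100, 20)]
        prev = HeadingState((0, 0), (1, 1), -90.0)
        out = tuft_heading(ears, prev)
        assert out.hpos == pytest.approx((110, 110))
        assert out.hdir == pytest.approx(-90.0)

    def test_largest_two_contours_are_ears(self):
        contours = [
            _contour(100, 100, 30),
            _contour(120, 100, 30),
            _contour(50, 50, 8),  # noise blob, must be ignored
        ]
        prev = HeadingState((0, 0), (1, 1), 90.0)
        out = tuft_heading(contours, prev)
        assert out.bpos == pytest.approx((110, 100))

    def test_single_contour_fails(self):
        with pytest.raises(EarsNotFoundError):
            tuft_heading([_contour(100, 100, 20)], HeadingState((0, 0), (1, 1), 0.0))

    def test_tie_breaks_to_ccw_candidate(self):
        # previous heading 0 deg is 90 deg from both candidates
        ears = [_contour(100, 100, 20), _contour(120, 100, 20)]
        prev = HeadingState((0, 0), (1, 1), 0.0)
        out = tuft_heading(ears, prev)
        assert out.hpos == pytest.approx((110, 90))
        assert out.hdir == pytest.approx(90.0)

    def test_candidates_antipodal_and_chosen_is_closer(self, rng):
        for _ in range(20):
            c1 = rng.uniform(20, 80, 2)
            c2 = c1 + rng.uniform(5, 30, 2)
            prev_dir = float(rng.uniform(-180, 180))
            ears = [_contour(*c1.astype(int), 20), _contour(*c2.astype(int), 20)]
            prev = HeadingState((0, 0), (1, 1), prev_dir)
            out = tuft_heading(ears, prev)
            rejected = (out.hdir + 180) if out.hdir <= 0 else (out.hdir - 180)
            assert circular_diff(out.hdir, rejected) == pytest.approx(180.0)
            assert circular_diff(out.hdir, prev_dir) <= circular_diff(
                rejected, prev_dir
            ) + 1e-9


def _red_rgb():
    # a red whose OpenCV-scale hue falls in [175, 180)
    return (255, 0, 20)


class TestColorTag:
    def test_uniform_patch_centroid(self):
        frame = np.zeros((30, 30, 3), np.uint8)
        frame[10:14, 10:14] = _red_rgb()
        assert color_tag_bpos(frame) == pytest.approx((11.5, 11.5))

    def test_two_patch_weighted_mean(self):
        frame = np.zeros((40, 40, 3), np.uint8)
        frame[10:12, 10:12] = _red_rgb()
        frame[10:12, 30:32] = _red_rgb()
        cx, cy = color_tag_bpos(frame)
        assert cx == pytest.approx(20.5) and cy == pytest.approx(10.5)

    def test_no_red_pixels_fails(self):
        with pytest.raises(TagNotFoundError):
            color_tag_bpos(np.zeros((10, 10, 3), np.uint8))

    def test_out_of_range_hue_excluded(self):
        frame = np.zeros((10, 10, 3), np.uint8)
        frame[2:4, 2:4] = (0, 255, 0)  # green
        with pytest.raises(TagNotFoundError):
            color_tag_bpos(frame)


class TestApplyDegTh:
    def _state(self, d):
        return HeadingState((10, 0), (0, 0), d)

    def test_small_change_accepted(self):
        out = apply_deg_th(self._state(10), self._state(15), 40)
        assert out.hdir == 15

    def test_large_jump_rejected(self):
        out = apply_deg_th(self._state(10), self._state(170), 40)
        assert out.hdir == 10

    def test_wraparound_accepted(self):
        out = apply_deg_th(self._state(170), self._state(-170), 40)
        assert out.hdir == -170
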