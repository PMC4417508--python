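import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myoseg.fiber_filter import convexity, eccentricity, filter_fibers, remove_objects
from myoseg.image_io import AnalysisParams


# ---------------------------------------------------------------- oracles
def gift_wrap_hull(points):
    """Jarvis-march convex hull of (x, y) points; returns CCW vertex list."""
    pts = sorted(set(map(tuple, points)))
    if len(pts) == 1:
        return pts

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    start = min(pts)
    hull = [start]
    while True:
        cand = pts[0] if pts[0] != hull[-1] else pts[1]
        for p in pts:
            if p == hull[-1]:
                continue
            c = cross(hull[-1], cand, p)
            if c < 0 or (
                c == 0
                and (p[0] - hull[-1][0]) ** 2 + (p[1] - hull[-1][1]) ** 2
                > (cand[0] - hull[-1][0]) ** 2 + (cand[1] - hull[-1][1]) ** 2
            ):
                cand = p
        if cand == start:
            return hull
        hull.append(cand)


def shoelace(verts):
    area = 0.0
    for (x0, y0), (x1, y1) in zip(verts, verts[1:] + verts[:1]):
        area += x0 * y1 - x1 * y0
    return abs(area) / 2.0


def convexity_oracle(region_bool):
    rows, cols = np.nonzero(region_bool)
    corners = set()
    for r, c in zip(rows.tolist(), cols.tolist()):
        corners.update({(c, r), (c + 1, r), (c, r + 1), (c + 1, r + 1)})
    return len(rows) / shoelace(gift_wrap_hull(corners))


def eccentricity_oracle(region_bool):
    rows, cols = np.nonzero(region_bool)
    n = len(rows)
    mr, mc = rows.mean(), cols.mean()
    mu20 = sum((c - mc) ** 2 for c in cols) / n
    mu02 = sum((r - mr) ** 2 for r in rows) / n
    mu11 = sum((r - mr) * (c - mc) for r, c in zip(rows, cols)) / n
    common = math.sqrt((mu20 - mu02) ** 2 + 4 * mu11**2)
    lam1 = (mu20 + mu02 + common) / 2
    lam2 = (mu20 + mu02 - common) / 2
    if lam1 <= 0:
        return 0.0
    return math.sqrt(max(0.0, 1 - lam2 / lam1))


def disk(radius, pad=2):
    size = 2 * radius + 2 * pad + 1
    yy, xx = np.mgrid[0:size, 0:size]
    return (yy - size // 2) ** 2 + (xx - size // 2) ** 2 <= radius**2


# ---------------------------------------------------------------- eccentricity
class TestEccentricity:
    def test_circle_is_near_zero(self):
        assert eccentricity(disk(100)) < 0.05

    def test_line_is_one(self):
        region = np.zeros((5, 110), dtype=bool)
        region[2, 5:105] = True
        assert eccentricity(region) == pytest.approx(1.0)

    def test_two_to_one_ellipse(self):
        # semi-axes a = 2b: closed form sqrt(1 - b^2/a^2) = sqrt(0.75)
        a, b = 160.0, 80.0
        yy, xx = np.mgrid[0:400, 0:400]
        region = ((xx - 200) / a) ** 2 + ((yy - 200) / b) ** 2 <= 1.0
        assert eccentricity(region) == pytest.approx(math.sqrt(0.75), abs=0.01)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            eccentricity(np.zeros((4, 4), dtype=bool))

    def test_single_pixel_is_zero(self):
        region = np.zeros((3, 3), dtype=bool)
        region[1, 1] = True
        assert eccentricity(region) == 0.0


# ---------------------------------------------------------------- convexity
class TestConvexity:
    @pytest.mark.parametrize("shape", ["square", "rect", "pixel"])
    def test_convex_rasters_score_exactly_one(self, shape):
        region = np.zeros((30, 30), dtype=bool)
        if shape == "square":
            region[5:25, 5:25] = True
        elif shape == "rect":
            region[5:10, 2:28] = True
        else:
            region[7, 7] = True
        assert convexity(region) == pytest.approx(1.0, abs=1e-12)

    def test_plus_sign_is_five_sevenths(self):
        region = np.zeros((5, 5), dtype=bool)
        region[1:4, 2] = True
        region[2, 1:4] = True
        value = convexity(region)
        assert value == pytest.approx(5.0 / 7.0, abs=1e-12)
        assert value == pytest.approx(convexity_oracle(region), abs=1e-12)

    def test_stellate_shape_below_threshold(self):
        # thin cross arms: strongly concave
        region = np.zeros((41, 41), dtype=bool)
        region[18:23, :] = True
        region[:, 18:23] = True
        assert convexity(region) < 0.8

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            convexity(np.zeros((4, 4), dtype=bool))

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_oracle(self, seed):
        r = np.random.default_rng(seed)
        region = r.random((12, 12)) < 0.45
        rows, cols = np.nonzero(region)
        if rows.size == 0:
            return
        lab = np.zeros_like(region, dtype=int)
        lab[region] = 1
        # restrict to a single connected component to mimic one fiber
        from scipy import ndimage as ndi

        comp, n = ndi.label(region, structure=np.ones((3, 3)))
        region = comp == 1
        assert convexity(region) == pytest.approx(convexity_oracle(region), rel=1e-9)
        assert eccentricity(region) == pytest.approx(eccentricity_oracle(region), rel=1e-9)


# ---------------------------------------------------------------- filter
class TestFilterFibers:
    def test_edge_touching_rejected(self, default_params):
        mask = np.zeros((30, 30), dtype=np.int64)
        mask[0:5, 10:15] = 1  # touches row 0
        mask[10:26, 10:26] = 2  # interior, 16x16 px = 106 um2 at 0.645
        out, report = filter_fibers(mask, default_params)
        rep = report.set_index("label")
        assert not rep.loc[1, "kept"] and rep.loc[1, "reason"] == "edge"
        assert rep.loc[2, "kept"]
        assert (out == mask * (mask == 2)).all()

    def test_small_square_rejected_under_defaults(self, default_params):
        # 10x10 px at 0.645 um/px -> 41.6 um2 < 100
        mask = np.zeros((30, 30), dtype=np.int64)
        mask[10:20, 10:20] = 1
        out, report = filter_fibers(mask, default_params)
        assert report.loc[0, "reason"] == "too_small"
        assert report.loc[0, "area_um2"] == pytest.approx(100 * 0.645**2)

    def test_interior_square_kept(self, default_params):
        mask = np.zeros((60, 60), dtype=np.int64)
        mask[10:50, 10:50] = 1  # 1600 px = 666 um2
        out, report = filter_fibers(mask, default_params)
        assert report.loc[0, "kept"]
        assert (out == mask).all()

    def test_eccentric_region_rejected(self):
        params = AnalysisParams(pixel_size=1.0)
        mask = np.zeros((40, 300), dtype=np.int64)
        mask[18:20, 10:290] = 1  # long thin bar, area 560 um2, ecc ~ 1
        _, report = filter_fibers(mask, params)
        assert report.loc[0, "reason"] == "eccentricity"

    def test_concave_region_rejected(self):
        params = AnalysisParams(pixel_size=1.0, max_eccentricity=1.0)
        mask = np.zeros((60, 60), dtype=np.int64)
        mask[20:40, 5:55] = 1
        mask[25:40, 15:45] = 0  # carve a deep bay
        _, report = filter_fibers(mask, params)
        assert report.loc[0, "reason"] == "convexity"

    def test_first_failing_rule_reported(self, default_params):
        mask = np.zeros((30, 30), dtype=np.int64)
        mask[0, 0:3] = 1  # touches edge AND too small AND a line
        _, report = filter_fibers(mask, default_params)
        assert report.loc[0, "reason"] == "edge"

    def test_idempotent(self, clean_section, default_params):
        from myoseg.segmentation import initial_segmentation

        image, gt, spec = clean_section
        mask = initial_segmentation(image)
        once, _ = filter_fibers(mask, default_params)
        twice, report = filter_fibers(once, default_params)
        assert np.array_equal(once, twice)
        assert report["kept"].all()

    def test_kept_pixels_unchanged(self, clean_section, default_params):
        from myoseg.segmentation import initial_segmentation

        image, gt, spec = clean_section
        mask = initial_segmentation(image)
        out, report = filter_fibers(mask, default_params)
        for lab in report.loc[report["kept"], "label"]:
            assert np.array_equal(out == lab, mask == lab)


class TestRemoveObjects:
    def _mask(self):
        mask = np.zeros((20, 20), dtype=np.int64)
        mask[1:5, 1:5] = 1
        mask[8:12, 8:12] = 2
        mask[15:19, 15:19] = 3
        return mask

    def test_empty_ids_identity(self):
        mask = self._mask()
        out, unknown = remove_objects(mask, [])
        assert np.array_equal(out, mask) and unknown == []

    def test_remove_all(self):
        out, _ = remove_objects(self._mask(), [1, 2, 3])
        assert (out == 0).all()

    def test_remove_one_of_three(self):
        out, _ = remove_objects(self._mask(), [2])
        assert set(np.unique(out)) == {0, 1, 3}

    def test_unknown_ids_reported(self):
        out, unknown = remove_objects(self._mask(), [2, 99])
        assert unknown == [99]
        assert set(np.unique(out)) == {0, 1, 3}
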