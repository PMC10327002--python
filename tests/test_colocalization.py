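"""Circle-circle lens geometry and the two colocalization methods."""

import math

import numpy as np
import pytest

from punctacoloc import (
    BinaryMask,
    Punctum,
    ROISpec,
    circle_overlap_area,
    circles_colocalize,
    circular_colocalize_image,
    pixel_colocalize_image,
)


def make_punctum(pid, x, y, radius, channel="red"):
    area = math.pi * radius**2
    return Punctum(
        id=pid,
        channel=channel,
        centroid_x=x,
        centroid_y=y,
        area=int(round(area)),
        equiv_radius=radius,
        circularity=1.0,
        pixels=np.empty((0, 2), dtype=int),
    )


def closed_form_lens(r1, r2, d):
    """Independent closed-form circle-intersection area (standard formula)."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return math.pi * min(r1, r2) ** 2
    term1 = r1**2 * math.acos((d**2 + r1**2 - r2**2) / (2 * d * r1))
    term2 = r2**2 * math.acos((d**2 + r2**2 - r1**2) / (2 * d * r2))
    root = 0.5 * math.sqrt(
        (-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2)
    )
    return term1 + term2 - root


class TestCirclesColocalize:
    def test_overlapping(self):
        p1 = make_punctum(1, 0, 0, 3)
        p2 = make_punctum(1, 0, 4, 2, "green")
        assert circles_colocalize(p1, p2)  # d = 4 < 5

    def test_tangency_is_not_colocalization(self):
        p1 = make_punctum(1, 0, 0, 3)
        p2 = make_punctum(1, 5, 0, 2, "green")
        assert not circles_colocalize(p1, p2)  # d == r1 + r2 exactly

    def test_coincident_centers(self):
        assert circles_colocalize(make_punctum(1, 2, 2, 1), make_punctum(1, 2, 2, 3, "green"))


class TestCircleOverlapArea:
    def test_containment_limit(self):
        assert circle_overlap_area(5, 5, 0) == pytest.approx(25 * math.pi)
        assert circle_overlap_area(1, 10, 2) == pytest.approx(math.pi)

    def test_tangent_and_separated(self):
        assert circle_overlap_area(2, 3, 5) == 0.0
        assert circle_overlap_area(2, 3, 9) == 0.0

    def test_unit_circles_at_unit_distance(self):
        # 2*acos(1/2) - sqrt(3)/2 * ... = 1.2284 (classical lens value)
        assert circle_overlap_area(1, 1, 1) == pytest.approx(1.2284, abs=5e-5)

    def test_symmetry(self, rng):
        for r1, r2, d in rng.uniform(0.1, 10, size=(50, 3)):
            assert circle_overlap_area(r1, r2, d) == pytest.approx(
                circle_overlap_area(r2, r1, d), rel=1e-12
            )

    def test_against_closed_form(self, rng):
        r1, r2 = rng.uniform(0.1, 10, size=(2, 10_000))
        d = rng.uniform(0, 22, size=10_000)
        for a, b, dd in zip(r1, r2, d):
            assert circle_overlap_area(a, b, dd) == pytest.approx(
                closed_form_lens(a, b, dd), rel=1e-6, abs=1e-9
            )

    def test_against_polygonal_oracle(self, rng):
        shapely = pytest.importorskip("shapely")
        from shapely.geometry import Point

        for r1, r2, d in rng.uniform(0.5, 5, size=(100, 3)):
            expected = (
                Point(0, 0).buffer(r1, quad_segs=512).intersection(
                    Point(d, 0).buffer(r2, quad_segs=512)
                ).area
            )
            assert circle_overlap_area(r1, r2, d) == pytest.approx(expected, abs=1e-3 * max(1, expected))

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            circle_overlap_area(-1, 2, 1)
        with pytest.raises(ValueError):
            circle_overlap_area(1, 2, -0.5)


class TestCircularColocalizeImage:
    def test_one_red_two_green_gives_two_records(self):
        red = [make_punctum(1, 10, 10, 3)]
        green = [make_punctum(1, 12, 10, 2, "green"), make_punctum(2, 10, 13, 2, "green")]
        records = circular_colocalize_image(red, green, "img")
        assert len(records) == 2
        assert {r.green_id for r in records} == {1, 2}
        assert all(r.red_id == 1 and r.method == "circular" for r in records)
        assert all(r.overlap_area > 0 for r in records)

    def test_disjoint_sets_give_none(self):
        red = [make_punctum(1, 0, 0, 1)]
        green = [make_punctum(1, 50, 50, 1, "green")]
        assert circular_colocalize_image(red, green) == []

    def test_chord_midpoint_center(self):
        # c1=(0,0) r=3, c2=(4,0) r=2: t = (16+9-4)/32 = 21/32 -> x = 2.625
        red = [make_punctum(1, 0, 0, 3)]
        green = [make_punctum(1, 4, 0, 2, "green")]
        (rec,) = circular_colocalize_image(red, green)
        assert rec.center_x == pytest.approx(4 * 21 / 32)
        assert rec.center_y == pytest.approx(0.0)

    def test_concentric_center_is_midpoint(self):
        (rec,) = circular_colocalize_image(
            [make_punctum(1, 5, 5, 2)], [make_punctum(1, 5, 5, 1, "green")]
        )
        assert (rec.center_x, rec.center_y) == (5.0, 5.0)

    def test_overlap_bounded_by_smaller_circle(self, rng):
        red = [make_punctum(i, x, y, r) for i, (x, y, r) in enumerate(rng.uniform(1, 30, (10, 3)))]
        green = [
            make_punctum(i, x, y, r, "green")
            for i, (x, y, r) in enumerate(rng.uniform(1, 30, (10, 3)))
        ]
        for rec in circular_colocalize_image(red, green):
            r_red = red[rec.red_id].equiv_radius
            r_green = green[rec.green_id].equiv_radius
            assert rec.overlap_area <= math.pi * min(r_red, r_green) ** 2 + 1e-9


class TestPixelColocalizeImage:
    def test_identical_masks(self, rng):
        mask = rng.random((30, 30)) < 0.2
        records = pixel_colocalize_image([BinaryMask(mask), BinaryMask(mask.copy())])
        from scipy import ndimage

        _, n = ndimage.label(mask, np.ones((3, 3)))
        assert len(records) == n
        assert sum(r.overlap_area for r in records) == mask.sum()

    def test_disjoint_masks(self):
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[:5] = True
        b[6:] = True
        assert pixel_colocalize_image([BinaryMask(a), BinaryMask(b)]) == []

    def test_three_channel_empty_blue(self, rng):
        full = BinaryMask(np.ones((10, 10), bool))
        empty = BinaryMask(np.zeros((10, 10), bool))
        assert pixel_colocalize_image([full, full, empty]) == []

    def test_total_overlap_area_identity(self, rng):
        a = rng.random((40, 40)) < 0.4
        b = rng.random((40, 40)) < 0.4
        records = pixel_colocalize_image([BinaryMask(a), BinaryMask(b)], min_size=1)
        assert sum(r.overlap_area for r in records) == (a & b).sum()
        assert all(r.method == "pixel2" for r in records)

    def test_min_size_and_roi_filter_components(self):
        a = np.zeros((20, 20), bool)
        a[2:4, 2:4] = True  # area 4, centroid (2.5, 2.5)
        a[10, 10] = True  # area 1
        records = pixel_colocalize_image([BinaryMask(a), BinaryMask(a.copy())], min_size=2)
        assert len(records) == 1 and records[0].overlap_area == 4
        roi = ROISpec(kind="circle", cx=10, cy=10, radius=2)
        records = pixel_colocalize_image([BinaryMask(a), BinaryMask(a.copy())], roi=roi)
        assert len(records) == 1 and records[0].center_x == 10.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            pixel_colocalize_image(
                [BinaryMask(np.zeros((5, 5), bool)), BinaryMask(np.zeros((6, 6), bool))]
            )
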