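"""Canonical region definitions, polygon realization, and region assignment."""

import json

import numpy as np
import pytest
from shapely.geometry import Polygon

from twinmark.errors import (
    DegeneratePolygon,
    MalformedLandmarkFile,
    NoFaceFound,
)
from twinmark.landmark_regions import (
    FACE_OVAL_CONTOUR,
    REGION_NAMES,
    FaceLandmarks,
    FileReplayBackend,
    Landmark,
    RegionDefinition,
    assign_regions,
    canonical_regions,
    detect_landmarks,
    point_in_region,
    read_landmarks,
    region_polygon,
    write_landmarks,
)


class TestCanonicalRegions:
    def test_left_eye_indices_are_frozen(self):
        assert canonical_regions()["L_EYE"].indices == (463, 257, 359, 253)

    def test_nose_ring_is_closed(self):
        nose = canonical_regions()["NOSE"]
        assert nose.indices == (8, 240, 98, 164, 327, 460, 8)
        assert nose.closed

    def test_eight_regions_with_indices_in_mesh_range(self):
        regs = canonical_regions()
        assert tuple(regs.regions.keys()) == REGION_NAMES
        assert len(list(regs)) == 8
        for r in regs:
            assert all(0 <= i <= 463 for i in r.indices)

    def test_output_is_identical_across_calls(self):
        a, b = canonical_regions(), canonical_regions()
        assert all(a[n].indices == b[n].indices for n in REGION_NAMES)

    def test_oval_default_differs_from_printed_duplicate(self):
        default = canonical_regions()["OVAL_FACE"]
        printed = canonical_regions(oval_as_printed=True)["OVAL_FACE"]
        assert default.indices == FACE_OVAL_CONTOUR
        assert printed.indices == canonical_regions()["FACE_CURVE"].indices


class TestRegionPolygon:
    def test_unit_square_stub_gives_square(self, unit_square_landmarks):
        region = RegionDefinition(name="NOSE", indices=(0, 1, 2, 3), closed=False)
        poly = Polygon(region_polygon(unit_square_landmarks, region))
        assert poly.equals(Polygon([(0, 0), (4, 0), (4, 4), (0, 4)]))

    @pytest.mark.parametrize("name", REGION_NAMES)
    def test_template_regions_are_simple_with_positive_area(self, template, regions, name):
        poly = Polygon(region_polygon(template, regions[name]))
        assert poly.is_valid and poly.area > 0

    def test_collinear_points_are_degenerate(self, unit_square_landmarks):
        # indices 100, 121, 142 lie on one diagonal of the filler grid
        region = RegionDefinition(name="NOSE", indices=(100, 121, 142), closed=False)
        with pytest.raises(DegeneratePolygon):
            region_polygon(unit_square_landmarks, region)

    def test_collinear_points_degenerate_under_hull_too(self, unit_square_landmarks):
        region = RegionDefinition(name="L_EYE", indices=(100, 121, 142), closed=False)
        with pytest.raises(DegeneratePolygon):
            region_polygon(unit_square_landmarks, region)


def _winding_number_inside(p, ring):
    """Independent oracle: winding number with explicit boundary handling."""
    x, y = p
    n = len(ring)
    # boundary check first (inclusive rule)
    for i in range(n):
        (x0, y0), (x1, y1) = ring[i], ring[(i + 1) % n]
        cross = (x1 - x0) * (y - y0) - (y1 - y0) * (x - x0)
        if abs(cross) < 1e-12:
            if min(x0, x1) - 1e-12 <= x <= max(x0, x1) + 1e-12 and \
               min(y0, y1) - 1e-12 <= y <= max(y0, y1) + 1e-12:
                return True
    wn = 0
    for i in range(n):
        (x0, y0), (x1, y1) = ring[i], ring[(i + 1) % n]
        if y0 <= y:
            if y1 > y and (x1 - x0) * (y - y0) - (y1 - y0) * (x - x0) > 0:
                wn += 1
        elif y1 <= y and (x1 - x0) * (y - y0) - (y1 - y0) * (x - x0) < 0:
            wn -= 1
    return wn != 0


class TestPointInRegion:
    @pytest.mark.parametrize("point,expected", [
        ((2, 2), True),
        ((5, 5), False),
        ((0, 2), True),   # on the edge: inclusive rule
        ((0, 0), True),   # on a vertex
    ])
    def test_square_membership(self, point, expected):
        square = [(0, 0), (4, 0), (4, 4), (0, 4)]
        assert point_in_region(point, square) is expected

    def test_agrees_with_winding_number_oracle_on_random_polygons(self, rng):
        """1,000 random points against random simple (star-shaped) polygons."""
        n_checked = 0
        while n_checked < 1000:
            nv = int(rng.integers(3, 9))
            angles = np.sort(rng.uniform(0, 2 * np.pi, nv))
            radii = rng.uniform(1.0, 4.0, nv)
            ring = [(float(r * np.cos(a)), float(r * np.sin(a)))
                    for r, a in zip(radii, angles)]
            if Polygon(ring).area < 0.5:
                continue
            pts = rng.uniform(-4.5, 4.5, size=(25, 2))
            for p in pts:
                p = (float(p[0]), float(p[1]))
                assert point_in_region(p, ring) == _winding_number_inside(p, ring)
            n_checked += 25


class TestAssignRegions:
    def test_nose_centroid_is_in_nose_and_oval(self, template, regions, region_polygons):
        c = region_polygons["NOSE"].representative_point()
        labels = assign_regions([(c.x, c.y)], template, regions)
        assert {"NOSE", "OVAL_FACE"} <= labels[0]

    def test_point_outside_face_hull_gets_no_labels(self, template, regions):
        assert assign_regions([(2.0, 2.0)], template, regions)[0] == frozenset()

    @pytest.mark.parametrize("name", ["NOSE", "LIPS", "L_EYE", "FACE_CURVE"])
    def test_region_vertices_belong_to_their_region(self, template, regions, name):
        verts = [template.xy(i) for i in regions[name].indices]
        labels = assign_regions(verts, template, regions)
        assert all(name in labs for labs in labels)

    def test_invariant_under_joint_translation_and_scaling(self, template, regions, rng):
        pts = rng.uniform(100, 400, size=(40, 2))
        base = assign_regions(pts, template, regions)
        s, tx, ty = 2.5, 37.0, -11.0
        moved = FaceLandmarks(
            points=tuple(
                Landmark(index=p.index, x=s * p.x + tx, y=s * p.y + ty, z=p.z)
                for p in template.points
            ),
            image_width=template.image_width, image_height=template.image_height,
        )
        transformed = assign_regions(pts * s + np.array([tx, ty]), moved, regions)
        assert base == transformed


class TestLandmarkIO:
    def test_json_round_trip_is_lossless(self, template, tmp_path):
        path = tmp_path / "lm.json"
        write_landmarks(template, path)
        back = read_landmarks(path)
        assert back == template

    def test_csv_round_trip_is_lossless(self, template, tmp_path):
        path = tmp_path / "lm.csv"
        write_landmarks(template, path)
        back = read_landmarks(path)
        assert back == template

    def test_wrong_count_rejected(self, template, tmp_path):
        path = tmp_path / "short.json"
        payload = {
            "image_width": 512, "image_height": 512,
            "points": [{"index": p.index, "x": p.x, "y": p.y, "z": p.z}
                       for p in template.points[:467]],
        }
        path.write_text(json.dumps(payload))
        with pytest.raises(MalformedLandmarkFile):
            read_landmarks(path)

    def test_duplicate_index_rejected(self, template, tmp_path):
        path = tmp_path / "dup.json"
        pts = [{"index": p.index, "x": p.x, "y": p.y, "z": p.z} for p in template.points]
        pts[10]["index"] = 11
        path.write_text(json.dumps({"image_width": 512, "image_height": 512, "points": pts}))
        with pytest.raises(MalformedLandmarkFile):
            read_landmarks(path)


class TestDetectionBackends:
    def test_replay_backend_returns_stored_landmarks(self, template):
        backend = FileReplayBackend(store={"img.png": template})
        got = detect_landmarks("img.png", backend)
        assert got == template
        assert len(got.points) == 468

    def test_empty_store_raises_no_face_found(self):
        with pytest.raises(NoFaceFound):
            detect_landmarks("blank.png", FileReplayBackend())

    def test_replay_face_box_covers_the_mesh(self, template):
        backend = FileReplayBackend(store={"img.png": template})
        box = backend.detect_face("img.png")
        assert len(box.coarse_points) == 6
        xs = [p.x for p in template.points]
        assert box.x0 <= min(xs) and box.x1 > max(xs)
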