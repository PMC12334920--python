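"""The 468-point face-mesh landmark model and its canonical facial regions.

The face mesh used throughout this package is the standard 468-vertex facial
landmark topology: every detected face is described by 468 ordered points in
pixel coordinates (origin top-left, x rightward, y downward).  Eight named
regions -- the two eyes, the two eyebrows, the nose, the lips, the lower-face
"face curve", and the whole-face oval -- are defined as fixed subsets of mesh
vertex indices.  This module houses those frozen index lists, realizes a
region as a polygon over a concrete set of landmarks, and assigns arbitrary
image points (e.g. detected keypoints) to the regions that contain them.

Geometry conventions
--------------------
* Membership is boundary-inclusive: a point exactly on a region contour
  belongs to the region.
* Assignment is multi-label: the face oval overlaps every other region, so a
  point inside the nose also belongs to the oval.
* Eye and eyebrow index lists do not trace a simple ring, so their polygons
  are the 2-D convex hull of the indexed points; nose, lips, face-curve and
  oval keep the listed vertex order as a closed ring (repeated indices are
  dropped after their first appearance).
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import shapely
from shapely.geometry import MultiPoint, Polygon

from .errors import (
    BackendUnavailable,
    DegeneratePolygon,
    MalformedLandmarkFile,
    NoFaceFound,
)

logger = logging.getLogger(__name__)

N_LANDMARKS = 468

REGION_NAMES = (
    "L_EYE",
    "R_EYE",
    "L_EYEBROW",
    "R_EYEBROW",
    "NOSE",
    "LIPS",
    "FACE_CURVE",
    "OVAL_FACE",
)

#: Frozen per-region mesh-vertex index lists, exactly as published.
_REGION_INDEX_LISTS: dict[str, tuple[int, ...]] = {
    "L_EYE": (463, 257, 359, 253),
    "R_EYE": (130, 27, 243, 23),
    "L_EYEBROW": (276, 283, 282, 295, 285, 300, 293, 334, 296, 336),
    "R_EYEBROW": (46, 53, 52, 65, 55, 70, 63, 105, 66, 107),
    "NOSE": (8, 240, 98, 164, 327, 460, 8),
    "LIPS": (
        61, 146, 46, 91, 181, 84, 17, 314, 405, 321, 375, 291, 65, 185, 40,
        39, 37, 0, 267, 269, 270, 409, 291, 78, 95, 88, 178, 87, 14, 317,
        402, 318, 324, 308, 78, 191, 80, 81, 82, 13, 312, 311, 310, 415, 308,
    ),
    "FACE_CURVE": (
        138, 214, 212, 57, 61, 14, 291, 287, 432, 434, 367, 379, 400, 377,
        152, 148, 176, 149, 138,
    ),
}

#: Standard face-oval contour of the 468 topology (the published lists print
#: the face-curve indices twice; see the ``oval_as_printed`` switch).
FACE_OVAL_CONTOUR: tuple[int, ...] = (
    10, 338, 297, 332, 284, 251, 389, 356, 454, 323, 361, 288, 397, 365,
    379, 378, 400, 377, 152, 148, 176, 149, 150, 136, 172, 58, 132, 93,
    234, 127, 162, 21, 54, 103, 67, 109,
)

#: Regions whose printed order is not a simple ring; polygons use convex hull.
HULL_REGIONS = frozenset({"L_EYE", "R_EYE", "L_EYEBROW", "R_EYEBROW"})


@dataclass(frozen=True)
class Landmark:
    """One mesh vertex: id in 0..467 plus pixel position (z is relative depth)."""

    index: int
    x: float
    y: float
    z: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.index < N_LANDMARKS:
            raise ValueError(f"landmark index {self.index} outside 0..467")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("landmark coordinates must be finite")


@dataclass(frozen=True)
class FaceLandmarks:
    """All 468 landmarks of one face, ordered by mesh-vertex index."""

    points: tuple[Landmark, ...]
    image_width: int
    image_height: int

    def __post_init__(self) -> None:
        if len(self.points) != N_LANDMARKS:
            raise ValueError(f"expected {N_LANDMARKS} landmarks, got {len(self.points)}")
        indices = [p.index for p in self.points]
        if sorted(indices) != list(range(N_LANDMARKS)):
            raise ValueError("landmark indices must be 0..467 each exactly once")
        if indices != list(range(N_LANDMARKS)):
            object.__setattr__(
                self, "points", tuple(sorted(self.points, key=lambda p: p.index))
            )

    def xy(self, index: int) -> tuple[float, float]:
        p = self.points[index]
        return (p.x, p.y)

    def coords(self, indices: Iterable[int]) -> np.ndarray:
        return np.array([self.xy(i) for i in indices], dtype=float)


@dataclass(frozen=True)
class FaceBox:
    """Half-open face rectangle with the detector's six coarse landmarks."""

    x0: float
    y0: float
    x1: float
    y1: float
    coarse_points: tuple[tuple[float, float], ...]
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError("face box must satisfy x0<x1 and y0<y1")
        if len(self.coarse_points) != 6:
            raise ValueError("face box carries exactly 6 coarse landmarks")


@dataclass(frozen=True)
class RegionDefinition:
    name: str
    indices: tuple[int, ...]
    closed: bool

    def __post_init__(self) -> None:
        if any(not 0 <= i < N_LANDMARKS for i in self.indices):
            raise ValueError(f"region {self.name} has out-of-range indices")
        if len(set(self.indices)) < 3:
            raise ValueError(f"region {self.name} needs >= 3 distinct indices")


@dataclass(frozen=True)
class RegionSet:
    regions: Mapping[str, RegionDefinition] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if tuple(self.regions.keys()) != REGION_NAMES:
            missing = set(REGION_NAMES) - set(self.regions)
            raise ValueError(f"region set must contain exactly {REGION_NAMES}; missing {missing}")

    def __getitem__(self, name: str) -> RegionDefinition:
        return self.regions[name]

    def __iter__(self):
        return iter(self.regions.values())


def canonical_regions(oval_as_printed: bool = False) -> RegionSet:
    """Return the eight canonical regions with their frozen index lists.

    ``oval_as_printed=True`` reproduces the published face-oval list, which
    duplicates the face-curve indices; the default uses the standard face-oval
    contour of the 468 topology so that the oval actually encloses the face.
    """
    regions: dict[str, RegionDefinition] = {}
    for name in REGION_NAMES:
        if name == "OVAL_FACE":
            idx = _REGION_INDEX_LISTS["FACE_CURVE"] if oval_as_printed else FACE_OVAL_CONTOUR
        else:
            idx = _REGION_INDEX_LISTS[name]
        regions[name] = RegionDefinition(
            name=name, indices=idx, closed=len(idx) > 1 and idx[0] == idx[-1]
        )
    return RegionSet(regions=regions)


def _ring_indices(region: RegionDefinition) -> list[int]:
    """Listed order with repeats dropped after their first appearance."""
    seen: set[int] = set()
    ring = []
    for i in region.indices:
        if i not in seen:
            seen.add(i)
            ring.append(i)
    return ring


def region_polygon(
    landmarks: FaceLandmarks, region: RegionDefinition
) -> list[tuple[float, float]]:
    """Realize a region as a simple closed polygon over concrete landmarks.

    Returns the ordered exterior vertices (without the closing repeat).
    Raises :class:`DegeneratePolygon` when the indexed points are collinear or
    the listed ring self-intersects.
    """
    coords = landmarks.coords(_ring_indices(region))
    if region.name in HULL_REGIONS:
        hull = MultiPoint([tuple(c) for c in coords]).convex_hull
        if not isinstance(hull, Polygon) or hull.area <= 0:
            raise DegeneratePolygon(
                f"{region.name}: indexed points are collinear (no enclosed area)"
            )
        ring = list(hull.exterior.coords)[:-1]
        return [(float(x), float(y)) for x, y in ring]
    poly = Polygon([tuple(c) for c in coords])
    if not poly.is_valid or poly.area <= 0:
        raise DegeneratePolygon(
            f"{region.name}: listed ring is collinear or self-intersecting"
        )
    ring = list(poly.exterior.coords)[:-1]
    return [(float(x), float(y)) for x, y in ring]


def _as_polygon(polygon) -> Polygon:
    return polygon if isinstance(polygon, Polygon) else Polygon(list(polygon))


def point_in_region(p: tuple[float, float], polygon) -> bool:
    """Boundary-inclusive point-in-polygon membership."""
    return bool(_as_polygon(polygon).covers(shapely.Point(p)))


def assign_regions(
    points: Sequence[tuple[float, float]] | np.ndarray,
    landmarks: FaceLandmarks,
    regions: RegionSet,
) -> list[frozenset[str]]:
    """Multi-label region assignment for a batch of image points.

    A point inside both OVAL_FACE and NOSE is labeled with both; a point
    outside every region gets an empty set.  Boundary points count as inside.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return []
    geoms = shapely.points(pts[:, 0], pts[:, 1])
    labels: list[set[str]] = [set() for _ in range(len(pts))]
    for region in regions:
        poly = Polygon(region_polygon(landmarks, region))
        inside = shapely.covers(poly, geoms)
        for i in np.nonzero(inside)[0]:
            labels[int(i)].add(region.name)
    return [frozenset(s) for s in labels]


# -- serialization ------------------------------------------------------------

def write_landmarks(landmarks: FaceLandmarks, path) -> None:
    """Write landmarks as JSON (or CSV when the path ends in .csv)."""
    path = str(path)
    if path.endswith(".csv"):
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["index", "x", "y", "z", "image_width", "image_height"])
            for p in landmarks.points:
                w.writerow([p.index, repr(p.x), repr(p.y),
                            "" if p.z is None else repr(p.z),
                            landmarks.image_width, landmarks.image_height])
        return
    payload = {
        "image_width": landmarks.image_width,
        "image_height": landmarks.image_height,
        "points": [
            {"index": p.index, "x": p.x, "y": p.y, "z": p.z} for p in landmarks.points
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def _build_landmarks(rows, width, height) -> FaceLandmarks:
    seen = set()
    pts = []
    for index, x, y, z in rows:
        if index in seen:
            raise MalformedLandmarkFile(f"duplicate landmark index {index}")
        seen.add(index)
        pts.append(Landmark(index=index, x=x, y=y, z=z))
    if len(pts) != N_LANDMARKS:
        raise MalformedLandmarkFile(f"expected {N_LANDMARKS} landmarks, found {len(pts)}")
    return FaceLandmarks(points=tuple(pts), image_width=width, image_height=height)


def read_landmarks(path) -> FaceLandmarks:
    """Read a landmark file written by :func:`write_landmarks` (JSON or CSV)."""
    path = str(path)
    if path.endswith(".csv"):
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            rows, width, height = [], None, None
            for rec in reader:
                width = int(rec["image_width"])
                height = int(rec["image_height"])
                z = float(rec["z"]) if rec.get("z") else None
                rows.append((int(rec["index"]), float(rec["x"]), float(rec["y"]), z))
        if width is None:
            raise MalformedLandmarkFile("empty landmark CSV")
        return _build_landmarks(rows, width, height)
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise MalformedLandmarkFile(str(exc)) from exc
    try:
        rows = [(r["index"], r["x"], r["y"], r.get("z")) for r in payload["points"]]
        return _build_landmarks(rows, payload["image_width"], payload["image_height"])
    except (KeyError, TypeError, ValueError) as exc:
        raise MalformedLandmarkFile(str(exc)) from exc


def export_region_definitions(regions: RegionSet, path) -> None:
    """Export region definitions as JSON for audit."""
    payload = {
        r.name: {"indices": list(r.indices), "closed": r.closed} for r in regions
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


# -- detection backends -------------------------------------------------------

class LandmarkBackend:
    """Contract: map an image reference to landmarks and a face box."""

    def detect_landmarks(self, image) -> FaceLandmarks:  # pragma: no cover - contract
        raise NotImplementedError

    def detect_face(self, image) -> FaceBox:  # pragma: no cover - contract
        raise NotImplementedError


class FileReplayBackend(LandmarkBackend):
    """Replay stored landmarks keyed by image reference (path or id).

    When several faces are stored for one key the highest-confidence entry is
    returned and a warning is logged (single-face crops are assumed upstream).
    """

    def __init__(self, store: Mapping[str, FaceLandmarks] | None = None,
                 boxes: Mapping[str, FaceBox] | None = None) -> None:
        self.store = dict(store or {})
        self.boxes = dict(boxes or {})

    def detect_landmarks(self, image) -> FaceLandmarks:
        key = str(image)
        entry = self.store.get(key)
        if entry is None:
            raise NoFaceFound(f"no stored landmarks for {key!r}")
        if isinstance(entry, (list, tuple)):
            if len(entry) > 1:
                logger.warning("multiple faces stored for %r; keeping highest confidence", key)
            entry = max(entry, key=lambda lm_conf: lm_conf[1])[0]
        return entry

    def detect_face(self, image) -> FaceBox:
        key = str(image)
        if key in self.boxes:
            return self.boxes[key]
        if key in self.store:
            return face_box_from_landmarks(self.detect_landmarks(image))
        raise NoFaceFound(f"no stored face box for {key!r}")


def face_box_from_landmarks(landmarks: FaceLandmarks, confidence: float = 1.0) -> FaceBox:
    """Bounding box of the mesh, with six spread mesh vertices as coarse points."""
    xs = np.array([p.x for p in landmarks.points])
    ys = np.array([p.y for p in landmarks.points])
    coarse_ids = (33, 263, 1, 61, 291, 199)  # eyes, nose tip, mouth corners, chin
    coarse = tuple(landmarks.xy(i) for i in coarse_ids)
    return FaceBox(
        x0=float(xs.min()), y0=float(ys.min()),
        x1=float(xs.max()) + 1.0, y1=float(ys.max()) + 1.0,
        coarse_points=coarse, confidence=confidence,
    )


class MediapipeBackend(LandmarkBackend):
    """Adapter for the external real-time face-mesh detector, when installed.

    Normalized detector outputs are scaled by image width/height on ingest.
    """

    def __init__(self) -> None:
        try:
            import mediapipe  # noqa: F401
        except ImportError as exc:
            raise BackendUnavailable(
                "mediapipe is not installed; use FileReplayBackend or the synthetic template"
            ) from exc
        self._mp = mediapipe

    def detect_landmarks(self, image) -> FaceLandmarks:
        arr = np.asarray(image)
        h, w = arr.shape[:2]
        with self._mp.solutions.face_mesh.FaceMesh(static_image_mode=True,
                                                   max_num_faces=2) as mesh:
            res = mesh.process(arr)
        if not res.multi_face_landmarks:
            raise NoFaceFound("face-mesh detector found no face")
        if len(res.multi_face_landmarks) > 1:
            logger.warning("multiple faces detected; keeping the first (highest confidence)")
        lm = res.multi_face_landmarks[0].landmark
        pts = tuple(
            Landmark(index=i, x=p.x * w, y=p.y * h, z=p.z) for i, p in enumerate(lm)
        )
        return FaceLandmarks(points=pts, image_width=w, image_height=h)

    def detect_face(self, image) -> FaceBox:
        return face_box_from_landmarks(self.detect_landmarks(image))


_BACKENDS: dict[str, type[LandmarkBackend]] = {"mediapipe": MediapipeBackend}


def detect_landmarks(image, backend: LandmarkBackend | str) -> FaceLandmarks:
    """Detect the 468 landmarks of the (single) face in an image.

    ``backend`` is either a backend object or a registered backend name.
    """
    if isinstance(backend, str):
        if backend not in _BACKENDS:
            raise BackendUnavailable(f"unknown landmark backend {backend!r}")
        backend = _BACKENDS[backend]()
    return backend.detect_landmarks(image)


def detect_face(image, backend: LandmarkBackend | str) -> FaceBox:
    if isinstance(backend, str):
        if backend not in _BACKENDS:
            raise BackendUnavailable(f"unknown landmark backend {backend!r}")
        backend = _BACKENDS[backend]()
    return backend.detect_face(image)
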