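"""Keypoint detection and description contracts, plus face cropping.

Descriptor kinds follow the classical local-feature families: SIFT produces
128-dimensional float descriptors compared with the Euclidean metric, SURF
64 (or 128 in extended mode) float dimensions, and ORB 256-bit binary strings
compared with the Hamming metric.  The actual detectors live behind backend
adapters: scikit-image provides the SIFT and ORB backends for real images;
SURF has no unencumbered implementation and its backend reports itself
unavailable; the synthetic backend replays planted keypoint/descriptor sets
and is the workhorse for detector-free testing.
"""

from __future__ import annotations

import base64
import json
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import BackendUnavailable, EmptyCrop, MalformedBundle, UnknownPairId

KINDS = ("SIFT", "SURF", "ORB")

#: metric per kind
METRICS = {"SIFT": "EUCLIDEAN", "SURF": "EUCLIDEAN", "ORB": "HAMMING"}

#: descriptor width per kind (bits for binary kinds)
WIDTHS = {"SIFT": 128, "SURF": 64, "SURF_EXTENDED": 128, "ORB": 256}


@dataclass(frozen=True)
class Keypoint:
    """A salient image location with its detection attributes."""

    x: float
    y: float
    size: float = 1.0
    angle: float | None = None
    response: float = 0.0

    def __post_init__(self) -> None:
        if self.size < 0:
            raise ValueError("keypoint size must be >= 0")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("keypoint coordinates must be finite")


@dataclass(frozen=True)
class DescriptorSet:
    """Row-aligned descriptors for a keypoint list.

    ``values`` has one row per keypoint.  Float kinds store float arrays;
    binary kinds store bit-packed ``uint8`` rows (``width`` is in bits).
    """

    kind: str
    values: np.ndarray
    metric: str = field(default="")

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown descriptor kind {self.kind!r}")
        expected_metric = METRICS[self.kind]
        if not self.metric:
            object.__setattr__(self, "metric", expected_metric)
        elif self.metric != expected_metric:
            raise ValueError(f"{self.kind} descriptors use the {expected_metric} metric")
        v = np.asarray(self.values)
        if v.ndim != 2:
            v = v.reshape(0, self.default_width(self.kind)) if v.size == 0 else v
        if v.ndim != 2:
            raise ValueError("descriptor values must be a 2-D matrix")
        object.__setattr__(self, "values", v)
        if self.metric == "EUCLIDEAN":
            w = v.shape[1]
            if v.size and self.kind == "SIFT" and w != 128:
                raise ValueError("SIFT descriptors are 128-dimensional")
            if v.size and self.kind == "SURF" and w not in (64, 128):
                raise ValueError("SURF descriptors are 64- or 128-dimensional")
        else:
            if v.size and v.shape[1] != WIDTHS["ORB"] // 8:
                raise ValueError("ORB descriptors are 256-bit (32 packed bytes) rows")
            if v.size and v.dtype != np.uint8:
                raise ValueError("binary descriptors must be packed uint8")

    @staticmethod
    def default_width(kind: str) -> int:
        return WIDTHS["ORB"] // 8 if kind == "ORB" else WIDTHS[kind]

    @property
    def n(self) -> int:
        return int(self.values.shape[0])

    @property
    def width(self) -> int:
        """Descriptor width in the kind's natural units (dims, or bits for ORB)."""
        if self.metric == "HAMMING":
            return int(self.values.shape[1]) * 8
        return int(self.values.shape[1])


def pack_bits(bits: np.ndarray) -> np.ndarray:
    """Pack an (n, 256) boolean/0-1 matrix into (n, 32) uint8 rows."""
    b = np.asarray(bits).astype(np.uint8)
    if b.size == 0:
        return np.zeros((0, WIDTHS["ORB"] // 8), dtype=np.uint8)
    return np.packbits(b, axis=1)


def unpack_bits(packed: np.ndarray) -> np.ndarray:
    if packed.size == 0:
        return np.zeros((0, WIDTHS["ORB"]), dtype=np.uint8)
    return np.unpackbits(np.asarray(packed, dtype=np.uint8), axis=1)


def keypoint_coords(keypoints) -> np.ndarray:
    """(n, 2) array of keypoint (x, y) positions."""
    if len(keypoints) == 0:
        return np.zeros((0, 2), dtype=float)
    return np.array([(kp.x, kp.y) for kp in keypoints], dtype=float)


# -- cropping -----------------------------------------------------------------

def crop_face(image: np.ndarray, box, margin_fraction: float = 0.10) -> np.ndarray:
    """Crop the face box expanded by ``margin_fraction`` and clamped to bounds.

    The margin is a fraction of the box width/height added on each side.
    """
    arr = np.asarray(image)
    h, w = arr.shape[:2]
    bw, bh = box.x1 - box.x0, box.y1 - box.y0
    if bw <= 0 or bh <= 0:
        raise EmptyCrop("face box has zero area")
    x0 = max(0, int(math.floor(box.x0 - margin_fraction * bw)))
    y0 = max(0, int(math.floor(box.y0 - margin_fraction * bh)))
    x1 = min(w, int(math.ceil(box.x1 + margin_fraction * bw)))
    y1 = min(h, int(math.ceil(box.y1 + margin_fraction * bh)))
    if x1 <= x0 or y1 <= y0:
        raise EmptyCrop("face box lies outside the image")
    return arr[y0:y1, x0:x1]


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Standard luma conversion; detectors operate on intensity."""
    arr = np.asarray(image)
    if arr.ndim == 2:
        return arr.astype(float)
    rgb = arr[..., :3].astype(float)
    return rgb @ np.array([0.2125, 0.7154, 0.0721])


# -- backends -----------------------------------------------------------------

class DescriptorBackend:
    """Contract: detect keypoints and compute row-aligned descriptors."""

    kind: str

    def detect_and_describe(self, image, mask=None):  # pragma: no cover - contract
        raise NotImplementedError


class SkimageSiftBackend(DescriptorBackend):
    kind = "SIFT"

    def detect_and_describe(self, image, mask=None):
        from skimage.feature import SIFT

        gray = to_grayscale(image)
        det = SIFT()
        try:
            det.detect_and_extract(gray)
        except RuntimeError:  # no keypoints found
            return [], DescriptorSet(kind="SIFT", values=np.zeros((0, 128)))
        # skimage keypoints are (row, col); convert to (x, y)
        kps = [
            Keypoint(x=float(c), y=float(r), size=float(s), angle=None, response=0.0)
            for (r, c), s in zip(det.keypoints, det.scales)
        ]
        desc = det.descriptors.astype(float)
        kps, desc = _apply_mask(kps, desc, mask)
        return kps, DescriptorSet(kind="SIFT", values=desc)


class SkimageOrbBackend(DescriptorBackend):
    kind = "ORB"

    def __init__(self, n_keypoints: int = 500) -> None:
        self.n_keypoints = n_keypoints

    def detect_and_describe(self, image, mask=None):
        from skimage.feature import ORB

        gray = to_grayscale(image)
        det = ORB(n_keypoints=self.n_keypoints)
        try:
            det.detect_and_extract(gray)
        except (RuntimeError, IndexError):
            return [], DescriptorSet(kind="ORB", values=np.zeros((0, 32), dtype=np.uint8))
        kps = [
            Keypoint(x=float(c), y=float(r), size=float(s), angle=float(a), response=float(v))
            for (r, c), s, a, v in zip(
                det.keypoints, det.scales, det.orientations, det.responses
            )
        ]
        desc = pack_bits(det.descriptors)
        kps, desc = _apply_mask(kps, desc, mask)
        return kps, DescriptorSet(kind="ORB", values=desc)


class SurfBackend(DescriptorBackend):
    """SURF is patent-encumbered; no installed implementation provides it."""

    kind = "SURF"

    def __init__(self, extended: bool = False) -> None:
        self.extended = extended
        raise BackendUnavailable(
            "no SURF implementation is available; use SIFT/ORB or the synthetic backend"
        )


def _apply_mask(kps, desc, mask):
    if mask is None:
        return kps, desc
    keep = [i for i, kp in enumerate(kps)
            if mask[min(int(kp.y), mask.shape[0] - 1), min(int(kp.x), mask.shape[1] - 1)]]
    return [kps[i] for i in keep], desc[keep] if len(keep) else desc[:0]


_BACKENDS: dict[str, type[DescriptorBackend]] = {
    "SIFT": SkimageSiftBackend,
    "SURF": SurfBackend,
    "ORB": SkimageOrbBackend,
}


def get_backend(kind: str) -> DescriptorBackend:
    kind = kind.upper()
    if kind not in _BACKENDS:
        raise BackendUnavailable(f"no backend registered for kind {kind!r}")
    return _BACKENDS[kind]()


def detect_and_describe(image, kind: str, backend: DescriptorBackend | None = None,
                        mask: np.ndarray | None = None):
    """Detect keypoints and compute descriptors of ``kind`` on one image.

    Returns ``(keypoints, DescriptorSet)`` with equal row counts.  ``mask``
    optionally restricts detection to a boolean image region.
    """
    if backend is None:
        backend = get_backend(kind)
    if backend.kind != kind.upper():
        raise BackendUnavailable(f"backend serves {backend.kind}, not {kind}")
    kps, desc = backend.detect_and_describe(image, mask=mask)
    if len(kps) != desc.n:
        raise MalformedBundle("backend returned misaligned keypoints and descriptors")
    return kps, desc


class SyntheticBackend(DescriptorBackend):
    """Replay planted keypoints/descriptors for (pair_id, side) requests.

    Built from a synthetic cohort; deterministic for a given store.
    """

    def __init__(self, kind: str, store: dict) -> None:
        self.kind = kind
        self.store = store  # (pair_id, side) -> (keypoints, DescriptorSet)

    def detect_and_describe(self, image, mask=None):
        key = image if isinstance(image, tuple) else tuple(str(image).split("::"))
        if key not in self.store:
            raise UnknownPairId(f"no planted data for {key!r}")
        kps, desc = self.store[key]
        return list(kps), desc


# -- bundle serialization -----------------------------------------------------

def write_bundle(path, keypoints_by_kind: dict) -> None:
    """Write a keypoint/descriptor bundle as portable JSON text.

    Float descriptors are stored as base64 little-endian float64; binary
    descriptors as base64 packed bytes.
    """
    payload = {}
    for kind, (kps, desc) in keypoints_by_kind.items():
        mat = desc.values
        if desc.metric == "EUCLIDEAN":
            raw = np.ascontiguousarray(mat, dtype="<f8").tobytes()
            dtype = "f8"
        else:
            raw = np.ascontiguousarray(mat, dtype=np.uint8).tobytes()
            dtype = "u1"
        payload[kind] = {
            "keypoints": [[kp.x, kp.y, kp.size, kp.angle, kp.response] for kp in kps],
            "descriptors": base64.b64encode(raw).decode("ascii"),
            "shape": list(mat.shape),
            "dtype": dtype,
        }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_bundle(path) -> dict:
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise MalformedBundle(str(exc)) from exc
    out = {}
    for kind, rec in payload.items():
        try:
            raw = base64.b64decode(rec["descriptors"])
            shape = tuple(rec["shape"])
            mat = np.frombuffer(raw, dtype="<f8" if rec["dtype"] == "f8" else np.uint8)
            mat = mat.reshape(shape).copy()
            kps = [
                Keypoint(x=x, y=y, size=s, angle=a, response=r)
                for x, y, s, a, r in rec["keypoints"]
            ]
        except (KeyError, ValueError, TypeError) as exc:
            raise MalformedBundle(f"bundle entry {kind!r}: {exc}") from exc
        if len(kps) != mat.shape[0]:
            raise MalformedBundle(f"bundle entry {kind!r}: row count mismatch")
        out[kind] = (kps, DescriptorSet(kind=kind, values=mat))
    return out
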