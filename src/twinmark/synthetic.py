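"""Synthetic fixtures: landmark template, planted keypoint pairs, cohorts.

Everything the verification pipeline consumes can be generated here without
any licensed face imagery: a deterministic 468-point landmark template whose
eight canonical regions are positive-area, interior-disjoint polygons (except
the whole-face oval, which contains them all); paired keypoint clouds with
planted correspondences and per-kind descriptors (isotropic Gaussian noise
for float kinds, i.i.d. bit flips for binary); and labeled cohorts whose
class difference is carried purely by class-conditional per-region mismatch
rates, mirroring the structure of the reported feature statistics (e.g. nose
mismatch concentration ~0.035 for same-person pairs vs ~0.072 for twins).

Template layout notes
---------------------
The published region index lists share a few vertices across regions (the
lips list includes the mouth corners and chin-line points of the face curve,
and two right-eyebrow indices).  Since each mesh index has a single position,
the template places those shared vertices so that every region ring stays a
simple polygon and region interiors remain disjoint: the lips/face-curve
share boundary chords through the mouth corners, the lips ring spikes up to
one stray eyebrow vertex on the right-eyebrow strip's lower edge, and the
other stray vertex coincides with a mouth corner as a zero-length ring edge,
so every shared vertex is a point of tangency rather than an overlap.  The layout is synthetic geometry, not facial anatomy; it
exists so that region counting has an exact, checkable ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .errors import InfeasibleSpec, UnknownPairId
from .keypoints import KINDS, DescriptorSet, Keypoint, pack_bits, unpack_bits
from .landmark_regions import (
    FACE_OVAL_CONTOUR,
    N_LANDMARKS,
    REGION_NAMES,
    FaceLandmarks,
    Landmark,
    RegionSet,
    canonical_regions,
    region_polygon,
)

IMAGE_SIZE = 512

#: the seven plantable (non-oval) regions
PLANT_REGIONS = tuple(n for n in REGION_NAMES if n != "OVAL_FACE")


# ---------------------------------------------------------------------------
# landmark template
# ---------------------------------------------------------------------------

def _oval_positions() -> dict[int, tuple[float, float]]:
    cx, cy, rx, ry = 256.0, 260.0, 175.0, 215.0
    pos = {}
    for j, idx in enumerate(FACE_OVAL_CONTOUR):
        a = math.radians(-10.0 * j)
        pos[idx] = (cx + rx * math.sin(a), cy - ry * math.cos(a))
    return pos


def _lips_ring_indices() -> list[int]:
    printed = canonical_regions()["LIPS"].indices
    seen, ring = set(), []
    for i in printed:
        if i not in seen:
            seen.add(i)
            ring.append(i)
    return ring


def _lips_positions() -> dict[int, tuple[float, float]]:
    """Lips ring traced in printed order as a simple polygon.

    The lips are a shallow crescent under the mouth line: the upper boundary
    sags between the two corners (61 right, 291 left), the lower boundary
    runs along the two corner-to-chin chords shared vertex-exactly with the
    face curve.  The two stray right-eyebrow indices in the printed list are
    handled geometrically: 46 becomes a short spike from the upper boundary
    to the eyebrow strip's lower edge, and 65 (wedged between the left corner
    and the chord, where every excursion would cross a neighbor region) is
    placed exactly on the left corner as a zero-length ring edge.
    """
    p61, p14, p291 = (278.0, 390.0), (256.0, 412.0), (234.0, 390.0)
    ring = _lips_ring_indices()  # 42 unique indices
    i61, i291, i14 = ring.index(61), ring.index(291), ring.index(14)  # 0, 11, 27
    n = len(ring)
    pos: dict[int, tuple[float, float]] = {}
    for p, idx in enumerate(ring):
        if p == i61:
            pos[idx] = p61
        elif p == i291:
            pos[idx] = p291
        elif p == i14:
            pos[idx] = p14
        elif idx == 46:       # spike tip on the eyebrow strip's lower edge
            pos[idx] = (285.0, 364.5)
        elif idx == 65:       # coincides with the left corner (see docstring)
            pos[idx] = p291
        elif p < i291:        # sagging upper boundary, right -> left
            pos[idx] = (278.0 - 4.0 * p, 390.0 + 6.0 * math.sin(math.pi * p / i291))
        elif p < i14:         # chord 291 -> 14 (shared with the face curve)
            t = (p - i291) / (i14 - i291)
            pos[idx] = (p291[0] + 22.0 * t, p291[1] + 22.0 * t)
        else:                 # chord 14 -> 61 (shared with the face curve)
            t = (p - i14) / (n - i14)
            pos[idx] = (p14[0] + 22.0 * t, p14[1] - 22.0 * t)
    return pos


_FIXED_POSITIONS: dict[int, tuple[float, float]] = {
    # left eye (subject's left, image right) and right eye: axis-aligned quads
    463: (300, 200), 257: (340, 200), 359: (340, 222), 253: (300, 222),
    130: (172, 200), 27: (212, 200), 243: (212, 222), 23: (172, 222),
    # left eyebrow: two-row band above the left eye
    276: (296, 168), 283: (308, 164), 282: (320, 162), 295: (332, 164), 285: (344, 168),
    300: (298, 182), 293: (310, 178), 334: (322, 176), 296: (334, 178), 336: (346, 182),
    # right eyebrow: oblique strip between nose and mouth whose lower edge
    # (the line y = 390 - 0.5 (x - 234)) passes exactly through the shared
    # lip-spike tip 46 and ends at the shared mouth-corner vertex 65
    53: (250, 382), 52: (270, 372), 55: (290, 362), 70: (310, 352),
    63: (252, 373), 105: (272, 363), 66: (292, 353), 107: (312, 343),
    # nose hexagon (index 8 at the bridge, 164 at the base)
    8: (256, 296), 240: (238, 322), 98: (246, 344), 164: (256, 350),
    327: (266, 344), 460: (274, 322),
    # face-curve inner boundary (right -> left, dipping through the mouth)
    138: (329, 415), 214: (319, 404), 212: (306, 397), 57: (290, 393),
    287: (222, 393), 432: (206, 397), 434: (193, 404), 367: (183, 415),
}


def make_landmark_template(seed: int | None = None) -> FaceLandmarks:
    """Deterministic 468-point layout realizing the canonical regions.

    The optional seed only jitters the filler vertices (those belonging to no
    region); region geometry is fixed so planted counts have exact ground
    truth.
    """
    pos: dict[int, tuple[float, float]] = {}
    pos.update(_oval_positions())
    pos.update(_lips_positions())
    pos.update(_FIXED_POSITIONS)
    # remaining indices: tight spiral on the forehead, inside the oval only
    rest = [i for i in range(N_LANDMARKS) if i not in pos]
    rng = np.random.default_rng(0 if seed is None else seed)
    golden = math.pi * (3 - math.sqrt(5))
    for j, idx in enumerate(rest):
        r = 4.0 + 36.0 * j / max(len(rest) - 1, 1)
        a = golden * j
        jitter = rng.uniform(-0.3, 0.3, size=2) if seed is not None else (0.0, 0.0)
        pos[idx] = (256.0 + r * math.cos(a) + jitter[0], 110.0 + r * math.sin(a) + jitter[1])
    points = tuple(
        Landmark(index=i, x=float(pos[i][0]), y=float(pos[i][1]), z=0.0)
        for i in range(N_LANDMARKS)
    )
    return FaceLandmarks(points=points, image_width=IMAGE_SIZE, image_height=IMAGE_SIZE)


# ---------------------------------------------------------------------------
# cohort specification
# ---------------------------------------------------------------------------

#: class-conditional per-region mismatch-concentration means (u_r / U); the
#: listed regions' values follow the reported feature statistics, eyebrows
#: (not reported) get a modest effect of the same order
DEFAULT_MISMATCH_MEANS = {
    0: {"NOSE": 0.0352, "L_EYE": 0.0352, "R_EYE": 0.0366, "FACE_CURVE": 0.0455,
        "LIPS": 0.0362, "L_EYEBROW": 0.0360, "R_EYEBROW": 0.0360},
    1: {"NOSE": 0.0720, "L_EYE": 0.0666, "R_EYE": 0.0678, "FACE_CURVE": 0.0748,
        "LIPS": 0.0564, "L_EYEBROW": 0.0500, "R_EYEBROW": 0.0500},
}

#: class-independent per-region matched-concentration rates (m_r / M)
DEFAULT_MATCH_RATES = {
    "L_EYE": 0.11, "R_EYE": 0.11, "L_EYEBROW": 0.08, "R_EYEBROW": 0.08,
    "NOSE": 0.10, "LIPS": 0.12, "FACE_CURVE": 0.15,
}


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a synthetic twin-verification cohort."""

    n_same: int = 50
    n_twin: int = 50
    keypoints_per_image: int = 300
    match_fraction: float = 0.5
    mismatch_rate_means: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MISMATCH_MEANS.items()})
    mismatch_rate_sd: float = 0.02
    match_region_rates: dict = field(default_factory=lambda: dict(DEFAULT_MATCH_RATES))
    background_inside_oval: float = 0.5
    #: float kinds: isotropic Gaussian sigma; binary kinds: per-bit flip rate
    descriptor_noise_sigma: float = 0.05
    kinds: tuple = ("SIFT", "SURF", "ORB")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_same < 0 or self.n_twin < 0 or self.n_same + self.n_twin < 1:
            raise InfeasibleSpec("cohort needs at least one pair")
        if not 0 < self.match_fraction < 1:
            raise InfeasibleSpec("match_fraction must be in (0, 1)")
        if self.keypoints_per_image < 2:
            raise InfeasibleSpec("need at least 2 keypoints per image")
        if self.mismatch_rate_sd < 0 or not 0 <= self.background_inside_oval <= 1:
            raise InfeasibleSpec("rate sd must be >= 0 and fractions in [0, 1]")
        for label, rates in self.mismatch_rate_means.items():
            bad = {r: v for r, v in rates.items() if not 0 <= v <= 1}
            if bad:
                raise InfeasibleSpec(f"label {label} rates outside [0,1]: {bad}")
            if sum(rates.values()) > 1:
                raise InfeasibleSpec(f"label {label} mismatch rates sum above 1")
        if sum(self.match_region_rates.values()) > 1:
            raise InfeasibleSpec("match region rates sum above 1")
        if any(k not in KINDS for k in self.kinds) or not self.kinds:
            raise InfeasibleSpec(f"kinds must be a non-empty subset of {KINDS}")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth for one generated pair."""

    pair_id: str
    label: int
    matched_a: frozenset[int]
    correspondences: dict            # A index -> B index
    region_matched: dict             # region -> planted matched count (A side)
    region_mismatched: dict          # region -> planted mismatched count (A side)
    drawn_mismatch_rates: dict       # region -> the pair's drawn rate
    M: int
    U: int
    K: int


class _TemplateGeometry:
    """Cached region polygons and samplers over the landmark template."""

    def __init__(self, landmarks: FaceLandmarks, regions: RegionSet) -> None:
        self.landmarks = landmarks
        self.regions = regions
        self.polys = {
            r.name: Polygon(region_polygon(landmarks, r)) for r in regions
        }

    def sample_in(self, name: str, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform points strictly inside region `name` and outside the other
        plantable regions (the layout makes them interior-disjoint)."""
        return self._rejection(n, rng, inside=[name],
                               outside=[r for r in PLANT_REGIONS if r != name])

    def sample_oval_background(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self._rejection(n, rng, inside=["OVAL_FACE"], outside=list(PLANT_REGIONS))

    def sample_outside_face(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self._rejection(n, rng, inside=[], outside=["OVAL_FACE"])

    def _rejection(self, n, rng, inside, outside) -> np.ndarray:
        if n == 0:
            return np.zeros((0, 2))
        if inside:
            minx, miny, maxx, maxy = self.polys[inside[0]].bounds
        else:
            minx = miny = 0.0
            maxx = maxy = float(IMAGE_SIZE)
        out = []
        need = n
        for _ in range(200):  # expected few iterations; hard stop for safety
            cand = rng.uniform((minx, miny), (maxx, maxy), size=(max(4 * need, 64), 2))
            pts = shapely.points(cand[:, 0], cand[:, 1])
            ok = np.ones(len(cand), dtype=bool)
            for name in inside:
                ok &= shapely.contains(self.polys[name], pts)
            for name in outside:
                ok &= ~shapely.covers(self.polys[name], pts)
            sel = cand[ok]
            out.append(sel[:need])
            need -= len(sel[:need])
            if need == 0:
                return np.vstack(out)
        raise InfeasibleSpec(f"rejection sampling failed for {inside or 'background'}")


_GEOMETRY_CACHE: dict[int, _TemplateGeometry] = {}


def template_geometry() -> _TemplateGeometry:
    if 0 not in _GEOMETRY_CACHE:
        _GEOMETRY_CACHE[0] = _TemplateGeometry(make_landmark_template(), canonical_regions())
    return _GEOMETRY_CACHE[0]


def _draw_counts(total: int, rates: dict, rng: np.random.Generator) -> dict:
    """Multinomial region-count draw: binomial marginals per region, never
    exceeding the budget."""
    names = list(rates)
    probs = [rates[r] for r in names]
    rest = 1.0 - sum(probs)
    if rest < 0:
        raise InfeasibleSpec(f"region rates sum to {sum(probs):.3f} > 1")
    drawn = rng.multinomial(total, probs + [rest])
    return {r: int(c) for r, c in zip(names, drawn[:-1])}


def _random_descriptors(kind: str, n: int, rng: np.random.Generator) -> np.ndarray:
    if kind == "ORB":
        return pack_bits(rng.integers(0, 2, size=(n, 256)))
    dim = 128 if kind == "SIFT" else 64
    return rng.standard_normal((n, dim))


def _noisy_copy(kind: str, values: np.ndarray, sigma: float,
                rng: np.random.Generator) -> np.ndarray:
    if sigma == 0:
        return values.copy()
    if kind == "ORB":
        bits = unpack_bits(values)
        flips = rng.random(bits.shape) < sigma
        return pack_bits(bits ^ flips)
    return values + sigma * rng.standard_normal(values.shape)


def synth_pair(spec: CohortSpec, label: int, pair_seed, pair_id: str = "pair"):
    """Generate one image pair's bundles and ground truth.

    Returns ``(bundle_a, bundle_b, truth)`` where each bundle maps kind ->
    ``(keypoints, DescriptorSet)``.  A planted fraction of A's keypoints has a
    descriptor counterpart in B (A's descriptor plus noise); every other
    keypoint gets an independent random descriptor, so a brute-force matcher
    with the ratio test recovers exactly the planted correspondences when the
    noise is small.
    """
    if label not in spec.mismatch_rate_means:
        raise ValueError(f"no rates configured for label {label}")
    rng = np.random.default_rng(pair_seed)
    geom = template_geometry()
    K = spec.keypoints_per_image
    M = int(round(spec.match_fraction * K))
    U = K - M

    means = spec.mismatch_rate_means[label]
    drawn = {
        r: float(np.clip(rng.normal(means[r], spec.mismatch_rate_sd), 0.0, 1.0))
        for r in PLANT_REGIONS
    }
    u_counts = _draw_counts(U, drawn, rng)
    m_counts = _draw_counts(M, {r: spec.match_region_rates.get(r, 0.0)
                                for r in PLANT_REGIONS}, rng)

    def _positions(region_counts: dict, total: int) -> tuple[np.ndarray, dict]:
        chunks, planted = [], dict(region_counts)
        for r in PLANT_REGIONS:
            chunks.append(geom.sample_in(r, region_counts[r], rng))
        rest = total - sum(region_counts.values())
        inside = int(rng.binomial(rest, spec.background_inside_oval)) if rest else 0
        chunks.append(geom.sample_oval_background(inside, rng))
        chunks.append(geom.sample_outside_face(rest - inside, rng))
        planted["OVAL_FACE"] = sum(region_counts.values()) + inside
        return np.vstack(chunks), planted

    pos_matched, m_planted = _positions(m_counts, M)
    pos_mismatched, u_planted = _positions(u_counts, U)
    pos_a = np.vstack([pos_matched, pos_mismatched])
    perm_a = rng.permutation(K)
    pos_a = pos_a[perm_a]
    # index i of the pre-shuffle layout lands at position inv[i]
    inv_a = np.empty(K, dtype=int)
    inv_a[perm_a] = np.arange(K)
    matched_a = frozenset(int(inv_a[i]) for i in range(M))

    # B: planted counterparts at the matched positions plus fresh clutter
    pos_b_clutter, _ = _positions(u_counts, U)
    pos_b = np.vstack([pos_matched, pos_b_clutter])
    perm_b = rng.permutation(K)
    inv_b = np.empty(K, dtype=int)
    inv_b[perm_b] = np.arange(K)
    pos_b = pos_b[perm_b]
    correspondences = {int(inv_a[i]): int(inv_b[i]) for i in range(M)}

    def _kps(pos: np.ndarray) -> list[Keypoint]:
        return [Keypoint(x=float(x), y=float(y), size=2.0, angle=0.0, response=1.0)
                for x, y in pos]

    bundle_a, bundle_b = {}, {}
    for kind in spec.kinds:
        # generate in pre-shuffle layout (matched rows first), then shuffle
        # alongside the positions
        desc_pre_a = _random_descriptors(kind, K, rng)
        desc_pre_b_match = _noisy_copy(kind, desc_pre_a[:M], spec.descriptor_noise_sigma, rng)
        desc_pre_b = np.vstack([desc_pre_b_match, _random_descriptors(kind, U, rng)])
        bundle_a[kind] = (_kps(pos_a), DescriptorSet(kind=kind, values=desc_pre_a[perm_a]))
        bundle_b[kind] = (_kps(pos_b), DescriptorSet(kind=kind, values=desc_pre_b[perm_b]))

    truth = PlantedTruth(
        pair_id=pair_id, label=label, matched_a=matched_a,
        correspondences=correspondences,
        region_matched=m_planted, region_mismatched=u_planted,
        drawn_mismatch_rates=drawn, M=M, U=U, K=K,
    )
    return bundle_a, bundle_b, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

class CohortBackend:
    """Replayable per-pair backend over a generated cohort.

    Bundles are regenerated deterministically from the pair's seed on demand
    (one-pair cache), so large cohorts never hold all descriptors in memory.
    """

    def __init__(self, spec: CohortSpec, pair_seeds: dict, labels: dict) -> None:
        self.spec = spec
        self.pair_seeds = pair_seeds
        self.labels = labels
        self._cache: tuple | None = None

    def _bundles(self, pair_id: str):
        if self._cache is not None and self._cache[0] == pair_id:
            return self._cache[1], self._cache[2]
        if pair_id not in self.pair_seeds:
            raise UnknownPairId(pair_id)
        a, b, _ = synth_pair(self.spec, self.labels[pair_id],
                             self.pair_seeds[pair_id], pair_id=pair_id)
        self._cache = (pair_id, a, b)
        return a, b

    def landmarks(self, pair_id: str, side: str) -> FaceLandmarks:
        if pair_id not in self.pair_seeds:
            raise UnknownPairId(pair_id)
        return template_geometry().landmarks

    def detect(self, pair_id: str, side: str, kind: str):
        a, b = self._bundles(pair_id)
        # accept plain "A"/"B" or manifest side refs of the form "<pair>::A"
        token = side.split("::")[-1].upper()
        if token not in ("A", "B"):
            raise UnknownPairId(f"side reference {side!r} does not end in A or B")
        bundle = a if token == "A" else b
        kps, desc = bundle[kind]
        return list(kps), desc

    def truth(self, pair_id: str) -> PlantedTruth:
        if pair_id not in self.pair_seeds:
            raise UnknownPairId(pair_id)
        _, _, t = synth_pair(self.spec, self.labels[pair_id],
                             self.pair_seeds[pair_id], pair_id=pair_id)
        return t


@dataclass
class Cohort:
    spec: CohortSpec
    manifest: pd.DataFrame
    truth: pd.DataFrame
    backend: CohortBackend


def synth_cohort(spec: CohortSpec) -> Cohort:
    """Generate a labeled cohort of same-person and twin pairs.

    Label 0 pairs emulate two captures of one subject, label 1 pairs one
    capture of each co-twin; the two differ only in the class-conditional
    region mismatch rates.
    """
    seeds = np.random.SeedSequence(spec.seed).generate_state(spec.n_same + spec.n_twin)
    pair_ids, labels, pair_seeds = [], {}, {}
    for i in range(spec.n_same):
        pid = f"same_{i:04d}"
        pair_ids.append(pid)
        labels[pid] = 0
        pair_seeds[pid] = int(seeds[i])
    for i in range(spec.n_twin):
        pid = f"twin_{i:04d}"
        pair_ids.append(pid)
        labels[pid] = 1
        pair_seeds[pid] = int(seeds[spec.n_same + i])
    manifest = pd.DataFrame({
        "pair_id": pair_ids,
        "side_a": [f"{p}::A" for p in pair_ids],
        "side_b": [f"{p}::B" for p in pair_ids],
        "label": [labels[p] for p in pair_ids],
    })
    backend = CohortBackend(spec, pair_seeds, labels)
    rows = []
    for pid in pair_ids:
        t = backend.truth(pid)
        row = {"pair_id": pid, "label": t.label, "M": t.M, "U": t.U, "K": t.K}
        for r in PLANT_REGIONS:
            row[f"rate_{r}"] = t.drawn_mismatch_rates[r]
            row[f"u_{r}"] = t.region_mismatched[r]
            row[f"m_{r}"] = t.region_matched[r]
        row["u_OVAL_FACE"] = t.region_mismatched["OVAL_FACE"]
        row["m_OVAL_FACE"] = t.region_matched["OVAL_FACE"]
        rows.append(row)
    truth = pd.DataFrame(rows)
    return Cohort(spec=spec, manifest=manifest, truth=truth, backend=backend)


# ---------------------------------------------------------------------------
# procedural face image (smoke tests for real detectors)
# ---------------------------------------------------------------------------

def synth_face_image(seed: int = 0, textured: bool = True,
                     size: int = 256) -> np.ndarray:
    """Procedurally drawn face-like test card (uint8 grayscale).

    With ``textured=True`` the face carries multiplicative speckle so that
    blob/corner detectors find plenty of keypoints; ``textured=False`` returns
    a uniform blank control on which detectors find none.
    """
    img = np.full((size, size), 96, dtype=float)
    if not textured:
        return img.astype(np.uint8)
    from skimage.draw import disk, ellipse

    c = size / 2
    rr, cc = ellipse(c, c, 0.42 * size, 0.34 * size, shape=img.shape)
    img[rr, cc] = 200
    for dx in (-0.13, 0.13):  # eyes
        rr, cc = ellipse(0.40 * size, c + dx * size, 0.030 * size, 0.055 * size,
                         shape=img.shape)
        img[rr, cc] = 40
        rr, cc = disk((0.40 * size, c + dx * size), 0.012 * size, shape=img.shape)
        img[rr, cc] = 230
        rr, cc = ellipse(0.32 * size, c + dx * size, 0.012 * size, 0.06 * size,
                         shape=img.shape)  # brows
        img[rr, cc] = 60
    rr, cc = ellipse(0.55 * size, c, 0.07 * size, 0.018 * size, shape=img.shape)  # nose
    img[rr, cc] = 150
    rr, cc = ellipse(0.70 * size, c, 0.025 * size, 0.10 * size, shape=img.shape)  # mouth
    img[rr, cc] = 70
    rng = np.random.default_rng(seed)
    speckle = 1.0 + 0.35 * rng.standard_normal(img.shape)
    face = np.zeros_like(img, dtype=bool)
    rr, cc = ellipse(c, c, 0.42 * size, 0.34 * size, shape=img.shape)
    face[rr, cc] = True
    img[face] *= speckle[face]
    return np.clip(img, 0, 255).astype(np.uint8)
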