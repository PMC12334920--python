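"""Region-wise ratio features computed from a match/mismatch partition.

Given the matched/mismatched partition of a face pair's keypoints and their
region assignments, two 16-value feature schemas are supported per descriptor
kind:

* ``TABLE3`` (default): for each of the 8 canonical regions r, the matched
  ratio m_r / M and the mismatched ratio u_r / U, named
  ``{KIND}_{REGION}_{MATCH|MIS_MATCH}`` (e.g. ``ORB_NOSE_MIS_MATCH``).
* ``EQUATIONS``: the printed formula set -- the face-wide totals M/K and U/K,
  the seven-region concentrations sum(m_r)/M and sum(u_r)/U, and twelve
  per-region mismatch ratios u_r/M and u_r/U over curve, mouth, nose, eyes
  (left+right), eyebrows (left+right) and oval.

Here M, U and K are the matched, mismatched and total keypoint counts of the
pair, m_r and u_r the per-region matched/mismatched counts, and the "seven
regions" are the eight canonical ones minus the whole-face oval (whose
concentration would be ~1 by construction).  Region assignment is
multi-label, so a nose keypoint contributes to both NOSE and OVAL_FACE.
Zero-denominator ratios are defined as 0 and logged.  Features from several
descriptor kinds are fused by concatenation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DuplicateKind, SchemaMismatch, ZeroDenominatorWarning
from .keypoints import KINDS, keypoint_coords
from .landmark_regions import REGION_NAMES, FaceLandmarks, RegionSet, assign_regions
from .matching import MatchResult

SCHEMAS = ("TABLE3", "EQUATIONS")

#: the seven non-oval regions of the printed concentration formulas
SEVEN_REGIONS = tuple(n for n in REGION_NAMES if n != "OVAL_FACE")

#: printed per-region mismatch-ratio order of the twelve numbered ratios
_EQ_REGION_GROUPS = (
    ("FACE_CURVE",),            # curve
    ("LIPS",),                  # mouth
    ("NOSE",),                  # nose
    ("L_EYE", "R_EYE"),         # eyes
    ("L_EYEBROW", "R_EYEBROW"), # eyebrows
    ("OVAL_FACE",),             # oval
)

EQUATION_NAMES = (
    "TOTAL_MATCH", "TOTAL_MISMATCH", "RATIO_MATCH", "RATIO_MISMATCH",
    *[f"RATIO{i}" for i in range(1, 13)],
)


@dataclass(frozen=True)
class RegionCounts:
    """Matched/mismatched keypoint counts per region plus the pair totals."""

    m: dict[str, float]
    u: dict[str, float]
    M: float
    U: float
    K: float

    def __post_init__(self) -> None:
        if abs(self.M + self.U - self.K) > 1e-9:
            raise ValueError("M + U must equal K (partition conservation)")
        for r in REGION_NAMES:
            if not -1e-9 <= self.m.get(r, 0) <= self.M + 1e-9:
                raise ValueError(f"m[{r}] outside [0, M]")
            if not -1e-9 <= self.u.get(r, 0) <= self.U + 1e-9:
                raise ValueError(f"u[{r}] outside [0, U]")


@dataclass(frozen=True)
class RatioFeatures:
    """An ordered, named 16-value ratio feature vector for one descriptor kind."""

    kind: str
    schema: str
    values: dict[str, float]
    flagged: bool = False  # set when a ratio exceeded 1 (u_r > M in RATIO1..6)

    def __post_init__(self) -> None:
        if self.schema not in SCHEMAS:
            raise ValueError(f"unknown schema {self.schema!r}")
        if len(self.values) != 16:
            raise ValueError("a ratio feature vector has exactly 16 values")

    def as_array(self) -> np.ndarray:
        return np.array(list(self.values.values()), dtype=float)


@dataclass(frozen=True)
class FusedFeatures:
    """Concatenation of per-kind ratio features in a fixed kind order."""

    values: dict[str, float]
    kinds: tuple[str, ...]

    def as_array(self) -> np.ndarray:
        return np.array(list(self.values.values()), dtype=float)


def feature_names(kind: str, schema: str = "TABLE3") -> list[str]:
    """Frozen column order for one kind under a schema."""
    kind = kind.upper()
    if schema == "TABLE3":
        names = []
        for r in REGION_NAMES:
            names.append(f"{kind}_{r}_MATCH")
            names.append(f"{kind}_{r}_MIS_MATCH")
        return names
    return [f"{kind}_{n}" for n in EQUATION_NAMES]


def count_by_region(
    result: MatchResult,
    keypoints,
    landmarks: FaceLandmarks,
    regions: RegionSet,
    count_side: str = "A",
    keypoints_b=None,
) -> RegionCounts:
    """Count matched and mismatched keypoints per region.

    Counts are over image A's keypoints by default; ``count_side`` may be
    ``"A"``, ``"B"`` (requires ``keypoints_b``) or ``"MEAN"`` (average of
    both sides, giving fractional counts).  Multi-label points increment
    every region containing them.
    """
    def _one_side(kps, matched, mismatched):
        labels = assign_regions(keypoint_coords(kps), landmarks, regions)
        m = {r: 0.0 for r in REGION_NAMES}
        u = {r: 0.0 for r in REGION_NAMES}
        for i, labs in enumerate(labels):
            tgt = m if i in matched else u
            for r in labs:
                tgt[r] += 1.0
        return m, u, float(len(matched)), float(len(mismatched))

    side = count_side.upper()
    if side == "A":
        m, u, M, U = _one_side(keypoints, result.matched_a, result.mismatched_a)
    elif side == "B":
        if keypoints_b is None:
            raise ValueError("count_side='B' requires keypoints_b")
        m, u, M, U = _one_side(keypoints_b, result.matched_b, result.mismatched_b)
    elif side == "MEAN":
        if keypoints_b is None:
            raise ValueError("count_side='MEAN' requires keypoints_b")
        ma, ua, Ma, Ua = _one_side(keypoints, result.matched_a, result.mismatched_a)
        mb, ub, Mb, Ub = _one_side(keypoints_b, result.matched_b, result.mismatched_b)
        m = {r: (ma[r] + mb[r]) / 2 for r in REGION_NAMES}
        u = {r: (ua[r] + ub[r]) / 2 for r in REGION_NAMES}
        M, U = (Ma + Mb) / 2, (Ua + Ub) / 2
    else:
        raise ValueError(f"count_side must be A, B or MEAN, not {count_side!r}")
    return RegionCounts(m=m, u=u, M=M, U=U, K=M + U)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator in {what}; ratio defined as 0",
                      ZeroDenominatorWarning, stacklevel=3)
        return 0.0
    return num / den


def compute_features(counts: RegionCounts, schema: str = "TABLE3",
                     kind: str = "SIFT") -> RatioFeatures:
    """Compute one kind's 16 ratio features from region counts."""
    kind = kind.upper()
    if kind not in KINDS:
        raise ValueError(f"unknown descriptor kind {kind!r}")
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    values: dict[str, float] = {}
    flagged = False
    if schema == "TABLE3":
        for r in REGION_NAMES:
            values[f"{kind}_{r}_MATCH"] = _safe_div(counts.m[r], counts.M, f"{r} match ratio")
            values[f"{kind}_{r}_MIS_MATCH"] = _safe_div(counts.u[r], counts.U,
                                                        f"{r} mismatch ratio")
    else:
        values[f"{kind}_TOTAL_MATCH"] = _safe_div(counts.M, counts.K, "total match")
        values[f"{kind}_TOTAL_MISMATCH"] = _safe_div(counts.U, counts.K, "total mismatch")
        m7 = sum(counts.m[r] for r in SEVEN_REGIONS)
        u7 = sum(counts.u[r] for r in SEVEN_REGIONS)
        values[f"{kind}_RATIO_MATCH"] = _safe_div(m7, counts.M, "seven-region match")
        values[f"{kind}_RATIO_MISMATCH"] = _safe_div(u7, counts.U, "seven-region mismatch")
        for i, group in enumerate(_EQ_REGION_GROUPS, start=1):
            u_r = sum(counts.u[r] for r in group)
            v = _safe_div(u_r, counts.M, f"ratio{i}")
            if v > 1.0:
                flagged = True  # kept as computed; clipping would hide the signal
            values[f"{kind}_RATIO{i}"] = v
        for i, group in enumerate(_EQ_REGION_GROUPS, start=7):
            u_r = sum(counts.u[r] for r in group)
            values[f"{kind}_RATIO{i}"] = _safe_div(u_r, counts.U, f"ratio{i}")
    return RatioFeatures(kind=kind, schema=schema, values=values, flagged=flagged)


def fuse(features: list[RatioFeatures],
         order: tuple[str, ...] = ("SIFT", "SURF", "ORB")) -> FusedFeatures:
    """Concatenate per-kind feature vectors in the configured kind order.

    Supports any non-empty subset of kinds (single, pairwise, all three).
    """
    if not features:
        raise ValueError("nothing to fuse")
    kinds = [f.kind for f in features]
    if len(set(kinds)) != len(kinds):
        raise DuplicateKind(f"duplicate kinds in fusion request: {kinds}")
    schemas = {f.schema for f in features}
    if len(schemas) != 1:
        raise SchemaMismatch(f"cannot fuse mixed schemas {schemas}")
    by_kind = {f.kind: f for f in features}
    ordered = [by_kind[k] for k in order if k in by_kind]
    if len(ordered) != len(features):
        extra = set(by_kind) - set(order)
        raise ValueError(f"kinds {extra} missing from fusion order {order}")
    values: dict[str, float] = {}
    for f in ordered:
        values.update(f.values)
    return FusedFeatures(values=values, kinds=tuple(f.kind for f in ordered))
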