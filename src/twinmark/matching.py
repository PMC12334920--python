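"""Brute-force descriptor matching and the matched/mismatched partition.

Matching is one-directional and exhaustive: every descriptor of image A is
compared against every descriptor of image B (Euclidean distance for float
descriptors, Hamming for binary), the k nearest B neighbors are kept per A
keypoint, and a filter rule selects the "good matches".  The default filter
is Lowe's ratio test at 0.7 -- keep A_i's best match only when its distance
is below 70% of the second-best distance -- which is the standard reading of
the published 70% rule; two alternative readings are selectable for
sensitivity analysis.  Keypoints of A that own a good match are *matched*;
every other keypoint is *mismatched*, and the concentration of mismatched
points is the raw signal the ratio features are built from.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DuplicateQueryIndex, InsufficientNeighbors, MetricMismatch
from .keypoints import DescriptorSet, unpack_bits

logger = logging.getLogger(__name__)


class FilterRule(enum.Enum):
    LOWE_RATIO = "lowe"
    PAPER_LITERAL = "paper_literal"
    MIN_DIST_SCALE = "min_dist_scale"


class SingleNeighborPolicy(enum.Enum):
    KEEP = "keep"
    DROP = "drop"
    RAISE = "raise"


@dataclass(frozen=True)
class Match:
    index_a: int
    index_b: int
    distance: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.distance) or self.distance < 0:
            raise ValueError("match distance must be finite and >= 0")


@dataclass(frozen=True)
class MatchResult:
    """Partition of both images' keypoints into matched and mismatched sets."""

    good: tuple[Match, ...]
    matched_a: frozenset[int]
    mismatched_a: frozenset[int]
    matched_b: frozenset[int]
    mismatched_b: frozenset[int]
    rule: FilterRule = FilterRule.LOWE_RATIO
    threshold: float = 0.7

    @property
    def n_a(self) -> int:
        return len(self.matched_a) + len(self.mismatched_a)

    @property
    def n_b(self) -> int:
        return len(self.matched_b) + len(self.mismatched_b)


def distance_matrix(desc_a: DescriptorSet, desc_b: DescriptorSet) -> np.ndarray:
    if desc_a.kind != desc_b.kind or desc_a.metric != desc_b.metric:
        raise MetricMismatch(
            f"cannot match {desc_a.kind}/{desc_a.metric} against {desc_b.kind}/{desc_b.metric}"
        )
    if desc_a.n == 0 or desc_b.n == 0:
        return np.zeros((desc_a.n, desc_b.n))
    if desc_a.metric == "HAMMING":
        bits_a = unpack_bits(desc_a.values).astype(float)
        bits_b = unpack_bits(desc_b.values).astype(float)
        return cdist(bits_a, bits_b, metric="hamming") * bits_a.shape[1]
    return cdist(desc_a.values.astype(float), desc_b.values.astype(float))


def knn_match(desc_a: DescriptorSet, desc_b: DescriptorSet, k: int = 2) -> list[list[Match]]:
    """Exhaustive k-nearest-neighbor matching from A's descriptors into B's.

    Per A keypoint the k nearest B neighbors are returned sorted ascending by
    distance, ties broken by the smaller B index.  Lists are shorter when B
    has fewer than k descriptors.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    dmat = distance_matrix(desc_a, desc_b)
    n_a, n_b = dmat.shape
    kk = min(k, n_b)
    out: list[list[Match]] = []
    cols = np.arange(n_b)
    for i in range(n_a):
        order = np.lexsort((cols, dmat[i]))[:kk]
        out.append([Match(index_a=i, index_b=int(j), distance=float(dmat[i, j]))
                    for j in order])
    return out


def _best_matches(candidates: list[list[Match]]) -> list[Match]:
    return [c[0] for c in candidates if c]


def filter_good_matches(
    candidates: list[list[Match]],
    rule: FilterRule = FilterRule.LOWE_RATIO,
    ratio: float = 0.7,
    n_b: int | None = None,
    single_neighbor: SingleNeighborPolicy = SingleNeighborPolicy.KEEP,
) -> list[Match]:
    """Select the good matches from KNN candidate lists.

    Rules:

    * ``LOWE_RATIO`` (default): keep A_i's best match iff d1 < ratio * d2.
      Candidate lists with a single entry have no contesting neighbor; the
      ``single_neighbor`` policy keeps them (default, logged), drops them, or
      raises :class:`InsufficientNeighbors`.
    * ``PAPER_LITERAL``: keep iff d1 < ratio * min(n_A, n_B), reading the 70%
      rule as a fraction of the smaller descriptor count.
    * ``MIN_DIST_SCALE``: keep iff d1 <= ratio * d_min over all best matches
      (here ``ratio`` acts as the scale c >= 1).

    The result is sorted ascending by distance (ties by A index).
    """
    good: list[Match] = []
    if rule is FilterRule.LOWE_RATIO:
        n_single = 0
        for cand in candidates:
            if not cand:
                continue
            if len(cand) == 1:
                if single_neighbor is SingleNeighborPolicy.RAISE:
                    raise InsufficientNeighbors(
                        f"A index {cand[0].index_a} has a single neighbor under LOWE_RATIO"
                    )
                if single_neighbor is SingleNeighborPolicy.KEEP:
                    n_single += 1
                    good.append(cand[0])
                continue
            d1, d2 = cand[0].distance, cand[1].distance
            if d1 < ratio * d2 or d1 == d2 == 0.0:
                good.append(cand[0])
        if n_single:
            logger.info("kept %d single-neighbor candidates (no contesting neighbor)", n_single)
    elif rule is FilterRule.PAPER_LITERAL:
        if n_b is None:
            raise ValueError("PAPER_LITERAL requires n_b (descriptor count of image B)")
        bound = ratio * min(len(candidates), n_b)
        good = [m for m in _best_matches(candidates) if m.distance < bound]
    elif rule is FilterRule.MIN_DIST_SCALE:
        best = _best_matches(candidates)
        if best:
            d_min = min(m.distance for m in best)
            good = [m for m in best if m.distance <= ratio * d_min]
    else:  # pragma: no cover - exhaustive enum
        raise ValueError(f"unknown rule {rule}")
    return sorted(good, key=lambda m: (m.distance, m.index_a))


def cross_check(forward: list[Match], backward: list[Match]) -> list[Match]:
    """Mutual-best filter: keep forward matches whose B point maps back to A."""
    back_best = {m.index_a: m.index_b for m in backward}
    return [m for m in forward if back_best.get(m.index_b) == m.index_a]


def partition(n_a: int, n_b: int, good: list[Match],
              rule: FilterRule = FilterRule.LOWE_RATIO,
              threshold: float = 0.7) -> MatchResult:
    """Split both images' keypoints into matched and mismatched index sets.

    Matched sets are the endpoints of the good matches; mismatched sets are
    their complements, so counts are conserved on both sides.  Many-to-one B
    matches are allowed; ``matched_b`` counts distinct B endpoints.
    """
    a_idx = [m.index_a for m in good]
    if len(a_idx) != len(set(a_idx)):
        raise DuplicateQueryIndex("an A keypoint appears in more than one good match")
    for m in good:
        if not (0 <= m.index_a < n_a and 0 <= m.index_b < n_b):
            raise ValueError(f"match ({m.index_a},{m.index_b}) out of bounds")
    matched_a = frozenset(a_idx)
    matched_b = frozenset(m.index_b for m in good)
    return MatchResult(
        good=tuple(good),
        matched_a=matched_a,
        mismatched_a=frozenset(range(n_a)) - matched_a,
        matched_b=matched_b,
        mismatched_b=frozenset(range(n_b)) - matched_b,
        rule=rule,
        threshold=threshold,
    )


def match_pair(desc_a: DescriptorSet, desc_b: DescriptorSet,
               rule: FilterRule = FilterRule.LOWE_RATIO, ratio: float = 0.7,
               use_cross_check: bool = False,
               single_neighbor: SingleNeighborPolicy = SingleNeighborPolicy.KEEP,
               ) -> MatchResult:
    """KNN match, filter, (optionally cross-check) and partition in one call."""
    cands = knn_match(desc_a, desc_b, k=2)
    good = filter_good_matches(cands, rule=rule, ratio=ratio, n_b=desc_b.n,
                               single_neighbor=single_neighbor)
    if use_cross_check and good:
        back = filter_good_matches(knn_match(desc_b, desc_a, k=2), rule=rule,
                                   ratio=ratio, n_b=desc_a.n,
                                   single_neighbor=single_neighbor)
        good = cross_check(good, back)
    return partition(desc_a.n, desc_b.n, good, rule=rule, threshold=ratio)


def matches_to_csv(path, candidates: list[list[Match]], good: list[Match]) -> None:
    """Export best-neighbor matches as CSV (index_a, index_b, distance, kept)."""
    kept = {(m.index_a, m.index_b) for m in good}
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["index_a", "index_b", "distance", "kept"])
        for m in _best_matches(candidates):
            w.writerow([m.index_a, m.index_b, repr(m.distance),
                        int((m.index_a, m.index_b) in kept)])
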