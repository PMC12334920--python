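"""Per-pair feature extraction and labeled feature-table construction.

One pair of face images flows through: crop, landmark detection, per-kind
keypoint detection and description, brute-force matching with the good-match
filter, the matched/mismatched partition, region counting, the 16 ratio
features per descriptor kind, and fusion.  A pair manifest (CSV with columns
``pair_id,side_a,side_b,label``) maps to a rectangular feature table with one
row per processable pair; unprocessable pairs are skipped with a log record.
Runs are deterministic for fixed config and inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import pandas as pd

from .config import RunConfig
from .errors import BackendUnavailable, EmptyManifest, NoFaceFound, TwinmarkError
from .keypoints import read_bundle
from .landmark_regions import FaceLandmarks, canonical_regions, read_landmarks
from .matching import FilterRule, SingleNeighborPolicy, match_pair
from .ratio_features import compute_features, count_by_region, feature_names, fuse
from .synthetic import CohortBackend  # noqa: F401  (re-exported convenience)

logger = logging.getLogger(__name__)

BOOKKEEPING_COLUMNS = ("pair_id", "label")


@dataclass(frozen=True)
class PairRecord:
    pair_id: str
    side_a: str
    side_b: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 (same person) or 1 (identical twins)")


@dataclass
class FeatureTable:
    """Rectangular labeled feature table plus run metadata and skip log."""

    frame: pd.DataFrame
    config: RunConfig
    skipped: list = field(default_factory=list)

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in BOOKKEEPING_COLUMNS]

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.10g")
        sidecar = str(path) + ".run.json"
        with open(sidecar, "w") as fh:
            json.dump({
                "config": self.config.to_dict(),
                "config_hash": self.config.config_hash(),
                "skipped": self.skipped,
                "n_rows": int(len(self.frame)),
            }, fh, indent=2)


class PairBackend:
    """Contract the pipeline consumes: landmarks and keypoints per pair side."""

    def landmarks(self, pair_id: str, side: str) -> FaceLandmarks:  # pragma: no cover
        raise NotImplementedError

    def detect(self, pair_id: str, side: str, kind: str):  # pragma: no cover
        raise NotImplementedError


class BundleBackend(PairBackend):
    """Read precomputed landmark files and keypoint/descriptor bundles.

    The manifest's side references are interpreted as bundle paths; landmark
    files live next to them as ``<ref>.landmarks.json`` unless a shared
    template path is given.
    """

    def __init__(self, landmark_path: str | None = None) -> None:
        self.landmark_path = landmark_path
        self._cache: tuple | None = None

    def landmarks(self, pair_id: str, side_ref: str) -> FaceLandmarks:
        path = self.landmark_path or f"{side_ref}.landmarks.json"
        return read_landmarks(path)

    def detect(self, pair_id: str, side_ref: str, kind: str):
        if self._cache is None or self._cache[0] != side_ref:
            self._cache = (side_ref, read_bundle(side_ref))
        bundle = self._cache[1]
        if kind not in bundle:
            raise BackendUnavailable(f"bundle {side_ref} has no {kind} entry")
        return bundle[kind]


def process_pair(pair: PairRecord, config: RunConfig, backend: PairBackend,
                 regions=None) -> dict:
    """Extract one pair's fused feature row.

    Raises the underlying error (NoFaceFound, BackendUnavailable, ...) so the
    table builder can record the skip.
    """
    if regions is None:
        regions = canonical_regions(oval_as_printed=config.oval_as_printed)
    landmarks = backend.landmarks(pair.pair_id, pair.side_a)
    per_kind = []
    for kind in config.kinds:
        kps_a, desc_a = backend.detect(pair.pair_id, pair.side_a, kind)
        kps_b, desc_b = backend.detect(pair.pair_id, pair.side_b, kind)
        result = match_pair(
            desc_a, desc_b,
            rule=FilterRule(config.rule), ratio=config.ratio,
            use_cross_check=config.cross_check,
            single_neighbor=SingleNeighborPolicy(config.single_neighbor),
        )
        counts = count_by_region(result, kps_a, landmarks, regions,
                                 count_side=config.count_side, keypoints_b=kps_b)
        per_kind.append(compute_features(counts, schema=config.schema, kind=kind))
    fused = fuse(per_kind, order=config.kinds)
    row = {"pair_id": pair.pair_id, "label": pair.label}
    row.update(fused.values)
    return row


def read_manifest(path) -> list[PairRecord]:
    frame = pd.read_csv(path, dtype={"pair_id": str, "side_a": str, "side_b": str})
    if frame.empty:
        raise EmptyManifest(f"manifest {path} has no rows")
    return [
        PairRecord(pair_id=r.pair_id, side_a=r.side_a, side_b=r.side_b,
                   label=int(r.label))
        for r in frame.itertuples()
    ]


def build_table(manifest, config: RunConfig, backend: PairBackend) -> FeatureTable:
    """Build the labeled feature table for a manifest (path, DataFrame or list).

    Row order follows the manifest; pairs whose extraction fails are skipped
    and recorded.  Column order is frozen: pair_id, label, then the fused
    feature names in kind order.
    """
    if isinstance(manifest, pd.DataFrame):
        if manifest.empty:
            raise EmptyManifest("manifest has no rows")
        pairs = [PairRecord(pair_id=str(r.pair_id), side_a=str(r.side_a),
                            side_b=str(r.side_b), label=int(r.label))
                 for r in manifest.itertuples()]
    elif isinstance(manifest, (list, tuple)):
        if not manifest:
            raise EmptyManifest("manifest has no rows")
        pairs = list(manifest)
    else:
        pairs = read_manifest(manifest)
    rows, skipped = [], []
    for pair in pairs:
        try:
            rows.append(process_pair(pair, config, backend))
        except (NoFaceFound, BackendUnavailable, TwinmarkError) as exc:
            logger.warning("skipping pair %s: %s", pair.pair_id, exc)
            skipped.append({"pair_id": pair.pair_id, "error": type(exc).__name__,
                            "message": str(exc)})
    columns = list(BOOKKEEPING_COLUMNS)
    for kind in config.kinds:
        columns.extend(feature_names(kind, config.schema))
    frame = pd.DataFrame(rows, columns=columns)
    if skipped:
        logger.warning("skipped %d of %d pairs", len(skipped), len(pairs))
    return FeatureTable(frame=frame, config=config, skipped=skipped)
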