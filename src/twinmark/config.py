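"""Run configuration with validation and YAML round-trip.

Defaults reproduce the published settings where the source states them
(ratio-test threshold 0.7, 20% test split, all three descriptor kinds); the
remaining defaults are the package's documented choices.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace

import yaml

from .errors import ConfigInvalid
from .keypoints import KINDS

MODEL_KINDS = (
    "MAX_MARGIN_KERNEL",        # RBF-kernel support vector machine
    "GRADIENT_BOOSTED_TREES_A", # LightGBM
    "GRADIENT_BOOSTED_TREES_B", # XGBoost
    "NEAREST_CENTROID",
)

MODEL_ALIASES = {
    "svm": "MAX_MARGIN_KERNEL", "svc": "MAX_MARGIN_KERNEL",
    "lgbm": "GRADIENT_BOOSTED_TREES_A", "gbt_a": "GRADIENT_BOOSTED_TREES_A",
    "xgb": "GRADIENT_BOOSTED_TREES_B", "gbt_b": "GRADIENT_BOOSTED_TREES_B",
    "nc": "NEAREST_CENTROID",
}


@dataclass(frozen=True)
class RunConfig:
    kinds: tuple = ("SIFT", "SURF", "ORB")
    schema: str = "TABLE3"
    rule: str = "lowe"
    ratio: float = 0.7
    count_side: str = "A"
    test_fraction: float = 0.20
    stratified: bool = True
    model_kind: str = "MAX_MARGIN_KERNEL"
    seed: int = 0
    oval_as_printed: bool = False
    cross_check: bool = False
    single_neighbor: str = "keep"

    def __post_init__(self) -> None:
        object.__setattr__(self, "kinds", tuple(k.upper() for k in self.kinds))
        self.validate()

    def validate(self) -> None:
        if not self.kinds or any(k not in KINDS for k in self.kinds):
            raise ConfigInvalid(f"kinds must be a non-empty subset of {KINDS}")
        if len(set(self.kinds)) != len(self.kinds):
            raise ConfigInvalid("duplicate descriptor kinds")
        if self.schema not in ("TABLE3", "EQUATIONS"):
            raise ConfigInvalid(f"unknown schema {self.schema!r}")
        if self.rule not in ("lowe", "paper_literal", "min_dist_scale"):
            raise ConfigInvalid(f"unknown matcher rule {self.rule!r}")
        if self.rule == "lowe" and not 0 < self.ratio <= 1:
            raise ConfigInvalid(f"lowe ratio must be in (0, 1], got {self.ratio}")
        if self.ratio <= 0:
            raise ConfigInvalid("ratio/scale must be positive")
        if self.count_side.upper() not in ("A", "B", "MEAN"):
            raise ConfigInvalid(f"count_side must be A, B or MEAN, not {self.count_side!r}")
        if not 0 < self.test_fraction < 1:
            raise ConfigInvalid("test_fraction must be in (0, 1)")
        if self.model_kind not in MODEL_KINDS:
            raise ConfigInvalid(f"model_kind must be one of {MODEL_KINDS}")
        if self.single_neighbor not in ("keep", "drop", "raise"):
            raise ConfigInvalid(f"unknown single_neighbor policy {self.single_neighbor!r}")

    def with_overrides(self, **kw) -> "RunConfig":
        if "model_kind" in kw and kw["model_kind"] in MODEL_ALIASES:
            kw["model_kind"] = MODEL_ALIASES[kw["model_kind"]]
        return replace(self, **kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["kinds"] = list(self.kinds)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigInvalid(f"config file {path} must contain a mapping")
    data.pop("_comment", None)
    try:
        return RunConfig(**data)
    except TypeError as exc:
        raise ConfigInvalid(str(exc)) from exc


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
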