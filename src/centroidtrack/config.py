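"""Run configuration: one structured object covering every tunable knob,
loadable from YAML, hashable for provenance logging.

Per-stage seeds are derived from the master seed with a stable scheme
(numpy SeedSequence over ``[master, stage-code, indices...]``), so any
stage of a run can be reproduced in isolation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .mesh import ComparabilityPolicy
from .registration import ICPConfig
from .simulate import DegradationConfig, Envelope, StudyConfig


@dataclass
class RunConfig:
    """Everything a full validation run needs, with working defaults."""

    seed: int = 0
    study: StudyConfig = field(default_factory=StudyConfig)
    comparability: ComparabilityPolicy = field(
        default_factory=ComparabilityPolicy.strict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "study": self.study.to_dict(),
            "comparability": {
                "face_count_ratio_bounds":
                    list(self.comparability.face_count_ratio_bounds),
                "area_ratio_bounds":
                    list(self.comparability.area_ratio_bounds),
                "max_bbox_extent_diff_mm":
                    self.comparability.max_bbox_extent_diff_mm,
                "max_edge_length_cv": self.comparability.max_edge_length_cv,
            },
        }

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        study_raw = dict(payload.get("study", {}))
        kwargs = {}
        if "envelope" in study_raw:
            env = study_raw.pop("envelope")
            study_raw["envelope"] = Envelope(
                x=tuple(env.get("x", (-15.0, 15.0))),
                y=tuple(env.get("y", (-15.0, 15.0))),
                z=tuple(env.get("z", (-5.0, 5.0))))
        for key in ("accurate_degradation", "reference_degradation"):
            if key in study_raw:
                study_raw[key] = DegradationConfig(**study_raw[key])
        if "icp" in study_raw:
            study_raw["icp"] = ICPConfig(**study_raw["icp"])
        if "rois" in study_raw:
            study_raw["rois"] = tuple(study_raw["rois"])
        kwargs["study"] = StudyConfig(**study_raw)
        comp_raw = payload.get("comparability")
        if comp_raw:
            comp = ComparabilityPolicy(
                face_count_ratio_bounds=tuple(
                    comp_raw.get("face_count_ratio_bounds", (0.9, 1.1))),
                area_ratio_bounds=tuple(
                    comp_raw.get("area_ratio_bounds", (0.9, 1.1))),
                max_bbox_extent_diff_mm=comp_raw.get(
                    "max_bbox_extent_diff_mm", 2.0),
                max_edge_length_cv=comp_raw.get("max_edge_length_cv", 0.6))
            kwargs["comparability"] = comp
        return cls(seed=int(payload.get("seed", 0)), **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(payload)

    def dump_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)
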