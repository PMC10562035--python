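"""Model settings: the single JSON-serializable configuration controlling
postprocessing, mimicking, scenarios, evaluation goals and the engine.

These settings deliberately do not configure the network's hyperparameters
for an already-trained checkpoint (those travel in the checkpoint sidecar);
they control what happens *around* a trained model, and are meant to be
hand-edited by the user between runs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from pydantic import BaseModel, Field, field_validator

from .dose_engine import BeamModel, EngineConfig
from .evaluate import ClinicalGoal
from .mimic import MimicConfig
from .postprocess import DvhRule

__all__ = ["ModelSettings", "default_settings"]


class PostprocessRule(BaseModel):
    roi: str
    kind: str
    dose_gy: float | None = None
    dose_rx_fraction: float | None = None
    volume_fraction: float = 1.0


class MimicSettings(BaseModel):
    # plan-stage weights, calibrated for tracking a predicted reference dose
    # (reference-dose *generation* keeps the MimicConfig defaults)
    roi_weights: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: {
            "PTV chest wall": (30.0, 100.0),
            "PTV nodes": (30.0, 100.0),
            "lungs": (8.0, 1.0),
            "heart": (8.0, 1.0),
            "esophagus": (8.0, 1.0),
        }
    )
    default_weights: tuple[float, float] = (2.0, 0.2)
    robust_rois: list[str] = Field(default_factory=lambda: ["PTV chest wall", "PTV nodes"])
    iterations: int = 200
    tolerance: float = 0.0


class ScenarioSettings(BaseModel):
    setup_mm: float = 5.0
    range_pct: float = 3.0


class GoalSettings(BaseModel):
    roi: str
    metric: str
    parameter: float
    threshold: float
    comparator: str


class EngineSettings(BaseModel):
    sigma_mm: float = 6.0
    sigma_growth: float = 0.02
    bragg_sigma_mm: float = 6.0
    plateau: float = 0.35
    sparsity_cutoff: float = 1e-4
    margin_mm: float = 12.0
    lateral_spacing_mm: float = 7.5
    layer_spacing_mm: float = 7.5


class TrainSettings(BaseModel):
    epochs: int = 30
    learning_rate: float = 1e-3
    level_channels: list[int] = Field(default_factory=lambda: [8, 16, 32])
    split: tuple[int, int] = (45, 3)  # train / validation counts (clinical default)


class ModelSettings(BaseModel):
    """Top-level settings document; round-trips losslessly through JSON."""

    rx_gy: float = 50.4
    fractions: int = 28  # metadata only; no per-fraction modeling
    roi_channel_map: dict[str, list[str]] = Field(
        default_factory=lambda: {
            "targets": ["PTV chest wall", "PTV nodes"],
            "lungs": ["lungs"],
            "heart_esophagus": ["heart", "esophagus"],
            "external": ["External"],
        }
    )
    dose_postprocessing: list[PostprocessRule] = Field(
        default_factory=lambda: [
            PostprocessRule(roi="esophagus", kind="max_dose_clamp", dose_gy=35.0),
            PostprocessRule(
                roi="PTV chest wall", kind="min_coverage",
                dose_rx_fraction=0.98, volume_fraction=1.0,
            ),
        ]
    )
    dose_mimicking: MimicSettings = Field(default_factory=MimicSettings)
    scenarios: ScenarioSettings = Field(default_factory=ScenarioSettings)
    goals: list[GoalSettings] = Field(
        default_factory=lambda: [
            GoalSettings(roi="PTV nodes", metric="V_pct_rx", parameter=95, threshold=95, comparator=">="),
            GoalSettings(roi="PTV chest wall", metric="V_pct_rx", parameter=95, threshold=95, comparator=">="),
            GoalSettings(roi="esophagus", metric="D_hotspot", parameter=0.03, threshold=40, comparator="<="),
            GoalSettings(roi="heart", metric="D_mean", parameter=1, threshold=1.25, comparator="<="),
            GoalSettings(roi="lungs", metric="V_abs", parameter=20, threshold=20, comparator="<="),
            GoalSettings(roi="lungs", metric="D_mean", parameter=1, threshold=10, comparator="<="),
            GoalSettings(roi="lungs", metric="V_abs", parameter=5, threshold=25, comparator="<="),
        ]
    )
    engine: EngineSettings = Field(default_factory=EngineSettings)
    train: TrainSettings = Field(default_factory=TrainSettings)
    seed: int = 0

    @field_validator("rx_gy")
    @classmethod
    def _rx_positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("rx_gy must be > 0")
        return v

    # -- conversions to runtime objects -----------------------------------
    def dvh_rules(self) -> list[DvhRule]:
        return [DvhRule(**r.model_dump()) for r in self.dose_postprocessing]

    def mimic_config(self) -> MimicConfig:
        m = self.dose_mimicking
        return MimicConfig(
            roi_weights={k: tuple(v) for k, v in m.roi_weights.items()},
            default_weights=tuple(m.default_weights),
            robust_rois=list(m.robust_rois),
            iterations=m.iterations,
            tolerance=m.tolerance,
        )

    def clinical_goals(self) -> list[ClinicalGoal]:
        return [ClinicalGoal(g.roi, g.metric, g.parameter, g.threshold, g.comparator) for g in self.goals]

    def engine_config(self) -> EngineConfig:
        e = self.engine
        return EngineConfig(
            beam_model=BeamModel(e.sigma_mm, e.sigma_growth, e.bragg_sigma_mm, e.plateau),
            sparsity_cutoff=e.sparsity_cutoff,
        )

    # -- persistence -------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.model_dump(mode="json"), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ModelSettings":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.model_validate(json.loads(text))

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def default_settings() -> ModelSettings:
    return ModelSettings()
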