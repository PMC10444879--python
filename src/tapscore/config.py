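"""Run configuration: every threshold and mode flag in one validated object.

Unknown keys are rejected outright — a silently ignored typo in a threshold
name would corrupt the science.  All stochastic components consume the
single ``seed``.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class RunConfig(BaseModel):
    """Pipeline-wide configuration with the published default thresholds."""

    model_config = ConfigDict(extra="forbid")

    seed: int

    # hand selection / signal cleaning
    handedness_threshold: float = Field(0.9, gt=0)
    presence_threshold: float = Field(0.90, gt=0)
    interpolation_window: int = Field(5, ge=1)
    interpolation_degree: int = Field(3, ge=1)
    min_gap_s: float = Field(0.1, gt=0)
    amplitude_floor_quantile: float = Field(0.25, ge=0, le=1)
    trough_iqr_fraction: float = Field(0.2, ge=0)

    # hesitation thresholds
    speed_threshold_deg_s: float = Field(50.0, gt=0)
    interruption_min_dur_s: float = Field(0.010, gt=0)
    freeze_min_dur_s: float = Field(0.020, gt=0)

    # features / screening / model
    entropy_bins: int = Field(10, ge=2)
    redundancy_r_threshold: float = Field(0.85, gt=0, le=1)
    significance_alpha: float = Field(0.01, gt=0, lt=1)
    n_selected_features: int = Field(22, ge=1)
    rfe_step: int = Field(2, ge=1)
    scaling: str = "standard"
    regressor: str = "lightgbm"
    paper_mode: bool = False
    use_smote: bool = False  # minority oversampling stub; kept off (degrades performance)

    # rater analysis
    icc_variant: str = "ICC2"
    krippendorff_level: str = "ordinal"

    @field_validator("use_smote")
    @classmethod
    def _no_smote(cls, v: bool) -> bool:
        if v:
            raise ValueError(
                "minority oversampling is deliberately not implemented; "
                "it degraded severity regression in evaluation"
            )
        return v

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a flat-key YAML config; keyword overrides win."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)
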