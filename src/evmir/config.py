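"""Pipeline configuration (pydantic schema).

Every default is printed into the run manifest — there are no hidden
defaults.  The defaults are the study conditions: haemolysis threshold 7
cycles with Tukey k = 1.5, four-SD outlier rule with 50% sample
invalidation, pairwise-variation threshold 0.15, classifier splits
80%/79% with seeds 375/101.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, Field, field_validator

from .panel import REFERENCE_TARGETS


class QCSettings(BaseModel):
    haemolysis_threshold: float = 7.0
    iqr_k: float = 1.5
    spikein_sd_mult: float = 2.0
    low_signal_max_cq: float = 35.0
    exclude_flagged: bool = False


class OutlierSettings(BaseModel):
    sd_mult: float = 4.0
    invalid_frac: float = Field(default=0.5, ge=0.0, le=1.0)


class SyntheticSettings(BaseModel):
    """Overrides for the synthetic cohort design; None = design default."""

    enabled: bool = True
    seed: int = 375
    cohort_sizes: Optional[dict[str, int]] = None
    sigma_sample: Optional[float] = None
    sigma_noise: Optional[float] = None
    corrupt: bool = True


class DesignSettings(BaseModel):
    logistic_fraction: float = Field(default=0.8, gt=0.0, lt=1.0)
    forest_fraction: float = Field(default=0.79, gt=0.0, lt=1.0)
    split_seed: int = 375
    cross_cohort_seed: int = 101
    n_trees: int = 500
    iterative_removal: bool = True


class PipelineConfig(BaseModel):
    plates: list[Path] = Field(default_factory=list)
    metadata: Optional[Path] = None
    synthetic: SyntheticSettings = SyntheticSettings()
    qc: QCSettings = QCSettings()
    calibration_mode: Literal["grand_mean", "reference_plate"] = "grand_mean"
    reference_plate: Optional[str] = None
    references: list[str] = Field(default_factory=lambda: list(REFERENCE_TARGETS))
    control_cohort: str = "HC"
    outliers: OutlierSettings = OutlierSettings()
    v_threshold: float = 0.15
    gate_posthoc: bool = True
    alpha: float = 0.05
    run_classifiers: bool = True
    designs: DesignSettings = DesignSettings()
    outdir: Path = Path("evmir_out")

    @field_validator("references")
    @classmethod
    def _nonempty_refs(cls, v: list[str]) -> list[str]:
        if not v:
            raise ValueError("at least one reference target is required")
        return v

    def input_mode(self) -> str:
        if self.plates and self.metadata:
            return "files"
        if self.synthetic.enabled:
            return "synthetic"
        raise ValueError("config needs either plate/metadata paths or synthetic.enabled")
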