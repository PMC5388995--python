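"""Analysis configuration: validated settings with base-case defaults.

Every model input — retention anchors, transition probabilities,
utilities, costing settings, discounting, sensitivity ranges — lives in
one `AnalysisConfig`, validated by pydantic before any computation.  The
defaults encode the 2011 Zambian base case (hospital-only versus
hospital + mobile ART); a YAML file can override any subset of fields.
The effective (merged) configuration can be re-emitted with
``to_yaml`` and re-loaded to reproduce a run exactly.
"""

from __future__ import annotations

import hashlib
from datetime import date
from importlib import resources
from typing import Literal

import yaml
from pydantic import BaseModel, Field, field_validator

__all__ = ["AnalysisConfig", "default_config", "load_config"]


class CostingConfig(BaseModel):
    zmk_per_usd: float = 5000.0
    annualization_rate: float = 0.03
    useful_life_years: dict[str, float] = Field(
        default_factory=lambda: {"building": 30.0, "furniture": 10.0, "vehicle": 5.0}
    )
    n_rural_centres: int = 5
    cost_table: str | None = None  # path; None -> packaged table


class RetentionConfig(BaseModel):
    interpolation: Literal["linear", "constant_hazard"] = "linear"
    # (years, retained fraction); anchors beyond 3 years are long-term
    # programme assumptions, not cohort observations
    original_anchors: list[tuple[float, float]] = Field(
        default_factory=lambda: [
            (1, 0.886), (2, 0.810), (3, 0.720),
            (10, 0.650), (20, 0.600), (30, 0.550), (40, 0.500),
        ]
    )
    intervention_anchors: list[tuple[float, float]] = Field(
        default_factory=lambda: [
            (1, 0.926), (2, 0.841), (3, 0.790),
            (10, 0.700), (20, 0.650), (30, 0.600), (40, 0.550),
        ]
    )


class ModelConfig(BaseModel):
    horizon: int = 40
    start_age: float = 30.0
    discount_rate: float = 0.03
    half_cycle_correction: Literal["initial_half_cycle", "trapezoidal", "none"] = (
        "initial_half_cycle"
    )
    event_ordering: Literal["death_first", "dropout_first", "independent"] = (
        "independent"
    )
    cost_accrual: Literal["retained_only", "all_alive"] = "retained_only"
    mortality_retained: float = 0.094
    mortality_not_retained: float = 0.375
    utility_retained: float = 0.82
    utility_not_retained: float = 0.53

    @field_validator(
        "mortality_retained", "mortality_not_retained",
        "utility_retained", "utility_not_retained",
    )
    @classmethod
    def _unit_interval(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("must lie in [0, 1]")
        return v


class CEAConfig(BaseModel):
    gdp_per_capita: float = 1408.0
    wtp_multiplier: int = 3


class ParamRangeConfig(BaseModel):
    low: float
    high: float


class ScenarioConfig(BaseModel):
    original_reduction: float
    intervention_reduction: float


class PSAConfig(BaseModel):
    n_iterations: int = 10_000
    seed: int = 20_110_412


class WTPGridConfig(BaseModel):
    start: float = 0.0
    stop: float = 6000.0
    step: float = 100.0


class SensitivityConfig(BaseModel):
    # one-way ranges; costs are the halved/doubled per-patient annual costs
    ranges: dict[str, ParamRangeConfig] = Field(
        default_factory=lambda: {
            "mortality_retained": ParamRangeConfig(low=0.04, high=0.17),
            "utility_retained": ParamRangeConfig(low=0.62, high=0.98),
            "start_age": ParamRangeConfig(low=20, high=50),
            "mortality_not_retained": ParamRangeConfig(low=0.27, high=0.51),
            "discount_rate": ParamRangeConfig(low=0.0, high=0.15),
            "cost_original": ParamRangeConfig(low=123.23, high=492.90),
            "cost_intervention": ParamRangeConfig(low=125.10, high=500.26),
        }
    )
    scenarios: dict[str, ScenarioConfig] = Field(
        default_factory=lambda: {
            "best": ScenarioConfig(original_reduction=0.10, intervention_reduction=0.03),
            "worst": ScenarioConfig(original_reduction=0.03, intervention_reduction=0.10),
        }
    )
    psa: PSAConfig = PSAConfig()
    wtp_grid: WTPGridConfig = WTPGridConfig()


class SyntheticConfig(BaseModel):
    n_patients: int = 32_428
    enrol_start: date = date(2010, 1, 1)
    enrol_end: date = date(2011, 12, 31)
    censor_date: date = date(2012, 12, 31)
    age_median: float = 33.0
    age_sd: float = 10.0
    visit_interval_months: int = 1
    ltfu_gap_months: int = 3


class AnalysisConfig(BaseModel):
    seed: int = 20_110_412
    costing: CostingConfig = CostingConfig()
    retention: RetentionConfig = RetentionConfig()
    model: ModelConfig = ModelConfig()
    cea: CEAConfig = CEAConfig()
    sensitivity: SensitivityConfig = SensitivityConfig()
    synthetic: SyntheticConfig = SyntheticConfig()

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            yaml.safe_load(self.model_dump_json()), sort_keys=True
        )

    def config_hash(self) -> str:
        """Short stable digest of the effective configuration."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def default_config() -> AnalysisConfig:
    """The packaged base-case configuration."""
    path = resources.files("artcea.data").joinpath("paper_basecase.yaml")
    with path.open() as fh:
        return AnalysisConfig.model_validate(yaml.safe_load(fh) or {})


def load_config(path: str | None = None) -> AnalysisConfig:
    """Load a YAML config; missing fields fall back to base-case defaults."""
    if path is None:
        return default_config()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return AnalysisConfig.model_validate(data)
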