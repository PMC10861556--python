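"""YAML scenario configuration with schema validation (pydantic models)."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError as PydanticValidationError

from .errors import ConfigError


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PanelConfig(_Strict):
    n_snps: int = Field(100, gt=0)
    maf_low: float = Field(0.05, gt=0, lt=0.5)
    maf_high: float = Field(0.45, gt=0, lt=0.5)
    class_mix: dict[str, float] | None = None
    effect_scale: float = Field(1.0, ge=0)


class CohortConfig(_Strict):
    n_families: int = Field(2000, gt=0)
    n_children: int = Field(1, ge=1, le=2)
    parent_pgs_corr: float = Field(0.0, gt=-1, lt=1)


class BirthweightConfig(_Strict):
    h2_maternal: float = Field(0.02, ge=0, lt=1)
    h2_fetal: float = Field(0.05, ge=0, lt=1)
    mean_g: float = 3500.0
    sd_g: float = Field(500.0, gt=0)


class DiseaseConfig(_Strict):
    beta_maternal: float = 0.0
    beta_child: float = 0.0
    prevalence: float = Field(0.1, gt=0, lt=1)
    mediation: str = Field("direct_pgs", pattern="^(direct_pgs|via_birthweight)$")
    endpoint: str = "disease"
    score: str = "M-SPECIFIC"


class ScoreConfig(_Strict):
    scores: list[str] | str = "all"
    standardize: str | None = Field("whole_cohort", pattern="^(whole_cohort|within_role)$")


class AssocConfig(_Strict):
    pairs: str = Field("mother", pattern="^(mother|father)$")
    score: str = "M-SPECIFIC"
    outcome: str = "disease"
    filter: str | None = Field(None, pattern="^(one_child_per_mother|max_4th_degree)$")
    use_covariates: bool = True
    n_boot: int = Field(0, ge=0)


class SiblingConfig(_Strict):
    enabled: bool = False
    score: str = "M-SPECIFIC"
    outcome: str = "disease"


class PowerConfig(_Strict):
    enabled: bool = False
    n_pairs: int = Field(36211, ge=100)
    prevalence: float = Field(0.0275, gt=0, lt=1)
    or_mother: float = Field(1.0, gt=0)
    or_child: float = Field(1.0, gt=0)
    reps: int = Field(1000, ge=100)
    alpha: float = Field(0.05, gt=0, lt=1)


class RunConfig(_Strict):
    """Full pipeline scenario (all sections optional with defaults)."""

    panel: PanelConfig = PanelConfig()
    cohort: CohortConfig = CohortConfig()
    birthweight: BirthweightConfig = BirthweightConfig()
    disease: DiseaseConfig = DiseaseConfig()
    score: ScoreConfig = ScoreConfig()
    assoc: AssocConfig = AssocConfig()
    sibling: SiblingConfig = SiblingConfig()
    power: PowerConfig = PowerConfig()


def load_config(path: str | Path) -> RunConfig:
    """Parse + validate a YAML scenario; errors name the offending key path."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return RunConfig.model_validate(raw)
    except PydanticValidationError as exc:
        msgs = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        )
        raise ConfigError(f"invalid configuration ({path}): {msgs}") from exc
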