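"""Configuration models for the simulator and the pipeline.

All tunables live here so that every run can be reproduced from a YAML file
plus a seed.  Defaults describe the study conditions the package emulates:
~300 mature beef cows in 14 mobs across 4 farms and 2 sampling years, tracked
at a 5-minute fix cadence for 7-28 days on rugged hill-country terrain, with
the six GRM5 genotypes at their observed herd frequencies.
"""

from __future__ import annotations

import hashlib
from typing import Literal

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

GENOTYPES = ("AA", "AB", "AC", "BB", "BC", "CC")
AGE_CLASSES = (1, 2, 3)

#: observed herd genotype counts (n = 306) used as default sampling weights
DEFAULT_GENOTYPE_COUNTS = {"AA": 3, "AB": 18, "AC": 31, "BB": 38, "BC": 109, "CC": 107}


class TerrainConfig(BaseModel):
    """Synthetic DEM: spectrally filtered Gaussian noise."""

    n_rows: int = 160
    n_cols: int = 160
    cell: float = 16.0          # m, matching a 16 m satellite DEM
    relief: float = 300.0       # m, max - min elevation
    smoothness: float = 8.0     # correlation length in cells

    @model_validator(mode="after")
    def _check(self):
        if self.n_rows < 16 or self.n_cols < 16:
            raise ValueError("terrain grid must be at least 16x16")
        if self.cell <= 0:
            raise ValueError("cell size must be positive")
        if self.relief < 0 or self.smoothness <= 0:
            raise ValueError("relief must be >= 0 and smoothness > 0")
        return self


class MovementParams(BaseModel):
    """Per-cow correlated-random-walk parameters.

    step_scale:
        mean 5-min step length, m (12 m/step ~ 3.5 km/d at full cadence).
    turn_concentration:
        inverse variance of the wrapped-normal turning angle; higher = straighter.
    attraction:
        pull toward the cow's home point per step; higher = smaller home range.
    elevation_pref:
        uphill drift as a fraction of step length (0 = none).
    """

    step_scale: float = 12.5
    turn_concentration: float = 2.0
    attraction: float = 0.004
    elevation_pref: float = 0.15

    @model_validator(mode="after")
    def _check(self):
        if self.step_scale <= 0 or self.turn_concentration <= 0:
            raise ValueError("step_scale and turn_concentration must be positive")
        if self.attraction < 0:
            raise ValueError("attraction must be >= 0")
        return self


class EffectConfig(BaseModel):
    """Genotype- and age-dependent multipliers applied to the base movement.

    Multipliers act on the log scale of attraction and turn concentration:
    carrying allele A lowers attraction (larger home range) and raises turn
    concentration (straighter paths); allele B does the opposite.  Age class 1
    (youngest) gets lower attraction, reproducing larger home ranges in young
    cows.  The default dial gives roughly a 20% spread in expected daily home
    range between the extreme genotypes.
    """

    attraction_mult_A: float = 0.78
    attraction_mult_B: float = 1.18
    turn_conc_mult_A: float = 1.30
    turn_conc_mult_B: float = 0.85
    age_attraction_mult: dict[int, float] = Field(
        default_factory=lambda: {1: 0.78, 2: 1.0, 3: 1.12}
    )


class SimulationConfig(BaseModel):
    seed: int = 0
    n_farms: int = 4
    n_years: int = 2
    n_mobs: int = 14
    cows_per_mob: int = 22
    days: int = 14
    fix_interval: int = 300     # s
    dropout_rate: float = 0.05
    bursty_dropout: bool = False
    outlier_rate: float = 0.0   # injected teleport fixes, off by default
    outlier_speed_factor: float = 2.0  # injected speed >= factor * speed_max
    genotype_mode: Literal["multinomial", "expected"] = "multinomial"
    genotype_freqs: dict[str, float] = Field(
        default_factory=lambda: {g: c / 306 for g, c in DEFAULT_GENOTYPE_COUNTS.items()}
    )
    age_class_freqs: dict[int, float] = Field(
        default_factory=lambda: {1: 0.30, 2: 0.35, 3: 0.35}
    )
    terrain: TerrainConfig = Field(default_factory=TerrainConfig)
    movement: MovementParams = Field(default_factory=MovementParams)
    effects: EffectConfig = Field(default_factory=EffectConfig)
    start: str = "2020-06-01T00:00:00Z"
    home_scatter: float = 120.0  # m, spread of home points within a mob

    @field_validator("genotype_freqs")
    @classmethod
    def _geno_freqs(cls, v):
        unknown = set(v) - set(GENOTYPES)
        if unknown:
            raise ValueError(f"unknown genotypes in genotype_freqs: {sorted(unknown)}")
        if abs(sum(v.values()) - 1.0) > 1e-9:
            raise ValueError("genotype_freqs must sum to 1")
        return v

    @field_validator("age_class_freqs")
    @classmethod
    def _age_freqs(cls, v):
        if set(v) - set(AGE_CLASSES):
            raise ValueError("age_class_freqs keys must be 1, 2, 3")
        if abs(sum(v.values()) - 1.0) > 1e-9:
            raise ValueError("age_class_freqs must sum to 1")
        return v

    @model_validator(mode="after")
    def _check(self):
        if self.days < 7:
            raise ValueError("days must be >= 7 (a week is the minimum window)")
        if self.days > 28:
            raise ValueError("days must be <= 28 (the analysis window cap)")
        if 86400 % self.fix_interval != 0:
            raise ValueError("fix_interval must divide 86400")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.n_mobs < self.n_farms * self.n_years:
            # mobs are spread over farm x year cells; each cell needs one
            raise ValueError("n_mobs must be >= n_farms * n_years")
        return self


class Thresholds(BaseModel):
    """Filtering thresholds of the behaviour pipeline."""

    fix_interval: int = 300
    day_rate_min: float = 0.75      # min fraction of expected daily fixes
    min_days: int = 7
    max_days: int = 28
    slope_gate_deg: float = 8.0     # herd median daily slope gate
    rare_genotype_freq: float = 0.05
    speed_max: float = 2.5          # m/s
    spike_speed: float = 1.5        # m/s
    turn_min_deg: float = 150.0
    timezone: str = "UTC"           # civil day boundary


class ModelOptions(BaseModel):
    glmm_mode: Literal["pql", "logit-lmm"] = "pql"
    alpha: float = 0.05
    quantile_rule: str = "linear"   # numpy linear-interpolation quantile


class PipelineConfig(BaseModel):
    fixes_path: str | None = None
    dem_path: str | None = None
    metadata_path: str | None = None
    outdir: str = "grazekit_out"
    seed: int = 0
    thresholds: Thresholds = Field(default_factory=Thresholds)
    model: ModelOptions = Field(default_factory=ModelOptions)
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
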