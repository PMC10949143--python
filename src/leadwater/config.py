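"""Configuration objects for every pipeline stage.

All configs are plain dataclasses that round-trip losslessly through YAML
(`PipelineConfig.to_yaml` / `from_yaml`).  Validation raises
:class:`ConfigError` naming the offending field; nothing is silently
clamped or defaulted at validation time.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from typing import Any

import yaml

RACE_GROUPS = ("Asian", "Black", "Hispanic", "White")


class ConfigError(ValueError):
    """Raised when a configuration value is invalid; message names the field."""


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigError(f"{name} must be in [0, 1], got {value!r}")


def _check_pos(name: str, value: float) -> None:
    if not value > 0:
        raise ConfigError(f"{name} must be > 0, got {value!r}")


@dataclass
class HierarchyConfig:
    """Branching factors of the nested geography.

    Blocks nest in block groups, block groups in tracts, tracts in
    community areas; identifiers are synthesized labels, not coordinates.
    """

    blocks_per_block_group: int = 4
    block_groups_per_tract: int = 3
    tracts_per_community_area: int = 8

    def validate(self) -> None:
        for name in ("blocks_per_block_group", "block_groups_per_tract",
                     "tracts_per_community_area"):
            if getattr(self, name) < 1:
                raise ConfigError(f"hierarchy.{name} must be >= 1")


@dataclass
class ContaminationConfig:
    """Logistic model for the latent probability that a block's water is
    lead contaminated.

    logit(p) = intercept + b_minority * (Black + Hispanic proportion)
             + sum_g b_race[g] * proportion_g
             + b_building_age * z(age) + b_log_population * z(log pop)
             + b_buildings * z(buildings) + community-area effect

    ``b_race`` (default all zero) allows single-group dependence, e.g. for
    parameter-recovery experiments.  The community-area random effect
    (sd ``sigma_community``) makes geography itself predictive, mirroring
    cities where contamination clusters by neighbourhood infrastructure
    vintage.
    """

    intercept: float = 0.9
    b_minority: float = 1.2
    b_race: dict[str, float] = field(default_factory=dict)
    b_building_age: float = 0.5
    b_log_population: float = -0.4
    b_buildings: float = 0.3
    sigma_community: float = 1.5

    def validate(self) -> None:
        if self.sigma_community < 0:
            raise ConfigError("contamination.sigma_community must be >= 0")
        for key in self.b_race:
            if key not in RACE_GROUPS:
                raise ConfigError(f"contamination.b_race has unknown group {key!r}")


@dataclass
class ScreeningConfig:
    """Selection into voluntary testing: logit(propensity) =
    intercept + b_white * (White proportion)."""

    intercept: float = -1.5
    b_white: float = 2.2

    def validate(self) -> None:  # no hard constraints; slopes may take any sign
        pass


@dataclass
class ConcentrationConfig:
    """Two-component log-normal mixture for per-draw lead concentration.

    Medians are in ppb for (first draw, 2-min flush, 5-min flush); the
    2-min flush is configured highest, matching the observed ordering of
    draw medians.  Values below ``detection_limit_ppb`` are reported as 0
    with a below-detection flag.
    """

    contaminated_median_ppb: tuple[float, float, float] = (3.4, 4.2, 2.0)
    contaminated_sigma: float = 1.0
    clean_median_ppb: tuple[float, float, float] = (0.30, 0.35, 0.20)
    clean_sigma: float = 0.8
    detection_limit_ppb: float = 1.0

    def validate(self) -> None:
        for name in ("contaminated_median_ppb", "clean_median_ppb"):
            medians = getattr(self, name)
            if len(medians) != 3 or any(m <= 0 for m in medians):
                raise ConfigError(f"concentrations.{name} must be 3 positive ppb values")
        _check_pos("concentrations.contaminated_sigma", self.contaminated_sigma)
        _check_pos("concentrations.clean_sigma", self.clean_sigma)
        _check_pos("concentrations.detection_limit_ppb", self.detection_limit_ppb)


@dataclass
class SurveyConfig:
    """Primary drinking-water source proportions by race group.

    Defaults put unfiltered-tap use near the reported citywide weighted
    percentages (overall ~20%; Black 14%, Hispanic 12%, White 32%).  The
    non-unfiltered remainder is split between filtered tap, bottled and
    other by the ``*_share`` fractions (which must sum to 1).
    """

    p_unfiltered_by_race: dict[str, float] = field(
        default_factory=lambda: {"Asian": 0.18, "Black": 0.14,
                                 "Hispanic": 0.12, "White": 0.32})
    filtered_share: float = 0.45
    bottled_share: float = 0.45
    other_share: float = 0.10
    area_noise_concentration: float = 300.0

    def validate(self) -> None:
        for race in RACE_GROUPS:
            if race not in self.p_unfiltered_by_race:
                raise ConfigError(f"survey.p_unfiltered_by_race missing group {race!r}")
            _check_prob(f"survey.p_unfiltered_by_race[{race!r}]",
                        self.p_unfiltered_by_race[race])
        total = self.filtered_share + self.bottled_share + self.other_share
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(
                f"survey filtered_share+bottled_share+other_share must sum to 1, got {total}")
        _check_pos("survey.area_noise_concentration", self.area_noise_concentration)


@dataclass
class GeneratorConfig:
    """Full synthetic-city generator settings."""

    hierarchy: HierarchyConfig = field(default_factory=HierarchyConfig)
    population_median: float = 58.0
    population_sigma: float = 0.75
    race_city_proportions: dict[str, float] = field(
        default_factory=lambda: {"Asian": 0.07, "Black": 0.29,
                                 "Hispanic": 0.30, "White": 0.34})
    race_concentration_area: float = 2.0
    race_concentration_block: float = 30.0
    other_race_share: float = 0.03
    frac_under5: float = 0.055
    frac_age5to9: float = 0.055
    buildings_mean: float = 16.0
    building_age_mean: float = 97.0
    building_age_sd: float = 15.0
    mean_tests_per_block: float = 3.2
    contamination: ContaminationConfig = field(default_factory=ContaminationConfig)
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    concentrations: ConcentrationConfig = field(default_factory=ConcentrationConfig)
    survey: SurveyConfig = field(default_factory=SurveyConfig)

    def validate(self) -> None:
        self.hierarchy.validate()
        _check_pos("generator.population_median", self.population_median)
        _check_pos("generator.population_sigma", self.population_sigma)
        for race in RACE_GROUPS:
            if race not in self.race_city_proportions:
                raise ConfigError(f"generator.race_city_proportions missing group {race!r}")
            _check_prob(f"generator.race_city_proportions[{race!r}]",
                        self.race_city_proportions[race])
        total = sum(self.race_city_proportions.values())
        if total <= 0:
            raise ConfigError("generator.race_city_proportions must have positive mass")
        _check_pos("generator.race_concentration_area", self.race_concentration_area)
        _check_pos("generator.race_concentration_block", self.race_concentration_block)
        _check_prob("generator.other_race_share", self.other_race_share)
        _check_prob("generator.frac_under5", self.frac_under5)
        _check_prob("generator.frac_age5to9", self.frac_age5to9)
        if self.frac_under5 + self.frac_age5to9 > 1.0:
            raise ConfigError("generator.frac_under5 + frac_age5to9 must be <= 1")
        _check_pos("generator.buildings_mean", self.buildings_mean)
        if self.building_age_mean < 0:
            raise ConfigError("generator.building_age_mean must be >= 0")
        _check_pos("generator.building_age_sd", self.building_age_sd)
        if self.mean_tests_per_block < 1.0:
            raise ConfigError("generator.mean_tests_per_block must be >= 1")
        self.contamination.validate()
        self.screening.validate()
        self.concentrations.validate()
        self.survey.validate()


@dataclass
class RiskModelConfig:
    """Classifier settings for the block-level contamination risk model."""

    model: str = "lightgbm"             # "lightgbm" or "logistic"
    threshold: float = 0.5
    test_size: float = 0.2
    cv_folds: int = 5
    tune: bool = True
    n_estimators: int = 200
    learning_rate_grid: tuple[float, ...] = (0.05, 0.1)
    num_leaves_grid: tuple[int, ...] = (15, 31)
    unit: str = "blocks"                # "blocks" or "tests" (robustness switch)
    outcome_draw: str = "second"        # which draw defines the label

    def validate(self) -> None:
        if self.model not in ("lightgbm", "logistic"):
            raise ConfigError(f"risk.model must be 'lightgbm' or 'logistic', got {self.model!r}")
        if not (0.0 < self.threshold < 1.0):
            raise ConfigError("risk.threshold must be in (0, 1)")
        if not (0.0 < self.test_size < 1.0):
            raise ConfigError("risk.test_size must be in (0, 1)")
        if self.cv_folds < 2:
            raise ConfigError("risk.cv_folds must be >= 2")
        if self.unit not in ("blocks", "tests"):
            raise ConfigError("risk.unit must be 'blocks' or 'tests'")
        if self.outcome_draw not in ("first", "second", "third"):
            raise ConfigError("risk.outcome_draw must be one of first/second/third")


@dataclass
class DisparityConfig:
    adjust_risk: bool = True
    unit: str = "blocks"
    robust_se: bool = False

    def validate(self) -> None:
        if self.unit not in ("blocks", "tests"):
            raise ConfigError("disparities.unit must be 'blocks' or 'tests'")


@dataclass
class MicrosimConfig:
    """Monte Carlo microsimulation settings.

    ``slope_*`` are the exposure-response parameters (% BLL increase per
    ppb after 150 days of exposure) and ship unset: they come from an
    external epidemiological study and must be supplied by the user.
    """

    n_reps: int = 10_000
    top_code_ppb: float = 10.0
    slope_point: float | None = None
    slope_ci_low: float | None = None
    slope_ci_high: float | None = None
    region_level: str = "block_group"   # finest level of the resampling pool
    exposure_days: int = 150            # documentation: validity horizon of the slope
    propagate_ppv_npv_uncertainty: bool = False  # Beta-resample PPV/NPV per replicate

    def validate(self) -> None:
        if self.n_reps < 1:
            raise ConfigError("microsim.n_reps must be >= 1")
        _check_pos("microsim.top_code_ppb", self.top_code_ppb)
        if self.slope_point is None or self.slope_ci_low is None or self.slope_ci_high is None:
            raise ConfigError(
                "microsim.slope_point/slope_ci_low/slope_ci_high must be set: the "
                "exposure-response slope is an external input with no authoritative default")
        if not (self.slope_ci_low <= self.slope_point <= self.slope_ci_high):
            raise ConfigError("microsim slope CI must satisfy ci_low <= point <= ci_high")
        if self.region_level not in ("block", "block_group", "tract", "community_area", "city"):
            raise ConfigError(f"microsim.region_level invalid: {self.region_level!r}")


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a full pipeline run."""

    n_blocks: int = 2000
    seed: int = 0
    out_dir: str = "leadwater_out"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    risk: RiskModelConfig = field(default_factory=RiskModelConfig)
    disparities: DisparityConfig = field(default_factory=DisparityConfig)
    microsim: MicrosimConfig = field(default_factory=MicrosimConfig)

    def validate(self) -> None:
        if self.n_blocks < 1:
            raise ConfigError("n_blocks must be >= 1")
        if not (0 <= self.seed < 2**31):
            raise ConfigError("seed must be in [0, 2^31)")
        self.generator.validate()
        self.risk.validate()
        self.disparities.validate()
        self.microsim.validate()

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        def build(klass, d):
            if d is None:
                return klass()
            kwargs = {}
            for f in dataclasses.fields(klass):
                if f.name not in d:
                    continue
                v = d[f.name]
                if dataclasses.is_dataclass(f.type) or f.name in _NESTED:
                    v = build(_NESTED[f.name], v)
                elif isinstance(v, list):
                    v = tuple(v)
                kwargs[f.name] = v
            return klass(**kwargs)

        _NESTED = {
            "hierarchy": HierarchyConfig, "contamination": ContaminationConfig,
            "screening": ScreeningConfig, "concentrations": ConcentrationConfig,
            "survey": SurveyConfig, "generator": GeneratorConfig,
            "risk": RiskModelConfig, "disparities": DisparityConfig,
            "microsim": MicrosimConfig,
        }
        return build(cls, data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(_tuples_to_lists(self.to_dict()), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(text) or {})

    def content_hash(self) -> str:
        """SHA-256 of the canonical YAML serialization."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()


def _tuples_to_lists(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_tuples_to_lists(v) for v in obj]
    return obj


# ---------------------------------------------------------------------------
# Stage seeding: one master seed, fixed per-stage offsets, so each stage is
# independently reproducible.  Derived seeds stay below 2^31.

_STAGE_OFFSETS = {"blocks": 11, "tests": 12, "survey": 13, "model": 14, "microsim": 15}


def stage_seed(master_seed: int, stage: str) -> int:
    if stage not in _STAGE_OFFSETS:
        raise ConfigError(f"unknown stage {stage!r}; expected one of {sorted(_STAGE_OFFSETS)}")
    return (master_seed * 100_003 + _STAGE_OFFSETS[stage]) % (2**31 - 1)
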