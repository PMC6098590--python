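"""Run configuration: validated YAML/JSON blocks mapped onto domain objects.

Every block is optional; omitted keys fall back to the national defaults in
:mod:`oxyaccess.defaults`, so an empty file is a valid baseline Zanzibar
configuration. Unknown keys are hard errors (no silent typo tolerance) and
all invariant violations are reported together by pydantic.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import defaults
from .access import AccessModel, DemandParams, PopulationState
from .errors import ConfigError
from .fixtures import FixtureSpec, generate_temperature_fixture
from .inventory import SupplyPlan
from .kinetics import KineticsParams, StrengthBands, TemperatureProfile, calibrate_kinetics


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PopulationBlock(_Block):
    annual_births: float = Field(defaults.DEFAULT_ANNUAL_BIRTHS, ge=0)
    literacy_rate: float = Field(defaults.DEFAULT_LITERACY, ge=0, le=1)
    wealth_quintile_shares: tuple[float, float, float, float, float] = (
        defaults.DEFAULT_WEALTH_SHARES
    )
    rural_share: float = Field(defaults.DEFAULT_RURAL_SHARE, ge=0, le=1)
    within_5km_share: float = Field(defaults.DEFAULT_WITHIN_5KM_SHARE, ge=0, le=1)
    growth_rate: float = defaults.DEFAULT_GROWTH_RATE

    @model_validator(mode="after")
    def _shares_sum_to_one(self) -> "PopulationBlock":
        total = sum(self.wealth_quintile_shares)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"wealth_quintile_shares must sum to 1, got {total}")
        return self

    def to_domain(self) -> PopulationState:
        return PopulationState(
            annual_births=self.annual_births,
            literacy_rate=self.literacy_rate,
            wealth_quintile_shares=self.wealth_quintile_shares,
            rural_share=self.rural_share,
            within_5km_share=self.within_5km_share,
            growth_rate=self.growth_rate,
        )


class AccessBlock(_Block):
    mode: Literal["anchored_linear", "logistic"] = "anchored_linear"
    or_wealth_richest: float = Field(defaults.OR_WEALTH_RICHEST, gt=0)
    or_literacy: float = Field(defaults.OR_LITERACY, gt=0)
    or_rural: float = Field(defaults.OR_RURAL, gt=0)
    #: marginal access probability the logistic baseline is calibrated to
    calibration_target: float = Field(defaults.DEFAULT_ACCESS_TARGET, gt=0, lt=1)
    #: fixes the access probability outright, bypassing the model
    p_access_override: Optional[float] = Field(None, ge=0, le=1)

    def to_domain(self) -> AccessModel:
        return AccessModel(
            or_wealth_richest=self.or_wealth_richest,
            or_literacy=self.or_literacy,
            or_rural=self.or_rural,
            mode=self.mode,
        )


class DemandBlock(_Block):
    prophylactic_doses_per_birth: float = Field(defaults.PROPHYLACTIC_DOSES_PER_BIRTH, ge=0)
    pph_rate: float = Field(defaults.PPH_RATE, ge=0, le=1)
    extra_doses_per_pph: float = Field(defaults.EXTRA_DOSES_PER_PPH, ge=0)
    therapeutic_dose_iu: float = Field(defaults.THERAPEUTIC_DOSE_IU, gt=0)

    def to_domain(self) -> DemandParams:
        return DemandParams(
            prophylactic_doses_per_birth=self.prophylactic_doses_per_birth,
            pph_rate=self.pph_rate,
            extra_doses_per_pph=self.extra_doses_per_pph,
            therapeutic_dose_iu=self.therapeutic_dose_iu,
        )


class SupplyBlock(_Block):
    annual_doses: int = Field(defaults.DEFAULT_ANNUAL_DOSES, ge=0)
    shipments_per_year: int = Field(defaults.DEFAULT_SHIPMENTS_PER_YEAR, ge=1)

    def to_domain(self) -> SupplyPlan:
        return SupplyPlan(
            annual_doses=self.annual_doses, shipments_per_year=self.shipments_per_year
        )


class KineticsBlock(_Block):
    anchor_low: tuple[float, float, float] = defaults.ANCHOR_LOW
    anchor_high: tuple[float, float, float] = defaults.ANCHOR_HIGH
    arrhenius_a: Optional[float] = Field(None, gt=0)
    activation_energy: Optional[float] = Field(None, ge=0)
    decay_mode: Literal["exponential", "discrete_linear"] = "exponential"

    @model_validator(mode="after")
    def _explicit_pair_complete(self) -> "KineticsBlock":
        if (self.arrhenius_a is None) != (self.activation_energy is None):
            raise ValueError("arrhenius_a and activation_energy must be given together")
        return self

    def to_domain(self) -> KineticsParams:
        if self.arrhenius_a is not None:
            return KineticsParams(
                arrhenius_a=self.arrhenius_a, activation_energy=self.activation_energy
            )
        return calibrate_kinetics(self.anchor_low, self.anchor_high)


class BandsBlock(_Block):
    full_min: float = defaults.FULL_STRENGTH_MIN
    double_min: float = defaults.DOUBLE_DOSE_MIN
    triple_min: float = defaults.TRIPLE_DOSE_MIN

    def to_domain(self) -> StrengthBands:
        return StrengthBands(
            full_min=self.full_min, double_min=self.double_min, triple_min=self.triple_min
        )


class FixtureBlock(_Block):
    mean_c: float = 27.0
    amplitude_c: float = Field(0.0, ge=0)
    noise_sd_c: float = Field(0.0, ge=0)
    weeks: int = Field(defaults.WEEKS_PER_YEAR, ge=1)
    seed: int = 0

    def to_domain(self) -> FixtureSpec:
        return FixtureSpec(
            mean_c=self.mean_c,
            amplitude_c=self.amplitude_c,
            noise_sd_c=self.noise_sd_c,
            weeks=self.weeks,
            seed=self.seed,
        )


class TemperatureBlock(_Block):
    kind: Literal["constant", "csv", "synthetic"] = "constant"
    constant_c: float = defaults.DEFAULT_STORAGE_TEMP_C
    csv_path: Optional[str] = None
    synthetic: FixtureBlock = FixtureBlock()

    @model_validator(mode="after")
    def _csv_path_required(self) -> "TemperatureBlock":
        if self.kind == "csv" and not self.csv_path:
            raise ValueError("temperature.kind 'csv' requires csv_path")
        return self

    def to_domain(self, base_dir: Path | None = None) -> TemperatureProfile:
        if self.kind == "constant":
            return TemperatureProfile.constant(self.constant_c)
        if self.kind == "csv":
            path = Path(self.csv_path)
            if base_dir is not None and not path.is_absolute():
                path = base_dir / path
            if not path.exists():
                raise ConfigError(f"temperature CSV does not exist: {path}")
            return TemperatureProfile.from_csv(path)
        return generate_temperature_fixture(self.synthetic.to_domain())


class ScenarioBlock(_Block):
    literacy_increase_per_year: float = Field(0.0, ge=0)
    birth_decline_per_year: float = Field(0.0, ge=0)
    start_year: int = Field(0, ge=0)
    horizon_years: int = Field(30, ge=1)
    cumulative_decline: bool = True
    allow_negative_growth: bool = False


class RunConfig(_Block):
    """Fully validated run configuration (see module docstring)."""

    population: PopulationBlock = PopulationBlock()
    access: AccessBlock = AccessBlock()
    demand: DemandBlock = DemandBlock()
    supply: SupplyBlock = SupplyBlock()
    kinetics: KineticsBlock = KineticsBlock()
    bands: BandsBlock = BandsBlock()
    temperature: TemperatureBlock = TemperatureBlock()
    scenario: ScenarioBlock = ScenarioBlock()
    seed: int = 0

    def config_hash(self) -> str:
        """Stable digest of the fully resolved configuration."""
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration.

    ``None`` or an empty file yields the all-defaults configuration.
    Raises :class:`ConfigError` listing every violated invariant, or naming
    the unknown key, rather than failing on the first problem.
    """
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file does not exist: {path}")
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        problems = "; ".join(
            f"{'.'.join(str(loc) for loc in err['loc'])}: {err['msg']}" for err in exc.errors()
        )
        raise ConfigError(f"invalid configuration: {problems}") from exc
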