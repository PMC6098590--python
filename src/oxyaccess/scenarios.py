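"""Multi-year projections: growth, literacy/family-planning interventions.

Zanzibar's population grows at 3% per year; literacy campaigns raise the
facility-delivery probability while family-planning interventions reduce
the birth growth rate. Each projected year re-runs the full 52-week
inventory engine (rather than scaling year-0 output) so temperature-band
interactions are respected.

The family-planning lever ("reduce the birth rate by x percentage points
per year") is applied cumulatively by default: the growth rate in
intervention year y is ``g0 - x*y``, clamped at zero unless negative growth
is explicitly allowed. A non-cumulative mode (a one-time step down to
``g0 - x``) is also available.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import pandas as pd

from . import defaults
from .access import (
    AccessModel,
    DemandParams,
    PopulationState,
    facility_access_probability,
)
from .errors import InvalidInputError
from .inventory import SupplyPlan, minimal_supply, simulate_year
from .kinetics import (
    KineticsParams,
    StrengthBands,
    TemperatureProfile,
    calibrate_kinetics,
    remaining_strength,
)

__all__ = [
    "InterventionSpec",
    "Trajectory",
    "project_population",
    "required_supply_trajectory",
    "access_decline_trajectory",
    "loss_fraction",
    "temperature_sweep",
]


@dataclass(frozen=True)
class InterventionSpec:
    """Literacy and family-planning intervention schedule.

    ``literacy_increase_per_year`` and ``birth_decline_per_year`` are
    fractions per year (0.02 means two percentage points annually).
    """

    literacy_increase_per_year: float = 0.0
    birth_decline_per_year: float = 0.0
    start_year: int = 0
    horizon_years: int = 30
    cumulative_decline: bool = True
    allow_negative_growth: bool = False

    def __post_init__(self) -> None:
        if self.horizon_years < 1:
            raise InvalidInputError(f"horizon_years must be >= 1, got {self.horizon_years}")
        if self.start_year < 0:
            raise InvalidInputError(f"start_year must be >= 0, got {self.start_year}")
        if self.literacy_increase_per_year < 0 or self.birth_decline_per_year < 0:
            raise InvalidInputError("intervention rates must be non-negative")


@dataclass(frozen=True)
class Trajectory:
    """Per-year population path: years 0..horizon inclusive."""

    years: tuple[int, ...]
    annual_births: tuple[float, ...]
    literacy_rate: tuple[float, ...]
    growth_rate: tuple[float, ...]
    base_population: PopulationState

    def __post_init__(self) -> None:
        n = len(self.years)
        if not (len(self.annual_births) == len(self.literacy_rate) == len(self.growth_rate) == n):
            raise InvalidInputError("trajectory arrays must have equal length")

    def population_at(self, index: int) -> PopulationState:
        return replace(
            self.base_population,
            annual_births=self.annual_births[index],
            literacy_rate=self.literacy_rate[index],
            growth_rate=self.growth_rate[index],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "births": self.annual_births,
                "literacy": self.literacy_rate,
                "growth_rate": self.growth_rate,
            }
        )


def project_population(pop: PopulationState, spec: InterventionSpec) -> Trajectory:
    """Compound births and ramp literacy over the intervention horizon.

    Year 0 is the baseline; year y births are
    ``births_0 * prod_{i=1..y} (1 + g_i)`` with ``g_i`` the (possibly
    intervention-reduced) growth rate in year i. Literacy is capped at 1.
    """
    years = list(range(spec.horizon_years + 1))
    births = [float(pop.annual_births)]
    literacy = [pop.literacy_rate]
    growth = [pop.growth_rate]
    for year in years[1:]:
        elapsed = max(0, year - spec.start_year)
        if spec.cumulative_decline:
            g = pop.growth_rate - spec.birth_decline_per_year * elapsed
        else:
            g = pop.growth_rate - (spec.birth_decline_per_year if elapsed > 0 else 0.0)
        if not spec.allow_negative_growth:
            g = max(0.0, g)
        births.append(births[-1] * (1.0 + g))
        literacy.append(min(1.0, pop.literacy_rate + spec.literacy_increase_per_year * elapsed))
        growth.append(g)
    return Trajectory(
        years=tuple(years),
        annual_births=tuple(births),
        literacy_rate=tuple(literacy),
        growth_rate=tuple(growth),
        base_population=pop,
    )


def required_supply_trajectory(
    traj: Trajectory,
    access_model: AccessModel,
    demand_params: DemandParams,
    shipments_per_year: int = defaults.DEFAULT_SHIPMENTS_PER_YEAR,
    temp: float | TemperatureProfile = defaults.DEFAULT_STORAGE_TEMP_C,
    bands: StrengthBands | None = None,
    kinetics: KineticsParams | None = None,
    p_access: float | None = None,
    target_ratio: float = 1.0,
) -> pd.DataFrame:
    """Annual doses needed each projected year for the target access ratio.

    Each year's requirement is found by the full bisection over the weekly
    engine with that year's births and literacy-driven access probability.
    Returns columns ``year, births, p_access, required_supply``.
    """
    rows = []
    for idx, year in enumerate(traj.years):
        pop_y = traj.population_at(idx)
        p_y = (
            p_access
            if p_access is not None
            else facility_access_probability(pop_y, access_model)
        )
        supply = minimal_supply(
            target_ratio, pop_y, access_model, demand_params,
            shipments_per_year=shipments_per_year, temp=temp,
            bands=bands, kinetics=kinetics, p_access=p_y,
        )
        rows.append((year, pop_y.annual_births, p_y, supply))
    return pd.DataFrame(rows, columns=["year", "births", "p_access", "required_supply"])


def access_decline_trajectory(
    fixed_supply: int,
    traj: Trajectory,
    access_model: AccessModel,
    demand_params: DemandParams,
    shipments_per_year: int = defaults.DEFAULT_SHIPMENTS_PER_YEAR,
    temp: float | TemperatureProfile = defaults.DEFAULT_STORAGE_TEMP_C,
    bands: StrengthBands | None = None,
    kinetics: KineticsParams | None = None,
    p_access: float | None = None,
) -> pd.DataFrame:
    """Average access ratio per projected year with the annual order frozen.

    Demand grows with the population while supply stays at ``fixed_supply``,
    so the series declines whenever growth is positive. Returns columns
    ``year, births, p_access, access_ratio``.
    """
    if fixed_supply <= 0:
        raise InvalidInputError(f"fixed_supply must be positive, got {fixed_supply}")
    profile = (
        temp if isinstance(temp, TemperatureProfile) else TemperatureProfile.constant(temp)
    )
    plan = SupplyPlan(annual_doses=fixed_supply, shipments_per_year=shipments_per_year)
    rows = []
    for idx, year in enumerate(traj.years):
        pop_y = traj.population_at(idx)
        p_y = (
            p_access
            if p_access is not None
            else facility_access_probability(pop_y, access_model)
        )
        result = simulate_year(
            pop_y, access_model, demand_params, plan, profile,
            bands=bands, kinetics=kinetics, p_access=p_y,
        )
        rows.append((year, pop_y.annual_births, p_y, result.average_access_ratio))
    return pd.DataFrame(rows, columns=["year", "births", "p_access", "access_ratio"])


def loss_fraction(ordered: float, required: float) -> float:
    """Share of the annual order not needed to meet demand.

    With 100,000 doses ordered nationally and 26,500 required for an
    average access ratio of 1, the implied loss is 73.5% — doses that are
    procured but never reach a patient.
    """
    if ordered <= 0:
        raise InvalidInputError(f"ordered must be positive, got {ordered}")
    if not 0 <= required <= ordered:
        raise InvalidInputError(
            f"required must lie in [0, ordered], got required={required}, ordered={ordered}"
        )
    return (ordered - required) / ordered


def temperature_sweep(
    temps_c: Sequence[float],
    pop: PopulationState,
    access_model: AccessModel,
    demand_params: DemandParams,
    plan: SupplyPlan,
    bands: StrengthBands | None = None,
    kinetics: KineticsParams | None = None,
    p_access: float | None = None,
) -> pd.DataFrame:
    """Constant-temperature yearly runs across a grid of storage temperatures.

    Returns columns ``temp_c, end_of_quarter_strength, average_access_ratio``.
    Strength (and hence the ratio) is flat up to roughly 30 degC and
    collapses above it: the quarter-end strength crosses the viability floor
    near 45 degC, producing weeks of zero effective doses late in each
    shipment cycle.
    """
    bands = bands or StrengthBands()
    kinetics = kinetics or calibrate_kinetics()
    rows = []
    for temp in temps_c:
        if not 0 < temp < 60:
            raise InvalidInputError(f"sweep temperatures must lie in (0, 60) degC, got {temp}")
        result = simulate_year(
            pop, access_model, demand_params, plan,
            TemperatureProfile.constant(temp),
            bands=bands, kinetics=kinetics, p_access=p_access,
        )
        rows.append(
            (
                temp,
                remaining_strength(1.0, temp, defaults.DAYS_PER_QUARTER, kinetics),
                result.average_access_ratio,
            )
        )
    return pd.DataFrame(
        rows, columns=["temp_c", "end_of_quarter_strength", "average_access_ratio"]
    )
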