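"""Weekly stock-and-flow engine for the national oxytocin inventory.

Each simulated week, in order:

1. a shipment cohort arrives at full strength if this is a shipment week;
2. every cohort in stock decays for 7 days at this week's storage
   temperature;
3. the post-decay stock is converted to effective doses with the banded
   multi-dosing rule, and the *weekly access ratio* is computed as

       effective doses / (weekly demand x weeks until the next shipment)

   where the count of weeks until the next shipment includes the current
   week, so the week immediately before an arrival has a denominator of a
   single week's demand — this produces the characteristic sawtooth with
   troughs just before each restock;
4. the week's demand (rounded up to whole patients) is served FIFO, each
   patient drawing 1, 2 or 3 physical vials from the serving cohort
   according to its strength band;
5. cohorts that have fallen below the 33% viability floor are written off.

The ratio is intentionally uncapped: over-supplied weeks report values
above 1. A year is 52 such weeks; the *average access ratio* is the
arithmetic mean of the 52 weekly ratios, and ``minimal_supply`` bisects the
annual order size until that average reaches a target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd

from . import defaults
from .access import AccessModel, DemandParams, PopulationState, facility_access_probability
from .access import weekly_demand as _weekly_demand
from .errors import (
    InvalidInputError,
    SearchFailureError,
    UndefinedRatioError,
)
from .kinetics import (
    KineticsParams,
    StrengthBands,
    TemperatureProfile,
    calibrate_kinetics,
    dose_multiplier,
    effective_doses,
    rate_constant,
)

__all__ = [
    "SupplyPlan",
    "DoseCohort",
    "WeeklyRecord",
    "SimulationResult",
    "InventoryState",
    "build_schedule",
    "weekly_access_ratio",
    "step_week",
    "simulate_year",
    "minimal_supply",
]


@dataclass(frozen=True)
class SupplyPlan:
    """Annual order split into equally sized, equally spaced shipments."""

    annual_doses: int
    shipments_per_year: int = defaults.DEFAULT_SHIPMENTS_PER_YEAR

    def __post_init__(self) -> None:
        if self.annual_doses < 0:
            raise InvalidInputError(f"annual_doses must be >= 0, got {self.annual_doses}")
        if self.shipments_per_year < 1:
            raise InvalidInputError(
                f"shipments_per_year must be >= 1, got {self.shipments_per_year}"
            )

    @property
    def doses_per_shipment(self) -> int:
        return round(self.annual_doses / self.shipments_per_year)

    @property
    def shipment_weeks(self) -> tuple[int, ...]:
        return build_schedule(self)


def build_schedule(plan: SupplyPlan) -> tuple[int, ...]:
    """Shipment calendar: week ``floor(52 i / n)`` for i = 0..n-1.

    Two shipments a year arrive at weeks {0, 26} (semiannual restock);
    four at {0, 13, 26, 39}.
    """
    n = plan.shipments_per_year
    return tuple(defaults.WEEKS_PER_YEAR * i // n for i in range(n))


@dataclass
class DoseCohort:
    """A batch of vials sharing an arrival week and decay history."""

    arrival_week: int
    doses_remaining: int
    strength: float = 1.0


@dataclass(frozen=True)
class WeeklyRecord:
    week: int
    effective_doses: int
    forward_demand: float
    access_ratio: float
    consumed: int
    shortfall: int


@dataclass
class InventoryState:
    """Mutable FIFO cohort list carried across weeks."""

    cohorts: list[DoseCohort] = field(default_factory=list)
    doses_supplied: int = 0
    doses_consumed: int = 0
    doses_written_off: int = 0

    @property
    def doses_on_hand(self) -> int:
        return sum(c.doses_remaining for c in self.cohorts)


@dataclass(frozen=True)
class SimulationResult:
    """One simulated year of weekly records plus dose bookkeeping.

    Dose conservation holds exactly:
    ``doses_supplied == doses_consumed + doses_written_off + doses_carried_over``.
    """

    records: tuple[WeeklyRecord, ...]
    average_access_ratio: float
    doses_supplied: int
    doses_consumed: int
    doses_written_off: int
    doses_carried_over: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "week": [r.week for r in self.records],
                "effective_doses": [r.effective_doses for r in self.records],
                "forward_demand": [r.forward_demand for r in self.records],
                "access_ratio": [r.access_ratio for r in self.records],
                "consumed": [r.consumed for r in self.records],
                "shortfall": [r.shortfall for r in self.records],
            }
        )


def weekly_access_ratio(
    effective: float, weekly_demand: float, weeks_to_next_shipment: int
) -> float:
    """Effective doses over the demand they must cover until the next arrival."""
    if weekly_demand <= 0:
        raise UndefinedRatioError(f"weekly demand must be positive, got {weekly_demand}")
    if weeks_to_next_shipment < 1:
        raise InvalidInputError(
            f"weeks_to_next_shipment must be >= 1, got {weeks_to_next_shipment}"
        )
    return effective / (weekly_demand * weeks_to_next_shipment)


def _weeks_to_next_shipment(week: int, shipment_weeks: tuple[int, ...]) -> int:
    # Counts the current week; after the last arrival the horizon is next
    # year's first shipment at week 52.
    upcoming = [w for w in shipment_weeks if w > week]
    next_week = min(upcoming) if upcoming else defaults.WEEKS_PER_YEAR + min(
        shipment_weeks, default=defaults.WEEKS_PER_YEAR
    )
    return next_week - week


def step_week(
    state: InventoryState,
    week: int,
    plan: SupplyPlan,
    temp_profile: TemperatureProfile,
    demand_per_week: float,
    bands: StrengthBands,
    kinetics: KineticsParams,
    decay_mode: str = "exponential",
) -> WeeklyRecord:
    """Advance the inventory by one week and return its record.

    Mutates ``state`` in place. Unmet demand is recorded as shortfall, never
    raised.
    """
    shipment_weeks = plan.shipment_weeks
    if week in shipment_weeks and plan.doses_per_shipment > 0:
        state.cohorts.append(DoseCohort(arrival_week=week, doses_remaining=plan.doses_per_shipment))
        state.doses_supplied += plan.doses_per_shipment

    temp_c = temp_profile.temperature_at(week)
    if decay_mode == "exponential":
        factor = math.exp(-rate_constant(temp_c, kinetics) * defaults.DAYS_PER_WEEK)
    else:
        factor = max(0.0, 1.0 - rate_constant(temp_c, kinetics) * defaults.DAYS_PER_WEEK)
    for cohort in state.cohorts:
        cohort.strength *= factor

    effective = sum(
        effective_doses(c.doses_remaining, c.strength, bands) for c in state.cohorts
    )

    # Serve demand FIFO, whole patients only; each patient's 1/2/3 vials come
    # atomically from one cohort, remaining patients roll to the next cohort
    # at its own multiplier.
    patients_to_serve = math.ceil(demand_per_week)
    consumed = 0
    for cohort in state.cohorts:
        if patients_to_serve == 0:
            break
        mult = dose_multiplier(cohort.strength, bands)
        if mult is None:
            continue
        servable = min(patients_to_serve, cohort.doses_remaining // mult)
        draw = servable * mult
        cohort.doses_remaining -= draw
        consumed += draw
        patients_to_serve -= servable
    state.doses_consumed += consumed

    survivors: list[DoseCohort] = []
    for cohort in state.cohorts:
        if cohort.strength < bands.triple_min:
            state.doses_written_off += cohort.doses_remaining
        elif cohort.doses_remaining > 0:
            survivors.append(cohort)
    state.cohorts = survivors

    weeks_to_next = _weeks_to_next_shipment(week, shipment_weeks)
    forward_demand = demand_per_week * weeks_to_next
    ratio = weekly_access_ratio(effective, demand_per_week, weeks_to_next)
    return WeeklyRecord(
        week=week,
        effective_doses=effective,
        forward_demand=forward_demand,
        access_ratio=ratio,
        consumed=consumed,
        shortfall=patients_to_serve,
    )


def simulate_year(
    pop: PopulationState,
    access_model: AccessModel,
    demand_params: DemandParams,
    plan: SupplyPlan,
    temp_profile: TemperatureProfile,
    bands: StrengthBands | None = None,
    kinetics: KineticsParams | None = None,
    p_access: float | None = None,
    decay_mode: str = "exponential",
    initial_state: InventoryState | None = None,
) -> SimulationResult:
    """Run 52 sequential weeks and summarise.

    ``p_access`` overrides the access probability computed from ``pop`` and
    ``access_model`` (useful for fixing it at a survey value). Demand must
    be strictly positive, otherwise the access ratio is undefined.
    """
    bands = bands or StrengthBands()
    kinetics = kinetics or calibrate_kinetics()
    if p_access is None:
        p_access = facility_access_probability(pop, access_model)
    demand = _weekly_demand(pop, p_access, demand_params)
    if demand <= 0:
        raise UndefinedRatioError(
            "weekly demand is zero (no births or no facility access); access ratio undefined"
        )
    state = initial_state if initial_state is not None else InventoryState()
    records = [
        step_week(state, week, plan, temp_profile, demand, bands, kinetics, decay_mode)
        for week in range(defaults.WEEKS_PER_YEAR)
    ]
    average = sum(r.access_ratio for r in records) / len(records)
    return SimulationResult(
        records=tuple(records),
        average_access_ratio=average,
        doses_supplied=state.doses_supplied,
        doses_consumed=state.doses_consumed,
        doses_written_off=state.doses_written_off,
        doses_carried_over=state.doses_on_hand,
    )


def minimal_supply(
    target_ratio: float,
    pop: PopulationState,
    access_model: AccessModel,
    demand_params: DemandParams,
    shipments_per_year: int = defaults.DEFAULT_SHIPMENTS_PER_YEAR,
    temp: float | TemperatureProfile = defaults.DEFAULT_STORAGE_TEMP_C,
    bands: StrengthBands | None = None,
    kinetics: KineticsParams | None = None,
    p_access: float | None = None,
    round_to: int = defaults.SUPPLY_ROUNDING,
) -> int:
    """Smallest annual order whose average access ratio reaches ``target_ratio``.

    The average ratio is monotone non-decreasing in the annual order, so the
    crossing point is found by doubling to bracket and integer bisection to
    a one-dose interval; the result is reported rounded to the nearest
    ``round_to`` doses (answers are conventionally quoted in hundreds).
    """
    if target_ratio <= 0:
        raise InvalidInputError(f"target_ratio must be positive, got {target_ratio}")
    profile = (
        temp if isinstance(temp, TemperatureProfile) else TemperatureProfile.constant(temp)
    )
    bands = bands or StrengthBands()
    kinetics = kinetics or calibrate_kinetics()

    def average_ratio(annual: int) -> float:
        plan = SupplyPlan(annual_doses=annual, shipments_per_year=shipments_per_year)
        result = simulate_year(
            pop, access_model, demand_params, plan, profile,
            bands=bands, kinetics=kinetics, p_access=p_access,
        )
        return result.average_access_ratio

    # UndefinedRatioError propagates from the first evaluation if demand is 0.
    lo, hi = 0, max(round_to, 1000)
    ratio_hi = average_ratio(hi)
    while ratio_hi < target_ratio:
        hi *= 2
        if hi > 2**34:
            raise SearchFailureError(
                f"target ratio {target_ratio} not reachable below {hi} annual doses"
            )
        ratio_hi = average_ratio(hi)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if average_ratio(mid) >= target_ratio:
            hi = mid
        else:
            lo = mid
    return round(hi / round_to) * round_to if round_to > 1 else hi
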