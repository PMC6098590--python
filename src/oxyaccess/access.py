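"""Facility-delivery access probability and weekly oxytocin demand.

The likelihood that a woman delivers at a health facility is driven by
wealth (richest quintile OR 2.55), literacy (OR 1.99) and rural residence
(OR 0.82). Two ways of turning those odds ratios into a population-level
probability are provided:

``anchored_linear``
    Pins the literacy response to the published endpoints — 41% facility
    delivery for a fully illiterate population, 53% for a fully literate
    one — by linear interpolation, with wealth/rural composition shifts
    applied as log-odds perturbations around that level. This mode
    reproduces the published access figures exactly and is the default.

``logistic``
    A principled logistic cell mixture: the population is partitioned into
    the eight cells of (richest-quintile x literate x rural) assuming
    independent composition, each cell gets probability
    ``expit(baseline + sum of ln(OR) * indicator)``, and the result is the
    share-weighted mean. The baseline log-odds is calibrated so the
    current-composition marginal hits a target (~50% for Zanzibar).

Demand: every facility birth receives one prophylactic dose, and the 2% of
women who develop postpartum hemorrhage need four additional therapeutic
doses, giving an expected 1.08 doses per facility birth. Demand is treated
as deterministic (expected value) and constant across weeks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from scipy.optimize import brentq
from scipy.special import expit, logit

from . import defaults
from .errors import InvalidInputError, NotCalibratedError, UnreachableTargetError

__all__ = [
    "PopulationState",
    "AccessModel",
    "DemandParams",
    "facility_access_probability",
    "calibrate_baseline",
    "weekly_demand",
    "distance_scenario",
]


def _check_fraction(value: float, name: str) -> float:
    if not 0 <= value <= 1:
        raise InvalidInputError(f"{name} must be in [0, 1], got {value}")
    return float(value)


@dataclass(frozen=True)
class PopulationState:
    """Population size and socioeconomic composition of the catchment area."""

    annual_births: float = defaults.DEFAULT_ANNUAL_BIRTHS
    literacy_rate: float = defaults.DEFAULT_LITERACY
    wealth_quintile_shares: tuple[float, ...] = defaults.DEFAULT_WEALTH_SHARES
    rural_share: float = defaults.DEFAULT_RURAL_SHARE
    within_5km_share: float = defaults.DEFAULT_WITHIN_5KM_SHARE
    growth_rate: float = defaults.DEFAULT_GROWTH_RATE

    def __post_init__(self) -> None:
        if self.annual_births < 0:
            raise InvalidInputError(f"annual_births must be >= 0, got {self.annual_births}")
        _check_fraction(self.literacy_rate, "literacy_rate")
        _check_fraction(self.rural_share, "rural_share")
        _check_fraction(self.within_5km_share, "within_5km_share")
        if len(self.wealth_quintile_shares) != 5:
            raise InvalidInputError("wealth_quintile_shares must have 5 entries")
        for share in self.wealth_quintile_shares:
            _check_fraction(share, "wealth quintile share")
        if abs(sum(self.wealth_quintile_shares) - 1.0) > 1e-9:
            raise InvalidInputError(
                f"wealth_quintile_shares must sum to 1, got {sum(self.wealth_quintile_shares)}"
            )

    @property
    def richest_share(self) -> float:
        return self.wealth_quintile_shares[-1]


@dataclass(frozen=True)
class AccessModel:
    """Odds ratios plus a calibrated baseline turning composition into access."""

    or_wealth_richest: float = defaults.OR_WEALTH_RICHEST
    or_literacy: float = defaults.OR_LITERACY
    or_rural: float = defaults.OR_RURAL
    baseline_log_odds: float | None = None
    mode: str = "anchored_linear"
    #: Literacy-endpoint anchors used by anchored_linear mode.
    access_illiterate: float = defaults.ACCESS_ILLITERATE
    access_literate: float = defaults.ACCESS_LITERATE

    def __post_init__(self) -> None:
        for name in ("or_wealth_richest", "or_literacy", "or_rural"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")
        if self.mode not in ("logistic", "anchored_linear"):
            raise InvalidInputError(f"mode must be 'logistic' or 'anchored_linear', got {self.mode!r}")
        if not 0 < self.access_illiterate < self.access_literate < 1:
            raise InvalidInputError("literacy anchors must satisfy 0 < illiterate < literate < 1")


@dataclass(frozen=True)
class DemandParams:
    """Doses required per facility birth."""

    prophylactic_doses_per_birth: float = defaults.PROPHYLACTIC_DOSES_PER_BIRTH
    pph_rate: float = defaults.PPH_RATE
    extra_doses_per_pph: float = defaults.EXTRA_DOSES_PER_PPH
    therapeutic_dose_iu: float = defaults.THERAPEUTIC_DOSE_IU

    def __post_init__(self) -> None:
        _check_fraction(self.pph_rate, "pph_rate")
        if self.prophylactic_doses_per_birth < 0 or self.extra_doses_per_pph < 0:
            raise InvalidInputError("dose counts must be non-negative")

    @property
    def doses_per_facility_birth(self) -> float:
        """Expected doses per facility delivery (1.08 at defaults)."""
        return self.prophylactic_doses_per_birth + self.pph_rate * self.extra_doses_per_pph


def _cell_mixture_probability(pop: PopulationState, model: AccessModel, baseline: float) -> float:
    """Share-weighted mean of the 8 covariate-cell logistic probabilities."""
    log_ors = (
        math.log(model.or_wealth_richest),
        math.log(model.or_literacy),
        math.log(model.or_rural),
    )
    prevalences = (pop.richest_share, pop.literacy_rate, pop.rural_share)
    total = 0.0
    for rich in (0, 1):
        for lit in (0, 1):
            for rural in (0, 1):
                indicators = (rich, lit, rural)
                share = 1.0
                for ind, prev in zip(indicators, prevalences):
                    share *= prev if ind else 1.0 - prev
                if share == 0.0:
                    continue
                eta = baseline + sum(lo * ind for lo, ind in zip(log_ors, indicators))
                total += share * float(expit(eta))
    return total


def facility_access_probability(pop: PopulationState, model: AccessModel) -> float:
    """Probability that a pregnant woman delivers at a health facility.

    See the module docstring for the two modes. In ``anchored_linear`` mode
    the default composition (richest share 0.20, rural share 0.50) returns
    the interpolated literacy response exactly; composition deviations act
    multiplicatively on the odds.
    """
    if model.mode == "anchored_linear":
        base = model.access_illiterate + (
            model.access_literate - model.access_illiterate
        ) * pop.literacy_rate
        perturbation = math.log(model.or_wealth_richest) * (
            pop.richest_share - defaults.DEFAULT_WEALTH_SHARES[-1]
        ) + math.log(model.or_rural) * (pop.rural_share - defaults.DEFAULT_RURAL_SHARE)
        if perturbation == 0.0:
            return base
        return float(expit(logit(base) + perturbation))
    if model.baseline_log_odds is None:
        raise NotCalibratedError(
            "logistic access model requires calibrate_baseline() before use"
        )
    return _cell_mixture_probability(pop, model, model.baseline_log_odds)


def calibrate_baseline(
    pop: PopulationState,
    model: AccessModel,
    target: float = defaults.DEFAULT_ACCESS_TARGET,
) -> AccessModel:
    """Return a logistic model whose marginal access probability equals ``target``.

    The cell-mixture probability is strictly increasing in the baseline
    log-odds, so a bracketed root find converges to the unique solution.
    """
    if not 0 < target < 1:
        raise UnreachableTargetError(f"target probability must be in (0, 1), got {target}")
    if model.mode != "logistic":
        raise InvalidInputError("baseline calibration applies to the logistic mode only")
    baseline = float(
        brentq(
            lambda b: _cell_mixture_probability(pop, model, b) - target,
            -60.0,
            60.0,
            xtol=1e-12,
        )
    )
    return replace(model, baseline_log_odds=baseline)


def weekly_demand(pop: PopulationState, p_access: float, d: DemandParams) -> float:
    """Expected oxytocin doses needed per week at the facilities.

    ``annual_births / 52`` weekly births, a fraction ``p_access`` of which
    occur at facilities, each consuming ``doses_per_facility_birth`` in
    expectation. Real-valued; rounding to whole vials happens only at the
    consumption step of the inventory engine.
    """
    _check_fraction(p_access, "p_access")
    return (
        pop.annual_births / defaults.WEEKS_PER_YEAR
        * p_access
        * d.doses_per_facility_birth
    )


def distance_scenario(
    pop: PopulationState, new_within_5km_share: float, model: AccessModel
) -> float:
    """Access probability after moving population to within 5 km of a facility.

    Distance enters the model only through the rural-residence odds ratio
    (0.82): the share newly within 5 km is reclassified from rural to
    non-rural. Because the OR is close to 1, even doubling the within-5km
    share moves the access probability by only a few percentage points.
    """
    _check_fraction(new_within_5km_share, "new_within_5km_share")
    moved = new_within_5km_share - pop.within_5km_share
    new_rural = min(1.0, max(0.0, pop.rural_share - moved))
    new_pop = replace(
        pop, rural_share=new_rural, within_5km_share=new_within_5km_share
    )
    return facility_access_probability(new_pop, model)
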