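"""Temperature-dependent first-order degradation of injectable oxytocin.

Oxytocin in solution (pH 4.5, its most stable formulation) degrades by
first-order kinetics with an Arrhenius rate constant

    k(T) = A * exp(-Ea / (R * T))        [1/day, T in kelvin]

so a dose stored ``t`` days at temperature ``T`` retains a fraction
``exp(-k(T) * t)`` of its labelled strength. Because published A/Ea pairs
for the relevant formulation are not directly usable, the pair is
calibrated from two quarter-decay stability anchors (80% remaining after
91 days at 35 degC, 20% at 45 degC by default).

Partially degraded stock is converted to *effective* doses by banded
multi-dosing: at >=85% strength a vial counts in full, at 54-85% two vials
are needed per patient, at 33-54% three, and below 33% the stock is not
viable at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import defaults
from .errors import CalibrationError, InvalidInputError

__all__ = [
    "KineticsParams",
    "StrengthBands",
    "TemperatureProfile",
    "rate_constant",
    "remaining_strength",
    "calibrate_kinetics",
    "effective_doses",
    "dose_multiplier",
]

_ABSOLUTE_ZERO_C = -273.15


@dataclass(frozen=True)
class KineticsParams:
    """Arrhenius parameters for first-order oxytocin decay.

    Parameters
    ----------
    arrhenius_a : float
        Pre-exponential factor A, 1/day. Must be positive.
    activation_energy : float
        Activation energy Ea, J/mol. Non-negative (zero means a
        temperature-independent rate).
    gas_constant : float
        Ideal gas constant R, J/(mol K).
    """

    arrhenius_a: float
    activation_energy: float
    gas_constant: float = defaults.GAS_CONSTANT

    def __post_init__(self) -> None:
        if not (math.isfinite(self.arrhenius_a) and self.arrhenius_a > 0):
            raise InvalidInputError(f"arrhenius_a must be positive, got {self.arrhenius_a}")
        if not (math.isfinite(self.activation_energy) and self.activation_energy >= 0):
            raise InvalidInputError(
                f"activation_energy must be non-negative, got {self.activation_energy}"
            )
        if self.gas_constant <= 0:
            raise InvalidInputError("gas_constant must be positive")


@dataclass(frozen=True)
class StrengthBands:
    """Half-open strength bands for banded multi-dosing.

    ``[full_min, 1]`` full credit, ``[double_min, full_min)`` double dosing,
    ``[triple_min, double_min)`` triple dosing, ``[0, triple_min)`` written
    off. The published band edges (50-85% and 33-54%) overlap on 50-54%; the
    54% edge is the only choice that partitions [0, 1], so it is kept.
    """

    full_min: float = defaults.FULL_STRENGTH_MIN
    double_min: float = defaults.DOUBLE_DOSE_MIN
    triple_min: float = defaults.TRIPLE_DOSE_MIN

    def __post_init__(self) -> None:
        if not 0 < self.triple_min < self.double_min < self.full_min < 1:
            raise InvalidInputError(
                "bands must satisfy 0 < triple_min < double_min < full_min < 1, got "
                f"({self.triple_min}, {self.double_min}, {self.full_min})"
            )


@dataclass(frozen=True)
class TemperatureProfile:
    """Step-function storage temperature by week.

    ``weeks`` are strictly increasing 0-based indices; the temperature of
    the last entry extends to the end of any simulated horizon.
    """

    weeks: tuple[int, ...]
    temps_c: tuple[float, ...]
    _weeks_arr: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.weeks) != len(self.temps_c) or not self.weeks:
            raise InvalidInputError("profile needs equal-length, non-empty weeks and temps")
        weeks = np.asarray(self.weeks, dtype=int)
        temps = np.asarray(self.temps_c, dtype=float)
        if weeks[0] < 0 or np.any(np.diff(weeks) <= 0):
            raise InvalidInputError("week indices must be non-negative and strictly increasing")
        if not np.all(np.isfinite(temps)) or np.any(temps <= _ABSOLUTE_ZERO_C):
            raise InvalidInputError("temperatures must be finite and above absolute zero")
        object.__setattr__(self, "_weeks_arr", weeks)

    @classmethod
    def constant(cls, temp_c: float, start_week: int = 0) -> "TemperatureProfile":
        return cls(weeks=(start_week,), temps_c=(float(temp_c),))

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[int, float]]) -> "TemperatureProfile":
        pairs = list(pairs)
        return cls(
            weeks=tuple(int(w) for w, _ in pairs),
            temps_c=tuple(float(t) for _, t in pairs),
        )

    @classmethod
    def from_csv(cls, path) -> "TemperatureProfile":
        """Read a ``week,temp_c`` CSV (header required, week 0-based)."""
        frame = pd.read_csv(path)
        missing = {"week", "temp_c"} - set(frame.columns)
        if missing:
            raise InvalidInputError(f"temperature CSV missing columns: {sorted(missing)}")
        return cls.from_pairs(zip(frame["week"], frame["temp_c"]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"week": list(self.weeks), "temp_c": list(self.temps_c)})

    def temperature_at(self, week: int) -> float:
        """Temperature in effect during ``week`` (last entry extends)."""
        if week < self.weeks[0]:
            raise InvalidInputError(
                f"week {week} precedes the start of the profile (week {self.weeks[0]})"
            )
        idx = int(np.searchsorted(self._weeks_arr, week, side="right")) - 1
        return self.temps_c[idx]


def _validate_temperature(t_celsius: float) -> float:
    if not math.isfinite(t_celsius) or t_celsius <= _ABSOLUTE_ZERO_C:
        raise InvalidInputError(f"temperature must be finite and above absolute zero, got {t_celsius}")
    return float(t_celsius)


def rate_constant(t_celsius: float, params: KineticsParams) -> float:
    """First-order decay rate constant k(T) = A exp(-Ea/RT), in 1/day."""
    t_kelvin = _validate_temperature(t_celsius) - _ABSOLUTE_ZERO_C
    return params.arrhenius_a * math.exp(
        -params.activation_energy / (params.gas_constant * t_kelvin)
    )


def remaining_strength(
    initial_strength: float,
    t_celsius: float,
    days: float,
    params: KineticsParams,
    mode: str = "exponential",
) -> float:
    """Fraction of labelled strength remaining after ``days`` at ``t_celsius``.

    The default ``exponential`` mode is the exact first-order solution
    ``s0 * exp(-k t)``. The ``discrete_linear`` mode instead applies the
    rate-times-interval update ``s <- s * (1 - 7 k)`` once per stored week
    (floored at zero, remainder days as a final partial step); it is a
    close approximation for ``7 k << 1`` and degrades faster near total
    decay.
    """
    if not 0 <= initial_strength <= 1:
        raise InvalidInputError(f"initial_strength must be in [0, 1], got {initial_strength}")
    if days < 0 or not math.isfinite(days):
        raise InvalidInputError(f"days must be finite and non-negative, got {days}")
    k = rate_constant(t_celsius, params)
    if mode == "exponential":
        return initial_strength * math.exp(-k * days)
    if mode == "discrete_linear":
        strength = float(initial_strength)
        full_weeks, remainder = divmod(float(days), float(defaults.DAYS_PER_WEEK))
        weekly_factor = max(0.0, 1.0 - defaults.DAYS_PER_WEEK * k)
        strength *= weekly_factor ** int(full_weeks)
        strength *= max(0.0, 1.0 - remainder * k)
        return strength
    raise InvalidInputError(f"unknown decay mode {mode!r}")


def calibrate_kinetics(
    anchor_low: tuple[float, float, float] = defaults.ANCHOR_LOW,
    anchor_high: tuple[float, float, float] = defaults.ANCHOR_HIGH,
    gas_constant: float = defaults.GAS_CONSTANT,
) -> KineticsParams:
    """Fit (A, Ea) exactly through two stability anchors.

    Each anchor is ``(temp degC, remaining fraction, days)``. The implied
    rate constants ``k_i = -ln(f_i)/days_i`` determine

        Ea = R * ln(k2/k1) / (1/T1 - 1/T2),   A = k1 * exp(Ea / (R T1))

    which is the unique first-order Arrhenius pair reproducing both anchors.
    """
    (t1_c, f1, d1), (t2_c, f2, d2) = anchor_low, anchor_high
    for frac in (f1, f2):
        if not 0 < frac < 1:
            raise CalibrationError(f"anchor fractions must lie in (0, 1), got {frac}")
    for days in (d1, d2):
        if days <= 0:
            raise CalibrationError(f"anchor durations must be positive, got {days}")
    if t1_c == t2_c:
        raise CalibrationError("anchor temperatures must be distinct")
    t1 = _validate_temperature(t1_c) - _ABSOLUTE_ZERO_C
    t2 = _validate_temperature(t2_c) - _ABSOLUTE_ZERO_C
    k1 = -math.log(f1) / d1
    k2 = -math.log(f2) / d2
    ea = gas_constant * math.log(k2 / k1) / (1.0 / t1 - 1.0 / t2)
    if ea < 0:
        raise CalibrationError(
            "anchors imply a rate that decreases with temperature; check their order"
        )
    a = k1 * math.exp(ea / (gas_constant * t1))
    return KineticsParams(arrhenius_a=a, activation_energy=ea, gas_constant=gas_constant)


def dose_multiplier(strength: float, bands: StrengthBands | None = None) -> int | None:
    """Vials needed per patient at this strength: 1, 2, 3, or None if non-viable."""
    bands = bands or StrengthBands()
    if strength >= bands.full_min:
        return 1
    if strength >= bands.double_min:
        return 2
    if strength >= bands.triple_min:
        return 3
    return None


def effective_doses(stock: int, strength: float, bands: StrengthBands | None = None) -> int:
    """Patient-treatments obtainable from ``stock`` vials at ``strength``.

    Full-strength stock counts vial-for-vial; weakened stock is divided by
    the banded multiplier and floored (vials are physical units); stock
    below the viability floor counts zero.
    """
    if stock < 0:
        raise InvalidInputError(f"stock must be non-negative, got {stock}")
    if not 0 <= strength <= 1:
        raise InvalidInputError(f"strength must be in [0, 1], got {strength}")
    mult = dose_multiplier(strength, bands)
    if mult is None:
        return 0
    return int(stock) // mult


def stability_table(
    temps_c: Sequence[float],
    days_grid: Sequence[float],
    params: KineticsParams,
    mode: str = "exponential",
) -> pd.DataFrame:
    """Remaining-strength table over a temperature x duration grid."""
    rows = [
        (t, d, remaining_strength(1.0, t, d, params, mode=mode))
        for t in temps_c
        for d in days_grid
    ]
    return pd.DataFrame(rows, columns=["temp_c", "days", "strength"])
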