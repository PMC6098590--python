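"""Synthetic temperature-log generation.

Zanzibar ambient temperatures follow a mild seasonal cycle; storage logs
are emulated as a sinusoid around an annual mean plus optional Gaussian
week-to-week noise. Fixtures are deterministic for a fixed seed and are
written in the standard ``week,temp_c`` CSV layout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import defaults
from .errors import InvalidInputError
from .kinetics import TemperatureProfile

__all__ = ["FixtureSpec", "generate_temperature_fixture"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic seasonal temperature log."""

    mean_c: float = 27.0
    amplitude_c: float = 0.0
    noise_sd_c: float = 0.0
    weeks: int = defaults.WEEKS_PER_YEAR
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_c < 0:
            raise InvalidInputError(f"amplitude_c must be >= 0, got {self.amplitude_c}")
        if self.noise_sd_c < 0:
            raise InvalidInputError(f"noise_sd_c must be >= 0, got {self.noise_sd_c}")
        if self.weeks < 1:
            raise InvalidInputError(f"weeks must be >= 1, got {self.weeks}")


def generate_temperature_fixture(spec: FixtureSpec) -> TemperatureProfile:
    """T(w) = mean + amplitude*sin(2*pi*w/52) + N(0, sd), seeded."""
    rng = np.random.default_rng(spec.seed)
    weeks = np.arange(spec.weeks)
    temps = (
        spec.mean_c
        + spec.amplitude_c * np.sin(2.0 * math.pi * weeks / defaults.WEEKS_PER_YEAR)
        + (rng.normal(0.0, spec.noise_sd_c, size=spec.weeks) if spec.noise_sd_c > 0 else 0.0)
    )
    return TemperatureProfile(weeks=tuple(int(w) for w in weeks), temps_c=tuple(map(float, temps)))
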