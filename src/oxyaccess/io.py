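"""CSV writers with a stable column order and reproducible formatting.

Floats are rendered at 6 significant digits so re-running the same
configuration produces byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import InvalidInputError
from .inventory import SimulationResult
from .kinetics import TemperatureProfile

__all__ = [
    "write_weekly_csv",
    "write_trajectory_csv",
    "write_temperature_csv",
    "read_temperature_csv",
    "write_frame_csv",
]

_FLOAT_FORMAT = "%.6g"


def write_frame_csv(frame: pd.DataFrame, path: str | Path, columns: list[str]) -> None:
    missing = set(columns) - set(frame.columns)
    if missing:
        raise InvalidInputError(f"frame is missing columns: {sorted(missing)}")
    frame.to_csv(path, index=False, columns=columns, float_format=_FLOAT_FORMAT)


def write_weekly_csv(result: SimulationResult, path: str | Path) -> None:
    """Weekly series: ``week,effective_doses,forward_demand,access_ratio,consumed,shortfall``."""
    write_frame_csv(
        result.to_frame(),
        path,
        ["week", "effective_doses", "forward_demand", "access_ratio", "consumed", "shortfall"],
    )


def write_trajectory_csv(frame: pd.DataFrame, path: str | Path) -> None:
    """Per-year scenario series: ``year,births,p_access`` plus the computed column."""
    value_cols = [c for c in ("required_supply", "access_ratio") if c in frame.columns]
    write_frame_csv(frame, path, ["year", "births", "p_access", *value_cols])


def write_temperature_csv(profile: TemperatureProfile, path: str | Path) -> None:
    write_frame_csv(profile.to_frame(), path, ["week", "temp_c"])


def read_temperature_csv(path: str | Path) -> TemperatureProfile:
    return TemperatureProfile.from_csv(path)
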