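"""Time units for rate constants and sampling schedules.

Every parameter set and release curve carries its time unit as metadata;
mixing units in arithmetic is an error, and conversions are explicit.
"""

from __future__ import annotations

from enum import Enum

import numpy as np

__all__ = ["TimeUnit", "convert_times", "convert_rate"]

_MINUTES_PER = {"minute": 1.0, "hour": 60.0, "day": 1440.0}


class TimeUnit(str, Enum):
    """Unit of the time axis (and hence of first-order rate constants)."""

    MINUTE = "minute"
    HOUR = "hour"
    DAY = "day"

    @property
    def minutes(self) -> float:
        """Length of one unit, in minutes."""
        return _MINUTES_PER[self.value]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def convert_times(values, from_unit: TimeUnit, to_unit: TimeUnit):
    """Convert time values between units (scalar or array)."""
    from_unit, to_unit = TimeUnit(from_unit), TimeUnit(to_unit)
    factor = from_unit.minutes / to_unit.minutes
    return np.asarray(values, dtype=float) * factor


def convert_rate(value: float, from_unit: TimeUnit, to_unit: TimeUnit) -> float:
    """Convert a first-order rate constant (1/time) between time units."""
    from_unit, to_unit = TimeUnit(from_unit), TimeUnit(to_unit)
    return float(value) * to_unit.minutes / from_unit.minutes
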