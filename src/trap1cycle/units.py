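"""Time-unit bookkeeping.

Every kinetic trace and rate constant in this package carries an explicit
time unit; conversions are always explicit operations, never implicit.
"""

from __future__ import annotations

#: seconds per unit
TIME_UNITS: dict[str, float] = {
    "s": 1.0,
    "min": 60.0,
    "hr": 3600.0,
    "day": 86400.0,
}


def check_time_unit(unit: str) -> str:
    if unit not in TIME_UNITS:
        raise ValueError(f"unknown time unit {unit!r}; expected one of {sorted(TIME_UNITS)}")
    return unit


def convert_time(value, from_unit: str, to_unit: str):
    """Convert a time (or array of times) between units."""
    check_time_unit(from_unit)
    check_time_unit(to_unit)
    return value * (TIME_UNITS[from_unit] / TIME_UNITS[to_unit])


def convert_rate(value, from_unit: str, to_unit: str):
    """Convert a first-order rate constant between per-`from_unit` and per-`to_unit`."""
    check_time_unit(from_unit)
    check_time_unit(to_unit)
    return value * (TIME_UNITS[to_unit] / TIME_UNITS[from_unit])
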