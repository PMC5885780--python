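"""Time-unit parsing and formatting helpers.

Internally every time is a float in seconds (SI).  Human-facing interfaces
(scheme configs, CLI output) use ps/ns/us/ms/s suffixes; ``us`` and the
unicode ``μs``/``µs`` are equivalent.
"""

from __future__ import annotations

import re

TIME_UNITS: dict[str, float] = {
    "ps": 1e-12,
    "ns": 1e-9,
    "us": 1e-6,
    "μs": 1e-6,  # μs (greek mu)
    "µs": 1e-6,  # µs (micro sign)
    "ms": 1e-3,
    "s": 1.0,
}

_TIME_RE = re.compile(
    r"^\s*([+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?)\s*"
    r"(ps|ns|us|μs|µs|ms|s)\s*$"
)


def parse_time(text: str) -> float:
    """Parse a time like ``'350ps'``, ``'1.1 ms'`` or ``'6.3e-1s'`` to seconds."""
    m = _TIME_RE.match(text)
    if m is None:
        raise ValueError(f"cannot parse time value {text!r} (expected <number><ps|ns|us|ms|s>)")
    return float(m.group(1)) * TIME_UNITS[m.group(2)]


def format_time(seconds: float, unit: str | None = None, precision: int = 17) -> str:
    """Format seconds with a unit suffix.

    With ``unit=None`` a natural unit is chosen from the magnitude; use
    ``precision=17`` (default) for lossless round-trips through ``parse_time``.
    """
    if unit is None:
        a = abs(seconds)
        if a == 0.0:
            unit = "s"
        elif a < 1e-9:
            unit = "ps"
        elif a < 1e-6:
            unit = "ns"
        elif a < 1e-3:
            unit = "us"
        elif a < 1.0:
            unit = "ms"
        else:
            unit = "s"
    if unit not in TIME_UNITS:
        raise ValueError(f"unknown time unit {unit!r}")
    return f"{seconds / TIME_UNITS[unit]:.{precision}g}{unit}"
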