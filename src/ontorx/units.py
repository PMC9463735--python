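"""Dose units and administration frequencies.

Daily-dose arithmetic needs two normalisations: converting a prescribed
dose into the unit a criterion is expressed in, and converting a dosing
frequency into administrations per 24 h.  Units carry a physical
dimension (mass, volume, biological activity); conversion is only
defined within a dimension — a volume dose checked against a mass
criterion is a *unit mismatch* and the corresponding check is skipped,
never silently coerced.

Base units per dimension: mg (mass), mL (volume), IU (biological
activity).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from fractions import Fraction


class UnitError(ValueError):
    """Unknown unit symbol or conversion across dimensions."""


class UnitMismatchError(UnitError):
    """Conversion requested between units of different dimensions."""


@dataclass(frozen=True)
class Unit:
    """A dose unit with a fixed factor to its dimension's base unit."""

    symbol: str
    dimension: str  # 'mass' | 'volume' | 'biological-activity'
    factor_to_base: float

    def __post_init__(self) -> None:
        if self.factor_to_base <= 0:
            raise UnitError(f"factor_to_base must be positive: {self.symbol}")


#: Units supported at launch.  Keys include common ASCII aliases.
UNITS: dict[str, Unit] = {}


def _register(unit: Unit, *aliases: str) -> None:
    UNITS[unit.symbol] = unit
    for alias in aliases:
        UNITS[alias] = unit


_register(Unit("mg", "mass", 1.0))
_register(Unit("g", "mass", 1000.0))
_register(Unit("µg", "mass", 0.001), "mcg", "ug")
_register(Unit("mL", "volume", 1.0), "ml")
_register(Unit("IU", "biological-activity", 1.0), "UI")


def get_unit(symbol: str) -> Unit:
    try:
        return UNITS[symbol]
    except KeyError:
        raise UnitError(f"unknown unit symbol: {symbol!r}") from None


def convert(value: float, from_unit: str | Unit, to_unit: str | Unit) -> float:
    """Convert ``value`` between two units of the same dimension."""
    src = get_unit(from_unit) if isinstance(from_unit, str) else from_unit
    dst = get_unit(to_unit) if isinstance(to_unit, str) else to_unit
    if src.dimension != dst.dimension:
        raise UnitMismatchError(
            f"cannot convert {src.symbol} ({src.dimension}) "
            f"to {dst.symbol} ({dst.dimension})"
        )
    return value * src.factor_to_base / dst.factor_to_base


@dataclass(frozen=True)
class Frequency:
    """A dosing frequency normalised to administrations per 24 h.

    ``every N h`` labels satisfy administrations_per_24h == 24/N; the
    base frequency is one administration every 24 h.
    """

    label: str
    administrations_per_24h: float

    def __post_init__(self) -> None:
        if self.administrations_per_24h <= 0:
            raise ValueError("administrations_per_24h must be positive")


_EVERY_N_H = re.compile(r"^\s*every\s+(\d+(?:\.\d+)?)\s*h(?:ours?)?\s*$", re.I)
_N_TIMES_DAILY = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*times\s+daily\s*$", re.I)
_QNH = re.compile(r"^\s*q\s*(\d+(?:\.\d+)?)\s*h\s*$", re.I)


def parse_frequency(text: str | float | int | Frequency) -> Frequency:
    """Parse a frequency from the accepted dialects.

    Accepted forms: ``"every N h"`` / ``"qNh"`` (24/N per day),
    ``"N times daily"``, or an explicit numeric administrations/24 h.
    PRN is *not* a frequency — it is a flag on the prescription.
    """
    if isinstance(text, Frequency):
        return text
    if isinstance(text, (int, float)):
        return Frequency(label=f"{text}/24 h", administrations_per_24h=float(text))
    m = _EVERY_N_H.match(text) or _QNH.match(text)
    if m:
        hours = float(m.group(1))
        if hours <= 0:
            raise ValueError(f"non-positive interval in frequency: {text!r}")
        per_day = float(Fraction(24) / Fraction(str(m.group(1))))
        return Frequency(label=text.strip(), administrations_per_24h=per_day)
    m = _N_TIMES_DAILY.match(text)
    if m:
        return Frequency(label=text.strip(), administrations_per_24h=float(m.group(1)))
    try:
        return Frequency(label=text.strip(), administrations_per_24h=float(text))
    except ValueError:
        raise ValueError(f"unparseable frequency: {text!r}") from None
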