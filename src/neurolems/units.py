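"""Dimensions, units and dimensional quantities.

LEMS (and hence NeuroML v2) makes every parameter and state variable a
dimensional quantity: a magnitude plus a unit whose dimension is declared
over the seven SI base dimensions.  Implementations are expected to check
units and convert everything to one consistent internal system before any
arithmetic happens.  This module is that machinery: quantities parse from
their text form (``"-65mV"``, ``"0.3"``), convert to SI, and dimension-check
against a registry of curated dimensions and units.

All units in scope are pure powers of ten relative to the SI unit of their
dimension (no offset units such as degrees Celsius); that covers every unit
used by the NeuroML core types.  Unknown unit symbols fail hard rather than
being treated as dimensionless -- silently dropping a unit is exactly the
class of simulator bug this layer exists to prevent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import ParseError, UnitError

__all__ = [
    "Dimension",
    "Unit",
    "Quantity",
    "UnitRegistry",
    "builtin_registry",
    "parse_quantity",
    "check_dimension",
    "format_quantity",
]

#: Name of the dimensionless "dimension".
DIMENSIONLESS = "none"


@dataclass(frozen=True)
class Dimension:
    """Integer exponents over the 7 SI base dimensions.

    Attributes follow the LEMS single-letter convention:
    ``m`` mass, ``l`` length, ``t`` time, ``i`` current, ``k`` temperature,
    ``n`` amount of substance, ``j`` luminous intensity.
    """

    name: str
    m: int = 0
    l: int = 0
    t: int = 0
    i: int = 0
    k: int = 0
    n: int = 0
    j: int = 0

    def exponents(self) -> tuple[int, ...]:
        return (self.m, self.l, self.t, self.i, self.k, self.n, self.j)


@dataclass(frozen=True)
class Unit:
    """A named scale for a dimension: ``10**power`` times the SI unit."""

    symbol: str
    dimension: str
    power: int


@dataclass(frozen=True)
class Quantity:
    """Magnitude + unit symbol (``None`` = dimensionless) + derived SI value."""

    magnitude: float
    unit: str | None
    si_value: float


class UnitRegistry:
    """Holds the dimension and unit tables that documents resolve against."""

    def __init__(self):
        self.dimensions: dict[str, Dimension] = {
            DIMENSIONLESS: Dimension(DIMENSIONLESS)
        }
        self.units: dict[str, Unit] = {}

    def add_dimension(self, dim: Dimension) -> None:
        self.dimensions[dim.name] = dim

    def add_unit(self, unit: Unit) -> None:
        if unit.dimension not in self.dimensions:
            raise UnitError(
                f"unit {unit.symbol!r} refers to unknown dimension {unit.dimension!r}"
            )
        self.units[unit.symbol] = unit

    def dimension_of(self, unit_symbol: str | None) -> Dimension:
        if unit_symbol is None:
            return self.dimensions[DIMENSIONLESS]
        try:
            unit = self.units[unit_symbol]
        except KeyError:
            raise UnitError(f"unknown unit symbol {unit_symbol!r}") from None
        return self.dimensions[unit.dimension]

    def copy(self) -> "UnitRegistry":
        reg = UnitRegistry()
        reg.dimensions.update(self.dimensions)
        reg.units.update(self.units)
        return reg


# Curated tables mirroring the NeuroML core-type conventions.  The paper does
# not enumerate them; this is the minimal set those core types assume, plus a
# few convenience symbols.
_DIMENSIONS = [
    Dimension("voltage", m=1, l=2, t=-3, i=-1),
    Dimension("time", t=1),
    Dimension("per_time", t=-1),
    Dimension("capacitance", m=-1, l=-2, t=4, i=2),
    Dimension("conductance", m=-1, l=-2, t=3, i=2),
    Dimension("conductanceDensity", m=-1, l=-4, t=3, i=2),
    Dimension("resistance", m=1, l=2, t=-3, i=-2),
    Dimension("current", i=1),
    Dimension("length", l=1),
    Dimension("area", l=2),
    Dimension("volume", l=3),
]

_UNITS = [
    ("V", "voltage", 0),
    ("mV", "voltage", -3),
    ("s", "time", 0),
    ("ms", "time", -3),
    ("us", "time", -6),
    ("per_s", "per_time", 0),
    ("per_ms", "per_time", 3),
    ("Hz", "per_time", 0),
    ("F", "capacitance", 0),
    ("uF", "capacitance", -6),
    ("nF", "capacitance", -9),
    ("pF", "capacitance", -12),
    ("S", "conductance", 0),
    ("mS", "conductance", -3),
    ("uS", "conductance", -6),
    ("nS", "conductance", -9),
    ("pS", "conductance", -12),
    ("S_per_m2", "conductanceDensity", 0),
    ("mS_per_cm2", "conductanceDensity", 1),
    ("ohm", "resistance", 0),
    ("kohm", "resistance", 3),
    ("Mohm", "resistance", 6),
    ("A", "current", 0),
    ("mA", "current", -3),
    ("uA", "current", -6),
    ("nA", "current", -9),
    ("pA", "current", -12),
    ("m", "length", 0),
    ("cm", "length", -2),
    ("um", "length", -6),
    ("m2", "area", 0),
    ("cm2", "area", -4),
    ("um2", "area", -12),
    ("m3", "volume", 0),
    ("cm3", "volume", -6),
    ("um3", "volume", -18),
]


def builtin_registry() -> UnitRegistry:
    """Return a fresh registry holding the curated dimension/unit tables."""
    reg = UnitRegistry()
    for dim in _DIMENSIONS:
        reg.add_dimension(dim)
    for symbol, dim, power in _UNITS:
        reg.add_unit(Unit(symbol, dim, power))
    return reg


_QUANTITY_RE = re.compile(
    r"""^\s*
        (?P<number>[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?)
        \s*
        (?P<unit>[A-Za-z_][A-Za-z_0-9]*)?
        \s*$""",
    re.VERBOSE,
)


def parse_quantity(text: str, registry: UnitRegistry) -> Quantity:
    """Parse ``"<number>[<unit>]"`` into a :class:`Quantity` with SI value.

    Bare numbers are dimensionless.  Whitespace between number and symbol is
    optional (``"0.07 per_ms"`` and ``"0.07per_ms"`` are equivalent).
    """
    if not isinstance(text, str):
        raise ParseError(f"quantity must be text, got {type(text).__name__}")
    match = _QUANTITY_RE.match(text)
    if match is None:
        raise ParseError(f"malformed quantity {text!r}")
    magnitude = float(match.group("number"))
    symbol = match.group("unit")
    if symbol is None:
        return Quantity(magnitude, None, magnitude)
    if symbol not in registry.units:
        raise UnitError(f"unknown unit symbol {symbol!r} in {text!r}")
    unit = registry.units[symbol]
    return Quantity(magnitude, symbol, magnitude * 10.0 ** unit.power)


def check_dimension(q: Quantity, expected: str, registry: UnitRegistry) -> bool:
    """True iff ``q``'s unit carries dimension ``expected``.

    A dimensionless quantity matches only the dimension named ``"none"``.
    Dimensions are compared by their base-dimension exponents, so aliases
    with identical exponents are interchangeable.  Pure predicate: never
    raises for a registered ``expected`` name.
    """
    expected_dim = registry.dimensions.get(expected)
    if expected_dim is None:
        return False
    if q.unit is None:
        return expected_dim.exponents() == (0,) * 7
    unit = registry.units.get(q.unit)
    if unit is None:
        return False
    actual = registry.dimensions.get(unit.dimension)
    return actual is not None and actual.exponents() == expected_dim.exponents()


def _format_magnitude(value: float) -> str:
    text = repr(float(value))
    if text.endswith(".0"):
        text = text[:-2]
    return text


def format_quantity(q: Quantity) -> str:
    """Canonical text form: no space between number and symbol (``-65mV``)."""
    if q.unit is None:
        return _format_magnitude(q.magnitude)
    return f"{_format_magnitude(q.magnitude)}{q.unit}"
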