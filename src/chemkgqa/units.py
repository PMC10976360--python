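"""SI unit conversion for physical quantities mentioned in questions.

The knowledge graph stores quantities in SI units, while users phrase
questions in whatever unit system they prefer ("boiling point between 100
and 120 °C").  Every number+unit mention is rewritten to its SI
equivalent before translation; shared-unit ranges convert both numbers.
Units are assumed dimensionally valid for the quantity they qualify.
All conversions are affine, ``si = scale * x + offset``, so they invert
exactly.

The shipped lexicon covers temperature (°C, °F, K) and pressure
(atm, bar, mmHg, Torr, kPa, MPa); it is a plain mapping, extensible via
configuration.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .generator import format_number

__all__ = [
    "UnitEntry",
    "Conversion",
    "PreprocessedQuestion",
    "DEFAULT_LEXICON",
    "convert_units",
    "to_si",
    "from_si",
]


@dataclass(frozen=True)
class UnitEntry:
    """Affine conversion of one unit surface form to its SI target."""

    dimension: str
    scale: float
    offset: float
    si_symbol: str


def to_si(value: float, entry: UnitEntry) -> float:
    return entry.scale * value + entry.offset


def from_si(si_value: float, entry: UnitEntry) -> float:
    return (si_value - entry.offset) / entry.scale


_F_SCALE = 5.0 / 9.0
_F_OFFSET = 459.67 * 5.0 / 9.0
_MMHG = 101325.0 / 760.0

DEFAULT_LEXICON: dict[str, UnitEntry] = {
    # temperature -> K
    "°C": UnitEntry("temperature", 1.0, 273.15, "K"),
    "degrees Celsius": UnitEntry("temperature", 1.0, 273.15, "K"),
    "degree Celsius": UnitEntry("temperature", 1.0, 273.15, "K"),
    "Celsius": UnitEntry("temperature", 1.0, 273.15, "K"),
    "°F": UnitEntry("temperature", _F_SCALE, _F_OFFSET, "K"),
    "degrees Fahrenheit": UnitEntry("temperature", _F_SCALE, _F_OFFSET, "K"),
    "degree Fahrenheit": UnitEntry("temperature", _F_SCALE, _F_OFFSET, "K"),
    "Fahrenheit": UnitEntry("temperature", _F_SCALE, _F_OFFSET, "K"),
    "Kelvin": UnitEntry("temperature", 1.0, 0.0, "K"),
    "K": UnitEntry("temperature", 1.0, 0.0, "K"),
    # pressure -> Pa
    "atm": UnitEntry("pressure", 101325.0, 0.0, "Pa"),
    "bar": UnitEntry("pressure", 1e5, 0.0, "Pa"),
    "mbar": UnitEntry("pressure", 100.0, 0.0, "Pa"),
    "mmHg": UnitEntry("pressure", _MMHG, 0.0, "Pa"),
    "Torr": UnitEntry("pressure", _MMHG, 0.0, "Pa"),
    "kPa": UnitEntry("pressure", 1000.0, 0.0, "Pa"),
    "MPa": UnitEntry("pressure", 1e6, 0.0, "Pa"),
    "Pa": UnitEntry("pressure", 1.0, 0.0, "Pa"),
}


@dataclass(frozen=True)
class Conversion:
    original: str
    converted: str
    dimension: str


@dataclass(frozen=True)
class PreprocessedQuestion:
    """A question after preprocessing (SI rewrite, optionally prompted)."""

    text: str
    conversions: tuple[Conversion, ...]
    original: str


_NUM = r"-?\d+(?:\.\d+)?"


def _unit_alternation(lexicon: dict[str, UnitEntry]) -> str:
    surfaces = sorted(lexicon, key=len, reverse=True)
    return "|".join(re.escape(s) for s in surfaces)


def convert_units(
    question: str, lexicon: dict[str, UnitEntry] | None = None
) -> PreprocessedQuestion:
    """Rewrite every number+unit mention to SI (prompt not yet prepended).

    Unknown units pass through unchanged; text without quantities is
    returned untouched with an empty conversion list.
    """
    if not question:
        raise ValueError("empty question")
    lex = lexicon if lexicon is not None else DEFAULT_LEXICON
    units = _unit_alternation(lex)
    conversions: list[Conversion] = []

    def _convert_one(value: str, entry: UnitEntry) -> str:
        return format_number(to_si(float(value), entry))

    def _sub_range(m: re.Match) -> str:
        entry = lex[m.group(3)]
        repl = (
            f"between {_convert_one(m.group(1), entry)} "
            f"and {_convert_one(m.group(2), entry)} {entry.si_symbol}"
        )
        if repl != m.group(0):
            conversions.append(Conversion(m.group(0), repl, entry.dimension))
            return repl
        return m.group(0)

    def _sub_single(m: re.Match) -> str:
        entry = lex[m.group(2)]
        repl = f"{_convert_one(m.group(1), entry)} {entry.si_symbol}"
        if repl != m.group(0):
            conversions.append(Conversion(m.group(0), repl, entry.dimension))
            return repl
        return m.group(0)

    text = re.sub(
        rf"between\s+({_NUM})\s+and\s+({_NUM})\s*({units})\b",
        _sub_range,
        question,
    )
    text = re.sub(rf"({_NUM})\s*({units})\b", _sub_single, text)
    return PreprocessedQuestion(
        text=text, conversions=tuple(conversions), original=question
    )
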