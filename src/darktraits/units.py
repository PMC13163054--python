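"""Numeric cleaning and dimensional routing of historical unit strings.

A century of respirometry literature records oxygen consumption in wildly
mixed dialects: ``cc O2`` for ``mL O2``, per-gram versus per-kilogram
normalization, per-minute versus per-hour rates, mass- versus whole-body
forms.  This module cleans raw numeric strings (confidence intervals,
parenthetical annotations, unicode minus signs, thousands separators) and
parses unit strings against a *closed* token table, routing each value to a
canonical intermediate unit:

===============  =========================
quantity kind    canonical unit
===============  =========================
oxygen_rate      mL O2 kg^-1 h^-1 (mass-specific) or mL O2 h^-1 (whole-body)
mass             kg
volume           mL
temperature      degC
===============  =========================

Unknown tokens always raise :class:`~darktraits.errors.UnknownUnit`; the
parser never guesses.  The dialect table ships as an editable TSV
(``data/unit_tokens.tsv``) and can be replaced via :func:`load_unit_table`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .errors import (
    AmbiguousUnit,
    ImplausibleTemperature,
    MissingBodyMass,
    NonPositiveMass,
    NonPositiveValue,
    UnknownUnit,
    UnparsableNumber,
)

# --------------------------------------------------------------------------
# dialect table
# --------------------------------------------------------------------------


def load_unit_table(path: str | Path | None = None) -> dict[str, tuple[str, float]]:
    """Load the token -> (kind, factor) dialect table.

    ``kind`` is one of {volume, mass, time, oxygen, temperature}; ``factor``
    converts one unit of the token to the kind's canonical unit (mL, kg,
    hours).  With no path, the table shipped with the package is used.
    """
    if path is None:
        text = (resources.files("darktraits") / "data/unit_tokens.tsv").read_text(
            encoding="utf-8"
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    table: dict[str, tuple[str, float]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        token, kind, factor = line.split("\t")
        table[token] = (kind, float(factor))
    return table


_TABLE = load_unit_table()

# --------------------------------------------------------------------------
# numeric cleaning
# --------------------------------------------------------------------------

_SUPERSCRIPT = str.maketrans("⁻⁰¹²³⁴⁵⁶⁷⁸⁹", "-0123456789")
_PAREN_RE = re.compile(r"\([^()]*\)|\[[^\[\]]*\]")
_PM_RE = re.compile(r"(?:±|\+/-|\+-).*$")
_THOUSANDS_RE = re.compile(r"(?<=\d),(?=\d{3}(?:\D|$))")
_RANGE_RE = re.compile(
    r"^[-+]?(?:\d+\.?\d*|\.\d+)\s*(?:-|–|—|\bto\b)\s*[-+]?(?:\d+\.?\d*|\.\d+)$"
)
_NUMBER_RE = re.compile(r"[-+]?(?:\d+\.?\d*|\.\d+)(?:[eE][-+]?\d+)?")


@dataclass(frozen=True)
class CleanNumber:
    """A point estimate recovered from a raw value string."""

    value: float
    stripped_annotations: tuple[str, ...] = ()

    @property
    def was_modified(self) -> bool:
        return bool(self.stripped_annotations)


def clean_numeric(raw: str) -> CleanNumber:
    """Extract the leading point estimate from a raw numeric string.

    Cleaning applies in fixed order: unicode minus / whitespace
    normalization, parenthetical removal, ``± tail`` removal, thousands
    separator removal.  A bare range (``"11.0–14.0"``) with no leading point
    estimate is rejected rather than averaged: conservative handling keeps
    only values an author actually printed as estimates.

    Raises
    ------
    UnparsableNumber
        If no numeric token survives, or the string is a bare range.
    """
    if not raw or not raw.strip():
        raise UnparsableNumber("empty value string")
    annotations: list[str] = []

    s = raw.translate(_SUPERSCRIPT).replace("−", "-").replace("\xa0", " ")
    s = re.sub(r"\s+", " ", s).strip()

    def _strip(pattern: re.Pattern[str], text: str) -> str:
        for frag in pattern.findall(text):
            if frag.strip():
                annotations.append(frag.strip())
        return pattern.sub("", text)

    s = _strip(_PAREN_RE, s)
    m = _PM_RE.search(s)
    if m and m.group(0).strip():
        annotations.append(m.group(0).strip())
        s = _PM_RE.sub("", s)
    if _THOUSANDS_RE.search(s):
        annotations.append(",")
        s = _THOUSANDS_RE.sub("", s)
    s = s.strip()

    if _RANGE_RE.match(s):
        raise UnparsableNumber(f"bare range with no point estimate: {raw!r}")
    m = _NUMBER_RE.search(s)
    if m is None:
        raise UnparsableNumber(f"no numeric token in {raw!r}")
    value = float(m.group(0))
    if value != value or value in (float("inf"), float("-inf")):
        raise UnparsableNumber(f"non-finite value in {raw!r}")
    return CleanNumber(value=value, stripped_annotations=tuple(annotations))


# --------------------------------------------------------------------------
# unit parsing
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class UnitDimension:
    """Dimensional signature of a parsed unit string."""

    quantity_kind: str  # oxygen_rate | mass | volume | temperature
    mass_exponent: int = 0
    time_exponent: int = 0
    scale_to_canonical: float = 1.0
    is_mass_specific: bool = False

    def __post_init__(self) -> None:
        if self.scale_to_canonical <= 0:
            raise ValueError("scale_to_canonical must be positive")
        if self.quantity_kind == "oxygen_rate" and self.time_exponent != -1:
            raise ValueError("oxygen_rate requires a time dimension")
        if self.is_mass_specific != (self.mass_exponent == -1):
            raise ValueError("is_mass_specific must mirror mass_exponent == -1")


_WORD_RE = re.compile(r"(/)|°?([a-zµ]+)\s*\^?(-?\d+)?")


def _tokenize(unit_string: str) -> list[tuple[str, int]]:
    s = unit_string.translate(_SUPERSCRIPT).replace("−", "-").lower()
    s = s.replace("·", " ").replace("*", " ").replace("℃", "c")
    tokens: list[tuple[str, int]] = []
    pending_div = False
    for m in _WORD_RE.finditer(s):
        if m.group(1):
            pending_div = True
            continue
        name, exp_s = m.group(2), m.group(3)
        if name == "per":
            pending_div = True
            continue
        exp = int(exp_s) if exp_s else 1
        # cubic-length and O2 tokens carry their digits in the token name
        if (name, exp) in (("cm", 3), ("mm", 3)):
            name, exp = name + "3", 1
        if (name, exp) == ("o", 2):
            name, exp = "o2", 1
        if pending_div:
            exp = -abs(exp)
            pending_div = False
        tokens.append((name, exp))
    if not tokens:
        raise UnknownUnit(f"no unit tokens in {unit_string!r}")
    return tokens


def parse_unit(
    unit_string: str, table: dict[str, tuple[str, float]] | None = None
) -> UnitDimension:
    """Parse a heterogeneous unit string into its dimensional signature.

    Dialects are recognized case-insensitively; exponent notations
    ``g-1``, ``g⁻¹``, ``/g`` and ``per g`` are equivalent.  The presence of
    an O2 marker routes the string to ``oxygen_rate``; the mass and time
    dimensions then decide mass-specific versus whole-body form.

    Raises
    ------
    UnknownUnit
        For any token outside the dialect table, or an unsupported
        dimensional combination.
    AmbiguousUnit
        For an oxygen quantity with no time dimension (cannot be a rate).
    """
    table = _TABLE if table is None else table
    tokens = _tokenize(unit_string)

    kinds: dict[str, list[tuple[str, int, float]]] = {}
    for name, exp in tokens:
        if name not in table:
            raise UnknownUnit(f"unknown unit token {name!r} in {unit_string!r}")
        kind, factor = table[name]
        kinds.setdefault(kind, []).append((name, exp, factor))

    if "oxygen" in kinds:
        vols = kinds.get("volume", [])
        masses = kinds.get("mass", [])
        times = kinds.get("time", [])
        if len(vols) != 1 or vols[0][1] != 1:
            raise UnknownUnit(
                f"oxygen rate needs exactly one volume unit: {unit_string!r}"
            )
        if not times:
            raise AmbiguousUnit(
                f"oxygen quantity with no time dimension: {unit_string!r}"
            )
        if len(times) != 1 or times[0][1] != -1:
            raise UnknownUnit(f"unsupported time exponent in {unit_string!r}")
        if masses and (len(masses) != 1 or masses[0][1] != -1):
            raise UnknownUnit(f"unsupported mass exponent in {unit_string!r}")
        if "temperature" in kinds:
            raise UnknownUnit(f"mixed dimensions in {unit_string!r}")
        scale = vols[0][2] / times[0][2]
        mass_exp = 0
        if masses:
            scale /= masses[0][2]
            mass_exp = -1
        return UnitDimension(
            quantity_kind="oxygen_rate",
            mass_exponent=mass_exp,
            time_exponent=-1,
            scale_to_canonical=scale,
            is_mass_specific=mass_exp == -1,
        )

    if set(kinds) == {"mass"} and len(kinds["mass"]) == 1 and kinds["mass"][0][1] == 1:
        return UnitDimension("mass", scale_to_canonical=kinds["mass"][0][2])
    if (
        set(kinds) == {"volume"}
        and len(kinds["volume"]) == 1
        and kinds["volume"][0][1] == 1
    ):
        return UnitDimension("volume", scale_to_canonical=kinds["volume"][0][2])
    if set(kinds) == {"temperature"} and len(kinds["temperature"]) == 1:
        return UnitDimension("temperature", scale_to_canonical=1.0)
    raise UnknownUnit(f"unsupported unit combination: {unit_string!r}")


# --------------------------------------------------------------------------
# normalizers
# --------------------------------------------------------------------------


def standardize_vo2(
    value: float, dim: UnitDimension, body_mass_kg: float | None = None
) -> tuple[float, str]:
    """Align an oxygen consumption value to mL O2 kg^-1 h^-1.

    Mass-specific inputs rescale directly; whole-body inputs divide by body
    mass.  Returns the standardized value and the detected source form
    (``"mass_specific"`` or ``"whole_body"``).
    """
    if dim.quantity_kind != "oxygen_rate":
        raise UnknownUnit(f"not an oxygen rate: {dim.quantity_kind}")
    if value < 0:
        raise NonPositiveValue(f"negative oxygen consumption: {value}")
    if dim.is_mass_specific:
        return value * dim.scale_to_canonical, "mass_specific"
    if body_mass_kg is None:
        raise MissingBodyMass(
            "whole-body oxygen rate requires body mass for normalization"
        )
    if body_mass_kg <= 0:
        raise NonPositiveMass(f"body mass must be positive, got {body_mass_kg}")
    return value * dim.scale_to_canonical / body_mass_kg, "whole_body"


def normalize_mass(value: float, unit_string: str) -> float:
    """Convert a mass in any supported unit to kilograms."""
    if value <= 0:
        raise NonPositiveValue(f"mass must be positive, got {value}")
    dim = parse_unit(unit_string)
    if dim.quantity_kind != "mass":
        raise UnknownUnit(f"not a mass unit: {unit_string!r}")
    return value * dim.scale_to_canonical


def normalize_brain(
    value: float, unit_string: str, density_g_per_ml: float = 1.036
) -> float:
    """Normalize a brain size (mass or volume unit) to millilitres.

    Volume units convert by metric scale; mass units convert through the
    configured tissue density (volume = mass / density).
    """
    if value <= 0:
        raise NonPositiveValue(f"brain size must be positive, got {value}")
    if density_g_per_ml <= 0:
        raise NonPositiveValue("tissue density must be positive")
    dim = parse_unit(unit_string)
    if dim.quantity_kind == "volume":
        return value * dim.scale_to_canonical
    if dim.quantity_kind == "mass":
        grams = value * dim.scale_to_canonical * 1000.0
        return grams / density_g_per_ml
    raise UnknownUnit(f"not a mass or volume unit: {unit_string!r}")


def normalize_temperature(
    raw: str, bounds_c: tuple[float, float] = (-10.0, 60.0)
) -> float:
    """Parse an experimental temperature string into degrees Celsius.

    Kelvin requires an explicit ``K`` marker; unmarked numbers follow the
    historical physiology convention and are read as degC.  Annotations are
    removed with :func:`clean_numeric` first.
    """
    is_kelvin = re.search(r"\bK\b", raw) is not None
    value = clean_numeric(raw).value
    if is_kelvin:
        value -= 273.15
    if not bounds_c[0] <= value <= bounds_c[1]:
        raise ImplausibleTemperature(
            f"{value:.2f} degC outside plausible range {bounds_c}"
        )
    return value
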