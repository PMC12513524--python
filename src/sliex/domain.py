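"""Lipid-marker vocabulary and the NCEP ATP III category classifier.

Four fasting serum markers make up the lipid profile: triglycerides (TG),
total cholesterol (TC), low-density lipoprotein cholesterol (LDL-C) and
high-density lipoprotein cholesterol (HDL-C).  Each marker has its own
ordinal ladder of NCEP ATP III categories; rank 0 is always the most
desirable category and larger ranks are worse.  For TG, TC and LDL-C higher
concentrations are worse; HDL-C is protective, so *low* values are abnormal.

Categories are assigned from half-open intervals closed at the lower bound
of each non-Normal category, so every positive concentration maps to exactly
one category in either unit system.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping

from .errors import DomainError, InvalidMeasurementError

__all__ = [
    "Marker",
    "Unit",
    "Category",
    "LipidPanel",
    "CATEGORY_LADDER",
    "categorize",
    "convert",
    "category_rank",
]


class Marker(str, enum.Enum):
    """One of the four lipid profile markers."""

    TG = "TG"
    TC = "TC"
    LDL_C = "LDL_C"
    HDL_C = "HDL_C"


class Unit(str, enum.Enum):
    """Concentration unit for a lipid panel."""

    MMOL_PER_L = "mmol/L"
    MG_PER_DL = "mg/dL"


class Category(str, enum.Enum):
    """NCEP ATP III category labels (not every label applies to every marker)."""

    NORMAL = "Normal"
    NEAR_OPTIMAL = "NearOptimal"
    BORDERLINE_HIGH = "BorderlineHigh"
    HIGH = "High"
    VERY_HIGH = "VeryHigh"
    ABNORMAL = "Abnormal"


#: Ordinal ladder per marker, best (rank 0) first.
CATEGORY_LADDER: dict[Marker, tuple[Category, ...]] = {
    Marker.TG: (
        Category.NORMAL,
        Category.BORDERLINE_HIGH,
        Category.HIGH,
        Category.VERY_HIGH,
    ),
    Marker.LDL_C: (
        Category.NORMAL,
        Category.NEAR_OPTIMAL,
        Category.BORDERLINE_HIGH,
        Category.HIGH,
        Category.VERY_HIGH,
    ),
    Marker.TC: (
        Category.NORMAL,
        Category.BORDERLINE_HIGH,
        Category.HIGH,
    ),
    Marker.HDL_C: (
        Category.NORMAL,
        Category.ABNORMAL,
    ),
}

# Ascending lower bounds of the non-Normal categories for the markers where
# higher is worse.  A value below the first bound is Normal; otherwise it
# falls in the last interval whose (closed) lower bound it reaches.
_UPPER_CUTS: dict[tuple[Marker, Unit], tuple[float, ...]] = {
    (Marker.TG, Unit.MMOL_PER_L): (1.69, 2.25, 5.64),
    (Marker.TG, Unit.MG_PER_DL): (150.0, 200.0, 500.0),
    (Marker.LDL_C, Unit.MMOL_PER_L): (2.58, 3.35, 4.13, 4.91),
    (Marker.LDL_C, Unit.MG_PER_DL): (100.0, 130.0, 160.0, 190.0),
    (Marker.TC, Unit.MMOL_PER_L): (5.17, 6.20),
    (Marker.TC, Unit.MG_PER_DL): (200.0, 240.0),
}

# HDL-C is protective: values at or above the cut are Normal.
_HDL_NORMAL_CUT: dict[Unit, float] = {
    Unit.MMOL_PER_L: 1.05,
    Unit.MG_PER_DL: 41.0,
}

# Standard clinical conversion factors, mg/dL per mmol/L.  Triglycerides
# (MW ~885.7) differ from the cholesterol markers (MW ~386.7).
_MG_PER_MMOL: dict[Marker, float] = {
    Marker.TG: 88.57,
    Marker.TC: 38.67,
    Marker.LDL_C: 38.67,
    Marker.HDL_C: 38.67,
}


def _check_value(value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value <= 0:
        raise InvalidMeasurementError(
            f"lipid concentration must be finite and > 0, got {value!r}"
        )
    return value


def _coerce_marker(marker: Marker | str) -> Marker:
    try:
        return Marker(marker)
    except ValueError:
        raise DomainError(f"unknown marker: {marker!r}") from None


def _coerce_unit(unit: Unit | str) -> Unit:
    try:
        return Unit(unit)
    except ValueError:
        raise DomainError(f"unknown unit: {unit!r}") from None


def category_rank(marker: Marker | str, category: Category) -> int:
    """Ordinal rank of ``category`` on ``marker``'s ladder (0 = best)."""
    marker = _coerce_marker(marker)
    ladder = CATEGORY_LADDER[marker]
    try:
        return ladder.index(category)
    except ValueError:
        raise DomainError(
            f"category {category!r} is not on the {marker.value} ladder {ladder}"
        ) from None


def categorize(marker: Marker | str, value: float, unit: Unit | str) -> Category:
    """Classify a concentration into its NCEP ATP III category.

    Classification happens in the supplied unit with that unit's cut points;
    no conversion is performed, so boundary values are never subject to
    rounding artefacts.

    Parameters
    ----------
    marker
        One of the four lipid markers.
    value
        Concentration, strictly positive and finite.
    unit
        ``mmol/L`` or ``mg/dL``.

    Returns
    -------
    Category
        The unique category whose half-open interval contains ``value``.
    """
    marker = _coerce_marker(marker)
    unit = _coerce_unit(unit)
    value = _check_value(value)

    if marker is Marker.HDL_C:
        return (
            Category.NORMAL if value >= _HDL_NORMAL_CUT[unit] else Category.ABNORMAL
        )

    cuts = _UPPER_CUTS[(marker, unit)]
    ladder = CATEGORY_LADDER[marker]
    rank = 0
    for cut in cuts:
        if value >= cut:
            rank += 1
        else:
            break
    return ladder[rank]


def convert(
    value: float, marker: Marker | str, from_unit: Unit | str, to_unit: Unit | str
) -> float:
    """Convert a concentration between mmol/L and mg/dL.

    TG uses 1 mmol/L = 88.57 mg/dL; the cholesterol markers use
    1 mmol/L = 38.67 mg/dL.  Round-trips are exact to ~1e-9 relative.
    """
    marker = _coerce_marker(marker)
    from_unit = _coerce_unit(from_unit)
    to_unit = _coerce_unit(to_unit)
    value = _check_value(value)
    if from_unit is to_unit:
        return value
    factor = _MG_PER_MMOL[marker]
    if from_unit is Unit.MMOL_PER_L:
        return value * factor
    return value / factor


@dataclass(frozen=True)
class LipidPanel:
    """One timepoint's lipid measurements.

    Parameters
    ----------
    values
        Mapping of marker to concentration; markers may be absent
        (missing data) but at least one must be present and all present
        values must be finite and strictly positive.
    unit
        The unit all values share.
    """

    values: Mapping[Marker, float]
    unit: Unit = Unit.MMOL_PER_L

    def __post_init__(self) -> None:
        coerced = {
            _coerce_marker(m): _check_value(v) for m, v in dict(self.values).items()
        }
        if not coerced:
            raise InvalidMeasurementError("a lipid panel needs at least one marker")
        object.__setattr__(self, "values", coerced)
        object.__setattr__(self, "unit", _coerce_unit(self.unit))

    @property
    def markers(self) -> frozenset[Marker]:
        return frozenset(self.values)

    def __getitem__(self, marker: Marker | str) -> float:
        return self.values[_coerce_marker(marker)]

    def __contains__(self, marker: object) -> bool:
        try:
            return _coerce_marker(marker) in self.values  # type: ignore[arg-type]
        except DomainError:
            return False

    def category(self, marker: Marker | str) -> Category:
        """NCEP category of ``marker`` in this panel."""
        marker = _coerce_marker(marker)
        return categorize(marker, self.values[marker], self.unit)
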