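"""The SLIEX scoring engine.

SLIEX condenses a pre/post lipid panel comparison into a single score out of
18.  Each marker contributes two components:

* a **change score** of +1 / 0 / -1 for raw improvement / no change /
  worsening of the concentration (improvement means a decrease for TG, TC
  and LDL-C, an increase for HDL-C), worth at most 4 points over the panel;
* a **weightage score** for the NCEP category transition from pre to post,
  worth at most 14 points over the panel.  For TG, LDL-C and TC the
  weightage follows a closed form in the rank difference
  ``d = rank(pre) - rank(post)``: ``d + 1`` when ``d >= 0`` (staying put
  earns the minimal-benefit +1) and ``d`` when the category worsens.
  HDL-C has only two categories with a special cell: staying Abnormal earns
  0 rather than +1.

The total is divided by the attainable maximum (18 for a complete panel;
rescaled when markers are missing) and multiplied by 100 to give the
percentage of improvement, classified Fair / Good / Very good / Excellent.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

from .domain import CATEGORY_LADDER, Category, LipidPanel, Marker, category_rank
from .errors import (
    DomainError,
    EmptyPanelError,
    InvalidMeasurementError,
    UnitMismatchError,
)

__all__ = [
    "Classification",
    "MarkerScore",
    "SliexResult",
    "WEIGHTAGE_RANGE",
    "MAX_CONTRIBUTION",
    "COMPLETE_PANEL_MAX",
    "change_score",
    "weightage_score",
    "classify_improvement",
    "score_panel",
    "max_weightage",
    "attainable_maximum",
]

#: Weightage score range (min, max) per marker.
WEIGHTAGE_RANGE: dict[Marker, tuple[int, int]] = {
    Marker.TG: (-3, 4),
    Marker.LDL_C: (-4, 5),
    Marker.HDL_C: (-1, 2),
    Marker.TC: (-2, 3),
}

#: Maximum points a marker can contribute: best change (+1) + best weightage.
MAX_CONTRIBUTION: dict[Marker, int] = {
    m: 1 + WEIGHTAGE_RANGE[m][1] for m in Marker
}

#: Attainable maximum for a complete four-marker panel (4 change + 14 weightage).
COMPLETE_PANEL_MAX: int = sum(MAX_CONTRIBUTION.values())

# Markers for which a *decrease* is an improvement.
_LOWER_IS_BETTER = frozenset({Marker.TG, Marker.TC, Marker.LDL_C})


class Classification(str, enum.Enum):
    """Four-level interpretation of the percentage of improvement."""

    FAIR = "Fair"
    GOOD = "Good"
    VERY_GOOD = "VeryGood"
    EXCELLENT = "Excellent"


def change_score(
    marker: Marker | str,
    pre: float,
    post: float,
    tolerance: float = 0.0,
) -> int:
    """Score the raw pre-to-post change of one marker as +1, 0 or -1.

    For TG, TC and LDL-C a decrease beyond ``tolerance`` scores +1 and an
    increase -1; for HDL-C the signs are mirrored.  Changes within
    ``tolerance`` (absolute, same unit as the values) score 0; the default
    tolerance of 0 treats only exact equality as "no change".
    """
    marker = Marker(marker) if not isinstance(marker, Marker) else marker
    for v in (pre, post):
        if not math.isfinite(v) or v <= 0:
            raise InvalidMeasurementError(
                f"pre/post values must be finite and > 0, got {v!r}"
            )
    if tolerance < 0:
        raise DomainError(f"tolerance must be >= 0, got {tolerance!r}")
    delta = post - pre
    if abs(delta) <= tolerance:
        return 0
    improved = delta < 0 if marker in _LOWER_IS_BETTER else delta > 0
    return 1 if improved else -1


def weightage_score(
    marker: Marker | str, pre_cat: Category, post_cat: Category
) -> int:
    """Score the NCEP category transition of one marker.

    Equivalent to looking up the (pre row, post column) cell of the
    marker's transition matrix.
    """
    marker = Marker(marker) if not isinstance(marker, Marker) else marker
    pre_rank = category_rank(marker, pre_cat)
    post_rank = category_rank(marker, post_cat)
    if marker is Marker.HDL_C:
        # 2x2 matrix: Normal->Normal +1, Abnormal->Normal +2,
        # Normal->Abnormal -1, Abnormal->Abnormal 0 (no minimal-benefit
        # point for remaining abnormal).
        if post_cat is Category.NORMAL:
            return 1 if pre_cat is Category.NORMAL else 2
        return -1 if pre_cat is Category.NORMAL else 0
    d = pre_rank - post_rank
    return d + 1 if d >= 0 else d


def classify_improvement(percent: float) -> Classification:
    """Map an (unrounded) percentage of improvement to its four-level band.

    < 25 Fair; 25-50 Good; > 50-75 Very good; > 75 Excellent.  Negative
    percentages (net worsening) fall in Fair.
    """
    if not math.isfinite(percent):
        raise DomainError(f"percent must be finite, got {percent!r}")
    if percent < 25:
        return Classification.FAIR
    if percent <= 50:
        return Classification.GOOD
    if percent <= 75:
        return Classification.VERY_GOOD
    return Classification.EXCELLENT


def max_weightage(marker: Marker | str) -> int:
    """Maximum weightage cell for ``marker``, by brute force over all
    (pre, post) category pairs."""
    marker = Marker(marker) if not isinstance(marker, Marker) else marker
    ladder = CATEGORY_LADDER[marker]
    return max(
        weightage_score(marker, pre, post) for pre in ladder for post in ladder
    )


def attainable_maximum(markers: frozenset[Marker] | set[Marker]) -> int:
    """Best possible total over the given present markers."""
    return sum(MAX_CONTRIBUTION[m] for m in markers)


@dataclass(frozen=True)
class MarkerScore:
    """Both score components for a single marker."""

    marker: Marker
    change: int
    weightage: int
    pre_category: Category
    post_category: Category

    @property
    def subtotal(self) -> int:
        return self.change + self.weightage


@dataclass(frozen=True)
class SliexResult:
    """Complete SLIEX evaluation of one pre/post panel pair.

    ``total = change_sum + weightage_sum`` is expressed against
    ``attainable_max`` (18 for a complete panel, less when markers are
    missing from either timepoint) as an unrounded ``percent``, which the
    ``classification`` interprets.  ``worsened`` flags a net-negative total.
    """

    per_marker: tuple[MarkerScore, ...]
    missing_markers: frozenset[Marker]
    subject_id: str | None = None
    arm: str | None = None
    change_sum: int = field(init=False)
    weightage_sum: int = field(init=False)
    total: int = field(init=False)
    attainable_max: int = field(init=False)
    percent: float = field(init=False)
    classification: Classification = field(init=False)

    def __post_init__(self) -> None:
        change_sum = sum(s.change for s in self.per_marker)
        weightage_sum = sum(s.weightage for s in self.per_marker)
        total = change_sum + weightage_sum
        attainable = attainable_maximum({s.marker for s in self.per_marker})
        object.__setattr__(self, "change_sum", change_sum)
        object.__setattr__(self, "weightage_sum", weightage_sum)
        object.__setattr__(self, "total", total)
        object.__setattr__(self, "attainable_max", attainable)
        object.__setattr__(self, "percent", 100.0 * total / attainable)
        object.__setattr__(
            self, "classification", classify_improvement(self.percent)
        )

    @property
    def worsened(self) -> bool:
        return self.total < 0

    def marker_score(self, marker: Marker | str) -> MarkerScore:
        marker = Marker(marker) if not isinstance(marker, Marker) else marker
        for s in self.per_marker:
            if s.marker is marker:
                return s
        raise KeyError(marker)

    def summary(self) -> str:
        """Human-readable one-result report."""
        lines = []
        header = " / ".join(
            p for p in (self.subject_id, self.arm) if p is not None
        )
        if header:
            lines.append(header)
        for s in self.per_marker:
            lines.append(
                f"  {s.marker.value:6s} change {s.change:+d}  "
                f"weightage {s.weightage:+d}  "
                f"({s.pre_category.value} -> {s.post_category.value})"
            )
        if self.missing_markers:
            missing = ", ".join(sorted(m.value for m in self.missing_markers))
            lines.append(f"  missing: {missing}")
        lines.append(
            f"  total {self.total}/{self.attainable_max}  "
            f"({round_percent(self.percent):.1f}%)  "
            f"{self.classification.value}"
        )
        return "\n".join(lines)


def round_percent(percent: float) -> float:
    """Round a percentage half-up to one decimal place (reporting only)."""
    from decimal import ROUND_HALF_UP, Decimal

    return float(Decimal(repr(percent)).quantize(Decimal("0.1"), ROUND_HALF_UP))


# Stable display/report order for the four markers.
_MARKER_ORDER = (Marker.TG, Marker.LDL_C, Marker.HDL_C, Marker.TC)


def score_panel(
    pre: LipidPanel,
    post: LipidPanel,
    tolerance: float = 0.0,
    subject_id: str | None = None,
    arm: str | None = None,
) -> SliexResult:
    """Score a pre/post lipid panel pair.

    Markers present in both panels are scored; any marker missing from
    either is excluded and the attainable maximum rescaled accordingly
    (e.g. a panel without TC is scored out of 14 instead of 18).

    Raises
    ------
    UnitMismatchError
        If the two panels use different units.
    EmptyPanelError
        If no marker is present in both panels.
    """
    if pre.unit is not post.unit:
        raise UnitMismatchError(
            f"pre panel in {pre.unit.value} but post panel in {post.unit.value}"
        )
    shared = pre.markers & post.markers
    if not shared:
        raise EmptyPanelError("no marker present in both pre and post panels")
    scores = []
    for marker in _MARKER_ORDER:
        if marker not in shared:
            continue
        pre_cat = pre.category(marker)
        post_cat = post.category(marker)
        scores.append(
            MarkerScore(
                marker=marker,
                change=change_score(marker, pre[marker], post[marker], tolerance),
                weightage=weightage_score(marker, pre_cat, post_cat),
                pre_category=pre_cat,
                post_category=post_cat,
            )
        )
    return SliexResult(
        per_marker=tuple(scores),
        missing_markers=frozenset(Marker) - shared,
        subject_id=subject_id,
        arm=arm,
    )
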