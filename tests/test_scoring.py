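"""The scoring engine: change scores, weightage matrices, totals and bands."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sliex import (
    CATEGORY_LADDER,
    COMPLETE_PANEL_MAX,
    MAX_CONTRIBUTION,
    WEIGHTAGE_RANGE,
    Category,
    Classification,
    LipidPanel,
    Marker,
    Unit,
    change_score,
    classify_improvement,
    max_weightage,
    round_percent,
    score_panel,
    weightage_score,
)
from sliex.errors import EmptyPanelError, InvalidMeasurementError, UnitMismatchError

N = Category.NORMAL
NO = Category.NEAR_OPTIMAL
B = Category.BORDERLINE_HIGH
H = Category.HIGH
V = Category.VERY_HIGH
A = Category.ABNORMAL

# The published transition matrices, frozen verbatim as the oracle:
# rows = pre-test category, columns = post-test category.
TG_MATRIX = {
    N: {N: 1, B: -1, H: -2, V: -3},
    B: {N: 2, B: 1, H: -1, V: -2},
    H: {N: 3, B: 2, H: 1, V: -1},
    V: {N: 4, B: 3, H: 2, V: 1},
}
LDL_MATRIX = {
    N: {N: 1, NO: -1, B: -2, H: -3, V: -4},
    NO: {N: 2, NO: 1, B: -1, H: -2, V: -3},
    B: {N: 3, NO: 2, B: 1, H: -1, V: -2},
    H: {N: 4, NO: 3, B: 2, H: 1, V: -1},
    V: {N: 5, NO: 4, B: 3, H: 2, V: 1},
}
HDL_MATRIX = {
    N: {N: 1, A: -1},
    A: {N: 2, A: 0},
}
TC_MATRIX = {
    N: {N: 1, B: -1, H: -2},
    B: {N: 2, B: 1, H: -1},
    H: {N: 3, B: 2, H: 1},
}
MATRICES = {
    Marker.TG: TG_MATRIX,
    Marker.LDL_C: LDL_MATRIX,
    Marker.HDL_C: HDL_MATRIX,
    Marker.TC: TC_MATRIX,
}


class TestChangeScore:
    @pytest.mark.parametrize(
        ("marker", "pre", "post", "expected"),
        [
            (Marker.TG, 0.86, 0.80, 1),     # decrease improves TG
            (Marker.TC, 3.00, 3.00, 0),     # exact no-change
            (Marker.LDL_C, 1.30, 1.60, -1), # increase worsens LDL-C
            (Marker.HDL_C, 0.86, 1.00, 1),  # increase improves HDL-C
            (Marker.HDL_C, 1.30, 1.20, -1),
        ],
    )
    def test_sign_convention(self, marker, pre, post, expected):
        assert change_score(marker, pre, post) == expected

    def test_tolerance_window(self):
        assert change_score(Marker.TG, 1.00, 0.98, tolerance=0.05) == 0
        assert change_score(Marker.TG, 1.00, 0.90, tolerance=0.05) == 1

    def test_rejects_nonpositive(self):
        with pytest.raises(InvalidMeasurementError):
            change_score(Marker.TG, 0.0, 1.0)

    @settings(deadline=None, max_examples=200)
    @given(
        marker=st.sampled_from(list(Marker)),
        pre=st.floats(min_value=0.01, max_value=20),
        post=st.floats(min_value=0.01, max_value=20),
    )
    def test_antisymmetry(self, marker, pre, post):
        assert change_score(marker, pre, post) == -change_score(marker, post, pre)


class TestWeightageScore:
    @pytest.mark.parametrize("marker", list(Marker))
    def test_matches_published_matrix_cell_by_cell(self, marker):
        """Closed form reproduces every cell of the transition matrix."""
        matrix = MATRICES[marker]
        for pre, row in matrix.items():
            for post, expected in row.items():
                assert weightage_score(marker, pre, post) == expected

    @pytest.mark.parametrize("marker", list(Marker))
    def test_range_and_maximum(self, marker):
        ladder = CATEGORY_LADDER[marker]
        cells = [
            weightage_score(marker, p, q)
            for p, q in itertools.product(ladder, ladder)
        ]
        lo, hi = WEIGHTAGE_RANGE[marker]
        assert min(cells) == lo
        assert max(cells) == hi == max_weightage(marker)

    def test_rejects_foreign_category(self):
        from sliex.errors import DomainError

        with pytest.raises(DomainError):
            weightage_score(Marker.TC, Category.VERY_HIGH, Category.NORMAL)

    def test_no_worsening_implies_positive_except_hdl_abnormal_stay(self):
        for marker in Marker:
            ladder = CATEGORY_LADDER[marker]
            for pre, post in itertools.product(ladder, ladder):
                if ladder.index(post) <= ladder.index(pre):
                    w = weightage_score(marker, pre, post)
                    if marker is Marker.HDL_C and pre is A and post is A:
                        assert w == 0
                    else:
                        assert w > 0


class TestClassifyImprovement:
    @pytest.mark.parametrize(
        ("percent", "expected"),
        [
            (38.888888, Classification.GOOD),
            (50.0, Classification.GOOD),       # 25-50 is Good, inclusive
            (50.0001, Classification.VERY_GOOD),
            (75.0, Classification.VERY_GOOD),
            (100.0, Classification.EXCELLENT),
            (24.999, Classification.FAIR),
            (-10.0, Classification.FAIR),      # net worsening still Fair
        ],
    )
    def test_bands(self, percent, expected):
        assert classify_improvement(percent) is expected

    def test_nonfinite_rejected(self):
        from sliex.errors import DomainError

        with pytest.raises(DomainError):
            classify_improvement(float("nan"))


class TestScorePanel:
    def test_hiit_worked_example(self, hiit_panels):
        res = score_panel(*hiit_panels)
        assert [s.change for s in res.per_marker] == [1, 1, 1, 0]
        assert [s.weightage for s in res.per_marker] == [1, 1, 1, 1]
        assert res.total == 7
        assert res.attainable_max == 18
        assert round_percent(res.percent) == 38.9
        assert res.classification is Classification.GOOD
        assert not res.worsened

    def test_mict_worked_example(self, mict_panels):
        res = score_panel(*mict_panels)
        assert [s.change for s in res.per_marker] == [0, -1, 1, -1]
        assert [s.weightage for s in res.per_marker] == [1, 1, 0, 1]
        assert res.total == 2
        assert round_percent(res.percent) == 11.1
        assert res.classification is Classification.FAIR

    def test_single_marker_panel(self):
        """A TG-only panel with no change scores 1/5 = 20%."""
        panel = LipidPanel({"TG": 1.0})
        res = score_panel(panel, panel)
        assert (res.change_sum, res.weightage_sum) == (0, 1)
        assert res.total == 1
        assert res.attainable_max == 5
        assert res.percent == pytest.approx(20.0)
        assert res.classification is Classification.FAIR
        assert res.missing_markers == frozenset(Marker) - {Marker.TG}

    def test_tc_missing_rescales_to_14(self, hiit_panels):
        pre, post = hiit_panels
        pre3 = LipidPanel({m: v for m, v in pre.values.items() if m is not Marker.TC})
        post3 = LipidPanel({m: v for m, v in post.values.items() if m is not Marker.TC})
        res = score_panel(pre3, post3)
        assert res.attainable_max == 14
        assert res.missing_markers == {Marker.TC}

    def test_unit_mismatch_and_empty_overlap(self):
        a = LipidPanel({"TG": 1.0}, Unit.MMOL_PER_L)
        b = LipidPanel({"TG": 90.0}, Unit.MG_PER_DL)
        with pytest.raises(UnitMismatchError):
            score_panel(a, b)
        c = LipidPanel({"TC": 4.0})
        with pytest.raises(EmptyPanelError):
            score_panel(a, c)

    def test_structural_constants(self):
        """18 = 4 change points + 14 weightage points; per-marker maxima."""
        assert COMPLETE_PANEL_MAX == 18
        assert sum(max_weightage(m) for m in Marker) == 14
        assert MAX_CONTRIBUTION == {
            Marker.TG: 5,
            Marker.LDL_C: 6,
            Marker.HDL_C: 3,
            Marker.TC: 4,
        }


# value strategy spanning every category of every marker (mmol/L)
_VALUES = st.floats(min_value=0.05, max_value=12.0)
_PANEL = st.fixed_dictionaries(
    {
        "TG": _VALUES,
        "LDL_C": _VALUES,
        "HDL_C": st.floats(min_value=0.05, max_value=3.0),
        "TC": _VALUES,
    }
)


class TestPanelProperties:
    @settings(deadline=None, max_examples=150)
    @given(pre=_PANEL, post=_PANEL)
    def test_bounds_and_decomposition(self, pre, post):
        res = score_panel(LipidPanel(pre), LipidPanel(post))
        assert res.total == res.change_sum + res.weightage_sum
        assert -4 <= res.change_sum <= 4
        assert -10 <= res.weightage_sum <= 14
        assert -14 <= res.total <= 18
        assert -77.8 <= res.percent <= 100.0 + 1e-9

    @settings(deadline=None, max_examples=100)
    @given(
        pre=_PANEL,
        post=_PANEL,
        marker=st.sampled_from(list(Marker)),
        factor=st.floats(min_value=0.5, max_value=0.95),
    )
    def test_total_monotone_in_single_marker_improvement(
        self, pre, post, marker, factor
    ):
        """Moving one post value in its improving direction never lowers
        the total."""
        base = score_panel(LipidPanel(pre), LipidPanel(post)).total
        better = dict(post)
        key = marker.value
        if marker is Marker.HDL_C:
            better[key] = post[key] / factor  # raise HDL-C
        else:
            better[key] = post[key] * factor  # lower TG/TC/LDL-C
        improved = score_panel(LipidPanel(pre), LipidPanel(better)).total
        assert improved >= base

    @settings(deadline=None, max_examples=100)
    @given(pre=_PANEL, post=_PANEL, marker=st.sampled_from(list(Marker)))
    def test_missing_marker_consistency(self, pre, post, marker):
        """Dropping one marker subtracts exactly its score and its maximum
        contribution."""
        full = score_panel(LipidPanel(pre), LipidPanel(post))
        kept_pre = {m: v for m, v in pre.items() if m != marker.value}
        kept_post = {m: v for m, v in post.items() if m != marker.value}
        part = score_panel(LipidPanel(kept_pre), LipidPanel(kept_post))
        dropped = full.marker_score(marker)
        assert part.total == full.total - dropped.subtotal
        assert part.attainable_max == full.attainable_max - MAX_CONTRIBUTION[marker]


def test_round_percent_half_up():
    assert round_percent(38.8888) == 38.9
    assert round_percent(11.1111) == 11.1
    assert round_percent(12.25) == 12.3  # half-up, not banker's rounding
    assert round_percent(-5.55) == -5.6  # ties round away from zero
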