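import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from hrscreen import errors
from hrscreen.phenotype import (
    DOWN1,
    DOWN2,
    DOWN3,
    NONE,
    PhenotypeSummary,
    UP1,
    UP2,
    UP3,
    build_summary_table,
    classify_h2ax,
    grade_hr,
    grade_sensitivity,
    grade_viability,
    render_h2ax,
    student_t_test,
)


class TestGradeHR:
    @pytest.mark.parametrize(
        "z,grade",
        [
            (-4.5, DOWN3), (-4.0, DOWN2), (-2.5, DOWN2), (-2.0, DOWN1),
            (-1.7, DOWN1), (-1.5, NONE), (0.0, NONE), (1.5, NONE),
            (1.7, UP1), (2.0, UP1), (2.5, UP2), (4.0, UP2), (4.5, UP3),
        ],
    )
    def test_band_assignment_with_strict_cutoffs(self, z, grade):
        assert grade_hr(z) == grade

    @given(st.floats(-20, 20), st.floats(0, 5))
    @settings(max_examples=200, deadline=None)
    def test_monotone_more_extreme_never_weaker(self, z, delta):
        order = [DOWN3, DOWN2, DOWN1, NONE]
        if z <= 0:
            assert order.index(grade_hr(z - delta)) <= order.index(grade_hr(z))
        else:
            up = [UP3, UP2, UP1, NONE]
            assert up.index(grade_hr(z + delta)) <= up.index(grade_hr(z))


class TestViability:
    def test_severe_and_null(self):
        rluc = [100, 100, 100]
        assert grade_viability([40, 40, 40], rluc) == "++"   # r = 0.6
        assert grade_viability([70, 70, 70], rluc) == "+"    # r = 0.3
        assert grade_viability([100, 100, 100], rluc) == NONE

    def test_boundaries_strict(self):
        rluc = [100.0] * 3
        assert grade_viability([50.0] * 3, rluc) == "+"   # exactly 50% decrease
        assert grade_viability([75.0] * 3, rluc) == NONE  # exactly 25% decrease

    def test_zero_rluc_mean_raises(self):
        with pytest.raises(errors.UndefinedRatioError):
            grade_viability([10, 10, 10], [0, 0, 0])

    def test_constructed_cohort_exclusion_count(self):
        # genes engineered so exactly 4 cross the 50% decrease line
        rluc = [1000.0] * 3
        factors = [0.3, 0.45, 0.49, 0.2, 0.6, 0.8, 1.0]
        grades = {
            f"g{i}": grade_viability([1000 * f] * 3, rluc)
            for i, f in enumerate(factors)
        }
        assert sum(g == "++" for g in grades.values()) == 4


class TestSensitivity:
    def _counts(self, untreated, ratios):
        out = {"untreated": [untreated] * 3}
        for cond, ratio in ratios.items():
            out[cond] = [untreated * ratio] * 3
        return out

    def test_footnote_cutoffs_with_inclusive_boundaries(self):
        rluc = self._counts(1000, {"cisplatin": 0.6})
        for d, expected in [(0.45, "+++"), (0.40, "+++"), (0.30, "++"),
                            (0.10, "+"), (0.05, NONE)]:
            gene = self._counts(800, {"cisplatin": 0.6 * (1 - d)})
            assert grade_sensitivity(gene, rluc)["cisplatin"] == expected, d

    def test_identical_ratios_grade_null(self):
        rluc = self._counts(1000, {"MMC": 0.5})
        gene = self._counts(400, {"MMC": 0.5})  # baseline-viability effect only
        assert grade_sensitivity(gene, rluc)["MMC"] == NONE

    def test_scale_invariance(self):
        rluc = self._counts(1000, {"IR": 0.7})
        gene = self._counts(900, {"IR": 0.7 * 0.65})
        scaled = {k: [v * 3.7 for v in vals] for k, vals in gene.items()}
        assert grade_sensitivity(gene, rluc) == grade_sensitivity(scaled, rluc)

    def test_zero_untreated_raises(self):
        rluc = self._counts(1000, {"IR": 0.7})
        with pytest.raises(errors.UndefinedRatioError):
            grade_sensitivity({"untreated": [0, 0, 0], "IR": [1, 1, 1]}, rluc)


class TestH2ax:
    def test_equal_means_yield_no_annotation(self):
        reps = {"1h": [50.0, 51, 49], "6h": [30.0, 31, 29]}
        assert classify_h2ax(reps, reps) == []

    def test_faster_removal_at_six_hours(self):
        gene = {"1h": [80.0, 81, 79], "6h": [10.0, 12, 11]}
        rluc = {"1h": [80.0, 79, 81], "6h": [30.0, 31, 29]}
        assert classify_h2ax(gene, rluc) == ["↓ 6h"]
        assert render_h2ax(["↓ 6h"]) == "↓ 6h"

    def test_p_matches_independent_oracle_to_1e10(self):
        gene, rluc = [10.0, 12.0, 11.0], [20.0, 21.0, 22.0]
        t, p = student_t_test(gene, rluc)
        t_ref, p_ref = sps.ttest_ind(gene, rluc, equal_var=True)
        assert t == pytest.approx(float(t_ref), abs=1e-10)
        assert p == pytest.approx(float(p_ref), abs=1e-10)

    @given(
        st.lists(st.floats(0, 100), min_size=2, max_size=6),
        st.lists(st.floats(0, 100), min_size=2, max_size=6),
        st.booleans(),
    )
    @settings(max_examples=100, deadline=None)
    def test_t_test_matches_scipy_everywhere(self, a, b, equal_var):
        t, p = student_t_test(a, b, equal_var=equal_var)
        t_ref, p_ref = sps.ttest_ind(a, b, equal_var=equal_var)
        if np.isfinite(t_ref):
            assert t == pytest.approx(float(t_ref), abs=1e-10)
            assert p == pytest.approx(float(p_ref), abs=1e-10)

    def test_symmetry_swapping_groups_flips_arrow(self):
        gene = {"1h": [80.0, 81, 79], "6h": [10.0, 12, 11]}
        rluc = {"1h": [80.0, 79, 81], "6h": [30.0, 31, 29]}
        assert classify_h2ax(gene, rluc) == ["↓ 6h"]
        assert classify_h2ax(rluc, gene) == ["↑ 6h"]
        _, p1 = student_t_test(gene["6h"], rluc["6h"])
        _, p2 = student_t_test(rluc["6h"], gene["6h"])
        assert p1 == p2

    def test_insufficient_replicates_raise(self):
        with pytest.raises(errors.MissingDataError):
            student_t_test([1.0], [2.0, 3.0])


class TestSummaryTable:
    def test_round_trip_and_nd_cells(self):
        rows = [
            PhenotypeSummary(gene="A", hr_grade_trigger1=DOWN2,
                             hr_grade_trigger2=DOWN1, viability_grade=NONE),
            PhenotypeSummary(gene="B"),
        ]
        df = build_summary_table(rows)
        assert list(df.gene) == ["A", "B"]
        assert df.loc[df.gene == "B", "cisplatin_grade"].item() == "n.d."

    def test_conflicting_duplicates_rejected(self):
        rows = [
            PhenotypeSummary(gene="A", viability_grade="+"),
            PhenotypeSummary(gene="A", viability_grade="++"),
        ]
        with pytest.raises(errors.ScreenError, match="duplicate"):
            build_summary_table(rows)

    def test_empty_input_empty_table(self):
        assert build_summary_table([]).empty
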