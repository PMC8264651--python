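"""Percentage change, EORTC coding, RCB mapping, concordance and Fisher test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fltrad.response import (
    ResponseRecord,
    background_correct,
    classify_eortc,
    concordance,
    fisher_exact_2x2,
    map_rcb,
    percent_change,
    summarize_flow,
)

from _oracles import fisher_oracle


class TestPercentChange:
    @pytest.mark.parametrize(
        "v1,v2,expected",
        [(10, 5, 50.0), (4, 6, -50.0), (9.1, 5.6, pytest.approx(38.46, abs=0.005))],
    )
    def test_worked_values(self, v1, v2, expected):
        assert percent_change(v1, v2) == expected

    def test_identity_and_doubling(self):
        assert percent_change(7.3, 7.3) == 0.0
        assert percent_change(7.3, 14.6) == -100.0

    def test_near_zero_baseline_flagged(self):
        assert np.isnan(percent_change(1e-12, 5.0))


class TestBackgroundCorrect:
    def test_subtracts_matched_statistics(self):
        assert background_correct((9, 5, 7), (1, 1, 1)) == (8, 4, 6)

    def test_floors_at_zero(self):
        assert background_correct((0.5, 0.4, 0.45), (1.0, 0.9, 0.8)) == (0, 0, 0)


class TestClassifyEortc:
    def test_partial_response_case(self):
        # 9.1 -> 5.6 is a 38% reduction with persisting uptake
        assert classify_eortc(9.1, 5.6) == "PMR"

    def test_complete_disappearance(self):
        assert classify_eortc(2.7, 0.0) == "CMR"

    def test_progression_above_25_percent(self):
        assert classify_eortc(10.0, 13.0) == "PMD"

    def test_stable_between_thresholds(self):
        assert classify_eortc(10.0, 9.0) == "SMD"

    def test_one_cycle_threshold_boundary(self):
        assert classify_eortc(100.0, 85.0) == "PMR"  # exactly 15%
        assert classify_eortc(100.0, 86.0) == "SMD"

    def test_cmr_tolerance_absorbs_background_noise(self):
        assert classify_eortc(5.0, 0.05, cmr_tolerance=0.1) == "CMR"
        assert classify_eortc(5.0, 0.05) == "PMR"

    def test_zero_baseline_unevaluable(self):
        with pytest.raises(ValueError):
            classify_eortc(0.0, 0.5)


class TestMapRcb:
    @pytest.mark.parametrize(
        "cat,code",
        [("RCB-0", 1), ("RCB-I", 1), ("RCB-II", 0), ("RCB-III", 0)],
    )
    def test_categories(self, cat, code):
        assert map_rcb(cat) == code

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            map_rcb("RCB-IV")


def study_records():
    """The emulated study's 15 evaluable patients: 7 CMR&pCR, 2 PMR&pCR,
    6 PMR&pPR, plus the 5 excluded enrollees (3 no histology, 2 no FLT2)."""
    records = []
    i = 0
    for eortc, rcb, count in [
        ("CMR", "RCB-0", 7),
        ("PMR", "RCB-0", 2),
        ("PMR", "RCB-II", 6),
    ]:
        for _ in range(count):
            i += 1
            records.append(ResponseRecord(f"P{i:03d}", eortc, rcb))
    for _ in range(3):
        i += 1
        records.append(ResponseRecord(f"P{i:03d}", "PMR", None))  # no histology
    for _ in range(2):
        i += 1
        records.append(ResponseRecord(f"P{i:03d}", None, "RCB-0"))  # no FLT2
    return records


class TestConcordance:
    def test_study_table(self):
        table, agreement = concordance(study_records())
        np.testing.assert_array_equal(table, [[7, 0], [2, 6]])
        assert agreement == 13

    def test_all_concordant_toy_set(self):
        recs = [
            ResponseRecord("a", "CMR", "RCB-0"),
            ResponseRecord("b", "CMR", "RCB-I"),
            ResponseRecord("c", "PMR", "RCB-II"),
            ResponseRecord("d", "SMD", "RCB-III"),
        ]
        _, agreement = concordance(recs)
        assert agreement == 4

    def test_empty_overlap_rejected(self):
        with pytest.raises(ValueError):
            concordance([ResponseRecord("a", "CMR", None)])


class TestFisher:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[7, 0], [2, 6]], pytest.approx(0.007, abs=5e-4)),
            ([[1, 0], [0, 1]], pytest.approx(1.0)),
            ([[5, 0], [0, 5]], pytest.approx(2 / 252, rel=1e-9)),
        ],
    )
    def test_known_tables(self, table, expected):
        assert fisher_exact_2x2(table) == expected

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 8), min_size=4, max_size=4))
    def test_matches_enumeration_oracle_small_tables(self, cells):
        table = [[cells[0], cells[1]], [cells[2], cells[3]]]
        n = sum(cells)
        if n == 0 or n > 20:
            return
        if (cells[0] + cells[1] == 0 or cells[2] + cells[3] == 0
                or cells[0] + cells[2] == 0 or cells[1] + cells[3] == 0):
            return  # degenerate margins: p = 1 by convention either way
        assert fisher_exact_2x2(table) == pytest.approx(
            fisher_oracle(table), rel=1e-9
        )

    def test_non_integer_cells_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1.5, 2], [3, 4]])
        with pytest.raises(ValueError):
            fisher_exact_2x2([[-1, 2], [3, 4]])


class TestPatientFlow:
    def test_study_accounting(self):
        flow = summarize_flow(study_records())
        assert flow["n_enrolled"] == 20
        assert flow["n_evaluable"] == 15
        assert flow["exclusions"] == {"no_histology": 3, "no_second_scan": 2}
        assert (flow["path_pcr"], flow["path_ppr"]) == (9, 6)
        assert (flow["pet_cr"], flow["pet_pr"]) == (7, 8)
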