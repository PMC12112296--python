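import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from faerspv.disprop import (ContingencyTable, SignalResult, build_contingency,
                             contingency_from_sets, flag_positive,
                             head_to_head_ror, ic_with_ic025, ror_with_ci,
                             screen_all_pts, signals_to_frame)
from faerspv.errors import FaersPVError, UndefinedSignalError
from faerspv.faers_ingest import CaseReport, DrugEntry, ReactionEntry
from faerspv.termset import TermSet
from faerspv.cohort import classify_cases, default_drug_classes
from conftest import make_case_table

RENAL = TermSet("renal", frozenset({"acute kidney injury",
                                    "tubulointerstitial nephritis"}))


class TestContingency:
    def test_direct_count(self):
        exposure = {f"E{i}" for i in range(4)}
        reference = {f"R{i}" for i in range(6)}
        events = {"E0", "E1", "R0"}
        t = contingency_from_sets(exposure, reference, events)
        assert (t.a, t.b, t.c, t.d) == (2, 2, 1, 5)

    def test_empty_exposure_group(self):
        t = contingency_from_sets(set(), {"R1", "R2"}, {"R1"})
        assert (t.a, t.b, t.c, t.d) == (0, 0, 1, 1)

    def test_overlap_is_logic_error_with_caseids(self):
        with pytest.raises(FaersPVError, match="C9"):
            contingency_from_sets({"C9"}, {"C9"}, set())

    def test_predicate_interface_counts_cases_once(self):
        cases = []
        for i in range(4):
            pts = ["acute kidney injury", "tubulointerstitial nephritis"] if i == 0 else ["nausea"]
            cases.append(CaseReport(
                caseid=f"C{i}", primaryid=str(i),
                drugs=[DrugEntry("nivolumab", "nivolumab", "PS" if i < 2 else "C")],
                reactions=[ReactionEntry(p) for p in pts]))
        t = build_contingency(
            cases,
            exposure_predicate=lambda c: c.drugs[0].role == "PS",
            event_predicate=lambda c: any(r.pt_name in RENAL for r in c.reactions),
            reference_predicate=lambda c: c.drugs[0].role != "PS")
        # the double-PT case contributes a single count
        assert (t.a, t.b, t.c, t.d) == (1, 1, 0, 2)


class TestRor:
    def test_balanced_table_is_null(self):
        r = ror_with_ci(ContingencyTable(5, 5, 5, 5))
        assert r.ror == pytest.approx(1.0)
        assert r.low * r.high == pytest.approx(1.0)  # symmetric on log scale

    def test_worked_example(self):
        r = ror_with_ci(ContingencyTable(20, 80, 100, 1800))
        assert r.ror == pytest.approx(4.5)
        assert r.low == pytest.approx(2.65, abs=0.005)
        assert r.high == pytest.approx(7.64, abs=0.005)

    def test_zero_cell_continuity_correction(self):
        r = ror_with_ci(ContingencyTable(3, 0, 10, 1000))
        assert r.corrected
        expected = (3.5 * 1000.5) / (0.5 * 10.5)
        assert r.ror == pytest.approx(expected)
        assert math.isfinite(r.high)

    def test_empty_margins_are_undefined(self):
        with pytest.raises(UndefinedSignalError):
            ror_with_ci(ContingencyTable(0, 0, 5, 5))
        with pytest.raises(UndefinedSignalError):
            ror_with_ci(ContingencyTable(5, 5, 0, 0))

    @given(st.tuples(*[st.integers(1, 400)] * 4))
    def test_point_estimate_inside_interval(self, cells):
        r = ror_with_ci(ContingencyTable(*cells))
        assert r.low <= r.ror <= r.high


class TestInformationComponent:
    def test_observed_equals_expected_gives_zero(self):
        # E = 110 * 100 / 1100 = 10 = O
        ic, _ = ic_with_ic025(ContingencyTable(10, 90, 100, 900))
        assert ic == pytest.approx(0.0)

    def test_worked_example_closed_form(self):
        # O = 8, E = 2 (margins 100 * 20 / 1000)
        t = ContingencyTable(8, 92, 12, 888)
        assert t.expected == pytest.approx(2.0)
        ic, ic025 = ic_with_ic025(t)
        assert ic == pytest.approx(math.log2(8.5 / 2.5), abs=1e-12)
        assert ic025 == pytest.approx(ic - 3.3 / math.sqrt(8.5) - 2.4 / 8.5**1.5,
                                      abs=1e-12)

    def test_zero_observed_is_negative_and_never_positive_flagged(self):
        t = ContingencyTable(0, 100, 50, 850)
        ic, ic025 = ic_with_ic025(t)
        assert ic < 0 and ic025 < ic
        r = SignalResult("pt", "g", 0, 1.0, 0.5, 2.0, ic, ic025, False)
        assert not flag_positive(r)

    def test_monte_carlo_close_to_closed_form(self):
        rng = np.random.default_rng(123)
        for t in [ContingencyTable(8, 92, 12, 888),
                  ContingencyTable(50, 950, 100, 9000),
                  ContingencyTable(3, 97, 30, 900)]:
            _, cf = ic_with_ic025(t)
            _, mc = ic_with_ic025(t, method="monte_carlo", n_draws=200_000, rng=rng)
            assert abs(cf - mc) < 0.15

    @given(st.integers(1, 50), st.integers(0, 200), st.integers(0, 200),
           st.integers(0, 2000))
    def test_ic_monotone_in_a_with_margins_fixed(self, a, b, c, d):
        """Moving a case from the no-event to the event cell (group size and
        reference fixed) can only raise the information component."""
        ic_lo, _ = ic_with_ic025(ContingencyTable(a, b + 1, c, d))
        ic_hi, _ = ic_with_ic025(ContingencyTable(a + 1, b, c, d))
        assert ic_hi > ic_lo or math.isclose(ic_hi, ic_lo)

    @given(st.tuples(*[st.integers(1, 300)] * 4))
    def test_ic025_below_ic(self, cells):
        ic, ic025 = ic_with_ic025(ContingencyTable(*cells))
        assert ic025 < ic

    @given(st.tuples(st.integers(1, 200), st.integers(1, 200),
                     st.integers(1, 200), st.integers(1, 200)))
    def test_shrinkage_pulls_toward_null(self, cells):
        """|IC| never exceeds |log2 O/E| on all-positive tables."""
        t = ContingencyTable(*cells)
        ic, _ = ic_with_ic025(t)
        raw = math.log2(t.a / t.expected)
        assert abs(ic) <= abs(raw) + 1e-12


class TestFlagPositive:
    @pytest.mark.parametrize("n, ror_low, ic025, expected", [
        (117, 95.87, 7.42, True),   # published combo tubulointerstitial nephritis row
        (2, 5.0, 1.0, False),       # below the report-count floor
        (10, 0.99, 0.5, False),     # ROR lower bound at or below 1
        (10, 1.5, 0.0, False),      # IC025 not above 0
        (3, 1.01, 0.01, True),
    ])
    def test_rule(self, n, ror_low, ic025, expected):
        r = SignalResult("pt", "g", n, 10, ror_low, 20, 5, ic025, False)
        assert flag_positive(r) is expected


CLASSES = default_drug_classes()


def _study_table(n_combo=30, n_other=400, eventful_combo=12, eventful_other=8):
    cases = []
    for i in range(n_combo):
        pts = ["tubulointerstitial nephritis"] if i < eventful_combo else ["nausea"]
        cases.append(dict(caseid=f"K{i}", primaryid=str(i + 1),
                          drugs=[("nivolumab", "PS"), ("omeprazole", "SS")],
                          reactions=pts))
    for i in range(n_other):
        pts = ["tubulointerstitial nephritis"] if i < eventful_other else ["rash"]
        cases.append(dict(caseid=f"O{i}", primaryid=str(1000 + i),
                          drugs=[("aspirin", "PS")], reactions=pts))
    return make_case_table(cases)


class TestScreenAndHeadToHead:
    def test_screen_counts_and_cells(self):
        table = _study_table()
        labels = classify_cases(table, CLASSES)
        results = screen_all_pts(table, labels, "ICI_PPI_COMBO", RENAL)
        assert [r.label for r in results] == ["tubulointerstitial nephritis"]
        t = results[0].table
        assert (t.a, t.b, t.c, t.d) == (12, 18, 8, 392)
        assert results[0].positive

    def test_pt_absent_from_group_omitted(self):
        table = _study_table(eventful_combo=0)
        labels = classify_cases(table, CLASSES)
        results = screen_all_pts(table, labels, "ICI_PPI_COMBO", RENAL)
        assert results == []

    def test_full_database_margins(self):
        table = _study_table()
        labels = classify_cases(table, CLASSES)
        results = screen_all_pts(table, labels, "ICI_PPI_COMBO", RENAL)
        t = results[0].table
        assert t.a + t.b == 30           # group size
        assert t.a + t.c == 20           # database-wide PT count

    def test_head_to_head_identical_proportions_gives_unit_ror(self):
        cases = []
        for i in range(20):
            pts = ["acute kidney injury"] if i % 2 == 0 else ["nausea"]
            cases.append(dict(caseid=f"A{i}", primaryid=str(i + 1),
                              drugs=[("nivolumab", "PS"), ("omeprazole", "SS")],
                              reactions=pts))
        for i in range(40):
            pts = ["acute kidney injury"] if i % 2 == 0 else ["nausea"]
            cases.append(dict(caseid=f"B{i}", primaryid=str(100 + i),
                              drugs=[("nivolumab", "PS")], reactions=pts))
        table = make_case_table(cases)
        labels = classify_cases(table, CLASSES)
        r = head_to_head_ror(table, labels, "ICI_PPI_COMBO", "ICI_MONO", RENAL)
        assert r.ror == pytest.approx(1.0)

    def test_empty_group_is_undefined(self):
        table = _study_table()
        labels = classify_cases(table, CLASSES)
        with pytest.raises(UndefinedSignalError):
            head_to_head_ror(table, labels, "ICI_PPI_COMBO", "PCAB_MONO", RENAL)

    def test_every_case_eventful_makes_a_equal_group_size(self):
        table = _study_table(n_combo=10, eventful_combo=10)
        labels = classify_cases(table, CLASSES)
        r = head_to_head_ror(table, labels, "ICI_PPI_COMBO", "OTHER", RENAL)
        assert r.table.a == 10 and r.table.b == 0

    def test_frame_has_audit_cells(self):
        table = _study_table()
        labels = classify_cases(table, CLASSES)
        frame = signals_to_frame(screen_all_pts(table, labels, "ICI_PPI_COMBO", RENAL))
        row = frame.iloc[0]
        assert row["a"] + row["b"] == 30
        assert set(frame.columns) >= {"pt", "n", "ror", "ror_low", "ror_high",
                                      "ic", "ic025", "positive"}


def test_ror_equals_exp_of_univariate_logistic_coefficient():
    """Ties the cross-product ROR to the logistic-regression odds ratio."""
    from faerspv.riskfactors import FactorSpec, fit_univariate_logistic
    import pandas as pd
    rng = np.random.default_rng(5)
    for _ in range(5):
        a, b, c, d = rng.integers(5, 80, size=4)
        t = ContingencyTable(int(a), int(b), int(c), int(d))
        r = ror_with_ci(t)
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        x = np.r_[np.ones(a + b), np.zeros(c + d)]
        res = fit_univariate_logistic(pd.Series(y), pd.Series(x.astype(str)),
                                      FactorSpec("exposed", "binary", reference="0.0"))
        assert res[0].odds_ratio == pytest.approx(r.ror, rel=1e-6)
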