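import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from faerspv._dates import parse_partial_date
from faerspv.faers_ingest import CaseReport, DrugEntry, ReactionEntry
from faerspv.onset import (MISSING_DATA, TEMPORAL_INCONSISTENCY, OnsetExclusion,
                           OnsetRecord, compute_tto, collect_onset_records,
                           kruskal_wallis, summarize_onset)
from faerspv.termset import TermSet

RENAL = TermSet("renal", frozenset({"acute kidney injury"}))
STUDY = {"nivolumab", "omeprazole"}


def _case(start, event, role="PS", pt="acute kidney injury", drug="nivolumab"):
    return CaseReport(
        caseid="C1", primaryid="1",
        event_dt=parse_partial_date(event),
        drugs=[DrugEntry(drug, drug, role, parse_partial_date(start))],
        reactions=[ReactionEntry(pt)])


class TestComputeTto:
    def test_simple_interval(self):
        rec = compute_tto(_case("20200101", "20200122"), RENAL, STUDY)
        assert isinstance(rec, OnsetRecord) and rec.tto_days == 21

    def test_event_before_start_is_temporal_inconsistency(self):
        res = compute_tto(_case("20200101", "20191231"), RENAL, STUDY)
        assert isinstance(res, OnsetExclusion)
        assert res.reason == TEMPORAL_INCONSISTENCY

    def test_same_day_onset_is_a_valid_zero(self):
        rec = compute_tto(_case("20200101", "20200101"), RENAL, STUDY)
        assert rec.tto_days == 0

    @pytest.mark.parametrize("start, event", [
        ("202001", "20200122"),   # month-precision start
        ("", "20200122"),         # missing start
        ("20200101", "202001"),   # month-precision event
        ("20200101", ""),         # missing event
    ])
    def test_partial_or_missing_dates_excluded(self, start, event):
        res = compute_tto(_case(start, event), RENAL, STUDY)
        assert isinstance(res, OnsetExclusion) and res.reason == MISSING_DATA

    def test_non_study_or_non_suspect_drug_gives_no_start(self):
        res = compute_tto(_case("20200101", "20200122", drug="aspirin"), RENAL, STUDY)
        assert isinstance(res, OnsetExclusion) and res.reason == MISSING_DATA
        res = compute_tto(_case("20200101", "20200122", role="C"), RENAL, STUDY)
        assert isinstance(res, OnsetExclusion) and res.reason == MISSING_DATA

    def test_earliest_start_among_study_suspects(self):
        case = CaseReport(
            caseid="C1", primaryid="1",
            event_dt=parse_partial_date("20200201"),
            drugs=[DrugEntry("nivolumab", "nivolumab", "PS", parse_partial_date("20200115")),
                   DrugEntry("omeprazole", "omeprazole", "SS", parse_partial_date("20200101"))],
            reactions=[ReactionEntry("acute kidney injury")])
        rec = compute_tto(case, RENAL, STUDY)
        assert rec.tto_days == 31


def test_eventful_cases_conserved_across_records_and_exclusions():
    import pandas as pd
    cases, specs = [], [("20200101", "20200111"), ("202001", "20200111"),
                       ("20200201", "20200111"), ("20200101", "")]
    for i, (s, e) in enumerate(specs):
        c = _case(s, e)
        c.caseid = f"C{i}"
        cases.append(c)
    labels = pd.Series("G", index=[f"C{i}" for i in range(4)])
    records, tally = collect_onset_records(cases, labels, RENAL, STUDY)
    assert len(records) + sum(tally.values()) == 4
    assert tally == {TEMPORAL_INCONSISTENCY: 1, MISSING_DATA: 2}


class TestSummarize:
    def test_even_n_median_is_midpoint(self):
        s = summarize_onset([OnsetRecord("a", "G", 5), OnsetRecord("b", "G", 6)])["G"]
        assert s.median_days == 5.5

    def test_hand_computed_hinges(self):
        recs = [OnsetRecord(str(i), "G", v) for i, v in enumerate(range(1, 9))]
        s = summarize_onset(recs)["G"]
        assert s.median_days == 4.5
        assert s.iqr == (2.5, 6.5)

    def test_curve_nondecreasing_and_ends_at_one(self):
        recs = [OnsetRecord(str(i), "G", v) for i, v in enumerate([3, 1, 3, 10, 7])]
        s = summarize_onset(recs)["G"]
        fracs = [f for _, f in s.cumulative_curve]
        assert fracs == sorted(fracs)
        assert fracs[-1] == 1.0
        assert s.cumulative_curve[-1][0] == 10

    def test_sample_median_recovers_lognormal_truth(self):
        rng = np.random.default_rng(17)
        draws = np.round(rng.lognormal(np.log(21), 2.4, 5000)).astype(int)
        recs = [OnsetRecord(str(i), "combo", int(v)) for i, v in enumerate(draws)]
        s = summarize_onset(recs)["combo"]
        assert 19.0 <= s.median_days <= 23.0


class TestKruskalWallis:
    def test_worked_example(self):
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert h == pytest.approx(3.857142857, abs=1e-9)
        assert p == pytest.approx(stats.chi2.sf(h, 1))

    def test_identical_groups_are_null(self):
        h, p = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_all_values_identical(self):
        assert kruskal_wallis([[2, 2], [2, 2, 2]]) == (0.0, 1.0)

    def test_brute_force_midrank_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            groups = [rng.integers(0, 8, size=rng.integers(3, 9)).tolist()
                      for _ in range(rng.integers(2, 5))]
            pooled = np.concatenate(groups).astype(float)
            if np.all(pooled == pooled[0]):
                continue
            ranks = stats.rankdata(pooled)
            n = len(pooled)
            h = 0.0
            i = 0
            for g in groups:
                r = ranks[i:i + len(g)]
                h += r.sum() ** 2 / len(g)
                i += len(g)
            h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
            _, t_counts = np.unique(pooled, return_counts=True)
            tie = 1 - np.sum(t_counts ** 3 - t_counts) / (n ** 3 - n)
            h_expected = h / tie
            h_got, _ = kruskal_wallis(groups)
            assert h_got == pytest.approx(h_expected, abs=1e-9)

    @given(st.lists(st.lists(st.integers(0, 30), min_size=2, max_size=8),
                    min_size=2, max_size=4))
    def test_invariant_under_strictly_monotone_transform(self, groups):
        h1, _ = kruskal_wallis(groups)
        transformed = [[(x + 1) ** 3 for x in g] for g in groups]
        h2, _ = kruskal_wallis(transformed)
        assert h1 == pytest.approx(h2, abs=1e-9)

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(19)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            groups = [rng.normal(size=25) for _ in range(3)]
            _, p = kruskal_wallis(groups)
            rejections += p < 0.05
        assert 0.036 <= rejections / n_sim <= 0.064
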