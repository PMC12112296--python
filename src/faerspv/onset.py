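"""Time-to-onset analysis of adverse events.

Time to onset (TTO) is the number of days from therapy start (START_DT of a
study-class suspect drug) to event development (EVENT_DT).  Both dates must
be known to day precision; a strictly negative interval is a temporal
inconsistency.  Excluded cases are tagged outcomes, not errors, so the
exclusion tally is conserved:  every eventful case maps to exactly one of
{record, temporal_inconsistency, missing_data}.

Group distributions are summarized by the median, the lower/upper hinges
(median-exclusive halves) and a cumulative distribution curve; medians are
compared across groups with the Kruskal–Wallis rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import median_and_hinges
from .faers_ingest import CaseReport
from .termset import TermSet, case_has_event

TEMPORAL_INCONSISTENCY = "temporal_inconsistency"
MISSING_DATA = "missing_data"


@dataclass(frozen=True)
class OnsetRecord:
    caseid: str
    group: str
    tto_days: int


@dataclass(frozen=True)
class OnsetExclusion:
    caseid: str
    group: str
    reason: str  # TEMPORAL_INCONSISTENCY or MISSING_DATA


@dataclass
class OnsetSummary:
    group: str
    n_with_tto: int
    median_days: float
    iqr: tuple[float, float]
    cumulative_curve: list[tuple[int, float]]  # (days, cumulative fraction)


def compute_tto(
    case: CaseReport,
    terms: TermSet,
    study_ingredients: set,
    suspect_roles: frozenset = frozenset({"PS", "SS"}),
) -> OnsetRecord | OnsetExclusion:
    """Time to onset for one eventful case, or a tagged exclusion.

    The interval runs from the earliest day-precision start date among the
    case's study-class suspect drugs to the earliest day-precision event
    date among matched reactions (falling back to the case-level event date,
    where the source dialect stores one event date per report).  Missing or
    partial dates exclude the case as ``missing_data``; an event strictly
    before the start excludes it as ``temporal_inconsistency``.  Same-day
    onset (0 days) is a valid record.
    """
    _, matched = case_has_event(case, terms)
    event_dates = [r.event_dt.to_date() for r in case.reactions
                   if r.pt_name in terms and r.event_dt.is_day]
    if not event_dates and case.event_dt.is_day:
        event_dates = [case.event_dt.to_date()]
    start_dates = [d.start_dt.to_date() for d in case.drugs
                   if d.ingredient in study_ingredients
                   and d.role in suspect_roles and d.start_dt.is_day]
    group = ""  # filled by callers that know the classification
    if not event_dates or not start_dates:
        return OnsetExclusion(case.caseid, group, MISSING_DATA)
    tto = (min(event_dates) - min(start_dates)).days
    if tto < 0:
        return OnsetExclusion(case.caseid, group, TEMPORAL_INCONSISTENCY)
    return OnsetRecord(case.caseid, group, int(tto))


def collect_onset_records(
    cases: list[CaseReport],
    labels: pd.Series | pd.DataFrame,
    terms: TermSet,
    study_ingredients: set,
    groups: list[str] | None = None,
    suspect_roles: frozenset = frozenset({"PS", "SS"}),
) -> tuple[list[OnsetRecord], dict]:
    """TTO records for every eventful case in the given groups, plus the
    exclusion tally ``{reason: count}`` for the run manifest."""
    if isinstance(labels, pd.DataFrame):
        labels = labels["label"]
    label_of = labels.to_dict()
    records: list[OnsetRecord] = []
    tally = {TEMPORAL_INCONSISTENCY: 0, MISSING_DATA: 0}
    for case in cases:
        group = label_of.get(case.caseid)
        if group is None or (groups is not None and group not in groups):
            continue
        eventful, _ = case_has_event(case, terms)
        if not eventful:
            continue
        res = compute_tto(case, terms, study_ingredients, suspect_roles)
        if isinstance(res, OnsetRecord):
            records.append(OnsetRecord(res.caseid, group, res.tto_days))
        else:
            tally[res.reason] += 1
    return records, tally


def summarize_onset(records: list[OnsetRecord]) -> dict[str, OnsetSummary]:
    """Per-group onset summary; empty groups are omitted (with a notice in
    the returned mapping's absence rather than an error)."""
    by_group: dict[str, list[int]] = {}
    for r in records:
        by_group.setdefault(r.group, []).append(r.tto_days)
    out: dict[str, OnsetSummary] = {}
    for group in sorted(by_group):
        values = np.sort(np.asarray(by_group[group]))
        q1, med, q3 = median_and_hinges(values)
        days, counts = np.unique(values, return_counts=True)
        cum = np.cumsum(counts) / values.size
        out[group] = OnsetSummary(
            group=group, n_with_tto=int(values.size), median_days=med,
            iqr=(q1, q3),
            cumulative_curve=[(int(d), float(f)) for d, f in zip(days, cum)],
        )
    return out


def kruskal_wallis(samples: list) -> tuple[float, float]:
    """Kruskal–Wallis H (midranks, tie-corrected) and chi-square p-value.

    Requires at least two nonempty groups.  When every pooled value is
    identical there is nothing to rank: H = 0 and p = 1 by convention.
    """
    if len(samples) < 2:
        raise ValueError("Kruskal-Wallis needs at least two groups")
    arrays = [np.asarray(s, dtype=float) for s in samples]
    if any(a.size == 0 for a in arrays):
        raise ValueError("Kruskal-Wallis groups must be nonempty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def onset_records_frame(records: list[OnsetRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.caseid, r.group, r.tto_days) for r in records],
        columns=["caseid", "group", "tto_days"],
    ).sort_values(["group", "caseid"], kind="mergesort").reset_index(drop=True)


def onset_summary_frame(summaries: dict[str, OnsetSummary]) -> pd.DataFrame:
    rows = [dict(group=s.group, n_with_tto=s.n_with_tto,
                 median_days=s.median_days, q1=s.iqr[0], q3=s.iqr[1])
            for s in summaries.values()]
    return pd.DataFrame(rows, columns=["group", "n_with_tto", "median_days", "q1", "q3"])


def cumulative_curves_frame(summaries: dict[str, OnsetSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries.values():
        for day, frac in s.cumulative_curve:
            rows.append(dict(group=s.group, tto_days=day, cumulative_fraction=frac))
    return pd.DataFrame(rows, columns=["group", "tto_days", "cumulative_fraction"])
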