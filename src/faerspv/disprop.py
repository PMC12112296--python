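"""Disproportionality statistics for drug–event report counts.

Every statistic is built on the 2×2 contingency table of deduplicated cases

====================  =========  ============
set                    event      no event
exposure group         a          b
reference set          c          d
====================  =========  ============

Two signal metrics are computed:

* **ROR** — the reporting odds ratio ``(a·d)/(b·c)`` with a Wald 95%
  confidence interval on the log scale,
  ``exp(ln ROR ± z · sqrt(1/a + 1/b + 1/c + 1/d))``.  When any cell is zero
  all four cells get the Haldane–Anscombe 0.5 continuity correction.

* **IC** — the shrinkage information component of the Bayesian confidence
  propagation neural network (BCPNN): with observed count ``O = a`` and
  expected count ``E = (a+b)(a+c)/n`` under independence,
  ``IC = log2((O + s)/(E + s))`` with shrink parameter ``s`` (default 0.5).
  The lower end of the 95% credibility interval uses the closed-form
  approximation ``IC025 = IC − 3.3(O+s)^(−1/2) − 2.4(O+s)^(−3/2)``; a
  Monte-Carlo mode draws the observed-to-expected ratio posterior
  Gamma(O+s, rate E+s) and returns the empirical 2.5th percentile for
  cross-validation.

A drug–event pair is a **positive signal** when n ≥ 3, the ROR lower bound
exceeds 1 and IC025 exceeds 0 — both metrics must agree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedSignalError, FaersPVError
from .faers_ingest import CaseReport, CaseTable
from .termset import TermSet

#: 97.5th normal percentile used for all 95% intervals (not rounded to 1.96).
Z95 = 1.959964


@dataclass(frozen=True)
class ContingencyTable:
    """The 2×2 counts behind a disproportionality statistic.

    Cells may be non-integral (analytic expectations use the same type).
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be nonnegative")

    @property
    def n_total(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def n_exposed(self) -> float:
        return self.a + self.b

    @property
    def n_reference(self) -> float:
        return self.c + self.d

    @property
    def expected(self) -> float:
        """Expected event count in the exposure group under independence."""
        if self.n_total == 0:
            raise UndefinedSignalError("empty contingency table")
        return (self.a + self.b) * (self.a + self.c) / self.n_total

    def corrected(self) -> "ContingencyTable":
        """All cells + 0.5 (Haldane–Anscombe continuity correction)."""
        return ContingencyTable(self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)


@dataclass
class RorResult:
    ror: float
    low: float
    high: float
    z: float
    p: float
    corrected: bool


@dataclass
class SignalResult:
    """Per-event, per-group statistics with positivity flag and audit cells."""

    label: str
    group: str
    n: int
    ror: float
    ror_low: float
    ror_high: float
    ic: float
    ic025: float
    positive: bool
    p: float = float("nan")
    table: ContingencyTable | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# Core statistics
# ---------------------------------------------------------------------------

def ror_with_ci(t: ContingencyTable, alpha: float = 0.05) -> RorResult:
    """Reporting odds ratio with Wald confidence interval.

    Undefined when the exposure or reference margin is empty.  Zero cells are
    handled by the 0.5 continuity correction; the all-zero table remains
    undefined.
    """
    if t.n_exposed == 0:
        raise UndefinedSignalError("no exposure cases (a + b = 0)")
    if t.n_reference == 0:
        raise UndefinedSignalError("no reference cases (c + d = 0)")
    corrected = min(t.a, t.b, t.c, t.d) == 0
    u = t.corrected() if corrected else t
    z_crit = stats.norm.ppf(1 - alpha / 2) if alpha != 0.05 else Z95
    log_ror = math.log(u.a) + math.log(u.d) - math.log(u.b) - math.log(u.c)
    se = math.sqrt(1 / u.a + 1 / u.b + 1 / u.c + 1 / u.d)
    z = log_ror / se
    p = 2.0 * stats.norm.sf(abs(z))
    return RorResult(
        ror=math.exp(log_ror),
        low=math.exp(log_ror - z_crit * se),
        high=math.exp(log_ror + z_crit * se),
        z=z, p=float(p), corrected=corrected,
    )


def ic_with_ic025(
    t: ContingencyTable,
    shrink: float = 0.5,
    method: str = "closed_form",
    n_draws: int = 1_000_000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Shrinkage information component and its 95% credibility lower bound.

    ``method="closed_form"`` (default) uses the two-term expansion of the
    gamma posterior quantile; ``method="monte_carlo"`` samples the
    observed-to-expected ratio posterior Gamma(O+shrink, rate E+shrink) and
    takes the empirical 2.5th percentile.
    """
    if shrink <= 0:
        raise ValueError("shrink parameter must be positive")
    if t.n_total == 0:
        raise UndefinedSignalError("empty contingency table")
    o = t.a
    e = t.expected
    ic = math.log2((o + shrink) / (e + shrink))
    if method == "closed_form":
        os = o + shrink
        ic025 = ic - 3.3 * os ** -0.5 - 2.4 * os ** -1.5
    elif method == "monte_carlo":
        rng = np.random.default_rng(0) if rng is None else rng
        draws = rng.gamma(shape=o + shrink, scale=1.0, size=int(n_draws)) / (e + shrink)
        ic025 = float(np.log2(np.quantile(draws, 0.025)))
    else:
        raise ValueError(f"unknown method {method!r}")
    return ic, ic025


def flag_positive(r: SignalResult, n_min: int = 3) -> bool:
    """Positivity rule: n ≥ n_min AND ROR lower bound > 1 AND IC025 > 0."""
    return bool(r.n >= n_min and r.ror_low > 1.0 and r.ic025 > 0.0)


# ---------------------------------------------------------------------------
# Table construction from case data
# ---------------------------------------------------------------------------

def contingency_from_sets(exposure_ids: set, reference_ids: set,
                          event_ids: set) -> ContingencyTable:
    """2×2 from caseid sets; exposure and reference must be disjoint."""
    overlap = exposure_ids & reference_ids
    if overlap:
        sample = sorted(overlap)[:5]
        raise FaersPVError(
            f"exposure and reference sets overlap ({len(overlap)} caseids, e.g. {sample})")
    a = len(exposure_ids & event_ids)
    c = len(reference_ids & event_ids)
    return ContingencyTable(a, len(exposure_ids) - a, c, len(reference_ids) - c)


def build_contingency(
    cases: Iterable[CaseReport],
    exposure_predicate: Callable[[CaseReport], bool],
    event_predicate: Callable[[CaseReport], bool],
    reference_predicate: Callable[[CaseReport], bool],
) -> ContingencyTable:
    """Count deduplicated cases into a 2×2 using three predicates.

    The counting unit is the case: a case with several matched reactions
    still contributes one count.  Overlapping exposure/reference predicates
    are a logic error reported with the offending caseids.
    """
    exposure, reference, events = set(), set(), set()
    for case in cases:
        if exposure_predicate(case):
            exposure.add(case.caseid)
        if reference_predicate(case):
            reference.add(case.caseid)
        if event_predicate(case):
            events.add(case.caseid)
    return contingency_from_sets(exposure, reference, events)


def event_caseids(table: CaseTable, terms: TermSet) -> set:
    """Caseids with at least one reaction in the term set."""
    r = table.reactions
    return set(r.loc[r["pt"].isin(terms.pts), "caseid"].unique())


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

def _signal(label: str, group: str, t: ContingencyTable, n_min: int,
            shrink: float, alpha: float) -> SignalResult:
    ror = ror_with_ci(t, alpha=alpha)
    ic, ic025 = ic_with_ic025(t, shrink=shrink)
    r = SignalResult(label=label, group=group, n=int(t.a), ror=ror.ror,
                     ror_low=ror.low, ror_high=ror.high, ic=ic, ic025=ic025,
                     positive=False, p=ror.p, table=t)
    r.positive = flag_positive(r, n_min=n_min)
    return r


def screen_all_pts(
    table: CaseTable,
    labels: pd.Series | pd.DataFrame,
    group_label: str,
    terms: TermSet,
    reference_mode: str = "full_database",
    reference_label: str | None = None,
    n_min: int = 3,
    shrink: float = 0.5,
    alpha: float = 0.05,
) -> list[SignalResult]:
    """Per-PT disproportionality screen for one exposure group.

    Counts each PT in the term set within the group against either the rest
    of the database (``full_database``) or another group (``other_group``),
    returning one :class:`SignalResult` per PT observed at least once in the
    group, sorted by PT name.
    """
    if isinstance(labels, pd.DataFrame):
        labels = labels["label"]
    if reference_mode not in ("full_database", "other_group"):
        raise ValueError(f"unknown reference mode {reference_mode!r}")
    group_ids = set(labels.index[labels == group_label])
    if reference_mode == "full_database":
        ref_ids = set(labels.index) - group_ids
    else:
        if reference_label is None:
            raise ValueError("other_group reference requires reference_label")
        ref_ids = set(labels.index[labels == reference_label])
    if not group_ids:
        raise UndefinedSignalError(f"group {group_label!r} is empty")
    if not ref_ids:
        raise UndefinedSignalError("reference set is empty")

    r = table.reactions
    r = r[r["pt"].isin(terms.pts)]
    in_group = r["caseid"].isin(group_ids)
    in_ref = r["caseid"].isin(ref_ids)
    a_counts = r.loc[in_group].groupby("pt")["caseid"].nunique()
    c_counts = r.loc[in_ref].groupby("pt")["caseid"].nunique()

    n_g, n_r = len(group_ids), len(ref_ids)
    results = []
    for pt in sorted(a_counts.index):
        a = int(a_counts[pt])
        c = int(c_counts.get(pt, 0))
        t = ContingencyTable(a, n_g - a, c, n_r - c)
        results.append(_signal(pt, group_label, t, n_min, shrink, alpha))
    return results


def head_to_head_ror(
    table: CaseTable,
    labels: pd.Series | pd.DataFrame,
    group_a_label: str,
    group_b_label: str,
    terms: TermSet,
    n_min: int = 3,
    shrink: float = 0.5,
    alpha: float = 0.05,
) -> SignalResult:
    """Any-event ROR of group A against group B as the reference.

    Reproduces the reference-group comparison design: the combination group
    screened against a monotherapy group, with a two-sided Wald p-value.
    """
    if isinstance(labels, pd.DataFrame):
        labels = labels["label"]
    a_ids = set(labels.index[labels == group_a_label])
    b_ids = set(labels.index[labels == group_b_label])
    if not a_ids or not b_ids:
        raise UndefinedSignalError(
            f"empty group in head-to-head comparison "
            f"({group_a_label}: {len(a_ids)}, {group_b_label}: {len(b_ids)})")
    events = event_caseids(table, terms)
    t = contingency_from_sets(a_ids, b_ids, events)
    return _signal(f"any:{terms.name}", f"{group_a_label}_vs_{group_b_label}",
                   t, n_min, shrink, alpha)


def signals_to_frame(results: list[SignalResult]) -> pd.DataFrame:
    """Table-1-style frame with audit cells for every screened event."""
    rows = []
    for r in results:
        t = r.table
        rows.append(dict(
            pt=r.label, group=r.group, n=r.n, ror=r.ror, ror_low=r.ror_low,
            ror_high=r.ror_high, ic=r.ic, ic025=r.ic025, positive=r.positive,
            p=r.p, a=t.a if t else np.nan, b=t.b if t else np.nan,
            c=t.c if t else np.nan, d=t.d if t else np.nan,
        ))
    return pd.DataFrame(rows, columns=[
        "pt", "group", "n", "ror", "ror_low", "ror_high", "ic", "ic025",
        "positive", "p", "a", "b", "c", "d"])
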