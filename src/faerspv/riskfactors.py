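"""Univariate logistic-regression screening of risk factors.

Within a cohort (typically the combination-therapy group), the outcome is a
binary event indicator per case and each factor is screened on its own:
``logit P(event) = β0 + β1 · x``.  Categorical factors are dummy-coded
against a declared reference level; continuous factors enter as-is or in
configurable bands.  Fitting is maximum likelihood by iteratively reweighted
least squares (Newton–Raphson), converged when the log-likelihood moves by
less than 1e-8, at most 50 iterations.  Intervals and p-values are Wald.

Complete-case rule: cases missing the outcome or the factor are dropped;
``n_used`` reports what remained.  Separated or non-converged fits are
flagged non-estimable rather than reported with exploded coefficients.

The module also tabulates co-reported events: among eventful cases, the
fraction whose reaction list contains at least one PT outside the event term
set, optionally broken down by a user-supplied PT → SOC map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .disprop import Z95
from .errors import ConfigError
from .termset import TermSet
from .faers_ingest import CaseTable

#: absolute log-odds beyond which a fit is declared separated
SEPARATION_BOUND = 15.0


@dataclass(frozen=True)
class FactorSpec:
    """One screened factor.

    kind: "categorical" (dummy-coded vs `reference`), "binary" (0/1) or
    "continuous" (single slope; optional `bands` turn it categorical).
    """

    name: str
    kind: str = "categorical"
    reference: str | None = None
    bands: tuple | None = None  # ((lo, hi, label), ...) for banded continuous

    def __post_init__(self):
        if self.kind not in ("categorical", "binary", "continuous"):
            raise ConfigError(f"unknown factor kind {self.kind!r}")


@dataclass
class LogisticFitResult:
    factor: str
    level: str  # non-reference level, or the factor name for slopes
    odds_ratio: float
    ci95: tuple[float, float]
    p_value: float
    n_used: int
    estimable: bool = True
    note: str = ""


@dataclass
class IRLSFit:
    beta: np.ndarray
    cov: np.ndarray
    converged: bool
    n_iter: int
    loglik_trace: list = field(default_factory=list)


def fit_logistic_irls(X: np.ndarray, y: np.ndarray, tol: float = 1e-8,
                      max_iter: int = 50) -> IRLSFit:
    """Logistic MLE by Newton–Raphson / IRLS on design matrix ``X``.

    The log-likelihood trace is kept so monotone ascent is checkable; weights
    are floored at 1e-10 to keep the normal equations solvable near
    saturation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)
    trace: list[float] = []
    converged = False
    cov = np.full((p, p), np.nan)
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        xtw = X.T * w
        info = xtw @ X
        score = X.T @ (y - mu)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            trace.append(ll)
            break
        beta = beta + step
        trace.append(ll)
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
    if converged or it == max_iter:
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        info = (X.T * w) @ X
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            pass
    return IRLSFit(beta=beta, cov=cov, converged=converged, n_iter=it,
                   loglik_trace=trace)


def _wald(beta: float, se: float) -> tuple[float, tuple[float, float], float]:
    orr = float(np.exp(beta))
    lo = float(np.exp(beta - Z95 * se))
    hi = float(np.exp(beta + Z95 * se))
    p = float(2.0 * stats.norm.sf(abs(beta) / se)) if se > 0 else float("nan")
    return orr, (lo, hi), p


def _band(values: pd.Series, bands) -> pd.Series:
    labels = pd.Series(pd.NA, index=values.index, dtype=object)
    for lo, hi, lab in bands:
        mask = (values >= lo) & (values < hi)
        labels[mask] = lab
    return labels


def fit_univariate_logistic(
    outcome: pd.Series,
    factor: pd.Series,
    spec: FactorSpec,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> list[LogisticFitResult]:
    """Screen one factor against a binary outcome.

    Returns one result per non-reference level (or one slope for a
    continuous factor).  Deterministic for a fixed input order: levels are
    processed in sorted order and the complete-case subset is index-aligned.
    """
    df = pd.DataFrame({"y": outcome, "x": factor}).dropna()
    df = df[df["x"] != ""] if df["x"].dtype == object else df
    y = df["y"].astype(float).to_numpy()
    n_used = len(df)
    name = spec.name

    def _not_estimable(level: str, note: str) -> LogisticFitResult:
        nan = float("nan")
        return LogisticFitResult(name, level, nan, (nan, nan), nan, n_used,
                                 estimable=False, note=note)

    if n_used == 0 or len(np.unique(y)) < 2:
        return [_not_estimable(name, "outcome has a single class among complete cases")]

    if spec.kind == "continuous" and spec.bands is None:
        x = df["x"].astype(float).to_numpy()
        if np.all(x == x[0]):
            return [_not_estimable(name, "no contrast: factor constant")]
        X = np.column_stack([np.ones_like(x), x])
        fit = fit_logistic_irls(X, y, tol=tol, max_iter=max_iter)
        if not fit.converged or abs(fit.beta[1]) > SEPARATION_BOUND:
            return [_not_estimable(name, "separation or non-convergence")]
        se = float(np.sqrt(fit.cov[1, 1]))
        orr, ci, p = _wald(float(fit.beta[1]), se)
        return [LogisticFitResult(name, name, orr, ci, p, n_used)]

    levels_series = (_band(df["x"].astype(float), spec.bands)
                     if spec.kind == "continuous" else df["x"].astype(str))
    keep = levels_series.notna()
    levels_series = levels_series[keep]
    y = y[keep.to_numpy()]
    n_used = int(keep.sum())
    observed = sorted(levels_series.unique())
    if len(observed) < 2:
        return [_not_estimable(name, "no contrast: factor constant")]
    reference = spec.reference
    if reference is None:
        reference = observed[0]
    if reference not in observed:
        raise ConfigError(
            f"factor {name!r}: reference level {reference!r} not observed")
    others = [lv for lv in observed if lv != reference]
    dummies = np.column_stack([(levels_series == lv).to_numpy(float) for lv in others])
    X = np.column_stack([np.ones(len(y)), dummies])
    fit = fit_logistic_irls(X, y, tol=tol, max_iter=max_iter)

    results = []
    for j, lv in enumerate(others, start=1):
        sub = y[levels_series.to_numpy() == lv]
        separated = sub.size and (sub.min() == sub.max())
        if (not fit.converged or abs(fit.beta[j]) > SEPARATION_BOUND or separated
                or not np.isfinite(fit.cov[j, j])):
            results.append(_not_estimable(
                str(lv), f"separation or non-convergence at level {lv!r}"))
            continue
        se = float(np.sqrt(fit.cov[j, j]))
        orr, ci, p = _wald(float(fit.beta[j]), se)
        results.append(LogisticFitResult(name, str(lv), orr, ci, p, n_used))
    return results


def screen_factors(
    data: pd.DataFrame,
    outcome_col: str,
    specs: list[FactorSpec],
) -> pd.DataFrame:
    """Forest-plot-ready frame: one row per factor level.

    ``data`` holds one row per case with the outcome column (0/1) and one
    column per factor (missing as NaN or empty string).
    """
    rows = []
    for spec in specs:
        if spec.name not in data.columns:
            continue
        for r in fit_univariate_logistic(data[outcome_col], data[spec.name], spec):
            rows.append(dict(factor=r.factor, level=r.level, odds_ratio=r.odds_ratio,
                             ci_low=r.ci95[0], ci_high=r.ci95[1], p=r.p_value,
                             n_used=r.n_used, estimable=r.estimable, note=r.note))
    return pd.DataFrame(rows, columns=["factor", "level", "odds_ratio", "ci_low",
                                       "ci_high", "p", "n_used", "estimable", "note"])


# ---------------------------------------------------------------------------
# Co-reported adverse events
# ---------------------------------------------------------------------------

@dataclass
class CoreportSummary:
    n_cases: int
    n_coreporting: int
    fraction: float
    breakdown: pd.DataFrame | None  # SOC, n, pct of co-reporting cases


def tabulate_coreported(
    table: CaseTable,
    eventful_caseids: set,
    terms: TermSet,
    soc_map: dict | None = None,
) -> CoreportSummary:
    """Fraction of eventful cases that also report a PT outside the term set.

    With a PT → SOC map, the extra-set PTs are bucketed by SOC with
    percentages relative to the co-reporting cases; without one the
    breakdown is skipped and only the fraction is computed.
    """
    r = table.reactions
    r = r[r["caseid"].isin(eventful_caseids)]
    outside = r[~r["pt"].isin(terms.pts)]
    co_ids = set(outside["caseid"].unique())
    n_cases = len(eventful_caseids)
    n_co = len(co_ids)
    frac = n_co / n_cases if n_cases else float("nan")
    breakdown = None
    if soc_map is not None and n_co:
        socs = outside.assign(soc=outside["pt"].map(soc_map).fillna("Unmapped"))
        per_soc = socs.drop_duplicates(["caseid", "soc"])["soc"].value_counts()
        breakdown = pd.DataFrame({
            "soc": per_soc.index,
            "n": per_soc.values,
            "pct_of_coreporting": [round(100.0 * v / n_co, 2) for v in per_soc.values],
        })
    return CoreportSummary(n_cases=n_cases, n_coreporting=n_co,
                           fraction=frac, breakdown=breakdown)
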