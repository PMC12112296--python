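"""Synthetic FAERS-like quarterly tables with a ground-truth manifest.

The generator emulates the structure of spontaneous-report data that the
pipeline consumes: dollar-delimited DEMO/DRUG/REAC/THER/OUTC tables with
duplicate case versions, partial dates, demographic missingness and
group-specific onset distributions — plus planted per-PT disproportionality
so every stage (parse → dedup → classify → screen → onset → risk factors)
can be tested against known truth without any external data.

The generative model, per case:

* exposure group fixed by configuration (ICI_MONO, PPI_MONO, ICI_PPI_COMBO,
  OTHER background); drugs drawn from group-specific agent mixes with
  suspect roles chosen so classification recovers the group exactly;
* each catalogue PT is an independent Bernoulli with probability
  ``base_rate × multiplier(group, pt)`` (capped at 1, with a manifest
  warning), optionally scaled by agent-specific multipliers for planted
  risk-factor effects;
* time to onset is log-normal per group (median and log-sd configured);
  EVENT_DT = START_DT + TTO, FDA_DT trails the event by a short lag;
* duplicates re-emit a case under a different PRIMARYID with an earlier (or
  tied) FDA_DT, so deduplication always recovers the configured case count;
* dates are truncated day → month → year → missing at configured rates,
  mirroring how partial dates appear in the real tables.

Default parameter values follow the reporting patterns of published
checkpoint-inhibitor / acid-suppressant renal safety tables (group mixes,
demographic margins, onset medians of 42 / 805 / 21 days); scale is reduced
to desk size.  What the generator does *not* emulate: the real database's
~25k-PT marginal structure, reporting-rate drift over time, and correlated
multi-drug regimens beyond the study classes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .disprop import ContingencyTable
from .errors import ConfigError

GROUPS = ("ICI_MONO", "PPI_MONO", "ICI_PPI_COMBO", "OTHER")

RENAL_PTS = (
    "acute kidney injury", "blood creatinine increased", "glomerulonephritis",
    "immune-mediated nephritis", "nephritis allergic", "nephropathy toxic",
    "nephrosclerosis", "nephrotic syndrome", "proteinuria", "renal impairment",
    "renal tubular acidosis", "renal tubular atrophy", "renal tubular disorder",
    "renal tubular injury", "renal tubular necrosis", "tubulointerstitial nephritis",
)

#: baseline per-report reporting probabilities (renal PTs roughly follow
#: database-wide relative frequencies; background PTs are common irAEs and
#: general-population terms)
DEFAULT_PT_RATES = {
    "acute kidney injury": 0.0097,
    "renal impairment": 0.0040,
    "blood creatinine increased": 0.0033,
    "tubulointerstitial nephritis": 0.0010,
    "proteinuria": 0.00087,
    "nephropathy toxic": 0.00050,
    "renal tubular necrosis": 0.00048,
    "nephrotic syndrome": 0.00033,
    "renal tubular disorder": 0.00015,
    "glomerulonephritis": 0.00012,
    "renal tubular acidosis": 0.00010,
    "nephrosclerosis": 0.000064,
    "renal tubular atrophy": 0.000044,
    "renal tubular injury": 0.000035,
    "nephritis allergic": 0.000018,
    "immune-mediated nephritis": 0.0000089,
    # background (non-renal) catalogue
    "nausea": 0.030, "fatigue": 0.025, "diarrhoea": 0.020, "rash": 0.015,
    "vomiting": 0.015, "headache": 0.015, "pyrexia": 0.012, "dyspnoea": 0.012,
    "pruritus": 0.010, "colitis": 0.004, "pneumonitis": 0.003,
    "hepatitis": 0.002, "hypothyroidism": 0.002, "drug ineffective": 0.050,
}

#: planted relative reporting-rate multipliers (group, pt) -> multiplier;
#: magnitudes follow the published signal pattern (strong tubulointerstitial
#: nephritis signal everywhere, strongest in the combination group)
DEFAULT_PLANTED = (
    ("ICI_MONO", "immune-mediated nephritis", 100.0),
    ("ICI_MONO", "tubulointerstitial nephritis", 4.5),
    ("ICI_MONO", "proteinuria", 4.0),
    ("PPI_MONO", "tubulointerstitial nephritis", 50.0),
    ("PPI_MONO", "acute kidney injury", 16.0),
    ("PPI_MONO", "nephrosclerosis", 34.0),
    ("ICI_PPI_COMBO", "tubulointerstitial nephritis", 115.0),
    ("ICI_PPI_COMBO", "acute kidney injury", 18.0),
    ("ICI_PPI_COMBO", "renal tubular acidosis", 40.0),
    ("ICI_PPI_COMBO", "glomerulonephritis", 24.0),
    # hallmark immune-related AEs co-reported in checkpoint-inhibitor groups
    ("ICI_MONO", "colitis", 10.0), ("ICI_MONO", "pneumonitis", 10.0),
    ("ICI_MONO", "hepatitis", 8.0), ("ICI_MONO", "hypothyroidism", 8.0),
    ("ICI_MONO", "rash", 3.0),
    ("ICI_PPI_COMBO", "colitis", 10.0), ("ICI_PPI_COMBO", "pneumonitis", 10.0),
    ("ICI_PPI_COMBO", "hepatitis", 8.0), ("ICI_PPI_COMBO", "hypothyroidism", 8.0),
    ("ICI_PPI_COMBO", "rash", 3.0),
)

_ICI_SINGLE = (("pembrolizumab", 0.384), ("nivolumab", 0.344), ("atezolizumab", 0.174),
               ("ipilimumab", 0.045), ("durvalumab", 0.026), ("avelumab", 0.013),
               ("cemiplimab", 0.012), ("tremelimumab", 0.002))
_PPI_MIX = (("esomeprazole", 0.367), ("lansoprazole", 0.281), ("pantoprazole", 0.194),
            ("omeprazole", 0.090), ("dexlansoprazole", 0.052), ("rabeprazole", 0.016))
_COMBO_ICI = (("nivolumab", 0.48), ("pembrolizumab", 0.33), ("atezolizumab", 0.10),
              ("durvalumab", 0.05), ("ipilimumab", 0.03), ("avelumab", 0.01))
_COMBO_PPI = (("omeprazole", 0.48), ("pantoprazole", 0.25), ("esomeprazole", 0.14),
              ("lansoprazole", 0.09), ("rabeprazole", 0.04))
_OTHER_DRUGS = ("aspirin", "metformin", "ibuprofen", "atorvastatin",
                "lisinopril", "amoxicillin", "paracetamol", "warfarin")

_REGION_CODES = {
    "Americas": ("US", "US", "US", "US", "CA", "BR"),
    "Europe": ("FR", "DE", "GB", "IT", "ES"),
    "Asia": ("JP", "JP", "CN", "KR"),
    "Oceania": ("AU", "NZ"),
    "Africa": ("ZA", "EG"),
    "Missing": ("",),
}

_DEFAULT_REGION_MIX = {
    "ICI_MONO": {"Americas": 0.321, "Europe": 0.275, "Asia": 0.386,
                 "Oceania": 0.015, "Africa": 0.002, "Missing": 0.001},
    "PPI_MONO": {"Americas": 0.944, "Europe": 0.045, "Asia": 0.006,
                 "Oceania": 0.002, "Africa": 0.0, "Missing": 0.003},
    "ICI_PPI_COMBO": {"Americas": 0.481, "Europe": 0.367, "Asia": 0.143,
                      "Oceania": 0.005, "Africa": 0.0, "Missing": 0.004},
    "OTHER": {"Americas": 0.60, "Europe": 0.25, "Asia": 0.12,
              "Oceania": 0.02, "Africa": 0.005, "Missing": 0.005},
}
_DEFAULT_SEX_MIX = {  # (male, female, missing)
    "ICI_MONO": (0.63, 0.30, 0.07),
    "PPI_MONO": (0.25, 0.34, 0.41),
    "ICI_PPI_COMBO": (0.55, 0.39, 0.06),
    "OTHER": (0.40, 0.50, 0.10),
}
_DEFAULT_REPORTER_MIX = {  # (healthcare, non-healthcare, missing)
    "ICI_MONO": (0.82, 0.17, 0.01),
    "PPI_MONO": (0.13, 0.53, 0.34),
    "ICI_PPI_COMBO": (0.97, 0.02, 0.01),
    "OTHER": (0.50, 0.40, 0.10),
}
_DEFAULT_AGE = {  # (median, sd, p_missing)
    "ICI_MONO": (70.0, 9.0, 0.85),
    "PPI_MONO": (61.0, 10.0, 0.95),
    "ICI_PPI_COMBO": (60.0, 8.0, 0.90),
    "OTHER": (55.0, 15.0, 0.70),
}
_DEFAULT_YEAR_MIX = {  # over bins 2004-2008 / 2009-2013 / 2014-2018 / 2019-2022
    "ICI_MONO": (0.0, 0.01, 0.27, 0.72),
    "PPI_MONO": (0.006, 0.015, 0.247, 0.732),
    "ICI_PPI_COMBO": (0.0, 0.0, 0.15, 0.85),
    "OTHER": (0.10, 0.15, 0.30, 0.45),
}
_YEAR_BIN_RANGES = ((2004, 2008), (2009, 2013), (2014, 2018), (2019, 2022))
_DEFAULT_OUTCOME_RATES = {
    "ICI_MONO": {"DE": 0.194, "LT": 0.113, "HO": 0.612, "DS": 0.031, "OT": 0.82},
    "PPI_MONO": {"DE": 0.111, "LT": 0.012, "HO": 0.118, "DS": 0.015, "OT": 0.95},
    "ICI_PPI_COMBO": {"DE": 0.043, "LT": 0.114, "HO": 0.548, "DS": 0.024, "OT": 0.78},
    "OTHER": {"DE": 0.10, "LT": 0.05, "HO": 0.30, "DS": 0.02, "OT": 0.70},
}
_DEFAULT_RENAL_MALIGNANCY = {"ICI_MONO": 0.017, "PPI_MONO": 0.0002,
                             "ICI_PPI_COMBO": 0.19, "OTHER": 0.01}


@dataclass(frozen=True)
class OnsetModel:
    """Log-normal time-to-onset: median in days, log-scale sd."""
    median_days: float
    sigma: float


DEFAULT_ONSET = {
    "ICI_MONO": OnsetModel(42.0, 1.5),
    "PPI_MONO": OnsetModel(805.0, 2.1),
    "ICI_PPI_COMBO": OnsetModel(21.0, 2.4),
    "OTHER": OnsetModel(120.0, 1.5),
}


@dataclass
class SyntheticConfig:
    """Generator parameters; ``seed`` is mandatory and drives all draws."""

    seed: int
    n_per_group: dict = field(default_factory=lambda: {
        "ICI_MONO": 4000, "PPI_MONO": 8000, "ICI_PPI_COMBO": 400, "OTHER": 40000})
    pt_rates: dict = field(default_factory=lambda: dict(DEFAULT_PT_RATES))
    event_pts: tuple = RENAL_PTS
    planted_signals: tuple = DEFAULT_PLANTED
    agent_event_multipliers: dict = field(default_factory=dict)
    duplicate_rate: float = 0.08
    date_precision_probs: dict = field(default_factory=lambda: {
        "day": 0.65, "month": 0.15, "year": 0.08, "missing": 0.12})
    onset_models: dict = field(default_factory=lambda: dict(DEFAULT_ONSET))
    quarter_label: str = "2023Q1"

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        for pt, rate in self.pt_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"rate for {pt!r} outside [0, 1]")
        for g, pt, m in self.planted_signals:
            if m <= 0:
                raise ConfigError(f"multiplier for ({g}, {pt}) must be > 0")
            if pt not in self.pt_rates:
                raise ConfigError(f"planted signal for unknown PT {pt!r}")
            if g not in GROUPS:
                raise ConfigError(f"planted signal for unknown group {g!r}")
        if abs(sum(self.date_precision_probs.values()) - 1.0) > 1e-9:
            raise ConfigError("date precision probabilities must sum to 1")

    # -- model accessors ----------------------------------------------------

    def multiplier(self, group: str, pt: str) -> float:
        m = 1.0
        for g, p, mult in self.planted_signals:
            if g == group and p == pt:
                m *= mult
        return m

    def group_pt_prob(self, group: str, pt: str) -> tuple[float, bool]:
        """Per-case event probability and whether the cap at 1 was hit."""
        if group not in self.n_per_group:
            raise ConfigError(f"unknown group {group!r}")
        if pt not in self.pt_rates:
            raise ConfigError(f"unknown PT {pt!r}")
        p = self.pt_rates[pt] * self.multiplier(group, pt)
        return (min(p, 1.0), p > 1.0)


@dataclass
class Manifest:
    """Ground truth for the emitted tables, consistent by construction."""

    seed: int
    n_cases_by_group: dict
    pt_counts_by_group: dict  # group -> {pt: true deduplicated case count}
    planted_multipliers: list
    duplicate_count: int
    onset_median_by_group: dict
    capped_probabilities: list
    n_reports_emitted: int

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class SyntheticDataset:
    tables: dict  # role -> DataFrame (DEMO, DRUG, REAC, THER, OUTC)
    manifest: Manifest
    config: SyntheticConfig


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _choice(rng, options, n):
    names = [o[0] for o in options]
    w = np.array([o[1] for o in options], dtype=float)
    return rng.choice(names, size=n, p=w / w.sum())


def _mix3(rng, probs, n, labels):
    return rng.choice(labels, size=n, p=np.array(probs) / np.sum(probs))


def _date_digits(dates: np.ndarray) -> np.ndarray:
    """YYYYMMDD strings from a datetime64[D] array (vectorized)."""
    dti = pd.DatetimeIndex(dates)
    return (dti.year * 10000 + dti.month * 100 + dti.day).astype(np.int64).astype(str)


def _format_dates(dates: np.ndarray, precision: np.ndarray) -> np.ndarray:
    dti = pd.DatetimeIndex(dates)
    day_s = (dti.year * 10000 + dti.month * 100 + dti.day).astype(np.int64).astype(str)
    month_s = (dti.year * 100 + dti.month).astype(np.int64).astype(str)
    year_s = dti.year.astype(np.int64).astype(str)
    return np.select(
        [precision == "day", precision == "month", precision == "year"],
        [day_s, month_s, year_s], default="")


def generate(config: SyntheticConfig, out_dir=None) -> SyntheticDataset:
    """Emit FAERS-dialect tables plus the ground-truth manifest.

    All randomness flows from ``config.seed``; the same seed and config give
    byte-identical files.  If ``out_dir`` is given the five tables are
    written as ``DEMO<quarter>.txt`` etc. with ``manifest.json`` beside them.
    """
    rng = np.random.default_rng(config.seed)
    groups_order = [g for g in GROUPS if config.n_per_group.get(g, 0) > 0]
    n_by_group = {g: int(config.n_per_group[g]) for g in groups_order}
    n_total = sum(n_by_group.values())
    group_arr = np.repeat(groups_order, [n_by_group[g] for g in groups_order])
    caseid_num = np.arange(1, n_total + 1)
    caseid = caseid_num.astype(str)
    primaryid = (caseid_num * 10 + 5).astype(str)  # survivor version

    pts = list(config.pt_rates)
    pt_idx = {p: j for j, p in enumerate(pts)}
    renal_cols = np.array([p in set(config.event_pts) for p in pts])

    # --- drugs -------------------------------------------------------------
    drug_rows = {"caseid": [], "ingredient": [], "role": []}
    agent_mult = np.ones(n_total)
    for g in groups_order:
        mask = group_arr == g
        n_g = int(mask.sum())
        if g == "ICI_MONO":
            dual = rng.random(n_g) < 0.187
            single = _choice(rng, _ICI_SINGLE, n_g)
            ing1 = np.where(dual, "nivolumab", single)
            drug_rows["caseid"].append(caseid[mask])
            drug_rows["ingredient"].append(ing1)
            drug_rows["role"].append(np.full(n_g, "PS"))
            drug_rows["caseid"].append(caseid[mask][dual])
            drug_rows["ingredient"].append(np.full(int(dual.sum()), "ipilimumab"))
            drug_rows["role"].append(np.full(int(dual.sum()), "SS"))
            primary_agent = ing1
        elif g == "PPI_MONO":
            primary_agent = _choice(rng, _PPI_MIX, n_g)
            drug_rows["caseid"].append(caseid[mask])
            drug_rows["ingredient"].append(primary_agent)
            drug_rows["role"].append(np.full(n_g, "PS"))
        elif g == "ICI_PPI_COMBO":
            ici = _choice(rng, _COMBO_ICI, n_g)
            ppi = _choice(rng, _COMBO_PPI, n_g)
            dual = rng.random(n_g) < 0.114  # add ipilimumab to model regimen combos
            swap = rng.random(n_g) < 0.5    # which partner carries the PS role
            drug_rows["caseid"].append(caseid[mask])
            drug_rows["ingredient"].append(ici)
            drug_rows["role"].append(np.where(swap, "SS", "PS"))
            drug_rows["caseid"].append(caseid[mask])
            drug_rows["ingredient"].append(ppi)
            drug_rows["role"].append(np.where(swap, "PS", "SS"))
            extra = dual & (ici != "ipilimumab")
            drug_rows["caseid"].append(caseid[mask][extra])
            drug_rows["ingredient"].append(np.full(int(extra.sum()), "ipilimumab"))
            drug_rows["role"].append(np.full(int(extra.sum()), "SS"))
            primary_agent = ppi  # agent-effect multipliers act on the PPI partner
        else:  # OTHER
            primary_agent = rng.choice(_OTHER_DRUGS, size=n_g)
            drug_rows["caseid"].append(caseid[mask])
            drug_rows["ingredient"].append(primary_agent)
            drug_rows["role"].append(np.full(n_g, "PS"))
        if config.agent_event_multipliers:
            mults = np.array([config.agent_event_multipliers.get((g, a), 1.0)
                              for a in primary_agent])
            agent_mult[mask] = mults

    drugs = pd.DataFrame({k: np.concatenate(v) for k, v in drug_rows.items()})

    # --- reactions ---------------------------------------------------------
    capped = []
    prob_by_group = np.zeros((len(groups_order), len(pts)))
    for i, g in enumerate(groups_order):
        for j, pt in enumerate(pts):
            p, was_capped = config.group_pt_prob(g, pt)
            prob_by_group[i, j] = p
            if was_capped:
                capped.append({"group": g, "pt": pt})
    gidx = np.repeat(np.arange(len(groups_order)),
                     [n_by_group[g] for g in groups_order])
    case_probs = prob_by_group[gidx]
    case_probs = np.where(renal_cols[None, :],
                          np.minimum(case_probs * agent_mult[:, None], 1.0),
                          case_probs)
    events = rng.random((n_total, len(pts))) < case_probs

    case_rows, pt_rows = np.nonzero(events)
    reac = pd.DataFrame({"caseid": caseid[case_rows],
                         "pt": np.array(pts, dtype=object)[pt_rows]})
    no_event = ~events.any(axis=1)
    filler = pd.DataFrame({"caseid": caseid[no_event],
                           "pt": "product use issue"})
    reac = pd.concat([reac, filler], ignore_index=True)

    renal_event = events[:, renal_cols].any(axis=1)

    # --- dates -------------------------------------------------------------
    bin_idx = np.empty(n_total, dtype=int)
    for g in groups_order:
        mask = group_arr == g
        bin_idx[mask] = rng.choice(4, size=int(mask.sum()),
                                   p=np.array(_DEFAULT_YEAR_MIX[g]) / sum(_DEFAULT_YEAR_MIX[g]))
    lo = np.array([r[0] for r in _YEAR_BIN_RANGES])[bin_idx]
    hi = np.array([r[1] for r in _YEAR_BIN_RANGES])[bin_idx]
    year = rng.integers(lo, hi + 1)
    day_of_year = rng.integers(0, 365, size=n_total)
    start = ((year - 1970).astype("timedelta64[Y]") + np.datetime64("1970", "Y")
             ).astype("datetime64[D]") + day_of_year.astype("timedelta64[D]")

    tto = np.zeros(n_total)
    for g in groups_order:
        mask = group_arr == g
        m = config.onset_models[g]
        tto[mask] = rng.lognormal(np.log(m.median_days), m.sigma, int(mask.sum()))
    # cap the log-normal upper tail so emitted dates stay within a plausible
    # reporting horizon (the cap sits far above every configured quartile)
    tto_days = np.minimum(np.round(tto).astype(int), 10_000)
    event_date = start + tto_days.astype("timedelta64[D]")
    fda_date = event_date + rng.integers(7, 121, size=n_total).astype("timedelta64[D]")

    prec_labels = np.array(list(config.date_precision_probs))
    prec_p = np.array(list(config.date_precision_probs.values()), dtype=float)
    start_prec = rng.choice(prec_labels, size=n_total, p=prec_p)
    event_prec = rng.choice(prec_labels, size=n_total, p=prec_p)
    start_str = _format_dates(start, start_prec)
    event_str = _format_dates(event_date, event_prec)
    fda_str = _date_digits(fda_date)

    # --- demographics ------------------------------------------------------
    sex = np.empty(n_total, dtype=object)
    country = np.empty(n_total, dtype=object)
    occp = np.empty(n_total, dtype=object)
    age_val = np.full(n_total, "", dtype=object)
    age_cod = np.full(n_total, "", dtype=object)
    indi = np.full(n_total, "", dtype=object)
    for g in groups_order:
        mask = group_arr == g
        n_g = int(mask.sum())
        sex[mask] = _mix3(rng, _DEFAULT_SEX_MIX[g], n_g, np.array(["M", "F", ""]))
        regions = rng.choice(list(_DEFAULT_REGION_MIX[g]), size=n_g,
                             p=np.array(list(_DEFAULT_REGION_MIX[g].values()))
                             / sum(_DEFAULT_REGION_MIX[g].values()))
        codes = np.empty(n_g, dtype=object)
        for r, opts in _REGION_CODES.items():
            rmask = regions == r
            if rmask.any():
                codes[rmask] = rng.choice(opts, size=int(rmask.sum()))
        country[mask] = codes
        rep = _mix3(rng, _DEFAULT_REPORTER_MIX[g], n_g,
                    np.array(["healthcare", "non-healthcare", ""]))
        occp[mask] = np.where(rep == "healthcare",
                              rng.choice(["MD", "PH", "OT"], size=n_g),
                              np.where(rep == "non-healthcare", "CN", ""))
        med, sd, p_miss = _DEFAULT_AGE[g]
        ages = np.clip(rng.normal(med, sd, n_g), 18, 95)
        known = rng.random(n_g) >= p_miss
        in_months = rng.random(n_g) < 0.1  # exercise unit conversion
        vals = np.where(in_months, np.round(ages * 12).astype(int).astype(str),
                        np.round(ages).astype(int).astype(str))
        cods = np.where(in_months, "MON", "YR")
        age_val[mask] = np.where(known, vals, "")
        age_cod[mask] = np.where(known, cods, "")
        diag = rng.random(n_g) < _DEFAULT_RENAL_MALIGNANCY[g]
        indi[mask] = np.where(diag, "renal cell carcinoma", "")

    wt_known = rng.random(n_total) >= 0.85
    wt = np.where(wt_known,
                  np.round(np.clip(rng.normal(72, 15, n_total), 35, 180), 1).astype(str),
                  "")

    demo = pd.DataFrame({
        "primaryid": primaryid, "caseid": caseid, "fda_dt": fda_str,
        "event_dt": event_str, "sex": sex, "age": age_val, "age_cod": age_cod,
        "wt": wt, "wt_cod": np.where(wt != "", "KG", ""),
        "reporter_country": country, "occp_cod": occp, "indi_pt": indi,
    })

    # --- outcomes ----------------------------------------------------------
    outc_rows = {"caseid": [], "outc_cod": []}
    for g in groups_order:
        mask = group_arr == g
        ids = caseid[mask]
        for code, p in _DEFAULT_OUTCOME_RATES[g].items():
            hit = rng.random(ids.size) < p
            outc_rows["caseid"].append(ids[hit])
            outc_rows["outc_cod"].append(np.full(int(hit.sum()), code))
    outc = pd.DataFrame({k: np.concatenate(v) for k, v in outc_rows.items()})

    # --- duplicates --------------------------------------------------------
    n_dup = int(round(config.duplicate_rate * n_total))
    dup_pos = np.sort(rng.choice(n_total, size=n_dup, replace=False)) if n_dup else np.array([], dtype=int)
    dup_demo = demo.iloc[dup_pos].copy()
    dup_demo["primaryid"] = (caseid_num[dup_pos] * 10 + 1).astype(str)
    tie = rng.random(n_dup) < 0.2  # same FDA_DT, lower PRIMARYID loses
    earlier = (fda_date[dup_pos]
               - rng.integers(30, 400, size=n_dup).astype("timedelta64[D]"))
    dup_fda = _date_digits(earlier)
    dup_demo["fda_dt"] = np.where(tie, dup_demo["fda_dt"], dup_fda)
    demo_all = pd.concat([demo, dup_demo], ignore_index=True)

    pid_map = demo_all[["primaryid", "caseid"]]

    def _childify(df: pd.DataFrame, cols: list) -> pd.DataFrame:
        out = df.merge(pid_map, on="caseid")
        return (out[["primaryid", "caseid"] + cols]
                .sort_values(["primaryid"] + cols, kind="mergesort")
                .reset_index(drop=True))

    drug_table = drugs.rename(columns={"ingredient": "drugname", "role": "role_cod"})
    drug_table = _childify(drug_table, ["drugname", "role_cod"])
    drug_table["drug_seq"] = (drug_table.groupby("primaryid").cumcount() + 1).astype(str)
    ther_table = drug_table[["primaryid", "caseid", "drug_seq"]].copy()
    ther_table = ther_table.merge(
        pd.DataFrame({"caseid": caseid, "start_dt": start_str}), on="caseid")
    ther_table = ther_table.rename(columns={"drug_seq": "dsg_drug_seq"})
    reac_table = _childify(reac, ["pt"])
    outc_table = _childify(outc, ["outc_cod"])
    demo_all = demo_all.sort_values("primaryid", kind="mergesort").reset_index(drop=True)

    # --- manifest ----------------------------------------------------------
    pt_counts = {}
    for i, g in enumerate(groups_order):
        mask = group_arr == g
        counts = events[mask].sum(axis=0)
        pt_counts[g] = {pts[j]: int(counts[j]) for j in range(len(pts)) if counts[j]}
    manifest = Manifest(
        seed=config.seed,
        n_cases_by_group=n_by_group,
        pt_counts_by_group=pt_counts,
        planted_multipliers=[list(x) for x in config.planted_signals],
        duplicate_count=n_dup,
        onset_median_by_group={g: config.onset_models[g].median_days
                               for g in groups_order},
        capped_probabilities=capped,
        n_reports_emitted=int(len(demo_all)),
    )

    tables = {"DEMO": demo_all, "DRUG": drug_table[["primaryid", "caseid", "drug_seq",
                                                    "role_cod", "drugname"]],
              "REAC": reac_table, "THER": ther_table, "OUTC": outc_table}
    dataset = SyntheticDataset(tables=tables, manifest=manifest, config=config)
    if out_dir is not None:
        write_tables(dataset, out_dir)
    return dataset


def write_tables(dataset: SyntheticDataset, out_dir) -> dict:
    """Write the five tables in the dollar-delimited dialect plus the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    q = dataset.config.quarter_label
    paths = {}
    for role, df in dataset.tables.items():
        p = out_dir / f"{role}{q}.txt"
        df.to_csv(p, sep="$", index=False)
        paths[role] = str(p)
    dataset.manifest.to_json(out_dir / "manifest.json")
    paths["manifest"] = str(out_dir / "manifest.json")
    return paths


# ---------------------------------------------------------------------------
# Analytic expectations and count-level simulation
# ---------------------------------------------------------------------------

def expected_table(config: SyntheticConfig, group: str, pt: str) -> ContingencyTable:
    """Expectation of each 2×2 cell under the generative model, with the
    full remaining database as the reference set.

    Agent-specific multipliers are not folded in (they default to 1); the
    expectation describes the group-level planted model.
    """
    p_g, _ = config.group_pt_prob(group, pt)
    n_g = config.n_per_group.get(group, 0)
    if n_g == 0:
        raise ConfigError(f"group {group!r} has no cases configured")
    a = n_g * p_g
    c = 0.0
    n_ref = 0
    for g, n in config.n_per_group.items():
        if g == group or n == 0:
            continue
        p, _ = config.group_pt_prob(g, pt)
        c += n * p
        n_ref += n
    return ContingencyTable(a, n_g - a, c, n_ref - c)


def simulate_contingency(config: SyntheticConfig, group: str, pt: str,
                         rng: np.random.Generator) -> ContingencyTable:
    """One binomial draw of the 2×2 under the generative model (count level;
    same law as :func:`generate` when no agent multipliers are configured)."""
    exp = expected_table(config, group, pt)
    n_g = int(exp.a + exp.b)
    p_g, _ = config.group_pt_prob(group, pt)
    a = int(rng.binomial(n_g, p_g))
    c = 0
    n_ref = 0
    for g, n in config.n_per_group.items():
        if g == group or n == 0:
            continue
        p, _ = config.group_pt_prob(g, pt)
        c += int(rng.binomial(int(n), p))
        n_ref += int(n)
    return ContingencyTable(a, n_g - a, c, n_ref - c)
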