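"""Parsing and deduplication of FAERS-style quarterly ASCII tables.

The FAERS public release distributes each quarter as dollar-sign-delimited
text files, one per table role (DEMO, DRUG, REAC, THER, OUTC).  A reported
case (CASEID) may appear as several report versions (PRIMARYID); analysis uses
one deduplicated case per CASEID: the version with the most recent FDA receipt
date (FDA_DT) survives, ties broken by the higher PRIMARYID.

Parsing is tolerant by design: malformed rows and orphan child rows (rows
whose PRIMARYID has no DEMO entry) are counted and skipped, never fatal.
Everything is held in a :class:`CaseTable` — a bundle of pandas DataFrames
keyed by ``primaryid``/``caseid`` — with an object-level :class:`CaseReport`
view for per-case logic.
"""

from __future__ import annotations

import io
import json
import logging
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._dates import PartialDate, parse_partial_date, MISSING_DATE
from .errors import FormatError

logger = logging.getLogger(__name__)

ROLE_CODES = ("PS", "SS", "C", "I")

#: Trailing tokens stripped from verbatim drug names during normalization.
SALT_SUFFIXES = frozenset({
    "sodium", "magnesium", "potassium", "calcium", "strontium", "zinc",
    "hydrochloride", "hcl", "sulfate", "sulphate", "mesylate", "besylate",
    "maleate", "tartrate", "bitartrate", "citrate", "succinate", "fumarate",
    "acetate", "phosphate", "nitrate", "bromide", "chloride",
    "monohydrate", "dihydrate", "trihydrate", "sesquihydrate", "hydrate",
    "anhydrous",
})

_OUTCOME_MAP = {
    "DE": "death",
    "LT": "life-threatening",
    "HO": "hospitalization",
    "DS": "disability",
}
_HEALTHCARE = {"MD", "PH", "HP", "OT", "RN"}
_NON_HEALTHCARE = {"CN", "LW"}
_AGE_TO_YEARS = {
    "": 1.0, "YR": 1.0, "YEAR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.0,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / (365.25 * 24.0),
}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RawReportRow:
    """One DEMO row: a report version before deduplication."""

    primaryid: str
    caseid: str
    fda_dt: PartialDate
    quarter_label: str = ""


@dataclass(frozen=True)
class DrugEntry:
    drug_name_raw: str
    ingredient: str
    role: str  # PS, SS, C, I
    start_dt: PartialDate = MISSING_DATE


@dataclass(frozen=True)
class ReactionEntry:
    pt_name: str
    event_dt: PartialDate = MISSING_DATE


@dataclass
class CaseReport:
    """One deduplicated spontaneous report."""

    caseid: str
    primaryid: str
    fda_dt: PartialDate = MISSING_DATE
    event_dt: PartialDate = MISSING_DATE
    sex: str = ""  # "M", "F" or "" (missing)
    age_years: float | None = None
    weight_kg: float | None = None
    country_code: str = ""
    reporter_type: str = ""  # "healthcare", "non-healthcare" or ""
    report_year: int | None = None
    indication: str = ""
    drugs: list[DrugEntry] = field(default_factory=list)
    reactions: list[ReactionEntry] = field(default_factory=list)
    outcomes: frozenset[str] = frozenset()


@dataclass
class IngestSummary:
    """Counters from one parse run, serializable into the run manifest."""

    rows_read: dict = field(default_factory=dict)
    rows_skipped: dict = field(default_factory=dict)
    orphan_rows: int = 0
    malformed_rows: dict = field(default_factory=dict)
    candidates: int = 0
    duplicates_removed: int = 0

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# CaseTable: the columnar container
# ---------------------------------------------------------------------------

DEMO_COLUMNS = [
    "primaryid", "caseid", "fda_dt", "event_dt", "sex", "age_years",
    "weight_kg", "country_code", "reporter_type", "report_year",
    "indication", "quarter",
]
DRUG_COLUMNS = ["primaryid", "caseid", "drug_seq", "drugname_raw",
                "ingredient", "role", "start_dt"]
REAC_COLUMNS = ["primaryid", "caseid", "pt"]
OUTC_COLUMNS = ["primaryid", "caseid", "outcome"]


@dataclass
class CaseTable:
    """Columnar view of a set of reports: one DEMO row per report version
    plus child tables for drugs, reactions and outcomes."""

    demo: pd.DataFrame
    drugs: pd.DataFrame
    reactions: pd.DataFrame
    outcomes: pd.DataFrame

    @property
    def n_cases(self) -> int:
        return int(self.demo["caseid"].nunique())

    @property
    def caseids(self) -> pd.Index:
        return pd.Index(sorted(self.demo["caseid"].unique()))

    def filter_primaryids(self, keep) -> "CaseTable":
        keep = set(keep)
        return CaseTable(
            demo=self.demo[self.demo["primaryid"].isin(keep)].reset_index(drop=True),
            drugs=self.drugs[self.drugs["primaryid"].isin(keep)].reset_index(drop=True),
            reactions=self.reactions[self.reactions["primaryid"].isin(keep)].reset_index(drop=True),
            outcomes=self.outcomes[self.outcomes["primaryid"].isin(keep)].reset_index(drop=True),
        )

    @staticmethod
    def concat(tables: list["CaseTable"]) -> "CaseTable":
        return CaseTable(
            demo=pd.concat([t.demo for t in tables], ignore_index=True),
            drugs=pd.concat([t.drugs for t in tables], ignore_index=True),
            reactions=pd.concat([t.reactions for t in tables], ignore_index=True),
            outcomes=pd.concat([t.outcomes for t in tables], ignore_index=True),
        )

    def to_case_reports(self) -> list[CaseReport]:
        """Materialize one :class:`CaseReport` per DEMO row.

        Intended for per-case logic and modest table sizes; the screening
        statistics operate on the DataFrames directly.
        """
        drugs_by_pid: dict = {}
        for row in self.drugs.itertuples(index=False):
            drugs_by_pid.setdefault(row.primaryid, []).append(
                DrugEntry(
                    drug_name_raw=row.drugname_raw,
                    ingredient=row.ingredient,
                    role=row.role,
                    start_dt=parse_partial_date(row.start_dt),
                )
            )
        reac_by_pid: dict = {}
        for row in self.reactions.itertuples(index=False):
            reac_by_pid.setdefault(row.primaryid, []).append(
                ReactionEntry(pt_name=row.pt)
            )
        outc_by_pid: dict = {}
        for row in self.outcomes.itertuples(index=False):
            outc_by_pid.setdefault(row.primaryid, set()).add(row.outcome)

        reports = []
        for row in self.demo.itertuples(index=False):
            pid = row.primaryid
            reports.append(
                CaseReport(
                    caseid=row.caseid,
                    primaryid=pid,
                    fda_dt=parse_partial_date(row.fda_dt),
                    event_dt=parse_partial_date(row.event_dt),
                    sex=row.sex,
                    age_years=None if pd.isna(row.age_years) else float(row.age_years),
                    weight_kg=None if pd.isna(row.weight_kg) else float(row.weight_kg),
                    country_code=row.country_code,
                    reporter_type=row.reporter_type,
                    report_year=None if pd.isna(row.report_year) else int(row.report_year),
                    indication=row.indication,
                    drugs=drugs_by_pid.get(pid, []),
                    reactions=reac_by_pid.get(pid, []),
                    outcomes=frozenset(outc_by_pid.get(pid, set())),
                )
            )
        return reports

    def write_csv(self, out_dir, prefix: str = "cases") -> dict:
        """Serialize as one case-level CSV plus keyed side tables."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in [("demo", self.demo), ("drugs", self.drugs),
                         ("reactions", self.reactions), ("outcomes", self.outcomes)]:
            p = out_dir / f"{prefix}_{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = str(p)
        return paths


# ---------------------------------------------------------------------------
# Drug-name normalization
# ---------------------------------------------------------------------------

_WS = re.compile(r"\s+")


def normalize_drug_name(raw: str, synonyms: dict | None = None) -> str:
    """Normalize a verbatim drug string to an ingredient name.

    Lower-cases, trims, strips trailing salt/hydrate tokens, then applies the
    synonym dictionary (brand → ingredient) if given.  Unmatched names are
    returned in normalized verbatim form; callers decide whether an unmatched
    name belongs to any study class (it never does).
    """
    s = _WS.sub(" ", str(raw).strip().lower()).strip(".")
    # drop a parenthesized qualifier, e.g. "opdivo (nivolumab)" -> try inner first
    m = re.match(r"^(.*?)\s*\((.+?)\)\s*$", s)
    if m and synonyms is not None:
        inner = normalize_drug_name(m.group(2), synonyms)
        if inner in synonyms.values() or inner in set(synonyms):
            s = m.group(2)
        else:
            s = m.group(1)
    elif m:
        s = m.group(1)
    tokens = s.split(" ")
    while len(tokens) > 1 and tokens[-1] in SALT_SUFFIXES:
        tokens.pop()
    s = " ".join(tokens)
    if synonyms:
        s = synonyms.get(s, s)
    return s


def normalize_pt(raw: str) -> str:
    """Case-normalize a MedDRA preferred term (lower-case, collapsed spaces)."""
    return _WS.sub(" ", str(raw).strip().lower())


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _read_table(src, role: str, required: list[str], summary: IngestSummary) -> pd.DataFrame:
    """Read one dollar-delimited table; enforce the header contract."""
    malformed = []

    def _on_bad(bad):  # pragma: no cover - exercised via dirty fixtures
        malformed.append(bad)
        return None

    if isinstance(src, (str, Path)):
        handle = src
    elif isinstance(src, bytes):
        handle = io.StringIO(src.decode())
    else:
        handle = src
    try:
        df = pd.read_csv(
            handle, sep="$", dtype=str, keep_default_na=False,
            engine="python", on_bad_lines=_on_bad, quoting=3,
        )
    except pd.errors.EmptyDataError:
        raise FormatError(role, "file is empty (missing header)")
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(role, f"missing required column(s) {missing}")
    summary.rows_read[role] = int(len(df))
    summary.malformed_rows[role] = len(malformed)
    if malformed:
        logger.warning("%s: skipped %d malformed row(s)", role, len(malformed))
    return df


def _col(df: pd.DataFrame, *names: str) -> pd.Series:
    """First present column among aliases, else an empty-string column."""
    for n in names:
        if n in df.columns:
            return df[n].fillna("").astype(str).str.strip()
    return pd.Series([""] * len(df), index=df.index, dtype=str)


def _date_rank(s: pd.Series) -> pd.Series:
    """Sortable 8-char key: partial dates zero-padded, missing lowest."""
    return s.map(lambda v: str(parse_partial_date(v)).ljust(8, "0"))


def _to_num(s: pd.Series) -> pd.Series:
    return pd.to_numeric(s.replace("", np.nan), errors="coerce")


def parse_quarter(
    demo_stream,
    drug_stream,
    reac_stream,
    ther_stream=None,
    outc_stream=None,
    quarter_label: str = "",
    synonyms: dict | None = None,
) -> tuple[CaseTable, IngestSummary]:
    """Parse one quarter's tables into CaseReport candidates.

    Streams may be paths or file-like objects of dollar-delimited text with a
    header row; the join key is ``primaryid``.  Child rows referencing a
    PRIMARYID absent from DEMO are skipped and counted.  Returns one candidate
    per PRIMARYID (deduplication across report versions is a separate step).
    """
    summary = IngestSummary()

    demo = _read_table(demo_stream, "DEMO", ["primaryid", "caseid"], summary)
    drug = _read_table(drug_stream, "DRUG", ["primaryid", "drugname"], summary)
    reac = _read_table(reac_stream, "REAC", ["primaryid", "pt"], summary)
    ther = (_read_table(ther_stream, "THER", ["primaryid", "start_dt"], summary)
            if ther_stream is not None else None)
    outc = (_read_table(outc_stream, "OUTC", ["primaryid", "outc_cod"], summary)
            if outc_stream is not None else None)

    # --- DEMO -------------------------------------------------------------
    pid = _col(demo, "primaryid")
    cid = _col(demo, "caseid")
    bad = (pid == "") | (cid == "")
    summary.rows_skipped["DEMO"] = int(bad.sum())
    demo = demo[~bad]
    pid, cid = pid[~bad], cid[~bad]

    age = _to_num(_col(demo, "age"))
    age_cod = _col(demo, "age_cod").str.upper()
    age_years = age * age_cod.map(lambda c: _AGE_TO_YEARS.get(c, np.nan))
    age_years = age_years.where((age_years >= 0) & (age_years <= 130))

    wt = _to_num(_col(demo, "wt"))
    wt_cod = _col(demo, "wt_cod").str.upper()
    weight_kg = wt.where(wt_cod.isin(["", "KG", "KGS"]), wt * 0.453592)
    weight_kg = weight_kg.where((weight_kg > 0) & (weight_kg < 400))

    sex = _col(demo, "sex", "gndr_cod").str.upper()
    sex = sex.where(sex.isin(["M", "F"]), "")

    occp = _col(demo, "occp_cod").str.upper()
    reporter = pd.Series(np.where(occp.isin(_HEALTHCARE), "healthcare",
                         np.where(occp.isin(_NON_HEALTHCARE), "non-healthcare", "")),
                         index=demo.index)

    fda_dt = _col(demo, "fda_dt")
    report_year = _to_num(fda_dt.str.slice(0, 4))

    demo_out = pd.DataFrame({
        "primaryid": pid.values,
        "caseid": cid.values,
        "fda_dt": fda_dt.values,
        "event_dt": _col(demo, "event_dt").values,
        "sex": sex.values,
        "age_years": age_years.values,
        "weight_kg": weight_kg.values,
        "country_code": _col(demo, "reporter_country", "occr_country").str.upper().values,
        "reporter_type": reporter.values,
        "report_year": report_year.values,
        "indication": _col(demo, "indi_pt").map(normalize_pt).values,
        "quarter": quarter_label,
    })
    known_pids = set(demo_out["primaryid"])
    summary.candidates = len(demo_out)

    def _attach(df: pd.DataFrame | None, role: str) -> pd.DataFrame:
        """Join caseid onto a child table; drop and count orphans."""
        if df is None:
            return pd.DataFrame(columns=["primaryid"])
        p = _col(df, "primaryid")
        orphan = ~p.isin(known_pids)
        n_orphan = int(orphan.sum())
        if n_orphan:
            logger.warning("%s: skipped %d row(s) with unknown primaryid", role, n_orphan)
            summary.orphan_rows += n_orphan
            df = df[~orphan]
        return df

    # --- DRUG (+THER start dates) -----------------------------------------
    drug = _attach(drug, "DRUG")
    dpid = _col(drug, "primaryid")
    role = _col(drug, "role_cod").str.upper()
    role = role.where(role.isin(ROLE_CODES), "C")
    seq = _col(drug, "drug_seq", "dsg_drug_seq")
    if (seq == "").all():
        seq = pd.Series(np.arange(1, len(drug) + 1).astype(str), index=drug.index)
    raw_names = _col(drug, "drugname")
    ingredient = raw_names.map(lambda s: normalize_drug_name(s, synonyms))
    drugs_out = pd.DataFrame({
        "primaryid": dpid.values,
        "drug_seq": seq.values,
        "drugname_raw": raw_names.values,
        "ingredient": ingredient.values,
        "role": role.values,
        "start_dt": "",
    })
    if ther is not None and len(ther):
        ther = _attach(ther, "THER")
        tkey = pd.DataFrame({
            "primaryid": _col(ther, "primaryid").values,
            "drug_seq": _col(ther, "dsg_drug_seq", "drug_seq").values,
            "start_dt_t": _col(ther, "start_dt").values,
        })
        # one start date per drug entry: keep the earliest-ranked
        tkey["rank"] = _date_rank(tkey["start_dt_t"])
        tkey = (tkey.sort_values(["primaryid", "drug_seq", "rank"])
                    .drop_duplicates(["primaryid", "drug_seq"], keep="first"))
        drugs_out = drugs_out.merge(
            tkey[["primaryid", "drug_seq", "start_dt_t"]],
            on=["primaryid", "drug_seq"], how="left")
        drugs_out["start_dt"] = drugs_out.pop("start_dt_t").fillna("")
    drugs_out = drugs_out.merge(demo_out[["primaryid", "caseid"]], on="primaryid")
    drugs_out = drugs_out[DRUG_COLUMNS]

    # --- REAC --------------------------------------------------------------
    reac = _attach(reac, "REAC")
    reac_out = pd.DataFrame({
        "primaryid": _col(reac, "primaryid").values,
        "pt": _col(reac, "pt").map(normalize_pt).values,
    })
    reac_out = reac_out[reac_out["pt"] != ""]
    reac_out = reac_out.merge(demo_out[["primaryid", "caseid"]], on="primaryid")
    reac_out = reac_out[REAC_COLUMNS]

    # --- OUTC --------------------------------------------------------------
    if outc is not None and len(outc):
        outc = _attach(outc, "OUTC")
        codes = _col(outc, "outc_cod").str.upper()
        outc_out = pd.DataFrame({
            "primaryid": _col(outc, "primaryid").values,
            "outcome": codes.map(lambda c: _OUTCOME_MAP.get(c, "other" if c else "")).values,
        })
        outc_out = outc_out[outc_out["outcome"] != ""]
        outc_out = outc_out.merge(demo_out[["primaryid", "caseid"]], on="primaryid")
        outc_out = outc_out[OUTC_COLUMNS]
    else:
        outc_out = pd.DataFrame(columns=OUTC_COLUMNS)

    table = CaseTable(demo=demo_out, drugs=drugs_out,
                      reactions=reac_out, outcomes=outc_out)
    table = _dedupe_within_case(table)
    return table, summary


def _dedupe_within_case(table: CaseTable) -> CaseTable:
    """Collapse within-report duplicates: drugs on (ingredient, role) keeping
    the earliest start date, reactions on pt, outcomes on code."""
    drugs = table.drugs.copy()
    drugs["_rank"] = _date_rank(drugs["start_dt"])
    # missing dates rank lowest; prefer a dated row when one exists
    drugs["_has"] = (drugs["_rank"] != "00000000").astype(int)
    drugs = (drugs.sort_values(["primaryid", "ingredient", "role", "_has", "_rank"],
                               ascending=[True, True, True, False, True])
                  .drop_duplicates(["primaryid", "ingredient", "role"], keep="first")
                  .drop(columns=["_rank", "_has"])
                  .reset_index(drop=True))
    return CaseTable(
        demo=table.demo.reset_index(drop=True),
        drugs=drugs,
        reactions=table.reactions.drop_duplicates(["primaryid", "pt"]).reset_index(drop=True),
        outcomes=table.outcomes.drop_duplicates(["primaryid", "outcome"]).reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# Deduplication across report versions
# ---------------------------------------------------------------------------

def deduplicate(table: CaseTable) -> tuple[CaseTable, int]:
    """Keep one report version per CASEID.

    The survivor maximizes (FDA_DT, PRIMARYID) lexicographically: the most
    recently received version wins, ties broken by the higher PRIMARYID.
    A missing FDA_DT ranks below any present date.  Output is sorted by
    caseid; returns the deduplicated table and the number of removed versions.
    """
    demo = table.demo.copy()
    demo["_fda_rank"] = _date_rank(demo["fda_dt"])
    demo["_pid_num"] = pd.to_numeric(demo["primaryid"], errors="coerce").fillna(-1)
    survivors = (demo.sort_values(["caseid", "_fda_rank", "_pid_num", "primaryid"])
                     .drop_duplicates("caseid", keep="last"))
    removed = len(demo) - len(survivors)
    out = table.filter_primaryids(survivors["primaryid"])
    out.demo = out.demo.sort_values("caseid", kind="mergesort").reset_index(drop=True)
    out.drugs = out.drugs.sort_values(["caseid", "drug_seq"], kind="mergesort").reset_index(drop=True)
    out.reactions = out.reactions.sort_values(["caseid", "pt"], kind="mergesort").reset_index(drop=True)
    out.outcomes = out.outcomes.sort_values(["caseid", "outcome"], kind="mergesort").reset_index(drop=True)
    return out, removed
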