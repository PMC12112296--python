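"""End-to-end orchestration: ingest → dedup → classify → screen → onset →
risk factors, with a reproducible run manifest.

All outputs are plain CSV/JSON with fixed column order; display values are
rounded to two decimals at serialization only, and every displayed number is
recomputable from the audit JSON written beside it.  Identical inputs and
configuration give byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import cohort as cohort_mod
from . import disprop, onset as onset_mod, riskfactors as rf
from .errors import ConfigError, UndefinedSignalError
from .faers_ingest import CaseTable, parse_quarter, deduplicate
from .termset import TermSet, default_renal_termset, load_termset

logger = logging.getLogger(__name__)

TABLE_ROLES = ("DEMO", "DRUG", "REAC", "THER", "OUTC")
STUDY_GROUPS = ("ICI_MONO", "PPI_MONO", "H2RA_MONO", "PCAB_MONO",
                "ICI_PPI_COMBO", "ICI_H2RA_COMBO", "ICI_PCAB_COMBO")


@dataclass
class RunConfig:
    input_dir: str
    out_dir: str
    quarters: list = field(default_factory=list)
    drug_classes_path: str | None = None
    termset_path: str | None = None
    reference_mode: str = "full_database"
    n_min: int = 3
    shrink: float = 0.5
    alpha: float = 0.05
    role_strictness: str = "ps_ss"
    combo_group: str = "ICI_PPI_COMBO"
    mono_groups: tuple = ("ICI_MONO", "PPI_MONO")
    soc_map_path: str | None = None

    def validate(self):
        if not Path(self.input_dir).is_dir():
            raise ConfigError(f"input directory {self.input_dir!r} does not exist")
        for p in (self.drug_classes_path, self.termset_path, self.soc_map_path):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"configured path {p!r} does not exist")
        if not self.quarters:
            raise ConfigError("no quarters configured")


@dataclass
class RunManifest:
    version: str
    config: dict
    stage_tallies: dict = field(default_factory=dict)
    termset: list = field(default_factory=list)
    notices: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _round_display(df: pd.DataFrame, cols: list) -> pd.DataFrame:
    out = df.copy()
    for c in cols:
        if c in out.columns:
            out[c] = out[c].astype(float).round(2)
    return out


def load_quarter_tables(input_dir, quarter: str, synonyms=None):
    """Parse one quarter from ``<ROLE><quarter>.txt`` files in a directory."""
    input_dir = Path(input_dir)
    paths = {}
    for role in TABLE_ROLES:
        p = input_dir / f"{role}{quarter}.txt"
        paths[role] = p if p.exists() else None
    for role in ("DEMO", "DRUG", "REAC"):
        if paths[role] is None:
            raise ConfigError(f"missing {role} table for quarter {quarter} in {input_dir}")
    return parse_quarter(paths["DEMO"], paths["DRUG"], paths["REAC"],
                         paths["THER"], paths["OUTC"],
                         quarter_label=quarter, synonyms=synonyms)


def run_all(config: RunConfig) -> RunManifest:
    """Execute the full analysis and write the output bundle.

    Outputs: per-group signal tables, cohort summary, head-to-head RORs,
    onset records/summaries/curves, risk-factor forest table, co-reported
    event table, audit JSON and the run manifest.  An empty combination
    group degrades to a structured "insufficient data" notice instead of an
    error.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(version=__version__, config=asdict(config))

    classes = (cohort_mod.load_drug_classes(config.drug_classes_path)
               if config.drug_classes_path else cohort_mod.default_drug_classes())
    terms = (load_termset(config.termset_path, name="renal_AE")
             if config.termset_path else default_renal_termset())
    manifest.termset = [list(r) for r in terms.to_rows()]

    # --- ingest + dedup ----------------------------------------------------
    tables, summaries = [], []
    for q in config.quarters:
        t, s = load_quarter_tables(config.input_dir, q, synonyms=classes.synonyms)
        tables.append(t)
        summaries.append(s)
    table = tables[0] if len(tables) == 1 else CaseTable.concat(tables)
    raw_reports = len(table.demo)
    table, removed = deduplicate(table)
    manifest.stage_tallies = {
        "raw_reports": raw_reports,
        "duplicates_removed": removed,
        "deduplicated_cases": table.n_cases,
        "ingest": [asdict(s) for s in summaries],
    }

    # --- classify ----------------------------------------------------------
    labels = cohort_mod.classify_cases(table, classes, config.role_strictness)
    group_sizes = labels["label"].value_counts().to_dict()
    manifest.stage_tallies["group_sizes"] = {k: int(v) for k, v in
                                             sorted(group_sizes.items())}

    cohort_summary = cohort_mod.summarize_cohort(table, labels, classes=classes)
    _round_display(cohort_summary, ["pct"]).to_csv(out_dir / "cohort_summary.csv", index=False)

    # --- per-group signal screens -----------------------------------------
    audit = {}
    for group in STUDY_GROUPS:
        if group_sizes.get(group, 0) == 0:
            continue
        results = disprop.screen_all_pts(
            table, labels, group, terms,
            reference_mode=config.reference_mode,
            n_min=config.n_min, shrink=config.shrink, alpha=config.alpha)
        frame = disprop.signals_to_frame(results)
        audit[group] = frame.to_dict(orient="records")
        disp = _round_display(frame.drop(columns=["a", "b", "c", "d", "p"]),
                              ["ror", "ror_low", "ror_high", "ic", "ic025"])
        disp.to_csv(out_dir / f"signals_{group}.csv", index=False)

    # --- head-to-head ------------------------------------------------------
    h2h_rows = []
    for ref_group in config.mono_groups:
        try:
            r = disprop.head_to_head_ror(table, labels, config.combo_group,
                                         ref_group, terms, n_min=config.n_min,
                                         shrink=config.shrink, alpha=config.alpha)
            t = r.table
            h2h_rows.append(dict(
                exposure=config.combo_group, reference=ref_group, n=r.n,
                ror=r.ror, ror_low=r.ror_low, ror_high=r.ror_high, p=r.p,
                a=t.a, b=t.b, c=t.c, d=t.d))
        except UndefinedSignalError as exc:
            manifest.notices.append(
                {"stage": "head_to_head", "reference": ref_group,
                 "notice": "insufficient data", "detail": str(exc)})
    if h2h_rows:
        frame = pd.DataFrame(h2h_rows)
        audit["head_to_head"] = frame.to_dict(orient="records")
        _round_display(frame, ["ror", "ror_low", "ror_high"]).to_csv(
            out_dir / "head_to_head.csv", index=False)

    # --- onset -------------------------------------------------------------
    study_ingredients = set().union(*classes.members.values())
    onset_groups = [g for g in (config.combo_group, *config.mono_groups)
                    if group_sizes.get(g, 0)]
    cases = table.to_case_reports()
    records, tally = onset_mod.collect_onset_records(
        cases, labels, terms, study_ingredients, groups=onset_groups)
    manifest.stage_tallies["onset_exclusions"] = tally
    onset_mod.onset_records_frame(records).to_csv(out_dir / "onset_records.csv", index=False)
    summaries_o = onset_mod.summarize_onset(records)
    onset_mod.onset_summary_frame(summaries_o).to_csv(out_dir / "onset_summary.csv", index=False)
    onset_mod.cumulative_curves_frame(summaries_o).to_csv(out_dir / "onset_curves.csv", index=False)
    samples = [[r.tto_days for r in records if r.group == g] for g in summaries_o]
    samples = [s for s in samples if s]
    if len(samples) >= 2:
        h, p = onset_mod.kruskal_wallis(samples)
        manifest.stage_tallies["kruskal_wallis"] = {"H": h, "p": p,
                                                    "groups": list(summaries_o)}

    # --- risk factors within the combination cohort ------------------------
    combo_ids = labels.index[labels["label"] == config.combo_group]
    if len(combo_ids) == 0:
        manifest.notices.append({"stage": "riskfactors",
                                 "notice": "insufficient data",
                                 "detail": f"empty group {config.combo_group}"})
    else:
        data = _riskfactor_frame(table, labels, classes, terms, combo_ids)
        specs = default_factor_specs(classes)
        forest = rf.screen_factors(data, "renal_event", specs)
        _round_display(forest, ["odds_ratio", "ci_low", "ci_high"]).to_csv(
            out_dir / "risk_factors.csv", index=False)

        event_ids = disprop.event_caseids(table, terms) & set(combo_ids)
        soc_map = _load_soc_map(config.soc_map_path) if config.soc_map_path else None
        co = rf.tabulate_coreported(table, event_ids, terms, soc_map=soc_map)
        pd.DataFrame([{"n_renal_cases": co.n_cases,
                       "n_coreporting": co.n_coreporting,
                       "pct_coreporting": round(100 * co.fraction, 2)
                       if co.n_cases else float("nan")}]).to_csv(
            out_dir / "coreported.csv", index=False)
        if co.breakdown is not None:
            co.breakdown.to_csv(out_dir / "coreported_soc.csv", index=False)

    (out_dir / "audit.json").write_text(json.dumps(audit, indent=2, sort_keys=True,
                                                   default=float))
    manifest.to_json(out_dir / "run_manifest.json")
    return manifest


def _load_soc_map(path) -> dict:
    df = pd.read_csv(path)
    return dict(zip(df.iloc[:, 0].str.lower(), df.iloc[:, 1]))


def _riskfactor_frame(table: CaseTable, labels: pd.DataFrame,
                      classes, terms: TermSet, combo_ids) -> pd.DataFrame:
    """One row per combination-cohort case with outcome and factor columns."""
    demo = table.demo.set_index("caseid").loc[list(combo_ids)]
    event_ids = disprop.event_caseids(table, terms)
    region_map = cohort_mod.default_region_map()

    d = table.drugs[table.drugs["caseid"].isin(combo_ids)].copy()
    d["ing"] = d["ingredient"].map(lambda s: classes.synonyms.get(s, s))
    d["cls"] = d["ing"].map(classes.ingredient_class)
    ppi = (d[d["cls"] == "PPI"].sort_values("ing")
           .drop_duplicates("caseid")[["caseid", "ing"]]
           .set_index("caseid")["ing"])

    frame = pd.DataFrame(index=demo.index)
    frame["renal_event"] = [1.0 if c in event_ids else 0.0 for c in demo.index]
    frame["sex"] = demo["sex"].replace("", np.nan)
    frame["age_years"] = demo["age_years"]
    frame["weight_kg"] = demo["weight_kg"]
    frame["region"] = demo["country_code"].map(
        lambda c: region_map.get(c, np.nan) if c else np.nan)
    frame["ici_regimen"] = labels.loc[demo.index, "ici_regimen"].replace("none", np.nan)
    frame["ppi_agent"] = ppi.reindex(demo.index)
    frame["diagnosis_renal_malignancy"] = (
        demo["indication"].isin(["renal cell carcinoma", "renal cancer",
                                 "kidney cancer"]).astype(float))
    return frame


def default_factor_specs(classes=None) -> list:
    """The default univariate screen: sex, age, weight, region, regimen,
    acid-suppressant agent and renal-malignancy diagnosis."""
    return [
        rf.FactorSpec("sex", "categorical", reference="F"),
        rf.FactorSpec("age_years", "continuous"),
        rf.FactorSpec("weight_kg", "continuous"),
        rf.FactorSpec("region", "categorical", reference="Asia"),
        rf.FactorSpec("ici_regimen", "categorical", reference="ICI_combination"),
        rf.FactorSpec("ppi_agent", "categorical", reference="omeprazole"),
        rf.FactorSpec("diagnosis_renal_malignancy", "binary", reference="0.0"),
    ]
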