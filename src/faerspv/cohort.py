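"""Exposure-group classification and cohort description.

Cases are classified into mutually exclusive exposure groups from
configurable drug-class dictionaries: checkpoint-inhibitor (ICI) monotherapy,
acid-suppressant monotherapy (PPI / H2RA / P-CAB), ICI + acid-suppressant
combinations, or OTHER (the database background).  Classification priority is
COMBO > MONO > OTHER:

* a class "matches" a case when at least one of its drugs belongs to the
  class with a suspect role (PS, or PS/SS under the default strictness);
* a COMBO label needs a suspect-role ICI match and a suspect-role match in
  one acid-suppressant class (PPI > H2RA > P-CAB priority when several);
* a MONO label needs exactly one study class present in the case *in any
  role* — monotherapy reference groups stay uncontaminated;
* everything else is OTHER.

The checkpoint-inhibitor regimen sub-label (PD-1 / PD-L1 / CTLA-4 /
ICI_combination) is derived from the molecular targets of the matched ICIs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._stats import proportion_pct, median_and_hinges
from .errors import ConfigError
from .faers_ingest import CaseReport, CaseTable

__all__ = [
    "DrugClasses", "ExposureGroup", "load_drug_classes", "default_drug_classes",
    "classify_case", "classify_cases", "ici_regimen_of", "summarize_cohort",
    "load_region_map", "default_region_map", "proportion_pct",
    "STUDY_CLASSES", "GROUP_LABELS",
]

STUDY_CLASSES = ("ICI", "PPI", "H2RA", "PCAB")
ASA_PRIORITY = ("PPI", "H2RA", "PCAB")
GROUP_LABELS = (
    "ICI_MONO", "PPI_MONO", "H2RA_MONO", "PCAB_MONO",
    "ICI_PPI_COMBO", "ICI_H2RA_COMBO", "ICI_PCAB_COMBO", "OTHER",
)

#: Molecular target of each checkpoint inhibitor, for the regimen sub-label.
ICI_TARGETS = {
    "pembrolizumab": "PD-1",
    "nivolumab": "PD-1",
    "cemiplimab": "PD-1",
    "atezolizumab": "PD-L1",
    "avelumab": "PD-L1",
    "durvalumab": "PD-L1",
    "ipilimumab": "CTLA-4",
    "tremelimumab": "CTLA-4",
}

_SUSPECT_ROLES = {"ps_only": frozenset({"PS"}), "ps_ss": frozenset({"PS", "SS"})}

_RENAL_MALIGNANCY_TERMS = frozenset({
    "renal cell carcinoma", "renal cancer", "renal neoplasm malignant",
    "kidney cancer", "renal cell carcinoma metastatic", "renal cancer metastatic",
})

YEAR_BINS = ((2004, 2008, "2004-2008"), (2009, 2013, "2009-2013"),
             (2014, 2018, "2014-2018"), (2019, 2023, "2019-2023Q1"))


# ---------------------------------------------------------------------------
# Dictionaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DrugClasses:
    """Validated drug-class dictionaries: ingredient -> class, alias -> ingredient."""

    members: dict  # class name -> frozenset of ingredients
    synonyms: dict  # alias -> ingredient

    @property
    def ingredient_class(self) -> dict:
        return {ing: cls for cls, ings in self.members.items() for ing in ings}

    def class_of(self, ingredient: str) -> str | None:
        ing = self.synonyms.get(ingredient, ingredient)
        return self.ingredient_class.get(ing)

    def canonical(self, ingredient: str) -> str:
        return self.synonyms.get(ingredient, ingredient)


def load_drug_classes(source) -> DrugClasses:
    """Load class dictionaries from a YAML/JSON path or an equivalent dict.

    Expected shape: ``{CLASS: {members: [...], synonyms: {alias: ingredient}}}``
    (a bare list is accepted as members).  An ingredient appearing in two
    classes is a configuration error.
    """
    if isinstance(source, (str, Path)):
        data = yaml.safe_load(Path(source).read_text())
    else:
        data = source
    if not isinstance(data, dict) or not data:
        raise ConfigError("drug-class dictionary must be a non-empty mapping")
    members: dict = {}
    synonyms: dict = {}
    seen: dict = {}
    for cls, spec in data.items():
        if isinstance(spec, dict):
            ings = spec.get("members", [])
            syns = spec.get("synonyms", {}) or {}
        else:
            ings, syns = spec, {}
        ings = [str(i).strip().lower() for i in ings]
        for ing in ings:
            if ing in seen and seen[ing] != cls:
                raise ConfigError(
                    f"ingredient {ing!r} appears in classes {seen[ing]!r} and {cls!r}")
            seen[ing] = cls
        members[str(cls)] = frozenset(ings)
        for alias, ing in syns.items():
            alias, ing = str(alias).strip().lower(), str(ing).strip().lower()
            if ing not in members[str(cls)]:
                raise ConfigError(f"synonym {alias!r} maps to unknown ingredient {ing!r}")
            synonyms[alias] = ing
    return DrugClasses(members=members, synonyms=synonyms)


def default_drug_classes() -> DrugClasses:
    """The packaged ICI / PPI / H2RA / P-CAB dictionaries."""
    ref = resources.files("faerspv").joinpath("data/drug_classes.yaml")
    with resources.as_file(ref) as p:
        return load_drug_classes(p)


def load_region_map(path) -> dict:
    """country_code -> region CSV (editable; unmapped codes become Missing)."""
    out = {}
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            out[rec["country_code"].strip().upper()] = rec["region"].strip()
    return out


def default_region_map() -> dict:
    ref = resources.files("faerspv").joinpath("data/region_map.csv")
    with resources.as_file(ref) as p:
        return load_region_map(p)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExposureGroup:
    """Result of classifying one case."""

    label: str
    matched_drugs: frozenset[str] = frozenset()
    ici_regimen: str = "none"


def ici_regimen_of(ici_labels) -> str:
    """Regimen sub-label from the set of matched ICI ingredient names."""
    targets = set()
    for lab in ici_labels:
        t = ICI_TARGETS.get(lab)
        if t is None:
            raise ConfigError(f"unknown checkpoint inhibitor {lab!r}")
        targets.add(t)
    if not targets:
        return "none"
    if len(targets) > 1:
        return "ICI_combination"
    return targets.pop()


def classify_case(case: CaseReport, classes: DrugClasses,
                  role_strictness: str = "ps_ss") -> ExposureGroup:
    """Assign one case to its exposure group (COMBO > MONO > OTHER)."""
    try:
        suspect_roles = _SUSPECT_ROLES[role_strictness]
    except KeyError:
        raise ConfigError(f"unknown role strictness {role_strictness!r}")

    present: dict[str, set] = {}
    suspect: dict[str, set] = {}
    for d in case.drugs:
        ing = classes.canonical(d.ingredient)
        cls = classes.ingredient_class.get(ing)
        if cls is None:
            continue
        present.setdefault(cls, set()).add(ing)
        if d.role in suspect_roles:
            suspect.setdefault(cls, set()).add(ing)

    regimen = ici_regimen_of(suspect.get("ICI", set()))

    if "ICI" in suspect:
        for asa in ASA_PRIORITY:
            if asa in suspect:
                matched = frozenset(suspect["ICI"]) | frozenset(suspect[asa])
                return ExposureGroup(f"ICI_{asa}_COMBO", matched, regimen)
    if len(present) == 1:
        (cls, _), = present.items()
        if cls in suspect:
            return ExposureGroup(f"{cls}_MONO", frozenset(suspect[cls]), regimen)
    return ExposureGroup("OTHER", frozenset(), regimen)


def classify_cases(table: CaseTable, classes: DrugClasses,
                   role_strictness: str = "ps_ss") -> pd.DataFrame:
    """Vectorized classification of every case in a deduplicated table.

    Returns a DataFrame indexed by caseid with columns ``label`` and
    ``ici_regimen``; agrees case-for-case with :func:`classify_case`.
    """
    try:
        suspect_roles = _SUSPECT_ROLES[role_strictness]
    except KeyError:
        raise ConfigError(f"unknown role strictness {role_strictness!r}")

    caseids = table.caseids
    d = table.drugs[["caseid", "ingredient", "role"]].copy()
    d["ing"] = d["ingredient"].map(lambda s: classes.synonyms.get(s, s))
    d["cls"] = d["ing"].map(classes.ingredient_class)
    d = d.dropna(subset=["cls"])

    def _flags(sub: pd.DataFrame) -> pd.DataFrame:
        if len(sub) == 0:
            return pd.DataFrame(0, index=caseids,
                                columns=list(STUDY_CLASSES)).astype(bool)
        ct = pd.crosstab(sub["caseid"], sub["cls"]).astype(bool)
        return ct.reindex(index=caseids, columns=list(STUDY_CLASSES),
                          fill_value=False)

    present = _flags(d)
    susp = _flags(d[d["role"].isin(suspect_roles)])

    n_present = present.sum(axis=1)
    combo_ppi = susp["ICI"] & susp["PPI"]
    combo_h2 = susp["ICI"] & ~susp["PPI"] & susp["H2RA"]
    combo_pc = susp["ICI"] & ~susp["PPI"] & ~susp["H2RA"] & susp["PCAB"]
    conds = [combo_ppi, combo_h2, combo_pc]
    labels = ["ICI_PPI_COMBO", "ICI_H2RA_COMBO", "ICI_PCAB_COMBO"]
    for cls in STUDY_CLASSES:
        conds.append((n_present == 1) & present[cls] & susp[cls])
        labels.append(f"{cls}_MONO")
    label = pd.Series(np.select(conds, labels, default="OTHER"), index=caseids)

    # regimen from suspect-role ICI drugs
    ici = d[(d["cls"] == "ICI") & d["role"].isin(suspect_roles)]
    regimen = pd.Series("none", index=caseids)
    if len(ici):
        per_case = (ici.assign(target=ici["ing"].map(ICI_TARGETS))
                       .groupby("caseid")["target"]
                       .agg(lambda s: "ICI_combination" if s.nunique() > 1 else s.iloc[0]))
        regimen.loc[per_case.index] = per_case
    return pd.DataFrame({"label": label, "ici_regimen": regimen})


# ---------------------------------------------------------------------------
# Cohort description (Table-2-style)
# ---------------------------------------------------------------------------

def _bin_year(y) -> str:
    if pd.isna(y):
        return "Missing"
    y = int(y)
    for lo, hi, lab in YEAR_BINS:
        if lo <= y <= hi:
            return lab
    return "Missing"


def summarize_cohort(table: CaseTable, labels: pd.DataFrame | pd.Series,
                     classes: DrugClasses | None = None,
                     region_map: dict | None = None,
                     groups: list[str] | None = None) -> pd.DataFrame:
    """Per-group descriptive table: region, reporter, report year, sex,
    age, renal-malignancy diagnosis, study-drug frequencies and outcomes.

    ``labels`` is the output of :func:`classify_cases` (or its ``label``
    Series).  Percentages are taken over the whole group including missing
    categories.  Returns a long-format DataFrame
    (group, section, level, n, pct).
    """
    if isinstance(labels, pd.DataFrame):
        labels = labels["label"]
    region_map = default_region_map() if region_map is None else region_map
    classes = default_drug_classes() if classes is None else classes

    demo = table.demo.set_index("caseid")
    demo = demo.join(labels.rename("group"))
    if groups is None:
        groups = sorted(demo["group"].dropna().unique())

    rows: list[dict] = []

    def _cat(section: str, series: pd.Series, sub: pd.DataFrame, gsize: int, group: str):
        counts = series.value_counts()
        for level, n in counts.items():
            rows.append(dict(group=group, section=section, level=str(level),
                             n=int(n), pct=proportion_pct(int(n), gsize)))

    for group in groups:
        sub = demo[demo["group"] == group]
        gsize = len(sub)
        rows.append(dict(group=group, section="total", level="cases",
                         n=gsize, pct=100.0 if gsize else float("nan")))
        if gsize == 0:
            continue
        region = sub["country_code"].map(lambda c: region_map.get(c, "Missing") if c else "Missing")
        _cat("region", region, sub, gsize, group)
        reporter = sub["reporter_type"].map(
            {"healthcare": "Healthcare professionals",
             "non-healthcare": "Non-healthcare professionals"}).fillna("Missing")
        _cat("reporter", reporter, sub, gsize, group)
        _cat("report_year", sub["report_year"].map(_bin_year), sub, gsize, group)
        sex = sub["sex"].map({"M": "Male", "F": "Female"}).fillna("Missing")
        sex = sex.where(sex.isin(["Male", "Female"]), "Missing")
        _cat("sex", sex, sub, gsize, group)

        ages = sub["age_years"].dropna()
        if len(ages):
            q1, med, q3 = median_and_hinges(ages.to_numpy())
            for lev, val in [("median", med), ("q1", q1), ("q3", q3),
                             ("n_known", float(len(ages)))]:
                rows.append(dict(group=group, section="age_years", level=lev,
                                 n=val, pct=float("nan")))

        diag = sub["indication"].isin(_RENAL_MALIGNANCY_TERMS).sum()
        rows.append(dict(group=group, section="diagnosis", level="renal malignancy",
                         n=int(diag), pct=proportion_pct(int(diag), gsize)))

        # study-class drug frequencies (suspect or concomitant) within group
        du = table.drugs[table.drugs["caseid"].isin(sub.index)].copy()
        du["ing"] = du["ingredient"].map(lambda s: classes.synonyms.get(s, s))
        du["cls"] = du["ing"].map(classes.ingredient_class)
        du = du.dropna(subset=["cls"]).drop_duplicates(["caseid", "ing"])
        for ing, n in du["ing"].value_counts().items():
            rows.append(dict(group=group, section="drug", level=ing,
                             n=int(n), pct=proportion_pct(int(n), gsize)))

        oc = table.outcomes[table.outcomes["caseid"].isin(sub.index)]
        for out, n in oc["outcome"].value_counts().items():
            rows.append(dict(group=group, section="outcome", level=out,
                             n=int(n), pct=proportion_pct(int(n), gsize)))
        n_missing_out = gsize - oc["caseid"].nunique()
        rows.append(dict(group=group, section="outcome", level="Missing",
                         n=int(n_missing_out), pct=proportion_pct(int(n_missing_out), gsize)))

    out = pd.DataFrame(rows, columns=["group", "section", "level", "n", "pct"])
    return out.sort_values(["group", "section", "level"], kind="mergesort").reset_index(drop=True)
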