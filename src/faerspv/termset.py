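"""Event-of-interest term sets.

An adverse event of interest is defined by a named set of MedDRA preferred
terms (PTs), typically assembled as the union of standardized queries (SMQs),
System Organ Class (SOC) subtrees and manual additions.  MedDRA itself is
licensed, so term lists are user-supplied plain text; the package ships a
reconstructed default renal list (see :func:`default_renal_termset`).

Matching is exact-string after normalization (lower-case, collapsed
whitespace) — no dictionary hierarchy walk.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from .faers_ingest import CaseReport, normalize_pt
from .errors import ConfigError

PROVENANCES = ("SMQ", "SOC", "manual")


@dataclass(frozen=True)
class TermSet:
    """Named collection of normalized preferred terms with per-PT provenance."""

    name: str
    pts: frozenset[str]
    provenance: dict = field(default_factory=dict, hash=False, compare=False)

    def __contains__(self, pt: str) -> bool:
        return normalize_pt(pt) in self.pts

    def __len__(self) -> int:
        return len(self.pts)

    def sorted_pts(self) -> list[str]:
        return sorted(self.pts)

    def to_rows(self) -> list[tuple[str, str]]:
        """(pt, provenance) rows for echoing into a run manifest."""
        return [(pt, self.provenance.get(pt, "manual")) for pt in self.sorted_pts()]


def _read_term_file(path) -> list[tuple[str, str | None]]:
    """Read a one-PT-per-line text file or a two-column (pt, provenance) CSV."""
    rows = []
    text = Path(path).read_text().strip()
    if not text:
        return rows
    first = text.splitlines()[0]
    if "," in first:
        for rec in csv.DictReader(text.splitlines()):
            keys = {k.strip().lower(): v for k, v in rec.items() if k}
            pt = keys.get("pt") or next(iter(rec.values()))
            rows.append((pt, keys.get("provenance")))
        if rows and rows[0][0].strip().lower() == "pt":  # headerless fallback
            rows = [(a, b) for a, b in rows if a.strip().lower() != "pt"]
    else:
        rows = [(line, None) for line in text.splitlines() if line.strip()]
    return rows


def build_termset(
    smq_files: Iterable = (),
    soc_files: Iterable = (),
    manual_list: Iterable[str] = (),
    name: str = "renal_AE",
) -> TermSet:
    """Union SMQ files, SOC files and a manual PT list into one TermSet.

    Duplicate PTs (after normalization) collapse keeping the first-seen
    provenance.  An empty union is a configuration error.
    """
    pts: dict[str, str] = {}

    def _add(pt: str, prov: str):
        key = normalize_pt(pt)
        if key and key not in pts:
            pts[key] = prov

    for f in smq_files:
        for pt, prov in _read_term_file(f):
            _add(pt, prov or "SMQ")
    for f in soc_files:
        for pt, prov in _read_term_file(f):
            _add(pt, prov or "SOC")
    for pt in manual_list:
        _add(pt, "manual")
    if not pts:
        raise ConfigError(f"term set {name!r}: no preferred terms configured")
    return TermSet(name=name, pts=frozenset(pts), provenance=pts)


def load_termset(path, name: str = "custom") -> TermSet:
    """Load a single term file (text or pt,provenance CSV)."""
    rows = _read_term_file(path)
    pts: dict[str, str] = {}
    for pt, prov in rows:
        key = normalize_pt(pt)
        if key and key not in pts:
            pts[key] = prov if prov in PROVENANCES else "manual"
    if not pts:
        raise ConfigError(f"term set {name!r}: file {path} contains no terms")
    return TermSet(name=name, pts=frozenset(pts), provenance=pts)


def default_renal_termset() -> TermSet:
    """The packaged renal adverse-event PT list.

    This is a reconstruction assembled from published signal tables and
    common renal SMQ members, not a licensed MedDRA export; override it with
    a full user-supplied list for production analyses.
    """
    ref = resources.files("faerspv").joinpath("data/renal_pts.csv")
    with resources.as_file(ref) as p:
        ts = load_termset(p, name="renal_AE")
    return ts


def case_has_event(case: CaseReport, terms: TermSet) -> tuple[bool, list[str]]:
    """Whether any of the case's reactions is in the term set.

    Returns the flag and the sorted list of matched PTs, so per-PT counting
    can credit a case once per matched PT while the any-event count credits
    it once overall.
    """
    matched = sorted({normalize_pt(r.pt_name) for r in case.reactions}
                     & terms.pts)
    return bool(matched), matched
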