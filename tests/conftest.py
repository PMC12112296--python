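import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from faerspv.faers_ingest import CaseTable, DRUG_COLUMNS, REAC_COLUMNS, OUTC_COLUMNS


# ---------------------------------------------------------------------------
# Hand-written three-case quarter in the dollar-delimited dialect
# ---------------------------------------------------------------------------

DEMO_TXT = """primaryid$caseid$fda_dt$event_dt$sex$age$age_cod$wt$wt_cod$reporter_country$occp_cod
1$C1$20200301$20200122$M$70$YR$80$KG$US$MD
2$C2$20200301$$F$61$YR$$$JP$CN
3$C3$20200215$20200210$$720$MON$$$FR$
"""

DRUG_TXT = """primaryid$drug_seq$role_cod$drugname$x_unknown
1$1$PS$NIVOLUMAB$z
1$2$SS$Omeprazole magnesium$z
2$1$PS$aspirin$z
3$1$PS$Pembrolizumab$z
99$1$PS$ghostdrug$z
"""

REAC_TXT = """primaryid$pt
1$Acute kidney injury
1$Nausea
2$Headache
3$Tubulointerstitial  Nephritis
"""

THER_TXT = """primaryid$dsg_drug_seq$start_dt
1$1$20200101
1$2$202001
3$1$20200105
"""

OUTC_TXT = """primaryid$outc_cod
1$HO
1$DE
2$OT
"""


@pytest.fixture
def tiny_quarter_streams():
    def _make():
        return dict(
            demo_stream=io.StringIO(DEMO_TXT),
            drug_stream=io.StringIO(DRUG_TXT),
            reac_stream=io.StringIO(REAC_TXT),
            ther_stream=io.StringIO(THER_TXT),
            outc_stream=io.StringIO(OUTC_TXT),
        )
    return _make


# ---------------------------------------------------------------------------
# Builders for synthetic in-memory case tables
# ---------------------------------------------------------------------------

def make_case_table(cases: list[dict]) -> CaseTable:
    """Build a CaseTable from compact dicts:
    {caseid, primaryid?, fda_dt?, event_dt?, sex?, drugs: [(ingredient, role, start_dt?)],
     reactions: [pt], outcomes: [..]}"""
    demo_rows, drug_rows, reac_rows, outc_rows = [], [], [], []
    for i, c in enumerate(cases, start=1):
        cid = str(c.get("caseid", f"C{i}"))
        pid = str(c.get("primaryid", i))
        demo_rows.append(dict(
            primaryid=pid, caseid=cid, fda_dt=str(c.get("fda_dt", "20200101")),
            event_dt=str(c.get("event_dt", "")), sex=c.get("sex", ""),
            age_years=c.get("age_years", np.nan),
            weight_kg=c.get("weight_kg", np.nan),
            country_code=c.get("country_code", ""),
            reporter_type=c.get("reporter_type", ""),
            report_year=c.get("report_year", np.nan),
            indication=c.get("indication", ""), quarter="T"))
        for j, d in enumerate(c.get("drugs", []), start=1):
            ing, role = d[0], d[1]
            start = d[2] if len(d) > 2 else ""
            drug_rows.append(dict(primaryid=pid, caseid=cid, drug_seq=str(j),
                                  drugname_raw=ing, ingredient=ing, role=role,
                                  start_dt=str(start)))
        for pt in c.get("reactions", []):
            reac_rows.append(dict(primaryid=pid, caseid=cid, pt=pt))
        for o in c.get("outcomes", []):
            outc_rows.append(dict(primaryid=pid, caseid=cid, outcome=o))
    return CaseTable(
        demo=pd.DataFrame(demo_rows),
        drugs=pd.DataFrame(drug_rows, columns=DRUG_COLUMNS),
        reactions=pd.DataFrame(reac_rows, columns=REAC_COLUMNS),
        outcomes=pd.DataFrame(outc_rows, columns=OUTC_COLUMNS),
    )
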