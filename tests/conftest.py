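"""Shared fixtures: hand-built reports and a small quarterly-file set."""

from __future__ import annotations

import datetime as dt

import pytest

from faersig.report_store import DrugEntry, ReportSet, SafetyReport


def mk_report(
    rid: str,
    case: str | None = None,
    version: str = "2020-06-01",
    drug: str = "DRUG X",
    role: str = "primary-suspect",
    extra_drugs: tuple = (),
    reactions: tuple = ("CATARACT",),
    age: float | None = 65.0,
    sex: str = "female",
    weight: float | None = 70.0,
    event_date: str | None = None,
    therapy_start: str | None = None,
    outcomes: tuple = ("other-serious",),
    year: int | None = None,
) -> SafetyReport:
    """One-line SafetyReport builder for tests."""
    vd = dt.date.fromisoformat(version)
    drugs = (
        DrugEntry(
            name_raw=drug,
            ingredient=drug,
            role=role,
            therapy_start=dt.date.fromisoformat(therapy_start) if therapy_start else None,
        ),
    ) + tuple(extra_drugs)
    return SafetyReport(
        report_id=rid,
        case_id=case or f"case-{rid}",
        version_date=vd,
        event_date=dt.date.fromisoformat(event_date) if event_date else None,
        report_year=year if year is not None else vd.year,
        age_years=age,
        sex=sex,
        weight_kg=weight,
        country="US",
        outcomes=frozenset(outcomes),
        drugs=drugs,
        reactions=frozenset(reactions),
    )


@pytest.fixture
def report_factory():
    return mk_report


@pytest.fixture
def ten_report_set() -> ReportSet:
    """4 cataract + 6 non-cataract reports; drug X in 3 event and 2
    non-event reports -> contingency table (3, 2, 1, 4)."""
    reports = [
        mk_report("E1", drug="DRUG X"),
        mk_report("E2", drug="DRUG X"),
        mk_report("E3", drug="DRUG X"),
        mk_report("E4", drug="DRUG Y"),
        mk_report("N1", drug="DRUG X", reactions=("NAUSEA",)),
        mk_report("N2", drug="DRUG X", reactions=("NAUSEA",)),
        mk_report("N3", drug="DRUG Y", reactions=("HEADACHE",)),
        mk_report("N4", drug="DRUG Y", reactions=("HEADACHE",)),
        mk_report("N5", drug="DRUG Z", reactions=("RASH",)),
        mk_report("N6", drug="DRUG Z", reactions=("RASH",)),
    ]
    return ReportSet.from_reports(reports)


_DEMO = """\
primaryid$caseid$fda_dt$event_dt$age$sex$wt$occr_country
R01$C01$20200115$20200110$65$F$70$US
R02$C02$20200120$$72$M$82.5$US
R03$C03$20200125$202003$58$F$65$US
R04$C04$20200130$2019$61$F$71$CA
R05$C05$20200204$20200201$121$M$80$US
R06$C06$20200210$$45$F$60$US
R07$C07$20200215$$67$$75$US
R08$C08$20200220$$70$M$$US
R09$C09$20200225$$55$F$58$US
R10$C10$20200301$$66$F$72$US
R11$C11$20200305$$59$M$90$US
R12$C12$20200310$$63$F$64$US
"""

_DRUG = """\
primaryid$drug_seq$drugname$role_cod
R01$1$Lipitor$PS
R02$1$DRUG Y$PS
R02$2$DRUG W$C
R03$1$DRUG X$PS
R04$1$DRUG X$PS
R05$1$DRUG Z$PS
R06$1$atorvastatin calcium$PS
R07$1$DRUG X$PS
R08$1$DRUG Y$PS
R09$1$DRUG Z$PS
R10$1$DRUG X$PS
R11$1$DRUG Y$PS
R12$1$DRUG Z$PS
"""

# R10, R11, R12 have no reaction rows -> join failures
_REAC = """\
primaryid$pt
R01$Cataract
R02$CATARACT
R03$NAUSEA
R04$CATARACT SUBCAPSULAR
R05$HEADACHE
R06$CATARACT
R07$RASH
R08$NAUSEA
R09$DIZZINESS
"""

_OUTC = """\
primaryid$outc_cod
R01$HO
R02$DE
R02$OT
"""

_THER = """\
primaryid$dsg_drug_seq$start_dt$end_dt
R01$1$20200101$
R03$1$20191201$20200301
"""


@pytest.fixture
def quarter_files(tmp_path):
    """12 DEMO rows, 3 of which lack REAC rows; includes partial dates,
    an implausible age and unknown sex (all must survive parsing)."""
    paths = {}
    for name, text in [("DEMO", _DEMO), ("DRUG", _DRUG), ("REAC", _REAC), ("OUTC", _OUTC), ("THER", _THER)]:
        p = tmp_path / f"{name}.txt"
        p.write_text(text)
        paths[name] = p
    return paths
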