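"""Shared fixtures: a hand-written 3-report quarter file set and helpers.

The hand fixture is small enough to join by eye; its expected SafetyReports
are frozen in HAND_EXPECTED below and every join assertion derives from
them.
"""

from __future__ import annotations

import pytest

from pvsignal import DrugEntry, SafetyReport

# three reports: R1 two drugs + two PTs + outcome + indication,
# R2 one drug + one PT, R3 drug but NO reaction rows (must be dropped);
# one orphan REAC row (R9) exercises the warning path
DEMO = """primaryid$caseid$caseversion$age$sex$occr_country
R1$CASE-A$1$53$F$US
R2$CASE-B$2$$M$
R3$CASE-C$1$44$F$FR
"""
DRUG = """primaryid$drug_seq$role_cod$drugname
R1$1$PS$COSENTYX 150MG
R1$2$C$IBUPROFEN
R2$1$PS$taltz
R3$1$PS$ASPIRIN
"""
REAC = """primaryid$pt
R1$Crohn's disease
R1$Colitis
R2$Inflammatory bowel disease
R9$Headache
"""
OUTC = """primaryid$outc_cod
R1$HO
R1$OT
"""
INDI = """primaryid$indi_drug_seq$indi_pt
R1$1$Psoriasis
"""

HAND_EXPECTED = [
    SafetyReport(
        case_id="CASE-A", case_version=1, quarter="2016Q2",
        drugs=(DrugEntry("COSENTYX 150MG", "PS", "Psoriasis"),
               DrugEntry("IBUPROFEN", "C", None)),
        reaction_pts=("Crohn's disease", "Colitis"),
        outcome_codes=frozenset({"HO", "OT"}),
        age_years=53.0, sex="female", country="US", record_id="R1",
    ),
    SafetyReport(
        case_id="CASE-B", case_version=2, quarter="2016Q2",
        drugs=(DrugEntry("taltz", "PS", None),),
        reaction_pts=("Inflammatory bowel disease",),
        outcome_codes=frozenset(),
        age_years=None, sex="male", country=None, record_id="R2",
    ),
]


@pytest.fixture
def hand_quarter_dir(tmp_path):
    """Directory holding the hand-written 2016Q2 file set."""
    for name, text in (("DEMO", DEMO), ("DRUG", DRUG), ("REAC", REAC),
                       ("OUTC", OUTC), ("INDI", INDI)):
        (tmp_path / f"{name}2016Q2.txt").write_text(text)
    return tmp_path


def make_report(case_id="C1", version=1, quarter="2020Q1", pts=("Colitis",),
                drugs=(("COSENTYX", "PS"),), record_id=None, **kwargs) -> SafetyReport:
    """Terse SafetyReport builder for in-memory test collections."""
    return SafetyReport(
        case_id=case_id, case_version=version, quarter=quarter,
        drugs=tuple(DrugEntry(n, r) for n, r in drugs),
        reaction_pts=tuple(pts),
        record_id=record_id or f"{case_id}v{version}",
        **kwargs,
    )
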