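"""Bundled reference datasets.

The literature on IL-17-inhibitor-associated IBD reports 34 published cases
whose descriptive summary (demographics, onset, symptoms, labs, endoscopy,
therapy, outcome) is known only as marginal frequency tables — the
individual patient rows were never published. ``reference_case_series``
reconstructs a SYNTHETIC series of 34 cases whose marginals reproduce every
one of those published counts exactly (including median age 42 years, age
range 19-76, median onset 2.9 months, onset range 0.47-48 months). It is a
pipeline fixture, not patient data; within-case combinations of values are
arbitrary wherever the marginals leave them free.

The same series ships as ``data/literature_cases_synthetic.csv`` for use as
a CSV input example.
"""

from __future__ import annotations

from importlib import resources

from .cases import LiteratureCase
from .faers import DrugEntry, SafetyReport

#: Total adverse-event cases reported to FAERS per IL-17 inhibitor through
#: 2022Q3 — the denominators of the reporting-proportion calculations.
FAERS_REPORTED_TOTALS = {
    "secukinumab": 44_688,
    "ixekizumab": 24_406,
    "brodalumab": 1_796,
}

#: Published event-level tallies (No. of AEs) per drug and preferred term in
#: the IL-17 inhibitor gastrointestinal-inflammation analysis of FAERS
#: 2015Q1-2022Q3. Used as inputs when re-deriving group totals and
#: reporting proportions.
IBD_EVENT_COUNTS = {
    "secukinumab": {
        "Crohn's disease": 233, "Colitis ulcerative": 196,
        "Inflammatory bowel disease": 182,
    },
    "ixekizumab": {
        "Crohn's disease": 43, "Colitis ulcerative": 67,
        "Inflammatory bowel disease": 50,
    },
    "brodalumab": {
        "Crohn's disease": 1, "Colitis ulcerative": 2,
        "Inflammatory bowel disease": 0,
    },
}

COLITIS_EVENT_COUNTS = {
    "secukinumab": {
        "Colitis": 223, "Microscopic colitis": 28, "Ischaemic colitis": 10,
        "Proctitis": 10, "Proctitis ulcerative": 4, "Proctitis haemorrhagic": 0,
        "Enteritis": 22, "Enterocolitis": 10, "Enterocolitis haemorrhagic": 5,
        "Eosinophilic colitis": 1, "Colitis erosive": 1,
    },
    "ixekizumab": {
        "Colitis": 53, "Microscopic colitis": 8, "Ischaemic colitis": 2,
        "Proctitis": 0, "Proctitis ulcerative": 0, "Proctitis haemorrhagic": 1,
        "Enteritis": 2, "Enterocolitis": 1, "Enterocolitis haemorrhagic": 4,
        "Eosinophilic colitis": 1, "Colitis erosive": 1,
    },
    "brodalumab": {
        "Colitis": 3, "Microscopic colitis": 0, "Ischaemic colitis": 0,
        "Proctitis": 0, "Proctitis ulcerative": 0, "Proctitis haemorrhagic": 0,
        "Enteritis": 0, "Enterocolitis": 0, "Enterocolitis haemorrhagic": 0,
        "Eosinophilic colitis": 0, "Colitis erosive": 0,
    },
}

#: Published case-level characteristics of the 388 primary-suspect
#: gastrointestinal-inflammation cases: primary-suspect drug split and
#: bowel-disease classification.
PRIMARY_SUSPECT_DRUG_SPLIT = {"secukinumab": 348, "ixekizumab": 36, "brodalumab": 4}
BOWEL_DISEASE_SPLIT = {
    "Colitis ulcerative": 87,        # UC
    "Crohn's disease": 96,           # CD
    "Inflammatory bowel disease": 85,  # unclassified IBD
    "Colitis": 120,                  # the colitis arm
}

_BRAND_OF = {"secukinumab": "COSENTYX", "ixekizumab": "TALTZ", "brodalumab": "SILIQ"}


def reports_from_event_counts(
    counts: dict[str, dict[str, int]], quarter: str = "2020Q1"
) -> list[SafetyReport]:
    """Materialize per-drug per-PT event tallies as single-PT reports.

    Each tallied event becomes one report carrying exactly that preferred
    term with the drug as primary suspect, so pushing the collection through
    the tally pipeline reproduces the input counts and their group sums.
    """
    reports = []
    i = 0
    for drug, per_pt in counts.items():
        for pt, k in per_pt.items():
            for _ in range(k):
                reports.append(SafetyReport(
                    case_id=f"T{i:06d}", case_version=1, quarter=quarter,
                    drugs=(DrugEntry(_BRAND_OF[drug], "PS"),),
                    reaction_pts=(pt,), record_id=f"T{i:06d}",
                ))
                i += 1
    return reports


def characteristics_case_set(quarter: str = "2020Q1") -> list[SafetyReport]:
    """The 388 primary-suspect cases implied by the published characteristics.

    Each case carries one bowel-disease PT per the published UC/CD/uIBD/
    colitis split and one primary-suspect IL-17 inhibitor per the published
    drug split; all other fields are unknown (the published table itself is
    mostly Unknown). Synthetic: only the tabulated marginals are real.
    """
    pts = [pt for pt, k in BOWEL_DISEASE_SPLIT.items() for _ in range(k)]
    drugs = [d for d, k in PRIMARY_SUSPECT_DRUG_SPLIT.items() for _ in range(k)]
    assert len(pts) == len(drugs)
    return [
        SafetyReport(
            case_id=f"K{i:04d}", case_version=1, quarter=quarter,
            drugs=(DrugEntry(_BRAND_OF[drug], "PS"),),
            reaction_pts=(pt,), record_id=f"K{i:04d}",
        )
        for i, (pt, drug) in enumerate(zip(pts, drugs))
    ]

# ages: 1 case <=25, 23 in 26-50 (five 42s pin the median at 42), 9 in 51-75,
# 1 at 76; range 19-76
_AGES = (
    [19]
    + [27, 28, 30, 31, 33, 34, 35, 36, 38, 39, 40, 41, 42, 42, 42, 42, 42,
       43, 45, 46, 48, 49, 50]
    + [51, 53, 55, 58, 60, 63, 66, 70, 74]
    + [76]
)

# onset (months) for cases 0-26: bins 5/9/7/3/2/1, median (14th of 27) = 2.9,
# range 0.47-48
_ONSETS = [
    0.47, 0.5, 0.6, 0.7, 0.9,
    1.2, 1.5, 1.8, 2.0, 2.2, 2.5, 2.6, 2.7, 2.9,
    3.0, 3.5, 4.0, 4.5, 5.0, 5.5, 5.9,
    6.5, 8.0, 11.0,
    13.0, 20.0,
    48.0,
]

# relief (weeks) for cases 0-14: bins 3/7/5 under the [2,4) convention
_RELIEFS = [1.0, 1.5, 1.8, 2.0, 2.3, 2.6, 3.0, 3.3, 3.6, 3.9, 5.0, 6.0, 8.0, 10.0, 12.0]


def _ranges(spec: dict[str, range]) -> dict[int, str]:
    out: dict[int, str] = {}
    for label, idx in spec.items():
        for i in idx:
            out[i] = label
    return out


def reference_case_series() -> list[LiteratureCase]:
    """The 34-case synthetic reference series (deterministic, no RNG)."""
    n = 34
    drug = _ranges({"secukinumab": range(27), "ixekizumab": range(27, 34)})
    source = _ranges({"case_report": range(25), "case_series": range(25, 29)})
    sex = _ranges({"female": range(17), "male": range(17, 34)})
    region = _ranges({
        "USA": range(11), "Europe": range(11, 24), "Canada": range(24, 30),
        "Asia": range(30, 32), "other": range(32, 33),
    })
    indication = _ranges({
        "PsO": range(20), "PsA": range(20, 24), "PsO_and_PsA": range(24, 27),
        "AS": range(27, 34),
    })
    smoking = _ranges({"yes": range(8), "no": range(8, 12), "not_mentioned": range(12, 34)})
    prior_tnf = _ranges({"adalimumab": range(13), "etanercept": range(13, 24)})
    ibd_class = _ranges({"UC": range(13), "CD": range(13, 23), "unclassified": range(23, 28)})
    wbc = _ranges({"elevated": range(7), "normal": range(7, 8)})
    crp = _ranges({"elevated": range(16)})
    esr = _ranges({"elevated": range(6), "normal": range(6, 7)})
    fcal = _ranges({"elevated": range(4)})
    ct = _ranges({
        "bowel_wall_thickening": range(5), "pancolitis": range(5, 7),
        "colon_perforated": range(7, 8), "normal": range(8, 10),
    })
    therapy = _ranges({
        "none": range(1), "corticosteroids": range(1, 11),
        "tnf_antagonist": range(11, 17), "ustekinumab": range(17, 19),
        "five_asa": range(19, 20),
        "corticosteroids_plus_tnf_antagonist": range(20, 26),
        "corticosteroids_plus_five_asa": range(26, 30),
        "corticosteroids_plus_ustekinumab": range(30, 31),
    })
    outcome = _ranges({"recovered": range(27), "relapse": range(27, 29)})

    symptom_sets: dict[int, set[str]] = {i: set() for i in range(33)}
    for i in list(range(28)) + [30, 31]:
        symptom_sets[i].add("diarrhea")            # 30 cases
    for i in range(19):
        symptom_sets[i].add("abdominal_pain")      # 19
    for i in range(17):
        symptom_sets[i].add("bloody_diarrhea")     # 17
    for i in list(range(10)) + [28, 29]:
        symptom_sets[i].add("fever")               # 12
    for i in range(10, 15):
        symptom_sets[i].add("weight_loss")         # 5
    for i in range(15, 19):
        symptom_sets[i].add("chills")              # 4
    for i in range(19, 23):
        symptom_sets[i].add("nausea")              # 4
    symptom_sets[32] = {"asymptomatic"}            # 1

    colono: dict[int, set[str]] = {i: set() for i in range(28)}
    for i in range(13):
        colono[i].add("deep_ulcerations")          # 13
    for i in range(13, 21):
        colono[i].add("active_inflammation")       # 8
    for i in range(21, 27):
        colono[i].add("superficial_ulceration")    # 6
    for i in range(22, 28):
        colono[i].add("erythematous_mucosa")       # 6
    for i in range(5):
        colono[i].add("edematous")                 # 5
    for i in range(5, 9):
        colono[i].add("friable_mucosa")            # 4
    for i in range(9, 13):
        colono[i].add("absent_vascular_pattern")   # 4
    for i in range(13, 16):
        colono[i].add("hemorrhagic")               # 3

    histo: dict[int, set[str]] = {i: set() for i in range(25)}
    for i in range(11):
        histo[i].add("chronic_inflammation")       # 11
    for i in range(11, 19):
        histo[i].add("cryptitis")                  # 8
    for i in range(17, 25):
        histo[i].add("crypt_abscesses")            # 8
    for i in range(7):
        histo[i].add("granulomatous_lesions")      # 7

    cases = []
    for i in range(n):
        cases.append(LiteratureCase(
            drug=drug[i],
            source_kind=source.get(i),
            sex=sex[i],
            age_years=float(_AGES[i]),
            region=region.get(i),
            preexisting_ibd=i < 3,
            family_history_ibd=i < 5,
            indication=indication[i],
            smoking=smoking[i],
            prior_tnf=prior_tnf.get(i),
            onset_months=_ONSETS[i] if i < 27 else None,
            ibd_class=ibd_class.get(i),
            symptoms=frozenset(symptom_sets[i]) if i in symptom_sets else None,
            wbc=wbc.get(i),
            crp=crp.get(i),
            esr=esr.get(i),
            fecal_calprotectin=fcal.get(i),
            ct_findings=frozenset({ct[i]}) if i in ct else None,
            colonoscopy_findings=frozenset(colono[i]) if i in colono else None,
            histopathology_findings=frozenset(histo[i]) if i in histo else None,
            therapy=therapy.get(i),
            outcome=outcome.get(i),
            relief_weeks=_RELIEFS[i] if i < 15 else None,
        ))
    return cases


def reference_case_csv_path():
    """Path to the bundled synthetic case-series CSV."""
    return resources.files("pvsignal.data") / "literature_cases_synthetic.csv"
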