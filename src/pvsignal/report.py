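"""Publication-style output assembly: screening flow and case characteristics.

``characteristics_table`` reproduces the layout of a published "main
characteristics of primary-suspect cases" table: age bands, sex, reporting
country, reporting-year bands, primary-suspect drug, outcome codes,
indication, bowel-disease classification and onset-time bins, each with
counts and percentages of the selected case set. ``screening_counts``
records the screening flow (all reports -> window -> deduplicated ->
primary-suspect for the drug class -> event-group cases) in the order a
study flow chart presents it.
"""

from __future__ import annotations

import logging
from collections import Counter

import pandas as pd

from ._rounding import round_display
from .cases import bin_age, bin_onset
from .dispro import DEFAULT_GROUPS, EventGroup
from .faers import DrugDictionary, SafetyReport, _norm_pt, deduplicate, filter_window, select_reports
from .quarters import Quarter, QuarterWindow

logger = logging.getLogger(__name__)

OUTCOME_LABELS = {
    "DE": "Death",
    "LT": "Life-threatening",
    "HO": "Hospitalization-initial or prolonged",
    "DS": "Disability",
    "CA": "Congenital anomaly",
    "RI": "Required intervention",
    "OT": "Other medical significant condition",
}

_YEAR_BANDS = ((2015, 2016), (2017, 2018), (2019, 2020), (2021, 2022))

_INDICATION_MAP = {
    "ankylosing spondylitis": "Ankylosing spondylitis",
    "psoriasis": "Psoriasis",
    "psoriatic arthropathy": "Psoriatic arthropathy",
    "psoriatic arthritis": "Psoriatic arthropathy",
}

#: PT -> sub-classification rows of the bowel-disease section
_IBD_SUBTYPES = {
    "colitis ulcerative": "UC",
    "crohn's disease": "CD",
    "inflammatory bowel disease": "uIBD",
}


def primary_suspect_events(
    reports: list[SafetyReport],
    dictionary: DrugDictionary,
    groups: tuple[EventGroup, ...] = DEFAULT_GROUPS,
    window: QuarterWindow | None = None,
) -> tuple[list[SafetyReport], dict[str, int]]:
    """Screen a raw collection down to the analysis case set.

    Applies, in flow-chart order: quarter window -> deduplication ->
    primary-suspect exposure to any dictionary active -> at least one PT of
    an analysis event group. Returns the selected cases and the count at
    each screening step.
    """
    counts: dict[str, int] = {"all_reports": len(reports)}
    if window is not None:
        reports = filter_window(reports, window)
    counts["in_window"] = len(reports)
    reports = deduplicate(reports)
    counts["deduplicated"] = len(reports)
    exposed: list[SafetyReport] = []
    seen: set[str] = set()
    for active in dictionary.actives:
        for r in select_reports(reports, active, dictionary):
            if r.case_id not in seen:
                seen.add(r.case_id)
                exposed.append(r)
    counts["primary_suspect"] = len(exposed)
    group_pts = frozenset().union(*(g.norm_pts for g in groups))
    cases = [r for r in exposed if r.distinct_pts & group_pts]
    counts["event_cases"] = len(cases)
    for step, n in counts.items():
        logger.info("screening %s: %d", step, n)
    return cases, counts


def characteristics_table(
    cases: list[SafetyReport],
    dictionary: DrugDictionary,
    groups: tuple[EventGroup, ...] = DEFAULT_GROUPS,
) -> pd.DataFrame:
    """Characteristics of a selected case set, as (section, category, count, percent).

    Percentages use the full case count as denominator, rounded half-up to
    one decimal. Reports with several outcome codes count once per code; a
    report with no outcome code counts as Unknown. A case is classified IBD
    when it carries any IBD-group PT, otherwise under the second group;
    within IBD the UC/CD/uIBD rows count each sub-PT a case carries.
    """
    n = len(cases)
    rows: list[tuple[str, str, int]] = []

    def section(name: str, counter: dict[str, int], order: list[str]) -> None:
        for cat in order:
            rows.append((name, cat, counter.get(cat, 0)))

    ages = Counter(
        "Unknown" if r.age_years is None else bin_age(r.age_years) for r in cases
    )
    section("Age (years)", ages, ["<=25", "26-50", "51-75", ">=76", "Unknown"])

    sexes = Counter(
        {"female": "Female", "male": "Male", "unknown": "Unknown"}[r.sex] for r in cases
    )
    section("Gender", sexes, ["Female", "Male", "Unknown"])

    countries = Counter(
        "Unknown" if r.country is None
        else "United States" if r.country.strip().upper() in ("US", "USA", "UNITED STATES")
        else "Other countries"
        for r in cases
    )
    section("Reporting country", countries, ["United States", "Other countries", "Unknown"])

    years = Counter()
    for r in cases:
        y = Quarter.parse(r.quarter).year
        for lo, hi in _YEAR_BANDS:
            if lo <= y <= hi:
                years[f"{lo}-{hi}"] += 1
                break
        else:
            years["Other"] += 1
    order = [f"{lo}-{hi}" for lo, hi in _YEAR_BANDS]
    section("Reporting year", years, order + (["Other"] if years.get("Other") else []))

    ps_drug = Counter()
    for r in cases:
        actives = {
            m for d in r.drugs if d.role == "PS"
            if (m := dictionary.match(d.verbatim_name)) is not None
        }
        for a in sorted(actives):
            ps_drug[a] += 1
    section("Primary suspect drug", ps_drug, list(dictionary.actives))

    outcomes = Counter()
    for r in cases:
        if not r.outcome_codes:
            outcomes["Unknown"] += 1
        for code in r.outcome_codes:
            outcomes[OUTCOME_LABELS[code]] += 1
    section("Outcome", outcomes,
            [OUTCOME_LABELS[c] for c in ("DE", "LT", "HO", "DS", "CA", "RI", "OT")] + ["Unknown"])

    indications = Counter()
    for r in cases:
        pts = {
            _INDICATION_MAP.get(_norm_pt(d.indication_pt))
            for d in r.drugs if d.role == "PS" and d.indication_pt
        } - {None}
        if not pts:
            indications["Unknown"] += 1
        elif len(pts) == 1:
            indications[pts.pop()] += 1
        else:
            indications["Others"] += 1
    section("Reported indication", indications,
            ["Ankylosing spondylitis", "Psoriasis", "Psoriatic arthropathy", "Others", "Unknown"])

    ibd_group = groups[0]
    disease = Counter()
    for r in cases:
        pts = r.distinct_pts
        if pts & ibd_group.norm_pts:
            disease[f"All {ibd_group.name}"] += 1
            for pt, label in _IBD_SUBTYPES.items():
                if pt in pts:
                    disease[label] += 1
        else:
            disease[f"All {groups[1].name}" if len(groups) > 1 else "Other"] += 1
    order = [f"All {ibd_group.name}", "UC", "CD", "uIBD"]
    if len(groups) > 1:
        order.append(f"All {groups[1].name}")
    section("Bowel disease", disease, order)

    onsets = Counter(
        "Unknown" if r.onset_months is None else bin_onset(r.onset_months) for r in cases
    )
    section("Onset time of symptoms (months)", onsets,
            ["<1", "1-3", "3-6", "6-12", "12-24", ">24", "Unknown"])

    return pd.DataFrame(
        [(s, c, k, round_display(100 * k / n, 1) if n else 0.0) for s, c, k in rows],
        columns=["section", "category", "count", "percent"],
    )
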