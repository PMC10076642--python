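"""Ingestion of FAERS-style quarterly report files.

The FDA Adverse Event Reporting System publishes each quarter as a set of
'$'-delimited ASCII tables sharing a report identifier: DEMO (demographics,
one row per report version), DRUG (one row per drug entry, with a reporter-
assigned role code), REAC (one row per MedDRA preferred term), OUTC
(outcome codes) and INDI (indication PTs per drug entry). This module reads
those tables into :class:`SafetyReport` objects, collapses multiple
submitted versions of the same case to the latest one, matches free-text
drug names against a brand/generic dictionary, and selects reports by drug
role.

Exposure in the downstream disproportionality analysis is defined by the
primary-suspect (PS) role: the drug the reporter most suspected of causing
the event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd

from .quarters import Quarter, QuarterWindow

logger = logging.getLogger(__name__)

ROLE_CODES = ("PS", "SS", "C", "I")
OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")
SEXES = ("female", "male", "unknown")


class FormatError(ValueError):
    """A required column is missing or a table cannot be parsed."""


class ConfigError(ValueError):
    """Invalid analysis configuration (unknown active, empty group, ...)."""


class AmbiguousDrugNameError(ConfigError):
    """A verbatim drug name matches patterns of two different actives."""


@dataclass(frozen=True, slots=True)
class DrugEntry:
    """One drug row of a report: free-text name plus reporter-assigned role."""

    verbatim_name: str
    role: str
    indication_pt: str | None = None

    def __post_init__(self) -> None:
        if not self.verbatim_name:
            raise ValueError("verbatim_name must be non-empty")
        if self.role not in ROLE_CODES:
            raise ValueError(f"role must be one of {ROLE_CODES}, got {self.role!r}")


@dataclass(frozen=True, slots=True)
class SafetyReport:
    """One spontaneous adverse-event report (one version of one case)."""

    case_id: str
    case_version: int
    quarter: str
    drugs: tuple[DrugEntry, ...]
    reaction_pts: tuple[str, ...]
    outcome_codes: frozenset[str] = frozenset()
    age_years: float | None = None
    sex: str = "unknown"
    country: str | None = None
    #: months from suspect-drug start to event onset; not derivable from the
    #: five ingested tables, so always None after ingestion, but the
    #: synthetic generator may populate it for characteristics tables.
    onset_months: float | None = None
    record_id: str = ""

    def __post_init__(self) -> None:
        if self.case_version < 0:
            raise ValueError("case_version must be non-negative")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        bad = set(self.outcome_codes) - set(OUTCOME_CODES)
        if bad:
            raise ValueError(f"unknown outcome codes {sorted(bad)}")

    @property
    def distinct_pts(self) -> frozenset[str]:
        return frozenset(_norm_pt(p) for p in self.reaction_pts)


def _norm_pt(pt: str) -> str:
    """PT matching is case-insensitive exact equality after trimming."""
    return pt.strip().lower()


@dataclass(frozen=True)
class DrugDictionary:
    """Mapping from active-substance label to its brand/generic name patterns.

    Matching is a case-insensitive substring test on the trimmed verbatim
    name, because spontaneous-report drug strings carry doses and salts
    ("COSENTYX 150MG"). No pattern may belong to two actives.
    """

    entries: dict[str, frozenset[str]]
    _cache: dict[str, str | None] = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        norm: dict[str, frozenset[str]] = {}
        seen: dict[str, str] = {}
        for active, patterns in self.entries.items():
            pats = frozenset(p.strip().lower() for p in patterns)
            if not pats or "" in pats:
                raise ConfigError(f"active {active!r} has an empty pattern set or pattern")
            for p in pats:
                if p in seen and seen[p] != active:
                    raise ConfigError(f"pattern {p!r} maps to both {seen[p]!r} and {active!r}")
                seen[p] = active
            norm[active] = pats
        object.__setattr__(self, "entries", norm)

    @property
    def actives(self) -> tuple[str, ...]:
        return tuple(self.entries)

    def match(self, verbatim_name: str) -> str | None:
        """Return the unique active whose pattern occurs in the name, else None."""
        key = verbatim_name.strip().lower()
        if key in self._cache:
            return self._cache[key]
        hits = {a for a, pats in self.entries.items() if any(p in key for p in pats)}
        if len(hits) > 1:
            raise AmbiguousDrugNameError(
                f"name {verbatim_name!r} matches multiple actives: {sorted(hits)}"
            )
        result = hits.pop() if hits else None
        self._cache[key] = result
        return result


#: Brand + generic names of the three marketed IL-17 inhibitors, the study
#: drug class. Regional brand names can be added via configuration.
IL17_DICTIONARY = DrugDictionary(
    {
        "secukinumab": frozenset({"secukinumab", "cosentyx"}),
        "ixekizumab": frozenset({"ixekizumab", "taltz"}),
        "brodalumab": frozenset({"brodalumab", "siliq"}),
    }
)


def match_drug(verbatim_name: str, dictionary: DrugDictionary) -> str | None:
    """Functional wrapper around :meth:`DrugDictionary.match`."""
    return dictionary.match(verbatim_name)


# ---------------------------------------------------------------------------
# File reading

DELIMITER = "$"

_REQUIRED = {
    "demo": ("primaryid", "caseid", "caseversion", "age", "sex", "occr_country"),
    "drug": ("primaryid", "drug_seq", "role_cod", "drugname"),
    "reac": ("primaryid", "pt"),
    "outc": ("primaryid", "outc_cod"),
    "indi": ("primaryid", "indi_drug_seq", "indi_pt"),
}

_SEX_MAP = {"f": "female", "m": "male"}


def _read_table(path, kind: str, delimiter: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _REQUIRED[kind] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing} in {kind.upper()} table")
    logger.info("%s: read %d rows from %s", kind.upper(), len(df), path)
    return df


def _opt_float(s: str) -> float | None:
    s = s.strip()
    if not s:
        return None
    try:
        return float(s)
    except ValueError:
        return None


def read_quarter_files(
    demo_path,
    drug_path,
    reac_path,
    outc_path,
    indi_path,
    quarter: str,
    delimiter: str = DELIMITER,
) -> list[SafetyReport]:
    """Read one quarter's DEMO/DRUG/REAC/OUTC/INDI tables into reports.

    One :class:`SafetyReport` is produced per distinct ``primaryid`` in the
    DEMO table, with drug, reaction, outcome and indication rows joined by
    that key. Reports with no reaction row are dropped (there is nothing to
    analyse) and the dropped count is logged; orphan rows in the satellite
    tables (ids absent from DEMO) are logged as warnings, never fatal.

    Unparseable age/sex/country values degrade to unknown — spontaneous
    reports have large unknown strata and dropping them would bias counts.
    """
    Quarter.parse(quarter)  # validate the label early
    demo = _read_table(demo_path, "demo", delimiter)
    drug = _read_table(drug_path, "drug", delimiter)
    reac = _read_table(reac_path, "reac", delimiter)
    outc = _read_table(outc_path, "outc", delimiter)
    indi = _read_table(indi_path, "indi", delimiter)

    known = set(demo["primaryid"])
    for name, df in (("DRUG", drug), ("REAC", reac), ("OUTC", outc), ("INDI", indi)):
        orphans = (~df["primaryid"].isin(known)).sum()
        if orphans:
            logger.warning("%s: %d orphan rows with primaryid absent from DEMO", name, orphans)

    indications: dict[tuple[str, str], str] = {}
    for row in indi.itertuples(index=False):
        pt = row.indi_pt.strip()
        if pt:
            indications[(row.primaryid, row.indi_drug_seq)] = pt

    drugs_by_id: dict[str, list[DrugEntry]] = {}
    for row in drug.itertuples(index=False):
        pid = row.primaryid
        if pid not in known:
            continue
        name = row.drugname.strip()
        role = row.role_cod.strip().upper()
        if not name or role not in ROLE_CODES:
            continue
        drugs_by_id.setdefault(pid, []).append(
            DrugEntry(name, role, indications.get((pid, row.drug_seq)))
        )

    reac_by_id: dict[str, list[str]] = {}
    for row in reac.itertuples(index=False):
        pt = row.pt.strip()
        if pt and row.primaryid in known:
            reac_by_id.setdefault(row.primaryid, []).append(pt)

    outc_by_id: dict[str, set[str]] = {}
    for row in outc.itertuples(index=False):
        code = row.outc_cod.strip().upper()
        if code in OUTCOME_CODES and row.primaryid in known:
            outc_by_id.setdefault(row.primaryid, set()).add(code)

    reports: list[SafetyReport] = []
    n_no_reaction = 0
    for row in demo.drop_duplicates(subset="primaryid").itertuples(index=False):
        pid = row.primaryid
        pts = reac_by_id.get(pid)
        if not pts:
            n_no_reaction += 1
            continue
        try:
            version = int(row.caseversion)
        except ValueError:
            version = 0
        sex = _SEX_MAP.get(row.sex.strip().lower(), "unknown")
        country = row.occr_country.strip() or None
        reports.append(
            SafetyReport(
                case_id=row.caseid,
                case_version=version,
                quarter=quarter,
                drugs=tuple(drugs_by_id.get(pid, ())),
                reaction_pts=tuple(pts),
                outcome_codes=frozenset(outc_by_id.get(pid, set())),
                age_years=_opt_float(row.age),
                sex=sex,
                country=country,
                record_id=pid,
            )
        )
    if n_no_reaction:
        logger.info("dropped %d report(s) without any reaction PT", n_no_reaction)
    logger.info("quarter %s: %d reports ingested", quarter, len(reports))
    return reports


def read_quarter_dir(directory, window: QuarterWindow | None = None,
                     delimiter: str = DELIMITER) -> list[SafetyReport]:
    """Read every quarter file set ``DEMO<label>.txt`` ... found in a directory.

    File sets are discovered by the DEMO file name; quarters outside
    ``window`` (when given) are skipped.
    """
    from pathlib import Path

    directory = Path(directory)
    reports: list[SafetyReport] = []
    demo_files = sorted(directory.glob("DEMO*.txt"))
    if not demo_files:
        raise FormatError(f"no DEMO*.txt files found in {directory}")
    for demo in demo_files:
        label = demo.stem[len("DEMO"):]
        quarter = str(Quarter.parse(label))
        if window is not None and quarter not in window:
            logger.info("skipping quarter %s outside window", quarter)
            continue
        paths = {k: directory / f"{k.upper()}{label}.txt" for k in _REQUIRED}
        for k, p in paths.items():
            if not p.exists():
                raise FormatError(f"quarter {quarter}: missing companion file {p}")
        reports.extend(
            read_quarter_files(
                paths["demo"], paths["drug"], paths["reac"], paths["outc"], paths["indi"],
                quarter=quarter, delimiter=delimiter,
            )
        )
    return reports


# ---------------------------------------------------------------------------
# Case-level operations


def deduplicate(reports: list[SafetyReport]) -> list[SafetyReport]:
    """Collapse multiple versions of a case to a single report.

    FAERS ships every resubmission of a case; counting them all would
    double-count patients. Per case_id the report with the greatest
    (case_version, quarter, record_id) triple is retained — latest version,
    tie-broken by latest publication quarter, then by the lexicographically
    largest raw record id. Idempotent; input order of surviving cases is
    preserved.
    """
    def sort_key(r: SafetyReport):
        return (r.case_version, Quarter.parse(r.quarter), r.record_id)

    best: dict[str, SafetyReport] = {}
    order: list[str] = []
    n_dropped = 0
    for r in reports:
        cur = best.get(r.case_id)
        if cur is None:
            best[r.case_id] = r
            order.append(r.case_id)
        else:
            n_dropped += 1
            if sort_key(r) > sort_key(cur):
                best[r.case_id] = r
    if n_dropped:
        logger.info("deduplicate: dropped %d superseded version(s), %d unique cases",
                    n_dropped, len(best))
    return [best[cid] for cid in order]


def filter_window(reports: list[SafetyReport], window: QuarterWindow) -> list[SafetyReport]:
    """Keep reports whose file-of-origin quarter lies inside the window."""
    kept = [r for r in reports if r.quarter in window]
    if len(kept) != len(reports):
        logger.info("window %s-%s: kept %d of %d reports",
                    window.start, window.end, len(kept), len(reports))
    return kept


def select_reports(
    reports: list[SafetyReport],
    active: str,
    dictionary: DrugDictionary,
    role_filter: frozenset[str] | set[str] = frozenset({"PS"}),
) -> list[SafetyReport]:
    """Reports carrying >=1 drug entry that matches ``active`` with an allowed role.

    The default role filter is {PS}: primary-suspect exposure, the standard
    exposure definition in disproportionality analyses.
    """
    if active not in dictionary.entries:
        raise ConfigError(f"unknown active {active!r}; dictionary has {list(dictionary.entries)}")
    bad = set(role_filter) - set(ROLE_CODES)
    if bad:
        raise ConfigError(f"unknown role codes {sorted(bad)}")
    return [
        r for r in reports
        if any(d.role in role_filter and dictionary.match(d.verbatim_name) == active
               for d in r.drugs)
    ]


def with_onset(report: SafetyReport, onset_months: float | None) -> SafetyReport:
    """Return a copy of the report with onset_months set (generator use)."""
    return replace(report, onset_months=onset_months)
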