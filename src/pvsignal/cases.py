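"""Descriptive summary of published drug-associated IBD cases.

A literature case series is a table with one row per published patient:
demographics, indication for the suspect drug, time to symptom onset,
IBD classification, symptoms, laboratory markers, imaging, colonoscopy and
histopathology findings, therapy and outcome. This module validates such a
table against controlled vocabularies, bins onset and relief times, and
produces frequency tables with per-variable denominators (the "n =" of a
published table): a case missing a field is excluded from that variable
only, never from the series.

Set-valued variables (symptoms, findings) use the number of cases that
reported the variable as the denominator, so their percentages need not sum
to 100.
"""

from __future__ import annotations

import csv
import statistics
from dataclasses import dataclass, field, fields

import pandas as pd

from ._rounding import round_display

SOURCE_KINDS = ("case_report", "case_series")
SEXES = ("female", "male", "unknown")
REGIONS = ("USA", "Europe", "Canada", "Asia", "other", "unknown")
DRUGS = ("secukinumab", "ixekizumab", "brodalumab")
INDICATIONS = ("PsO", "PsA", "PsO_and_PsA", "AS", "other")
SMOKING = ("yes", "no", "not_mentioned")
PRIOR_TNF = ("adalimumab", "etanercept", "none")
IBD_CLASSES = ("UC", "CD", "unclassified")
SYMPTOMS = (
    "diarrhea", "bloody_diarrhea", "abdominal_pain", "fever", "chills",
    "nausea", "weight_loss", "asymptomatic",
)
LAB_LEVELS = ("normal", "elevated")
CT_FINDINGS = ("normal", "bowel_wall_thickening", "pancolitis", "colon_perforated")
COLONOSCOPY_FINDINGS = (
    "edematous", "erythematous_mucosa", "hemorrhagic", "friable_mucosa",
    "absent_vascular_pattern", "superficial_ulceration", "deep_ulcerations",
    "active_inflammation",
)
HISTOPATHOLOGY_FINDINGS = (
    "cryptitis", "crypt_abscesses", "granulomatous_lesions", "chronic_inflammation",
)
THERAPIES = (
    "none", "corticosteroids", "tnf_antagonist", "ustekinumab", "five_asa",
    "corticosteroids_plus_tnf_antagonist", "corticosteroids_plus_five_asa",
    "corticosteroids_plus_ustekinumab",
)
OUTCOMES = ("recovered", "relapse")

ONSET_BINS = ("<1", "1-3", "3-6", "6-12", "12-24", ">24")
RELIEF_BINS = ("<2w", "2-4w", ">4w")


class VocabularyError(ValueError):
    """A case-table value falls outside its controlled vocabulary."""


@dataclass(frozen=True)
class LiteratureCase:
    """One published case of IL-17-inhibitor-associated IBD.

    ``None`` means not reported; set-valued fields are frozensets of
    controlled terms. ``symptoms`` may be empty only when the patient was
    asymptomatic (then it holds "asymptomatic") or symptoms were unreported
    (then it is None).
    """

    drug: str
    sex: str = "unknown"
    source_kind: str | None = None
    age_years: float | None = None
    region: str | None = None
    preexisting_ibd: bool | None = None
    family_history_ibd: bool | None = None
    indication: str | None = None
    smoking: str = "not_mentioned"
    prior_tnf: str | None = None
    onset_months: float | None = None
    ibd_class: str | None = None
    symptoms: frozenset[str] | None = None
    wbc: str | None = None
    crp: str | None = None
    esr: str | None = None
    fecal_calprotectin: str | None = None
    ct_findings: frozenset[str] | None = None
    colonoscopy_findings: frozenset[str] | None = None
    histopathology_findings: frozenset[str] | None = None
    therapy: str | None = None
    outcome: str | None = None
    relief_weeks: float | None = None

    def __post_init__(self) -> None:
        _check("drug", self.drug, DRUGS)
        _check("sex", self.sex, SEXES)
        _check("source_kind", self.source_kind, SOURCE_KINDS, optional=True)
        _check("region", self.region, REGIONS, optional=True)
        _check("indication", self.indication, INDICATIONS, optional=True)
        _check("smoking", self.smoking, SMOKING)
        _check("prior_tnf", self.prior_tnf, PRIOR_TNF, optional=True)
        _check("ibd_class", self.ibd_class, IBD_CLASSES, optional=True)
        for name, vocab in (("wbc", LAB_LEVELS), ("crp", LAB_LEVELS),
                            ("esr", LAB_LEVELS), ("fecal_calprotectin", LAB_LEVELS),
                            ("therapy", THERAPIES), ("outcome", OUTCOMES)):
            _check(name, getattr(self, name), vocab, optional=True)
        for name, vocab in (("symptoms", SYMPTOMS), ("ct_findings", CT_FINDINGS),
                            ("colonoscopy_findings", COLONOSCOPY_FINDINGS),
                            ("histopathology_findings", HISTOPATHOLOGY_FINDINGS)):
            vals = getattr(self, name)
            if vals is not None:
                for v in vals:
                    _check(name, v, vocab)
        if self.onset_months is not None and self.onset_months <= 0:
            raise ValueError("onset_months must be positive when present")
        if self.relief_weeks is not None and self.relief_weeks <= 0:
            raise ValueError("relief_weeks must be positive when present")
        if self.symptoms is not None and not self.symptoms:
            raise ValueError("symptoms set may not be empty; use None when unreported")


def _check(name: str, value, vocab, optional: bool = False) -> None:
    if value is None:
        if optional:
            return
        raise VocabularyError(f"{name} is required")
    if value not in vocab:
        raise VocabularyError(f"{name}={value!r} not in vocabulary {vocab}")


# ---------------------------------------------------------------------------
# Binning and medians


def bin_onset(onset_months: float) -> str:
    """Half-open onset bins in months: [1,3) -> "1-3", etc.; >=24 -> ">24".

    Published bins share their boundary values; the half-open convention
    [lower, upper) resolves ties deterministically (3.0 -> "3-6",
    24.0 -> ">24").
    """
    if onset_months <= 0:
        raise ValueError("onset_months must be positive")
    edges = ((1, "<1"), (3, "1-3"), (6, "3-6"), (12, "6-12"), (24, "12-24"))
    for upper, label in edges:
        if onset_months < upper:
            return label
    return ">24"


def bin_relief(relief_weeks: float) -> str:
    """Half-open relief bins in weeks: [2,4) -> "2-4w", [4, inf) -> ">4w"."""
    if relief_weeks <= 0:
        raise ValueError("relief_weeks must be positive")
    if relief_weeks < 2:
        return "<2w"
    if relief_weeks < 4:
        return "2-4w"
    return ">4w"


def bin_age(age_years: float) -> str:
    """Age bands of published demographic tables: <=25, 26-50, 51-75, >=76."""
    if age_years <= 25:
        return "<=25"
    if age_years <= 50:
        return "26-50"
    if age_years <= 75:
        return "51-75"
    return ">=76"


def median_onset(cases: list[LiteratureCase]) -> float | None:
    """Median onset in months over cases reporting it; None when none do."""
    values = [c.onset_months for c in cases if c.onset_months is not None]
    return statistics.median(values) if values else None


def median_age(cases: list[LiteratureCase]) -> float | None:
    values = [c.age_years for c in cases if c.age_years is not None]
    return statistics.median(values) if values else None


def median_relief(cases: list[LiteratureCase]) -> float | None:
    values = [c.relief_weeks for c in cases if c.relief_weeks is not None]
    return statistics.median(values) if values else None


# ---------------------------------------------------------------------------
# Summaries


@dataclass(frozen=True)
class SummaryTable:
    """Frequency table for one variable: (category, count, percent, denominator)."""

    variable: str
    rows: tuple[tuple[str, int, float, int], ...] = field(default_factory=tuple)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["category", "count", "percent", "denominator"]
        ).assign(variable=self.variable)[
            ["variable", "category", "count", "percent", "denominator"]
        ]


def _pct(count: int, denom: int) -> float:
    return round_display(100 * count / denom, 1) if denom else 0.0


def _categorical(cases, variable, accessor, categories) -> SummaryTable:
    values = [accessor(c) for c in cases]
    values = [v for v in values if v is not None]
    denom = len(values)
    rows = []
    for cat in categories:
        n = sum(v == cat for v in values)
        rows.append((cat, n, _pct(n, denom), denom))
    return SummaryTable(variable, tuple(rows))


def _set_valued(cases, variable, accessor, categories) -> SummaryTable:
    reported = [accessor(c) for c in cases]
    reported = [v for v in reported if v is not None]
    denom = len(reported)
    rows = []
    for cat in categories:
        n = sum(cat in v for v in reported)
        rows.append((cat, n, _pct(n, denom), denom))
    return SummaryTable(variable, tuple(rows))


def _boolean(cases, variable, accessor, true_label, false_label) -> SummaryTable:
    values = [accessor(c) for c in cases]
    values = [v for v in values if v is not None]
    denom = len(values)
    n_true = sum(values)
    return SummaryTable(variable, (
        (true_label, n_true, _pct(n_true, denom), denom),
        (false_label, denom - n_true, _pct(denom - n_true, denom), denom),
    ))


def summarize_cases(cases: list[LiteratureCase]) -> list[SummaryTable]:
    """All descriptive frequency tables for a case series.

    Mutually exclusive variables count non-missing values against the
    non-missing denominator; set-valued variables count each term against
    the number of cases reporting that variable. Permutation-invariant in
    case order; empty input yields an empty list.
    """
    if not cases:
        return []
    tables = [
        _categorical(cases, "data_resource", lambda c: c.source_kind, SOURCE_KINDS),
        _categorical(cases, "sex", lambda c: c.sex if c.sex != "unknown" else None, SEXES[:2]),
        _categorical(cases, "age_band",
                     lambda c: None if c.age_years is None else bin_age(c.age_years),
                     ("<=25", "26-50", "51-75", ">=76")),
        _categorical(cases, "region", lambda c: c.region, REGIONS[:5]),
        _categorical(cases, "drug", lambda c: c.drug, DRUGS),
        _boolean(cases, "preexisting_ibd", lambda c: c.preexisting_ibd,
                 "pre-existing IBD", "new onset of IBD"),
        _boolean(cases, "family_history_ibd", lambda c: c.family_history_ibd,
                 "family history of IBD", "no family history"),
        _categorical(cases, "indication", lambda c: c.indication, INDICATIONS),
        _categorical(cases, "smoking", lambda c: c.smoking, SMOKING),
        _categorical(cases, "prior_tnf",
                     lambda c: c.prior_tnf if c.prior_tnf in ("adalimumab", "etanercept") else None,
                     ("adalimumab", "etanercept")),
        _categorical(cases, "onset_bin",
                     lambda c: None if c.onset_months is None else bin_onset(c.onset_months),
                     ONSET_BINS),
        _categorical(cases, "ibd_class", lambda c: c.ibd_class, IBD_CLASSES),
        _set_valued(cases, "initial_symptoms", lambda c: c.symptoms, SYMPTOMS),
        _categorical(cases, "wbc", lambda c: c.wbc, LAB_LEVELS),
        _categorical(cases, "crp", lambda c: c.crp, LAB_LEVELS),
        _categorical(cases, "esr", lambda c: c.esr, LAB_LEVELS),
        _categorical(cases, "fecal_calprotectin", lambda c: c.fecal_calprotectin, LAB_LEVELS),
        _set_valued(cases, "ct_findings", lambda c: c.ct_findings, CT_FINDINGS),
        _set_valued(cases, "colonoscopy_findings", lambda c: c.colonoscopy_findings,
                    COLONOSCOPY_FINDINGS),
        _set_valued(cases, "histopathology_findings", lambda c: c.histopathology_findings,
                    HISTOPATHOLOGY_FINDINGS),
        _categorical(cases, "therapy", lambda c: c.therapy, THERAPIES),
        _categorical(cases, "outcome", lambda c: c.outcome, OUTCOMES),
        _categorical(cases, "relief_bin",
                     lambda c: None if c.relief_weeks is None else bin_relief(c.relief_weeks),
                     RELIEF_BINS),
    ]
    return tables


def summary_frame(cases: list[LiteratureCase]) -> pd.DataFrame:
    """All summary tables stacked into one tidy DataFrame."""
    tables = summarize_cases(cases)
    if not tables:
        return pd.DataFrame(
            columns=["variable", "category", "count", "percent", "denominator"]
        )
    return pd.concat([t.to_frame() for t in tables], ignore_index=True)


# ---------------------------------------------------------------------------
# CSV I/O

_SET_FIELDS = ("symptoms", "ct_findings", "colonoscopy_findings", "histopathology_findings")
_FLOAT_FIELDS = ("age_years", "onset_months", "relief_weeks")
_BOOL_FIELDS = ("preexisting_ibd", "family_history_ibd")

CASE_COLUMNS = tuple(f.name for f in fields(LiteratureCase))


def load_case_table(path) -> list[LiteratureCase]:
    """Read a case-series CSV; empty cells mean 'not reported'.

    Set-valued columns are semicolon-joined controlled terms. Vocabulary
    violations raise :class:`VocabularyError` carrying the 1-based data line
    number.
    """
    cases = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(CASE_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise VocabularyError(f"{path}: missing column(s) {sorted(missing)}")
        for lineno, row in enumerate(reader, start=1):
            kwargs = {}
            for name in CASE_COLUMNS:
                raw = (row.get(name) or "").strip()
                if not raw:
                    continue
                if name in _SET_FIELDS:
                    kwargs[name] = frozenset(t.strip() for t in raw.split(";") if t.strip())
                elif name in _FLOAT_FIELDS:
                    kwargs[name] = float(raw)
                elif name in _BOOL_FIELDS:
                    kwargs[name] = raw.lower() in ("true", "yes", "1")
                else:
                    kwargs[name] = raw
            try:
                cases.append(LiteratureCase(**kwargs))
            except (VocabularyError, ValueError) as err:
                raise VocabularyError(f"{path} line {lineno}: {err}") from err
    return cases


def dump_case_table(cases: list[LiteratureCase], path) -> None:
    """Write a case series back to the CSV dialect read by load_case_table."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CASE_COLUMNS)
        for c in cases:
            row = []
            for name in CASE_COLUMNS:
                v = getattr(c, name)
                if v is None:
                    row.append("")
                elif name in _SET_FIELDS:
                    row.append(";".join(sorted(v)))
                elif name in _BOOL_FIELDS:
                    row.append("true" if v else "false")
                else:
                    row.append(str(v))
            writer.writerow(row)
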