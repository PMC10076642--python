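"""Disproportionality analysis: reporting odds ratios over 2x2 tables.

The reporting odds ratio (ROR) compares the odds of a target event among
reports of a target drug against the odds among all other reports:

    ROR = (a*d) / (b*c)

where, in event-level counting,

    a = target-event tallies among reports with the drug as primary suspect
    b = all other event tallies among those reports
    c = target-event tallies among all other reports
    d = all other event tallies among all other reports.

The 95% confidence interval is the Woolf (log-normal) interval
exp(ln ROR +/- 1.96*sqrt(1/a + 1/b + 1/c + 1/d)). A drug-event pair is
flagged as a signal when the CI lower bound exceeds 1 and the pair has at
least three cases. Any zero cell leaves the ROR and CI undefined (reported
as NA); no continuity correction is applied.

Counting convention
-------------------
Counts are event-level: each report contributes one tally per *distinct*
preferred term it carries, so a report with two PTs of the same event group
counts twice in that group's total. This makes a group's "total events of
interest" exactly the sum of its per-PT counts, the convention of published
ROR tables. Case-level counts (one per report) differ and are available via
the report-characteristics summary.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from ._rounding import round_display
from .faers import ConfigError, DrugDictionary, SafetyReport, _norm_pt

Z_95 = 1.96  # fixed two-sided 95% normal quantile; no multiplicity adjustment

#: Event groups of the gastrointestinal-inflammation analysis. "IBD" covers
#: reported diagnoses of Crohn's disease, ulcerative colitis and
#: undifferentiated IBD; "colitis" covers the colitis/proctitis/enteritis
#: preferred terms. PT strings are matched case-insensitively after trimming.
IBD_PTS = (
    "Crohn's disease",
    "Colitis ulcerative",
    "Inflammatory bowel disease",
)
COLITIS_PTS = (
    "Colitis",
    "Microscopic colitis",
    "Ischaemic colitis",
    "Proctitis",
    "Proctitis ulcerative",
    "Proctitis haemorrhagic",
    "Enteritis",
    "Enterocolitis",
    "Enterocolitis haemorrhagic",
    "Eosinophilic colitis",
    "Colitis erosive",
)


@dataclass(frozen=True)
class EventGroup:
    """A named set of MedDRA preferred terms analysed together."""

    name: str
    pts: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.pts:
            raise ConfigError(f"event group {self.name!r} has no preferred terms")

    @property
    def norm_pts(self) -> frozenset[str]:
        return frozenset(_norm_pt(p) for p in self.pts)


DEFAULT_GROUPS = (EventGroup("IBD", IBD_PTS), EventGroup("colitis", COLITIS_PTS))


@dataclass(frozen=True, slots=True)
class ContingencyTable:
    """The 2x2 event-tally table underlying one ROR."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True, slots=True)
class RorResult:
    """Point estimate, Woolf 95% CI, case count and signal flag for one pair.

    ror/ci_low/ci_high are None when any contingency cell is zero (NA in
    output tables). The signal flag is False whenever the CI is undefined.
    """

    ror: float | None
    ci_low: float | None
    ci_high: float | None
    n_cases: int
    signal: bool

    @property
    def defined(self) -> bool:
        return self.ror is not None


def compute_ror(table: ContingencyTable) -> RorResult:
    """Woolf ROR and 95% CI for a 2x2 table; NA if any cell is zero."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if 0 in (a, b, c, d):
        return RorResult(None, None, None, n_cases=a, signal=False)
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci_low = math.exp(math.log(ror) - Z_95 * se)
    ci_high = math.exp(math.log(ror) + Z_95 * se)
    result = RorResult(ror, ci_low, ci_high, n_cases=a, signal=False)
    return RorResult(ror, ci_low, ci_high, n_cases=a, signal=flag_signal(result))


def flag_signal(result: RorResult) -> bool:
    """Signal rule: CI lower bound above 1 with at least three cases."""
    return result.ci_low is not None and result.ci_low > 1 and result.n_cases >= 3


def proportion_of_reports(event_count: int, drug_total: int,
                          mode: str = "half_up") -> float | None:
    """Events of interest as a percentage of a drug's total reports.

    Returns 100*event_count/drug_total rounded to two decimals under the
    given display-rounding mode ("half_up" or "truncate"), or None (NA) when
    the drug has no reports at all.
    """
    if drug_total < 0 or event_count < 0:
        raise ValueError("counts must be non-negative")
    if drug_total == 0:
        return None
    return round_display(100 * event_count / drug_total, 2, mode)


# ---------------------------------------------------------------------------
# Tallies over report collections


def _tallies(reports: list[SafetyReport], actives: tuple[str, ...],
             dictionary: DrugDictionary):
    """One pass over the reports: global and per-active event-level tallies.

    Returns (total_events, global per-PT Counter, per-active per-PT Counter,
    per-active exposed event total, per-active exposed report count).
    """
    total_events = 0
    global_counts: Counter[str] = Counter()
    by_active: dict[str, Counter[str]] = {a: Counter() for a in actives}
    exposed_events: dict[str, int] = {a: 0 for a in actives}
    exposed_reports: dict[str, int] = {a: 0 for a in actives}
    for r in reports:
        pts = r.distinct_pts
        total_events += len(pts)
        global_counts.update(pts)
        exposures = {
            m for d in r.drugs if d.role == "PS"
            if (m := dictionary.match(d.verbatim_name)) in by_active
        }
        for active in exposures:
            by_active[active].update(pts)
            exposed_events[active] += len(pts)
            exposed_reports[active] += 1
    return total_events, global_counts, by_active, exposed_events, exposed_reports


def build_contingency(
    all_reports: list[SafetyReport],
    active: str,
    dictionary: DrugDictionary,
    pts: frozenset[str] | set[str] | tuple[str, ...],
) -> ContingencyTable:
    """Event-level 2x2 table for one drug x PT-set pair.

    ``all_reports`` must already be deduplicated; exposure is the active as
    primary suspect. Each report contributes one tally per distinct PT it
    carries, classified by (exposed, PT in ``pts``); the four cells sum to
    the database's total event tally.
    """
    if not pts:
        raise ConfigError("empty PT set")
    if active not in dictionary.entries:
        raise ConfigError(f"unknown active {active!r}")
    target = frozenset(_norm_pt(p) for p in pts)
    total, _global, by_active, exposed_events, _nrep = _tallies(
        all_reports, (active,), dictionary
    )
    a = sum(by_active[active][p] for p in target)
    b = exposed_events[active] - a
    c = sum(_global[p] for p in target) - a
    d = total - a - b - c
    return ContingencyTable(a, b, c, d)


def run_disproportionality(
    reports: list[SafetyReport],
    dictionary: DrugDictionary,
    groups: tuple[EventGroup, ...] = DEFAULT_GROUPS,
    actives: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Per-PT and per-group ROR table for every drug in the dictionary.

    Returns one row per drug x PT plus a "Total events of interest" row per
    drug x group, with columns drug, group, pt, count, ror, ci_low, ci_high,
    signal. Group totals equal the sum of their per-PT counts by the
    event-level counting convention. ``reports`` must be deduplicated.
    """
    if actives is None:
        actives = dictionary.actives
    names = [g.name for g in groups]
    if len(set(names)) != len(names):
        raise ConfigError("event group names must be unique")
    total, global_counts, by_active, exposed_events, _ = _tallies(
        reports, tuple(actives), dictionary
    )

    rows = []

    def add_row(active: str, group: str, pt_label: str, a: int, global_count: int):
        # global_count is the event set's tally over the whole database
        b = exposed_events[active] - a
        c = global_count - a
        d = total - a - b - c
        res = compute_ror(ContingencyTable(a, b, c, d))
        rows.append({
            "drug": active, "group": group, "pt": pt_label, "count": a,
            "ror": res.ror, "ci_low": res.ci_low, "ci_high": res.ci_high,
            "signal": res.signal,
        })

    for group in groups:
        norm = [(_norm_pt(p), p) for p in group.pts]
        for active in actives:
            for npt, pt in norm:
                a = by_active[active][npt]
                add_row(active, group.name, pt, a, global_counts[npt])
            total_a = sum(by_active[active][npt] for npt, _ in norm)
            total_global = sum(global_counts[npt] for npt, _ in norm)
            add_row(active, group.name, "Total events of interest", total_a, total_global)
    return pd.DataFrame(rows)


def format_result_table(table: pd.DataFrame, mode: str = "half_up") -> pd.DataFrame:
    """Display copy of a result table: 2-decimal rounding, 'NA' literals."""
    out = table.copy()
    for col in ("ror", "ci_low", "ci_high"):
        out[col] = [
            "NA" if v is None or pd.isna(v) else f"{round_display(v, 2, mode):.2f}"
            for v in out[col]
        ]
    return out
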