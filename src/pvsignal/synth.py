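"""Seeded synthetic FAERS-style report generator with planted associations.

The generator emulates the structure of a spontaneous-report database just
far enough to test the analysis pipeline end to end and to run parameter-
recovery studies:

* each report draws one primary-suspect (PS) drug from a multinomial over
  the configured actives (any leftover probability mass goes to a generic
  background substance);
* each event preferred term occurs independently per report with its
  background probability p0, except that reports whose PS drug carries a
  planted association with that PT use p1, where
  odds(p1) = odds_ratio * odds(p0) — odds-scale planting, so the reporting
  odds ratio estimand equals the planted value;
* reports that drew no event at all receive a filler PT, since a report
  without reactions would be dropped at ingestion;
* optional duplicate case versions are injected so deduplication is
  exercised; the in-memory return value is the latest version per case.

Everything is reproducible from the seed, and writing the '$'-delimited
DEMO/DRUG/REAC/OUTC/INDI files is byte-deterministic.

Real FAERS marginal distributions, MedDRA coding noise and secular
reporting trends are deliberately NOT modelled.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .faers import DrugEntry, SafetyReport
from .quarters import Quarter

logger = logging.getLogger(__name__)

BACKGROUND_ACTIVE = "background substance"
FILLER_PT = "Off label use"

_INDICATION_PTS = ("Psoriasis", "Psoriatic arthropathy", "Ankylosing spondylitis")


class SynthConfigError(ValueError):
    """Invalid generator configuration; message lists the offending fields."""


@dataclass(frozen=True)
class DrugSpec:
    """One active in the generator: label, name patterns, marginal probability."""

    active: str
    brands: tuple[str, ...]
    prob: float


@dataclass(frozen=True)
class EventSpec:
    pt: str
    background_prob: float


@dataclass(frozen=True)
class PlantedAssociation:
    active: str
    pt: str
    odds_ratio: float


@dataclass(frozen=True)
class SynthConfig:
    """Full specification of one synthetic report collection."""

    n_reports: int
    drugs: tuple[DrugSpec, ...]
    events: tuple[EventSpec, ...]
    planted: tuple[PlantedAssociation, ...] = ()
    #: distribution of submitted versions per case, e.g. {1: 0.8, 2: 0.2}
    versions_per_case: dict[int, float] = field(default_factory=lambda: {1: 1.0})
    quarters: tuple[str, ...] = ("2020Q1",)
    seed: int = 0
    age_missing_prob: float = 0.3
    sex_unknown_prob: float = 0.1
    country_unknown_prob: float = 0.2
    #: probability a report carries an onset time (not serialized to files)
    onset_prob: float = 0.0
    filler_pt: str = FILLER_PT

    def __post_init__(self) -> None:
        problems = []
        if self.n_reports <= 0:
            problems.append("n_reports must be positive")
        total_p = sum(d.prob for d in self.drugs)
        if not self.drugs:
            problems.append("drugs must be non-empty")
        if any(d.prob <= 0 for d in self.drugs):
            problems.append("drug marginal probabilities must be positive")
        if total_p > 1 + 1e-12:
            problems.append(f"drug marginal probabilities sum to {total_p} > 1")
        if any(not d.brands for d in self.drugs):
            problems.append("every drug needs at least one name pattern")
        for e in self.events:
            if not 0 < e.background_prob < 1:
                problems.append(f"background probability of {e.pt!r} must be in (0,1)")
        actives = {d.active for d in self.drugs}
        pts = {e.pt for e in self.events}
        seen = set()
        for p in self.planted:
            if p.odds_ratio <= 0:
                problems.append(f"odds ratio for ({p.active}, {p.pt}) must be positive")
            if p.active not in actives:
                problems.append(f"planted active {p.active!r} not in drug list")
            if p.pt not in pts:
                problems.append(f"planted PT {p.pt!r} not in event list")
            if (p.active, p.pt) in seen:
                problems.append(f"({p.active}, {p.pt}) planted more than once")
            seen.add((p.active, p.pt))
        if not self.versions_per_case:
            problems.append("versions_per_case must be non-empty")
        else:
            if any(k < 1 for k in self.versions_per_case):
                problems.append("version counts must be >= 1")
            if abs(sum(self.versions_per_case.values()) - 1) > 1e-9:
                problems.append("versions_per_case probabilities must sum to 1")
        for q in self.quarters:
            try:
                Quarter.parse(q)
            except ValueError as err:
                problems.append(str(err))
        if self.filler_pt in pts:
            problems.append("filler PT collides with an analysis event PT")
        if problems:
            raise SynthConfigError("invalid SynthConfig: " + "; ".join(problems))


def planted_event_prob(background_prob: float, odds_ratio: float) -> float:
    """p1 with odds(p1) = odds_ratio * odds(background_prob)."""
    odds = odds_ratio * background_prob / (1 - background_prob)
    return odds / (1 + odds)


def expected_contingency(config: SynthConfig, active: str, pt: str
                         ) -> tuple[float, float, float, float]:
    """Closed-form expected (a, b, c, d) under the generator model.

    Uses event-level counting including the filler-PT mechanism: a report's
    expected event tally is sum_j p_j plus the probability that no event
    fired (the filler). Serves as the analytic oracle for empirical counts.
    """
    actives = [d.active for d in config.drugs]
    if active not in actives:
        raise SynthConfigError(f"unknown active {active!r}")
    if pt not in {e.pt for e in config.events}:
        raise SynthConfigError(f"unknown event PT {pt!r}")
    planted = {(p.active, p.pt): p.odds_ratio for p in config.planted}

    def p_event(drug: str, event: EventSpec) -> float:
        theta = planted.get((drug, event.pt))
        return planted_event_prob(event.background_prob, theta) if theta else event.background_prob

    margins = {d.active: d.prob for d in config.drugs}
    leftover = 1 - sum(margins.values())
    if leftover > 1e-12:
        margins[BACKGROUND_ACTIVE] = leftover

    n = config.n_reports
    ea = eb = ec = ed = 0.0
    for drug, q in margins.items():
        probs = [p_event(drug, e) for e in config.events]
        p_none = float(np.prod([1 - p for p in probs]))
        mean_events = sum(probs) + p_none  # filler fires when nothing else did
        p_target = p_event(drug, EventSpec(pt, _background_of(config, pt)))
        if drug == active:
            ea += n * q * p_target
            eb += n * q * (mean_events - p_target)
        else:
            ec += n * q * p_target
            ed += n * q * (mean_events - p_target)
    return ea, eb, ec, ed


def _background_of(config: SynthConfig, pt: str) -> float:
    for e in config.events:
        if e.pt == pt:
            return e.background_prob
    raise SynthConfigError(f"unknown event PT {pt!r}")


# ---------------------------------------------------------------------------
# Generation


def generate_reports(config: SynthConfig, out_dir=None) -> list[SafetyReport]:
    """Draw a report collection; optionally write its FAERS-style files.

    Returns the deduplicated in-memory collection (latest version per case,
    exactly ``n_reports`` reports). When ``out_dir`` is given, every injected
    case version is written to '$'-delimited DEMO/DRUG/REAC/OUTC/INDI files,
    one set per quarter, so that ingest + deduplicate recovers the returned
    collection exactly.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_reports

    margins = [d.prob for d in config.drugs]
    leftover = 1 - sum(margins)
    drug_names = [d.active for d in config.drugs]
    brands = [d.brands for d in config.drugs]
    if leftover > 1e-12:
        drug_names.append(BACKGROUND_ACTIVE)
        brands.append((BACKGROUND_ACTIVE,))
        margins.append(leftover)
    margins = np.asarray(margins) / np.sum(margins)
    drug_idx = rng.choice(len(drug_names), size=n, p=margins)

    planted = {(p.active, p.pt): p.odds_ratio for p in config.planted}
    event_hits = np.zeros((n, len(config.events)), dtype=bool)
    for j, ev in enumerate(config.events):
        p_by_drug = np.array([
            planted_event_prob(ev.background_prob, planted[(d, ev.pt)])
            if (d, ev.pt) in planted else ev.background_prob
            for d in drug_names
        ])
        event_hits[:, j] = rng.random(n) < p_by_drug[drug_idx]

    brand_pick = rng.random(n)
    dose_pick = rng.random(n)
    age_raw = np.clip(rng.normal(48, 16, size=n), 18, 90).round(0)
    age_missing = rng.random(n) < config.age_missing_prob
    sex_draw = rng.random(n)
    country_draw = rng.random(n)
    quarter_idx = rng.integers(0, len(config.quarters), size=n)
    outc_ho = rng.random(n) < 0.08
    outc_ot = rng.random(n) < 0.25
    indi_draw = rng.integers(0, len(_INDICATION_PTS) + 1, size=n)
    onset_mask = rng.random(n) < config.onset_prob
    onset_vals = np.round(rng.lognormal(mean=1.0, sigma=1.0, size=n), 2)
    version_counts = list(config.versions_per_case)
    version_probs = np.array([config.versions_per_case[k] for k in version_counts], float)
    n_versions = rng.choice(version_counts, size=n, p=version_probs / version_probs.sum())

    reports: list[SafetyReport] = []
    all_versions: list[SafetyReport] = []
    for i in range(n):
        di = drug_idx[i]
        names = brands[di]
        name = names[int(brand_pick[i] * len(names)) % len(names)].upper()
        if dose_pick[i] < 0.3:
            name = f"{name} 150MG"
        indication = (
            _INDICATION_PTS[indi_draw[i] - 1] if indi_draw[i] > 0 else None
        )
        drugs = [DrugEntry(name, "PS", indication)]
        if i % 3 == 0:  # concomitant noise drug, never an exposure
            drugs.append(DrugEntry("IBUPROFEN", "C", None))
        pts = tuple(ev.pt for j, ev in enumerate(config.events) if event_hits[i, j])
        if not pts:
            pts = (config.filler_pt,)
        outcomes = set()
        if outc_ho[i]:
            outcomes.add("HO")
        if outc_ot[i]:
            outcomes.add("OT")
        case_id = f"C{config.seed % 100000:05d}{i:07d}"
        k = int(n_versions[i])
        quarter = config.quarters[quarter_idx[i]]
        base = dict(
            case_id=case_id,
            quarter=quarter,
            drugs=tuple(drugs),
            reaction_pts=pts,
            outcome_codes=frozenset(outcomes),
            age_years=None if age_missing[i] else float(age_raw[i]),
            sex=("female" if sex_draw[i] < 0.45
                 else "male" if sex_draw[i] < 0.9 else "unknown"),
            country=(None if country_draw[i] < config.country_unknown_prob
                     else "US" if country_draw[i] < 0.6 else "FR"),
            onset_months=float(onset_vals[i]) if onset_mask[i] else None,
        )
        for version in range(1, k + 1):
            rec = SafetyReport(case_version=version,
                               record_id=f"{case_id}V{version}", **base)
            all_versions.append(rec)
            if version == k:
                reports.append(rec)

    logger.info("generated %d cases (%d records incl. versions), seed=%d",
                len(reports), len(all_versions), config.seed)
    if out_dir is not None:
        write_faers_files(all_versions, out_dir)
    return reports


def write_faers_files(records: list[SafetyReport], out_dir, delimiter: str = "$") -> list[Path]:
    """Write records as '$'-delimited quarter file sets (DEMO<q>.txt, ...).

    onset_months has no column in the FAERS dialect and is not serialized.
    Output is byte-deterministic given the record list.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sex_code = {"female": "F", "male": "M", "unknown": ""}
    by_quarter: dict[str, list[SafetyReport]] = {}
    for r in records:
        by_quarter.setdefault(r.quarter, []).append(r)

    paths = []
    for quarter in sorted(by_quarter):
        recs = by_quarter[quarter]
        files = {}
        for kind, header in (
            ("DEMO", ["primaryid", "caseid", "caseversion", "age", "sex", "occr_country"]),
            ("DRUG", ["primaryid", "drug_seq", "role_cod", "drugname"]),
            ("REAC", ["primaryid", "pt"]),
            ("OUTC", ["primaryid", "outc_cod"]),
            ("INDI", ["primaryid", "indi_drug_seq", "indi_pt"]),
        ):
            path = out_dir / f"{kind}{quarter}.txt"
            fh = open(path, "w", newline="")
            writer = csv.writer(fh, delimiter=delimiter)
            writer.writerow(header)
            files[kind] = (fh, writer)
            paths.append(path)
        for r in recs:
            pid = r.record_id
            age = "" if r.age_years is None else f"{r.age_years:g}"
            files["DEMO"][1].writerow(
                [pid, r.case_id, r.case_version, age, sex_code[r.sex], r.country or ""]
            )
            for seq, d in enumerate(r.drugs, start=1):
                files["DRUG"][1].writerow([pid, seq, d.role, d.verbatim_name])
                if d.indication_pt:
                    files["INDI"][1].writerow([pid, seq, d.indication_pt])
            for pt in r.reaction_pts:
                files["REAC"][1].writerow([pid, pt])
            for code in sorted(r.outcome_codes):
                files["OUTC"][1].writerow([pid, code])
        for fh, _ in files.values():
            fh.close()
    return paths


# ---------------------------------------------------------------------------
# Ready-made study configuration


def study_config(
    n_reports: int = 50_000,
    planted: tuple[PlantedAssociation, ...] = (),
    seed: int = 0,
    exposed_marginal: float = 0.2,
    background_event_prob: float = 0.01,
    versions_per_case: dict[int, float] | None = None,
) -> SynthConfig:
    """Recovery-study configuration: one exposed drug at marginal 0.2.

    The target active carries the brand/generic names of secukinumab so the
    stock drug dictionary applies; the event list holds one analysis PT
    (background probability ``background_event_prob``) plus two inert
    background PTs.
    """
    return SynthConfig(
        n_reports=n_reports,
        drugs=(
            DrugSpec("secukinumab", ("secukinumab", "cosentyx"), exposed_marginal),
            DrugSpec("ixekizumab", ("ixekizumab", "taltz"), 0.15),
            DrugSpec("adalimumab", ("adalimumab", "humira"), 0.35),
        ),
        events=(
            EventSpec("Inflammatory bowel disease", background_event_prob),
            EventSpec("Headache", 0.02),
            EventSpec("Nausea", 0.015),
        ),
        planted=planted,
        versions_per_case=versions_per_case or {1: 1.0},
        seed=seed,
    )
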