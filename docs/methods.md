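# Methods

`pvsignal` implements a disproportionality analysis of spontaneous
adverse-event reports in the style used for the IL-17 inhibitor /
inflammatory-bowel-disease safety question, together with a descriptive
summarizer for published case series and a synthetic-data generator that
lets every step be validated against a known truth. This note records the
statistical model, the conventions the package fixes where the field leaves
room, and what the synthetic studies do and do not demonstrate.

## Disproportionality model

Spontaneous-report databases have no denominator of drug users, so risk
cannot be estimated; what can be estimated is whether a target event is
reported *disproportionately* often for a target drug. For each drug ×
event-set pair the package forms the 2×2 table

|                    | target event | other events |
|--------------------|--------------|--------------|
| drug (PS)          | a            | b            |
| all other reports  | c            | d            |

and computes the reporting odds ratio ROR = (a·d)/(b·c) with the Woolf
(log-normal) 95% interval exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d)).
A pair is flagged as a signal when the CI lower bound exceeds 1 **and**
a ≥ 3 cases. The z-value is fixed at 1.96 (two-sided 95%); no
multiple-testing adjustment is applied. These choices mirror routine
pharmacovigilance practice; PRR, IC/BCPNN and EBGM estimators are out of
scope (the module surface leaves room for them, but none is implemented).

Conventions the package fixes:

* **Exposure** is the primary-suspect (PS) role only. Secondary-suspect,
  concomitant and interacting drugs never define exposure.
* **Comparator** is the full remaining database, including reports of the
  other drugs in the dictionary. This is the conventional choice; its known
  cost is masking — a strong signal for one drug inflates the comparator
  event count of the others and can push their RORs below 1 (visible in
  `examples/synthetic_pipeline.py`).
* **Counting is event-level**: each report contributes one tally per
  *distinct* preferred term (PT) it carries. A report carrying two PTs of
  the same event group therefore counts twice in the group total — this is
  what makes a group's "total events of interest" exactly the sum of its
  per-PT counts, the convention of published ROR tables. Case-level counts
  (one per report) are produced separately by the characteristics table;
  the two tallies are different quantities and are never forced to agree.
* **Zero cells**: any zero cell leaves ROR and CI undefined (reported as
  the literal `NA`). No Haldane–Anscombe 0.5 correction is applied, so NA
  rows stay NA rather than acquiring a corrected estimate.
* **PT matching** is case-insensitive exact string equality after trimming;
  "Colitis ulcerative" never matches "Colitis". No MedDRA hierarchy is
  consulted.
* **Display rounding** is half-up to 2 decimals for RORs/CIs and 1 decimal
  for percentages; internal arithmetic is full precision. Reporting
  proportions support a second mode, truncation toward zero, because
  published safety tables are not consistent about which they used: of the
  five headline proportions in this analysis, four reproduce under half-up
  and one (611/44,688 → 1.36%) only under truncation. The mode is an
  explicit argument everywhere.

## Event groups and drug dictionary

The stock configuration analyses two disjoint MedDRA PT groups: **IBD**
(Crohn's disease, Colitis ulcerative, Inflammatory bowel disease) and
**colitis** (Colitis, Microscopic colitis, Ischaemic colitis, Proctitis,
Proctitis ulcerative, Proctitis haemorrhagic, Enteritis, Enterocolitis,
Enterocolitis haemorrhagic, Eosinophilic colitis, Colitis erosive). The
colitis group has the 11 tabulated PTs; accompanying prose sometimes claims
12, but no twelfth term is ever named, so 11 is what ships. Both groups are
ordinary `EventGroup` values and fully configurable.

Drug matching uses a case-insensitive substring test of brand/generic
patterns against the trimmed verbatim name ("COSENTYX 150MG" matches
`cosentyx`), because spontaneous-report drug strings carry doses, salts and
formulations. The stock dictionary maps secukinumab ↔ {secukinumab,
cosentyx}, ixekizumab ↔ {ixekizumab, taltz}, brodalumab ↔ {brodalumab,
siliq}; regional brand names are added via configuration, not code. A name
matching patterns of two actives is a hard error, since it means the
dictionary violates its uniqueness invariant.

## Ingestion and deduplication

Quarterly file sets are '$'-delimited ASCII tables (DEMO/DRUG/REAC/OUTC/
INDI) joined on the report identifier. Reports without any reaction PT are
dropped (logged); orphan satellite rows warn but never abort; unparseable
age/sex/country degrade to unknown rather than dropping the report, because
unknown strata are large and informative in this kind of data. The analysis
window (2015Q1–2022Q3 by default) is applied at file granularity — the
quarter of the file of origin, not any in-record date, which is the only
date the five ingested tables reliably carry.

Databases of this kind ship every resubmitted version of a case. The
deduplication rule keeps, per case id, the maximal (case_version, quarter,
record id) triple — latest version, tie-broken by latest publication
quarter, then lexicographically largest raw record id. The rule is
deterministic, idempotent, and logged.

The characteristics table has an onset-time section; onset is not derivable
from the five ingested tables (it needs therapy start and event dates), so
`SafetyReport.onset_months` exists as an optional field that ingestion
always leaves unset and the generator may populate. On real extracts the
onset rows are therefore all Unknown, which is the honest rendering.

## Case-series summarizer

Each variable is summarized over its *reporting denominator*: cases missing
a field are excluded from that variable only (the "n =" convention of
published tables). Set-valued variables (symptoms, imaging, endoscopy,
histopathology findings) count each term against the number of cases
reporting the variable, so their percentages need not sum to 100.

Bin boundaries are half-open `[lower, upper)` everywhere: onset bins
`<1, [1,3), [3,6), [6,12), [12,24), ≥24` months and relief bins
`<2, [2,4), ≥4` weeks. Published bins share boundary values ("1–3" and
"3–6" both contain 3), so some convention must be imposed; half-open
intervals resolve every tie deterministically (3.0 months → "3–6"; 4 weeks
→ ">4w"). One consequence: in a 15-value relief sample with bin counts
3/7/5, the median (8th value) necessarily lies in [2,4), i.e. strictly
below 4 weeks — a published median of exactly 4 weeks cannot coexist with
those bin counts under this convention. The bundled series has median
relief 3.3 weeks.

**Bundled reference series.** The 34 individual published cases behind the
descriptive analysis were never tabulated row by row; only marginal
frequency tables are public. `reference_case_series()` deterministically
reconstructs a *synthetic* series whose every marginal count matches the
published tables exactly (including median age 42, age range 19–76, median
onset 2.9 months, onset range 0.47–48 months). Joint combinations within a
case are arbitrary wherever the marginals leave them free, so the series
validates the summarization pipeline — it is not patient data and supports
no inference about co-occurrence. Where a published percentage disagrees
with its own count/denominator pair (e.g. chronic inflammation printed as
39.3% though 11/25 = 44.0%), the summarizer reports the recomputed value;
counts always match.

## Synthetic-data generator

The generator emulates exactly the features the pipeline consumes:

* one PS drug per report, multinomial over the configured actives
  (remaining probability mass goes to a generic background substance);
* independent Bernoulli event occurrence per PT per report at background
  probability p₀, switched to p₁ for planted (drug, PT) pairs with
  **odds-scale planting**: odds(p₁) = θ·odds(p₀). With the filler
  mechanism below, this makes the ROR estimand equal the planted θ up to a
  negligible correction (≈0.03% at the default study settings, checked
  analytically with `expected_contingency`);
* a filler PT for reports that drew no event, since reports without
  reactions are dropped at ingestion;
* duplicate case-version injection to exercise deduplication;
* plausible demographics with configurable missingness.

Same seed ⇒ byte-identical output files; written files re-read through
ingestion equal the in-memory collection field for field (asserted in
tests and in every recovery run's first replicate). Deliberately **not**
modelled: real marginal reporting frequencies, within-report event
correlation (comorbidity), MedDRA coding noise, and secular trends across
quarters. Consequently a passing recovery study shows the estimator and
plumbing are correct and calibrated under independence — it says nothing
about confounding, masking magnitude, or coding error in real FAERS data.

`expected_contingency` gives closed-form expected cells under this model
(the per-report expected tally is Σⱼpⱼ plus the probability that no event
fired), used as the analytic oracle for empirical counts within binomial
tolerance.

## Study sizes and numerical choices

The recovery studies run 100 replicates of 50,000 reports (exposure
marginal 0.2, background event probability 0.01) per planted effect size —
about 200 events in the exposed cell per replicate, giving a Monte-Carlo SE
of the mean log-ROR near 0.009, small enough to detect a 3% bias at 3 SE.
The type-I study uses 150 replicates of 4,000 reports under θ = 1 for all
pairs and checks the signal-flag rate stays at or below the one-sided 2.5%
the CI rule implies (plus Monte-Carlo slack); discreteness at small counts
makes the rule conservative, which the bound tolerates. Reduced-scale
variants (60 replicates × 20,000 reports at θ ∈ {1, 1.5}) back the
unbiasedness property in the routine suite. Replicate seeds are fixed
offsets from a single base seed, so every study is reproducible from one
integer.

## Known limitations

* Event-level counting double-counts reports carrying several PTs of one
  group; this matches published group totals but means group "events"
  exceed group "cases". Both tallies are available; they are not
  reconcilable into one number and the package does not pretend otherwise.
* The full-database comparator is subject to masking (see above).
* The signal rule is a screening heuristic, not a causal claim; no
  adjustment for confounding by indication is attempted or possible with
  these data.
* The case-series module performs no inferential statistics, matching the
  descriptive character of its sources.
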