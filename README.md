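# pvsignal

Reporting-odds-ratio signal detection for FAERS-style spontaneous
adverse-event reports, built around the safety question of whether IL-17
inhibitors (secukinumab, ixekizumab, brodalumab) are disproportionately
associated with new-onset or flaring inflammatory bowel disease (IBD) and
colitis.

It is a library for pharmacoepidemiologists and drug-safety analysts who
want the whole chain — quarterly-file ingestion, case deduplication,
brand/generic drug matching, MedDRA preferred-term event grouping, 2×2
contingency construction, ROR estimation and signal flagging, plus a
descriptive summarizer for published case series — as composable,
individually testable functions, with a seeded synthetic-report generator
so every step can be validated against planted ground truth.

## The statistic

For a drug × event-set pair, with event-level tallies

```
a = target events among reports with the drug as primary suspect (PS)
b = other events among those reports
c = target events among all other reports
d = other events among all other reports
```

the reporting odds ratio and its Woolf 95% confidence interval are

```
ROR = (a·d)/(b·c),   CI = exp( ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d) )
```

A pair is a **signal** when the CI lower bound exceeds 1 and a ≥ 3. Any
zero cell renders ROR and CI undefined (`NA`); no continuity correction is
applied. Counting is event-level (one tally per distinct PT per report), so
a group's "total events of interest" is exactly the sum of its per-PT
counts. See `docs/methods.md` for every convention and its rationale.

## Worked example

```python
from pvsignal import (
    IL17_DICTIONARY, PlantedAssociation, deduplicate, generate_reports,
    read_quarter_dir, run_disproportionality, study_config,
)

cfg = study_config(
    n_reports=20_000,
    planted=(PlantedAssociation("secukinumab", "Inflammatory bowel disease", 6.0),),
    seed=42,
    versions_per_case={1: 0.8, 2: 0.2},
)
generate_reports(cfg, out_dir="scratch/demo")          # writes DEMO2020Q1.txt, ...
reports = deduplicate(read_quarter_dir("scratch/demo"))
table = run_disproportionality(reports, IL17_DICTIONARY)
print(table[table.pt == "Total events of interest"].head(2))
```

prints (seed 42)

```
          drug group                        pt  count       ror    ci_low   ci_high  signal
3  secukinumab   IBD  Total events of interest    256  6.907999  5.643225  8.456236    True
7   ixekizumab   IBD  Total events of interest     27  0.384891  0.260040  0.569686   False
```

The 23,967 written records collapse to 20,000 unique cases after
deduplication; the planted secukinumab/IBD association is the only flagged
pair, recovered near the planted odds ratio of 6. The ixekizumab ROR falls
below 1 because the planted excess sits in its comparator — the masking
effect of a full-database reference.

The `examples/` directory holds one short script per capability
(`ror_from_counts.py`, `synthetic_pipeline.py`, `case_series_summary.py`,
`parameter_recovery.py`); each prints its numbers with a line on what they
mean. A thin CLI mirrors the same flows:

```bash
pvsignal dispro   --in faers_files/ --out results/
pvsignal describe --cases src/pvsignal/data/literature_cases_synthetic.csv --out results/
pvsignal simulate --out results/ --seed 1 --replicates 10 --odds-ratio 2.13
```

## Bundled data

`src/pvsignal/data/literature_cases_synthetic.csv` is a deterministic
**synthetic** reconstruction of the 34 published IL-17-inhibitor IBD cases:
individual rows were never published, so the series is built to match every
published marginal count exactly (median age 42 y, median onset 2.9 months)
and serves as a summarizer fixture, not as patient data.
`pvsignal.datasets` also carries the published per-PT event tallies and
report totals used as inputs to the proportion and group-total
computations.

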