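"""End-to-end pipeline on synthetic FAERS-style files.

Generate a seeded synthetic report collection with one planted drug-event
association (odds ratio 6), write it out in the '$'-delimited quarterly
file dialect, ingest and deduplicate the files, and run the full
disproportionality analysis. Only the planted pair should be flagged.
"""

import tempfile
from pathlib import Path

from pvsignal import (
    IL17_DICTIONARY,
    PlantedAssociation,
    deduplicate,
    format_result_table,
    generate_reports,
    read_quarter_dir,
    run_disproportionality,
    study_config,
)

cfg = study_config(
    n_reports=20_000,
    planted=(PlantedAssociation("secukinumab", "Inflammatory bowel disease", 6.0),),
    seed=42,
    versions_per_case={1: 0.8, 2: 0.2},  # a fifth of cases are resubmitted
)

with tempfile.TemporaryDirectory() as tmp:
    generate_reports(cfg, out_dir=tmp)
    raw = read_quarter_dir(Path(tmp))
    reports = deduplicate(raw)
    print(f"ingested {len(raw)} records -> {len(reports)} unique cases\n")
    table = run_disproportionality(reports, IL17_DICTIONARY)

totals = table[table.pt == "Total events of interest"]
print(format_result_table(totals).to_string(index=False))
print()
print("The planted secukinumab/IBD association is recovered with an ROR near")
print("the planted odds ratio of 6 and is the only flagged drug-group pair.")
print("The unplanted ixekizumab ROR falls below 1: the planted excess events")
print("sit in its comparator, the classic masking effect of a full-database")
print("reference in disproportionality analysis.")
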