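"""Descriptive summary of a literature case series.

Load the bundled synthetic 34-case series (constructed to reproduce the
published marginal counts of IL-17-inhibitor-associated IBD case reports),
and print the headline frequency tables and medians.
"""

from pvsignal import (
    load_case_table,
    median_age,
    median_onset,
    reference_case_csv_path,
    summarize_cases,
)

cases = load_case_table(reference_case_csv_path())
print(f"{len(cases)} published cases (synthetic reconstruction)")
print(f"median age:   {median_age(cases):g} years")
print(f"median onset: {median_onset(cases):g} months after starting the drug\n")

wanted = {"drug", "ibd_class", "initial_symptoms", "therapy", "outcome"}
for tbl in summarize_cases(cases):
    if tbl.variable not in wanted:
        continue
    denom = tbl.rows[0][3]
    print(f"{tbl.variable} (n = {denom})")
    for cat, count, pct, _ in tbl.rows:
        if count:
            print(f"  {cat:<40s} {count:>3d} ({pct}%)")
    print()

print("Percentages use each variable's reporting denominator (its 'n ='), so")
print("set-valued variables such as symptoms need not sum to 100%.")
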