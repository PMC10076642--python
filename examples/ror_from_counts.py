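"""Reporting odds ratio from a 2x2 table of event tallies.

Build the contingency table for one drug-event pair by hand, compute the
ROR with its Woolf 95% CI, and apply the signal rule (CI lower bound > 1
and at least three cases).
"""

from pvsignal import ContingencyTable, compute_ror

# a: target drug & target event, b: target drug & other events,
# c: other drugs & target event, d: other drugs & other events
table = ContingencyTable(a=20, b=80, c=10, d=90)
res = compute_ror(table)

print(f"ROR  = {res.ror:.2f}  (95% CI {res.ci_low:.2f}-{res.ci_high:.2f})")
print(f"n    = {res.n_cases} cases")
print(f"signal: {res.signal}")
print()
print("The event is reported about 2.25x more often, relative to all other")
print("events, for the target drug than for the rest of the database; the CI")
print("lower bound sits just below 1, so the pair is not flagged as a signal.")
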