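"""Quantify inclusion of a single cassette exon from junction reads.

PSI compares the mean corrected read count over the two inclusion junctions
(C1A, AC2) against the exclusion junction (C1C2); coverage gating uses the
raw counts.
"""

import stemsplice as ss
from stemsplice.quantify import STANDARD, assess_coverage, compute_inclusion

event = ss.ASEvent(
    event_id="exon_demo",
    event_type=ss.EventType.EX_SINGLE,
    gene_id="add3",
    scaffold="scaffold_1",
    strand="+",
    alt_spans=((5000, 5080),),
    alt_length=81,
    inclusion_junctions=("C1A", "AC2"),
    exclusion_junctions=("C1C2",),
)

for label, counts in [
    ("mostly included", {"C1A": 30, "AC2": 20, "C1C2": 5}),
    ("balanced", {"C1A": 30, "AC2": 20, "C1C2": 25}),
    ("shallow", {"C1A": 3, "AC2": 2, "C1C2": 2}),
]:
    psi = compute_inclusion(event, counts)
    covered = assess_coverage(event, counts, STANDARD)
    print(f"{label:16s} counts={counts}  PSI={psi:5.1f}  covered={covered}")

print(
    "\nPSI is the percent of transcripts including the exon; 'covered' says "
    "whether raw reads meet the (10, 10/5) minima so the value enters "
    "downstream statistics."
)
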