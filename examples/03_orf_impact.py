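"""Predict how splicing events affect the protein product.

The constructed transcripts cover frame-preserving exons, NMD-positioned
premature stops (further than 50 nt upstream of the last exon-exon
junction), junction-proximal stops that merely shorten the C-terminus, and
frame-shifting lengths.
"""

from stemsplice.orf import classify_impact
from stemsplice.simulate import simulate_transcripts

for case_id in ["f0_none_small_+", "f0_nmd_small_+", "f0_near_big_+",
                "f0_near_small_+", "f1_none_small_+", "ir_nmd"]:
    case = next(c for c in simulate_transcripts() if c.case_id == case_id)
    call = classify_impact(case.event, case.transcript, case.genome)
    print(
        f"{case_id:18s} region={call.region.value:5s} impact={call.impact.value:22s} "
        f"NMD={call.nmd}  truncation={call.truncation_aa} aa"
    )

print(
    "\nA frame-preserving exon without stops yields alternative protein "
    "isoforms; an in-frame stop >50 nt upstream of the final junction "
    "triggers NMD; a late stop only disrupts the ORF when it removes more "
    "than 100 amino acids."
)
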