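"""Positional RNA map: where is an RBP's motif enriched around regulated
exons?

GCUUGC (the MBNL-family consensus) is planted at 3x the background rate in
the first 20-nt bin of the downstream intron of 150 "signal" events; 500
background events carry the baseline rate everywhere.  The map tests each
bin with a one-sided Fisher exact test on high-affinity 7-mer windows,
Bonferroni-corrected over the tested bins.
"""

import itertools

import numpy as np

import stemsplice as ss
from stemsplice.motifs import bin_enrichment, extract_bins, select_high_affinity

cfg = ss.SimulationConfig(seed=21)
signal_ids = [f"sig{i}" for i in range(150)]
background_ids = [f"bg{i}" for i in range(500)]
signal, _ = ss.simulate_sequences(signal_ids, signal_ids, cfg, stream=1)
background, _ = ss.simulate_sequences(background_ids, [], cfg, stream=2)

# synthetic affinity table: GCUUGC-containing 7-mers score highest
rng = np.random.default_rng(0)
zscores = {
    "".join(k): (8.0 if "GCUUGC" in "".join(k) else float(rng.normal()))
    for k in itertools.product("ACGU", repeat=7)
}
high_affinity = select_high_affinity(zscores)  # top 10% -> 1639 7-mers

table = bin_enrichment(
    [extract_bins(s) for s in signal.values()],
    [extract_bins(s) for s in background.values()],
    high_affinity,
)
print(table[["signal_hits", "background_hits", "p_raw", "p_bonferroni",
             "significant"]].to_string())
print(
    f"\nminimum-p bin: {table['p_raw'].idxmin()} "
    "(BIN_D1 = first 20 nt of the downstream intron, where the motif was "
    "planted; all other bins stay at the baseline rate)."
)
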