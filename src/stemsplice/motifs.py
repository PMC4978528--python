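"""Positional RNA maps: binned 7-mer counting around alternative exons and
per-bin enrichment of high-affinity RBP motifs.

The first and last 80 nt of each flanking intron are split into 20-nt bins
(labels ``BIN_U1..U8`` upstream, ``BIN_D1..D8`` downstream, 5'->3' on the
transcribed strand); the whole exon is one bin (``EXON``).  Introns shorter
than 160 nt contribute no bins on their side.  For a given RNA-binding
protein the top 10% of 7-mers by affinity Z-score are the "high-affinity"
set; each bin is tested by a one-sided Fisher exact test on high-affinity
versus other 7-mer windows in signal versus background event sets, computed
only when the signal rate exceeds the background rate, with Bonferroni
correction over the bins actually tested.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import _revcomp

__all__ = [
    "EventSequences",
    "BIN_LABELS",
    "orient_event_sequences",
    "extract_bins",
    "count_kmers",
    "select_high_affinity",
    "bin_enrichment",
    "scan_rbp_library",
]

BIN_SIZE = 20
FLANK = 80
MIN_INTRON = 160

BIN_LABELS: tuple[str, ...] = (
    *(f"BIN_U{i}" for i in range(1, 9)),
    "EXON",
    *(f"BIN_D{i}" for i in range(1, 9)),
)


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class EventSequences:
    """Sequences around one alternative exon, on the transcribed strand."""

    upstream_intron: str
    exon: str
    downstream_intron: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "upstream_intron", _to_rna(self.upstream_intron))
        object.__setattr__(self, "exon", _to_rna(self.exon))
        object.__setattr__(self, "downstream_intron", _to_rna(self.downstream_intron))


def orient_event_sequences(
    upstream_plus: str, exon_plus: str, downstream_plus: str, strand: str
) -> EventSequences:
    """Build transcribed-strand sequences from plus-strand genomic segments.

    For a minus-strand event the genomically-left intron is the downstream
    intron of the transcript, so segments are reverse-complemented and the
    flanks swapped.
    """
    if strand == "+":
        return EventSequences(upstream_plus, exon_plus, downstream_plus)
    if strand == "-":
        return EventSequences(
            _revcomp(downstream_plus), _revcomp(exon_plus), _revcomp(upstream_plus)
        )
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")


def extract_bins(seqs: EventSequences) -> dict[str, str]:
    """Split the flanks into labelled 20-nt bins plus the single exon bin.

    Returns only the bins present: short introns (<160 nt) contribute none
    on their side.
    """
    bins: dict[str, str] = {}
    up, down = seqs.upstream_intron, seqs.downstream_intron
    if len(up) >= MIN_INTRON:
        for i in range(4):
            bins[f"BIN_U{i + 1}"] = up[i * BIN_SIZE : (i + 1) * BIN_SIZE]
        tail = up[-FLANK:]
        for i in range(4):
            bins[f"BIN_U{i + 5}"] = tail[i * BIN_SIZE : (i + 1) * BIN_SIZE]
    bins["EXON"] = seqs.exon
    if len(down) >= MIN_INTRON:
        for i in range(4):
            bins[f"BIN_D{i + 1}"] = down[i * BIN_SIZE : (i + 1) * BIN_SIZE]
        tail = down[-FLANK:]
        for i in range(4):
            bins[f"BIN_D{i + 5}"] = tail[i * BIN_SIZE : (i + 1) * BIN_SIZE]
    return bins


def count_kmers(
    profiles: Iterable[Mapping[str, str]], k: int = 7
) -> dict[str, Counter]:
    """Total occurrences of every k-mer per bin label, summed over events.

    All overlapping windows are counted; windows containing N are skipped.
    """
    totals: dict[str, Counter] = {}
    for bins in profiles:
        for label, seq in bins.items():
            counter = totals.setdefault(label, Counter())
            for i in range(len(seq) - k + 1):
                window = seq[i : i + k]
                if "N" not in window:
                    counter[window] += 1
    return totals


def select_high_affinity(
    zscores: Mapping[str, float], fraction: float = 0.10
) -> frozenset[str]:
    """The ceil(fraction * N) 7-mers with the highest affinity Z-score.

    Ties at the cutoff are broken lexicographically (smallest kept) so the
    set size is deterministic.
    """
    items = [(kmer, z) for kmer, z in zscores.items() if z is not None and not math.isnan(z)]
    if not items:
        raise ValueError("no defined Z-scores")
    n_keep = math.ceil(fraction * len(items))
    items.sort(key=lambda kz: (-kz[1], kz[0]))
    return frozenset(kmer for kmer, _ in items[:n_keep])


def _bin_hits(
    profiles: Sequence[Mapping[str, str]], kmer_set: frozenset[str], k: int = 7
) -> tuple[Counter, Counter]:
    """(high-affinity window count, total window count) per bin label."""
    hits: Counter = Counter()
    totals: Counter = Counter()
    for bins in profiles:
        for label, seq in bins.items():
            n = len(seq) - k + 1
            if n <= 0:
                continue
            h = t = 0
            for i in range(n):
                window = seq[i : i + k]
                if "N" in window:
                    continue
                t += 1
                if window in kmer_set:
                    h += 1
            hits[label] += h
            totals[label] += t
    return hits, totals


def bin_enrichment(
    signal: Sequence[Mapping[str, str]],
    background: Sequence[Mapping[str, str]],
    kmer_set: frozenset[str],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-bin enrichment of high-affinity 7-mer windows, signal vs background.

    Each bin forms a 2x2 table of [high-affinity, other] windows by
    [signal, background].  The one-sided Fisher exact p is computed only when
    the signal rate exceeds the background rate (otherwise p = 1); the
    Bonferroni factor is the number of bins tested for this comparison.
    """
    if not signal or not background:
        raise ValueError("signal and background sets must both be non-empty")
    s_hits, s_tot = _bin_hits(signal, kmer_set)
    b_hits, b_tot = _bin_hits(background, kmer_set)
    labels = [
        lab for lab in BIN_LABELS if s_tot.get(lab, 0) > 0 and b_tot.get(lab, 0) > 0
    ]
    n_tested = len(labels)
    rows = []
    for lab in labels:
        hs, ts = s_hits[lab], s_tot[lab]
        hb, tb = b_hits[lab], b_tot[lab]
        enriched = hs / ts > hb / tb
        if enriched:
            # upper tail of the hypergeometric: P(X >= hs)
            p = float(stats.hypergeom.sf(hs - 1, ts + tb, hs + hb, ts))
        else:
            p = 1.0
        p_corr = min(1.0, p * n_tested)
        rows.append(
            {
                "bin": lab,
                "signal_hits": hs,
                "signal_windows": ts,
                "background_hits": hb,
                "background_windows": tb,
                "enriched": enriched,
                "p_raw": p,
                "p_bonferroni": p_corr,
                "significant": p_corr < alpha,
            }
        )
    return pd.DataFrame(rows).set_index("bin")


def scan_rbp_library(
    signal: Sequence[Mapping[str, str]],
    background: Sequence[Mapping[str, str]],
    library: Mapping[str, Mapping[str, float]],
    cutoff: float = 1e-4,
    fraction: float = 0.10,
) -> pd.DataFrame:
    """Rank RBPs by their strongest per-bin enrichment.

    For each RBP the top-``fraction`` 7-mers define the high-affinity set;
    the minimum raw p over bins is recorded, and RBPs passing ``cutoff`` are
    returned sorted by ascending minimum p.
    """
    rows = []
    for rbp, zmap in library.items():
        kset = select_high_affinity(zmap, fraction)
        table = bin_enrichment(signal, background, kset, alpha=1.0)
        if table.empty:
            continue
        min_p = float(table["p_raw"].min())
        best_bin = table["p_raw"].idxmin()
        rows.append({"rbp_id": rbp, "min_p": min_p, "best_bin": best_bin})
    out = pd.DataFrame(rows, columns=["rbp_id", "min_p", "best_bin"])
    out = out[out["min_p"] < cutoff].sort_values("min_p").reset_index(drop=True)
    return out
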