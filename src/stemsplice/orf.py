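"""Predicted impact of splicing events on the protein product.

Each event is mapped onto a transcript model (CDS vs UTR), then classified:
frame-preserving coding events without premature stops generate alternative
protein isoforms (ORF-preserving); frame-shifting lengths disrupt the ORF on
the isoform carrying the shift; an in-frame stop inside the alternative
segment triggers nonsense-mediated decay when it lies more than 50 nt
upstream of the final exon-exon junction of the inclusion isoform, and a
non-NMD stop still counts as disruption when the truncated protein is more
than 100 amino acids shorter than the annotated isoform (otherwise it is an
alternative C-terminus, i.e. ORF-preserving).

Events whose alternative sequence is part of the annotated transcript treat
the annotated isoform as the inclusion form (exclusion is the novel
isoform); unannotated alternative sequence is projected into the transcript
after its upstream exon, and intron retention is evaluated on the inclusion
isoform with the intron read in the upstream exon's frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ASEvent, EventType, TranscriptModel, _revcomp
from .differential import DifferentialCall

__all__ = [
    "Region",
    "Impact",
    "ImpactCall",
    "map_event_to_region",
    "classify_impact",
    "classify_multiexon_group",
    "summarize_impacts",
    "NMD_DISTANCE_NT",
    "TRUNCATION_AA",
]

#: a premature stop further than this upstream of the last exon-exon junction
#: of the inclusion isoform is predicted to trigger NMD
NMD_DISTANCE_NT = 50
#: a non-NMD premature stop disrupts the ORF when the protein loses more
#: than this many amino acids relative to the annotated isoform
TRUNCATION_AA = 100

_STOPS = {"TAA", "TAG", "TGA"}


class Region(str, Enum):
    CDS = "CDS"
    UTR5 = "UTR5"
    UTR3 = "UTR3"
    NONCODING = "NONCODING"
    MIXED = "MIXED"


class Impact(str, Enum):
    ORF_PRESERVING = "ORF_PRESERVING"
    DISRUPT_ON_INCLUSION = "DISRUPT_ON_INCLUSION"
    DISRUPT_ON_EXCLUSION = "DISRUPT_ON_EXCLUSION"
    NONCODING = "NONCODING"


@dataclass(frozen=True)
class ImpactCall:
    event_id: str
    region: Region
    impact: Impact
    nmd: bool
    truncation_aa: int
    stop_in_alt: bool = False

    def __post_init__(self) -> None:
        if self.nmd and self.impact is Impact.ORF_PRESERVING:
            raise ValueError("an NMD-triggering event cannot be ORF-preserving")


# -- geometry helpers --------------------------------------------------------

def _exon_union_contains(exons: Sequence[tuple[int, int]], span: tuple[int, int]) -> bool:
    return any(s <= span[0] and span[1] <= e for s, e in exons)


def _alt_is_annotated(event: ASEvent, transcript: TranscriptModel) -> bool:
    """True when every alternative span lies inside the transcript's exons
    (the annotated isoform then already includes the alternative sequence)."""
    if event.event_type is EventType.IR:
        return False  # the annotated transcript splices the intron out
    return all(_exon_union_contains(transcript.exons, sp) for sp in event.alt_spans)


def _inclusion_chain(
    event: ASEvent, transcript: TranscriptModel
) -> tuple[tuple[int, int], ...]:
    """Exon chain (transcription order) of the inclusion isoform."""
    genomic = sorted(transcript.exons)
    if event.event_type is EventType.IR:
        lo, hi = event.alt_spans[0]
        merged: list[tuple[int, int]] = []
        i = 0
        while i < len(genomic):
            s, e = genomic[i]
            if e == lo - 1 and i + 1 < len(genomic) and genomic[i + 1][0] == hi + 1:
                merged.append((s, genomic[i + 1][1]))
                i += 2
            else:
                merged.append((s, e))
                i += 1
        chain = merged
        if sum(e - s + 1 for s, e in chain) != transcript.length + event.alt_length:
            raise ValueError(
                f"event {event.event_id}: retained intron does not match an "
                f"intron of {transcript.transcript_id}"
            )
    elif _alt_is_annotated(event, transcript):
        chain = genomic
    else:
        extra = [sp for sp in event.alt_spans]
        for sp in extra:
            for s, e in genomic:
                if not (sp[1] < s or sp[0] > e):
                    raise ValueError(
                        f"event {event.event_id}: unannotated alt span {sp} "
                        f"overlaps an exon of {transcript.transcript_id}"
                    )
        chain = sorted(genomic + extra)
    if transcript.strand == "-":
        chain = sorted(chain, reverse=True)
    return tuple(chain)


def _exclusion_chain(
    event: ASEvent, transcript: TranscriptModel
) -> tuple[tuple[int, int], ...]:
    genomic = sorted(transcript.exons)
    if event.event_type is EventType.IR or not _alt_is_annotated(event, transcript):
        chain = genomic
    else:
        chain = [ex for ex in genomic if tuple(ex) not in {tuple(sp) for sp in event.alt_spans}]
        removed = len(genomic) - len(chain)
        if removed != len(event.alt_spans):
            raise ValueError(
                f"event {event.event_id}: annotated alt spans must coincide "
                f"with whole exons of {transcript.transcript_id}"
            )
    if transcript.strand == "-":
        chain = sorted(chain, reverse=True)
    return tuple(chain)


def _chain_pos(
    chain: Sequence[tuple[int, int]], strand: str, genomic_pos: int
) -> int | None:
    """1-based transcript coordinate of a genomic position within a chain."""
    offset = 0
    for s, e in chain:
        if s <= genomic_pos <= e:
            return offset + (genomic_pos - s + 1 if strand == "+" else e - genomic_pos + 1)
        offset += e - s + 1
    return None


def _chain_mrna(
    chain: Sequence[tuple[int, int]], strand: str, scaffold_seq: str
) -> str:
    parts = []
    for s, e in chain:
        seg = scaffold_seq[s - 1 : e]
        if strand == "-":
            seg = _revcomp(seg)
        parts.append(seg)
    return "".join(parts).upper().replace("U", "T")


def _first_stop(mrna: str, cds_start: int) -> tuple[int, int | None]:
    """(number of amino acids translated, transcript coord of the stop
    codon's last base, or None when no stop before the mRNA end)."""
    aa = 0
    for i in range(cds_start - 1, len(mrna) - 2, 3):
        codon = mrna[i : i + 3]
        if codon in _STOPS:
            return aa, i + 3
        aa += 1
    return aa, None


def _start_codon_genomic(transcript: TranscriptModel) -> list[int]:
    """Genomic positions of the three start-codon bases."""
    chain = transcript.exons
    positions = []
    offset = 0
    targets = {transcript.cds_start, transcript.cds_start + 1, transcript.cds_start + 2}
    for s, e in chain:
        for t in sorted(targets):
            rel = t - offset
            if 1 <= rel <= e - s + 1:
                positions.append(s + rel - 1 if transcript.strand == "+" else e - rel + 1)
        offset += e - s + 1
    return positions


# -- public operations -------------------------------------------------------

def map_event_to_region(
    event: ASEvent, transcript: TranscriptModel | None
) -> Region:
    """Locate the alternative sequence relative to the transcript's CDS.

    Annotated alternative spans are compared against the CDS interval in
    transcript coordinates (MIXED when straddling a boundary); unannotated
    spans are projected from the 3' end of their upstream exon.
    """
    if transcript is None:
        return Region.NONCODING
    genomic = sorted(transcript.exons)
    lo = min(sp[0] for sp in event.alt_spans)
    hi = max(sp[1] for sp in event.alt_spans)
    if event.scaffold != transcript.scaffold or hi < genomic[0][0] or lo > genomic[-1][1]:
        raise ValueError(
            f"event {event.event_id} lies outside transcript "
            f"{transcript.transcript_id}"
        )
    if event.event_type is not EventType.IR and _alt_is_annotated(event, transcript):
        coords: list[int] = []
        for s, e in event.alt_spans:
            for g in (s, e):
                t = transcript.genomic_to_transcript(g)
                assert t is not None
                coords.append(t)
        t_lo, t_hi = min(coords), max(coords)
        if t_hi < transcript.cds_start:
            return Region.UTR5
        if t_lo > transcript.cds_end:
            return Region.UTR3
        if t_lo >= transcript.cds_start and t_hi <= transcript.cds_end:
            return Region.CDS
        return Region.MIXED
    # unannotated or retained intron: project from the upstream exon's 3' end
    if transcript.strand == "+":
        upstream = [ex for ex in genomic if ex[1] < lo]
        if not upstream:
            raise ValueError(
                f"event {event.event_id}: no upstream exon in "
                f"{transcript.transcript_id}"
            )
        anchor = max(upstream)[1]
    else:
        upstream = [ex for ex in genomic if ex[0] > hi]
        if not upstream:
            raise ValueError(
                f"event {event.event_id}: no upstream exon in "
                f"{transcript.transcript_id}"
            )
        anchor = min(upstream)[0]
    t = transcript.genomic_to_transcript(anchor)
    assert t is not None
    if t < transcript.cds_start:
        return Region.UTR5
    if t >= transcript.cds_end:
        return Region.UTR3
    return Region.CDS


def classify_impact(
    event: ASEvent,
    transcript: TranscriptModel | None,
    genome: Mapping[str, str],
) -> ImpactCall:
    """Classify the event's predicted effect on the protein product."""
    region = map_event_to_region(event, transcript)
    if region in (Region.UTR5, Region.UTR3, Region.NONCODING):
        return ImpactCall(event.event_id, region, Impact.NONCODING, False, 0)
    assert transcript is not None
    scaffold_seq = str(genome[event.scaffold])

    annotated_aa = transcript.n_codons - 1  # stop codon excluded

    # annotated start codon inside the alternative sequence: the isoform
    # lacking the alternative sequence lacks the start
    start_positions = _start_codon_genomic(transcript)
    if any(
        any(s <= p <= e for s, e in event.alt_spans) for p in start_positions
    ):
        return ImpactCall(
            event.event_id, region, Impact.DISRUPT_ON_EXCLUSION, False, annotated_aa
        )

    incl_chain = _inclusion_chain(event, transcript)
    excl_chain = _exclusion_chain(event, transcript)
    annotated_inclusion = (
        event.event_type is not EventType.IR and _alt_is_annotated(event, transcript)
    )
    novel_chain = excl_chain if annotated_inclusion else incl_chain
    novel_is_inclusion = not annotated_inclusion

    # map the start codon into the isoform under evaluation
    start_g = start_positions[0]

    def _evaluate(chain: Sequence[tuple[int, int]]) -> tuple[int, int | None, int]:
        """(aa translated, stop-codon end coord or None, last-EEJ coord)."""
        mrna = _chain_mrna(chain, transcript.strand, scaffold_seq)
        cstart = _chain_pos(chain, transcript.strand, start_g)
        if cstart is None:
            raise ValueError(
                f"event {event.event_id}: start codon lost from isoform chain"
            )
        aa, stop_end = _first_stop(mrna, cstart)
        lengths = [e - s + 1 for s, e in chain]
        last_eej = sum(lengths[:-1]) if len(lengths) > 1 else 0
        return aa, stop_end, last_eej

    frame_preserving = event.alt_length % 3 == 0

    if not frame_preserving:
        aa, stop_end, last_eej = _evaluate(novel_chain)
        nmd = stop_end is not None and (last_eej - stop_end) > NMD_DISTANCE_NT
        truncation = max(0, annotated_aa - aa)
        impact = (
            Impact.DISRUPT_ON_INCLUSION
            if novel_is_inclusion
            else Impact.DISRUPT_ON_EXCLUSION
        )
        return ImpactCall(event.event_id, region, impact, nmd, truncation)

    # frame-preserving: a premature stop can only come from the alternative
    # segment read in the upstream exon's frame; evaluate the inclusion isoform
    aa_incl, stop_end, last_eej = _evaluate(incl_chain)
    expected_aa = annotated_aa + (
        event.alt_length // 3 if not annotated_inclusion else 0
    )
    premature = aa_incl < expected_aa
    if not premature:
        return ImpactCall(event.event_id, region, Impact.ORF_PRESERVING, False, 0)
    truncation = max(0, annotated_aa - aa_incl)
    nmd = stop_end is not None and (last_eej - stop_end) > NMD_DISTANCE_NT
    if nmd or truncation > TRUNCATION_AA:
        return ImpactCall(
            event.event_id,
            region,
            Impact.DISRUPT_ON_INCLUSION,
            nmd,
            truncation,
            stop_in_alt=True,
        )
    # short, junction-proximal truncation: alternative C-terminus
    return ImpactCall(
        event.event_id, region, Impact.ORF_PRESERVING, False, truncation,
        stop_in_alt=True,
    )


def classify_multiexon_group(
    alt_lengths: Sequence[int],
    member_impacts: Sequence[ImpactCall],
    inclusion_pattern: Mapping[str, Sequence[bool]],
) -> dict[str, Impact]:
    """Per-cell-class impact for a group of neighbouring cassette exons.

    ``inclusion_pattern`` maps a class label to which member exons its
    isoform includes.  The class isoform preserves the ORF iff the summed
    included lengths keep the frame (net shift 0 mod 3) and no included
    member introduces a qualifying stop (NMD-positioned or truncating by
    more than 100 aa).
    """
    if len(alt_lengths) != len(member_impacts):
        raise ValueError("one impact call per member exon is required")
    out: dict[str, Impact] = {}
    for label, included in inclusion_pattern.items():
        if len(included) != len(alt_lengths):
            raise ValueError(
                f"class {label!r}: inclusion pattern length does not match group"
            )
        net = sum(l for l, inc in zip(alt_lengths, included) if inc) % 3
        stop_disrupts = any(
            inc
            and imp.stop_in_alt
            and (imp.nmd or imp.truncation_aa > TRUNCATION_AA)
            for imp, inc in zip(member_impacts, included)
        )
        out[label] = (
            Impact.ORF_PRESERVING
            if net == 0 and not stop_disrupts
            else Impact.DISRUPT_ON_INCLUSION
        )
    return out


def summarize_impacts(
    impact_calls: Mapping[str, ImpactCall],
    differential_calls: Iterable[DifferentialCall],
    events: Iterable[ASEvent] | None = None,
) -> tuple[pd.DataFrame, float | None]:
    """Contingency of impact class by differential direction.

    Returns per-(event_type, direction, impact) counts plus the Pearson
    chi-squared p-value for independence of impact and direction (None when
    the table is degenerate).
    """
    types = {ev.event_id: ev.event_type.value for ev in events} if events else {}
    rows = []
    for call in differential_calls:
        if call.event_id not in impact_calls:
            continue
        imp = impact_calls[call.event_id]
        rows.append(
            {
                "event_type": types.get(call.event_id, "NA"),
                "direction": call.direction,
                "impact": imp.impact.value,
            }
        )
    if not rows:
        raise ValueError("no differential event has an impact call")
    df = pd.DataFrame(rows)
    counts = (
        df.groupby(["event_type", "direction", "impact"]).size().rename("n").reset_index()
    )
    pivot = pd.crosstab(df["direction"], df["impact"])
    if pivot.shape[0] < 2 or pivot.shape[1] < 2:
        return counts, None
    chi2 = stats.chi2_contingency(pivot.to_numpy())
    return counts, float(chi2.pvalue)
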