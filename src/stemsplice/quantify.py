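"""Inclusion-level quantification from junction reads and coverage gating.

Inclusion levels (PSI for exons, PIR for retained introns, PSU for
alternative splice-site choice) are derived only from junction reads:
mappability-corrected counts enter the estimate, while coverage gating uses
the raw ("actual") counts.  For exon and intron events

    PSI = 100 * mean(inclusion-junction counts)
          / (mean(inclusion) + mean(exclusion)),

the averaging reflecting that a single included molecule supports every
inclusion junction of the event once.  Alt3/Alt5 events report the usage of
the focal splice site among all junctions of the event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core import (
    ASEvent,
    EventType,
    InclusionTable,
    JunctionCountMatrix,
    SampleManifest,
)

logger = logging.getLogger("stemsplice")

__all__ = [
    "CoverageRegime",
    "STANDARD",
    "STRICT",
    "compute_inclusion",
    "assess_coverage",
    "build_inclusion_table",
    "compute_crpkm",
]


@dataclass(frozen=True)
class CoverageRegime:
    """Minimum raw-read thresholds for a sample to count as covered.

    ``STANDARD`` encodes the (10, 10, 5) minima used throughout the
    FACS-fraction comparisons; ``STRICT`` the (15, 15, 10) minima used for
    single-replicate knockdown samples and is defined for exon events only.
    """

    name: str
    sum_min: int       # minimum on the summed exclusion (or all-junction) reads
    major_min: int     # minimum on the better-covered inclusion junction
    minor_min: int     # minimum on the other inclusion junction
    exon_only: bool = False


STANDARD = CoverageRegime("STANDARD", 10, 10, 5)
STRICT = CoverageRegime("STRICT", 15, 15, 10, exon_only=True)


def compute_inclusion(
    event: ASEvent, counts: Mapping[str, float]
) -> float | None:
    """Inclusion level in [0, 100] for one sample, or None when undefined.

    ``counts`` maps junction id to mappability-corrected count.  A missing
    junction or zero total evidence makes the value undefined.
    """
    try:
        incl = [float(counts[j]) for j in event.inclusion_junctions]
        excl = [float(counts[j]) for j in event.exclusion_junctions]
    except KeyError:
        return None
    if any(np.isnan(incl)) or any(np.isnan(excl)):
        return None
    if event.event_type in (EventType.ALT3, EventType.ALT5):
        total = sum(incl) + sum(excl)
        if total == 0:
            return None
        return min(100.0, max(0.0, 100.0 * sum(incl) / total))
    mean_incl = float(np.mean(incl))
    mean_excl = float(np.mean(excl))
    if mean_incl + mean_excl == 0:
        return None
    return min(100.0, max(0.0, 100.0 * mean_incl / (mean_incl + mean_excl)))


def assess_coverage(
    event: ASEvent,
    raw_counts: Mapping[str, float],
    regime: CoverageRegime = STANDARD,
) -> bool:
    """Whether one sample has sufficient raw junction reads for this event.

    Exon events pass when summed exclusion reads reach ``sum_min`` OR the two
    inclusion junctions reach (``major_min``, ``minor_min``); microexons use
    summed inclusion reads instead of the pairwise rule; intron retention
    mirrors the exon rule on its exon-intron junction pair; Alt3/Alt5 require
    ``sum_min`` reads summed over all junctions of the event.
    """
    if regime.exon_only and event.event_type in (
        EventType.IR,
        EventType.ALT3,
        EventType.ALT5,
    ):
        raise ValueError(
            f"{regime.name} coverage is defined only for exon events, not "
            f"{event.event_type.value}"
        )
    try:
        incl = [float(raw_counts[j]) for j in event.inclusion_junctions]
        excl = [float(raw_counts[j]) for j in event.exclusion_junctions]
    except KeyError:
        return False
    if any(np.isnan(incl)) or any(np.isnan(excl)):
        return False

    etype = event.event_type
    if etype in (EventType.ALT3, EventType.ALT5):
        return sum(incl) + sum(excl) >= regime.sum_min
    if etype is EventType.MIC:
        return sum(excl) >= regime.sum_min or sum(incl) >= regime.sum_min
    # EX_SINGLE / EX_MULTI / IR: pairwise rule on the two inclusion junctions
    # (multi-cassette events use their two best-covered inclusion junctions,
    # mirroring the C1A/AC2 pair of the single-exon case).
    pair = sorted(incl, reverse=True)[:2]
    if len(pair) == 1:
        pair = pair + [0.0]
    return sum(excl) >= regime.sum_min or (
        pair[0] >= regime.major_min and pair[1] >= regime.minor_min
    )


def build_inclusion_table(
    events: Iterable[ASEvent],
    counts: JunctionCountMatrix,
    manifest: SampleManifest,
    regime: CoverageRegime = STANDARD,
) -> InclusionTable:
    """Compose inclusion values and coverage flags into an event x sample table.

    Events referencing junctions absent from the count matrix get undefined,
    uncovered cells (warned once per event).  The result is independent of
    event and sample ordering in the inputs.
    """
    sample_ids = [s for s in manifest.sample_ids if s in counts.samples]
    events = list(events)
    values = np.full((len(events), len(sample_ids)), np.nan)
    flags = np.zeros((len(events), len(sample_ids)), dtype=bool)
    raw_cols = {s: counts.raw[s] for s in sample_ids}
    corr_cols = {s: counts.corrected[s] for s in sample_ids}
    for i, ev in enumerate(events):
        if not counts.has_junctions(ev.junctions):
            missing = [j for j in ev.junctions if j not in counts.junctions]
            logger.warning(
                "event %s: junction(s) %s absent from count matrix; cells left "
                "undefined and uncovered",
                ev.event_id,
                missing,
            )
            continue
        for j, s in enumerate(sample_ids):
            psi = compute_inclusion(ev, corr_cols[s])
            if psi is not None:
                values[i, j] = psi
            flags[i, j] = assess_coverage(ev, raw_cols[s], regime)
    index = pd.Index([ev.event_id for ev in events], name="event_id")
    return InclusionTable(
        pd.DataFrame(values, index=index, columns=sample_ids),
        pd.DataFrame(flags, index=index, columns=sample_ids),
    )


def compute_crpkm(
    mappable_positions: float, gene_read_count: float, library_total: float
) -> float:
    """Mappability-corrected reads per kilobase per million mapped reads.

    cRPKM = 1e9 * reads / (mappable positions * total mapped reads).
    """
    if mappable_positions <= 0:
        raise ValueError("mappable_positions must be positive")
    if library_total <= 0:
        raise ValueError("library_total must be positive")
    if gene_read_count < 0:
        raise ValueError("gene_read_count must be non-negative")
    return 1e9 * gene_read_count / (mappable_positions * library_total)
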