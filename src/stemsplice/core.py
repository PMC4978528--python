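"""Core domain types shared by every stage of the pipeline.

Coordinates are 1-based and inclusive throughout, and "upstream"/"downstream"
are always resolved on the transcribed strand.  An :class:`ASEvent` describes
one alternative-splicing event purely in terms of the junctions whose read
counts quantify it; all downstream statistics are junction-read based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EventType",
    "ASEvent",
    "SampleInfo",
    "SampleManifest",
    "JunctionCountMatrix",
    "InclusionTable",
    "TranscriptModel",
    "ValidationError",
    "DIFF_GROUPS",
]

#: sample groups pooled as "differentiated" in X1-vs-diff comparisons
DIFF_GROUPS = ("XINS", "WW_DEPLETED")


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


class EventType(str, Enum):
    """Alternative-splicing event classes.

    ``EX_SINGLE``/``EX_MULTI`` are long (>27 nt) cassette exons (single or a
    group of neighbouring alternative exons), ``MIC`` microexons of 3-27 nt,
    ``IR`` intron retention, and ``ALT3``/``ALT5`` alternative acceptor/donor
    splice-site choice.
    """

    EX_SINGLE = "EX_SINGLE"
    EX_MULTI = "EX_MULTI"
    MIC = "MIC"
    IR = "IR"
    ALT3 = "ALT3"
    ALT5 = "ALT5"


_CASSETTE_TYPES = (EventType.EX_SINGLE, EventType.EX_MULTI, EventType.MIC)


@dataclass(frozen=True)
class ASEvent:
    """One alternative-splicing event.

    ``alt_spans`` holds the genomic interval(s) of the alternative sequence
    (one per member exon for multi-cassette groups; the retained intron for
    IR).  ``inclusion_junctions``/``exclusion_junctions`` name the junctions
    whose reads support the inclusion and exclusion isoforms respectively
    (EEJs, or exon-intron junctions for IR inclusion).
    """

    event_id: str
    event_type: EventType
    gene_id: str
    scaffold: str
    strand: str
    alt_spans: tuple[tuple[int, int], ...]
    alt_length: int
    inclusion_junctions: tuple[str, ...]
    exclusion_junctions: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"event {self.event_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.alt_spans:
            raise ValidationError(f"event {self.event_id}: no alt_spans")
        for start, end in self.alt_spans:
            if start < 1 or end < start:
                raise ValidationError(
                    f"event {self.event_id}: invalid span {start}-{end}"
                )
        if not self.inclusion_junctions or not self.exclusion_junctions:
            raise ValidationError(
                f"event {self.event_id}: inclusion and exclusion junction sets "
                "must both be non-empty"
            )
        if set(self.inclusion_junctions) & set(self.exclusion_junctions):
            raise ValidationError(
                f"event {self.event_id}: inclusion and exclusion junctions overlap"
            )
        span_lengths = [end - start + 1 for start, end in self.alt_spans]
        if self.alt_length != sum(span_lengths):
            raise ValidationError(
                f"event {self.event_id}: alt_length {self.alt_length} does not "
                f"match alt_spans total {sum(span_lengths)}"
            )
        if self.event_type is EventType.MIC:
            if not (3 <= self.alt_length <= 27):
                raise ValidationError(
                    f"event {self.event_id}: microexon length must be 3-27 nt, "
                    f"got {self.alt_length}"
                )
        elif self.event_type is EventType.EX_SINGLE:
            if self.alt_length <= 27:
                raise ValidationError(
                    f"event {self.event_id}: EX_SINGLE exon must be >27 nt "
                    f"(3-27 nt exons are MIC), got {self.alt_length}"
                )
            if len(self.inclusion_junctions) != 2:
                raise ValidationError(
                    f"event {self.event_id}: EX_SINGLE needs exactly two "
                    "inclusion junctions (C1A, AC2)"
                )
        elif self.event_type is EventType.EX_MULTI:
            bad = [l for l in span_lengths if l <= 27]
            if bad:
                raise ValidationError(
                    f"event {self.event_id}: EX_MULTI member exons must each be "
                    f">27 nt, got {bad}"
                )
        elif self.event_type is EventType.IR:
            if len(self.alt_spans) != 1:
                raise ValidationError(
                    f"event {self.event_id}: IR must have a single retained-intron span"
                )
            if len(self.inclusion_junctions) != 2:
                raise ValidationError(
                    f"event {self.event_id}: IR needs exactly two inclusion "
                    "exon-intron junctions"
                )

    @property
    def junctions(self) -> tuple[str, ...]:
        return self.inclusion_junctions + self.exclusion_junctions


_KNOWN_GROUPS = {"X1", "X2", "XINS", "WW", "WW_DEPLETED", "CONTROL"}


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    group: str
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.group not in _KNOWN_GROUPS and not self.group.startswith("KD:"):
            raise ValidationError(
                f"sample {self.sample_id}: unknown group {self.group!r}; allowed: "
                f"{sorted(_KNOWN_GROUPS)} or KD:<label>"
            )


class SampleManifest:
    """Ordered collection of samples with group lookups.

    Manifest order is meaningful: deterministic tie-breaks downstream (e.g.
    the Mean80 trim) resolve ties by manifest position.
    """

    def __init__(self, samples: Iterable[SampleInfo]):
        self.samples: list[SampleInfo] = list(samples)
        seen: set[str] = set()
        for s in self.samples:
            if s.sample_id in seen:
                raise ValidationError(f"duplicate sample_id {s.sample_id!r}")
            seen.add(s.sample_id)
        self._by_id = {s.sample_id: s for s in self.samples}

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[SampleInfo]:
        return iter(self.samples)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def group_of(self, sample_id: str) -> str:
        return self._by_id[sample_id].group

    def samples_in(self, *groups: str) -> list[str]:
        wanted = set(groups)
        return [s.sample_id for s in self.samples if s.group in wanted]

    def diff_samples(self) -> list[str]:
        """Samples of the pooled differentiated group (Xins + depleted WW)."""
        return self.samples_in(*DIFF_GROUPS)


class JunctionCountMatrix:
    """Raw and mappability-corrected read counts per junction x sample.

    Coverage gating works on raw counts ("actual reads, before mappability
    correction"); inclusion levels are computed from corrected counts.
    """

    def __init__(self, raw: pd.DataFrame, corrected: pd.DataFrame | None = None):
        if corrected is None:
            corrected = raw.astype(float).copy()
        if not raw.index.equals(corrected.index) or not raw.columns.equals(
            corrected.columns
        ):
            raise ValidationError("raw and corrected matrices must be aligned")
        if (raw.to_numpy() < 0).any() or (corrected.to_numpy() < 0).any():
            raise ValidationError("negative junction counts")
        self.raw = raw
        self.corrected = corrected

    @property
    def junctions(self) -> pd.Index:
        return self.raw.index

    @property
    def samples(self) -> pd.Index:
        return self.raw.columns

    def has_junctions(self, junctions: Sequence[str]) -> bool:
        return all(j in self.raw.index for j in junctions)

    def raw_counts(self, sample_id: str) -> Mapping[str, float]:
        return self.raw[sample_id]

    def corrected_counts(self, sample_id: str) -> Mapping[str, float]:
        return self.corrected[sample_id]


class InclusionTable:
    """Event x sample inclusion levels (PSI/PSU/PIR, 0-100) with coverage flags.

    ``values`` may be NaN (undefined); a present value with ``covered`` False
    is retained but excluded from all downstream statistics.
    """

    def __init__(self, values: pd.DataFrame, covered: pd.DataFrame):
        if not values.index.equals(covered.index) or not values.columns.equals(
            covered.columns
        ):
            raise ValidationError("values and coverage flags must be aligned")
        vals = values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=0.0) > 100:
                raise ValidationError("inclusion values must lie in [0, 100]")
        self.values = values.astype(float)
        self.covered = covered.astype(bool)

    @property
    def events(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def covered_values(self, event_id: str, sample_ids: Sequence[str]) -> np.ndarray:
        """Values for the given samples that are covered and defined."""
        cols = [s for s in sample_ids if s in self.values.columns]
        v = self.values.loc[event_id, cols].to_numpy(dtype=float)
        c = self.covered.loc[event_id, cols].to_numpy(dtype=bool)
        keep = c & ~np.isnan(v)
        return v[keep]

    def subset_events(self, event_ids: Sequence[str]) -> "InclusionTable":
        ids = [e for e in event_ids if e in self.values.index]
        return InclusionTable(self.values.loc[ids], self.covered.loc[ids])

    def equals(self, other: "InclusionTable") -> bool:
        va, vb = self.values, other.values
        return (
            va.index.equals(vb.index)
            and va.columns.equals(vb.columns)
            and np.allclose(va.to_numpy(), vb.to_numpy(), equal_nan=True, atol=1e-9)
            and self.covered.equals(other.covered)
        )


@dataclass(frozen=True)
class TranscriptModel:
    """Exon chain plus CDS annotation for one transcript.

    ``exons`` are genomic intervals ordered 5'->3' on the transcribed strand
    (descending genomic coordinates for '-' transcripts).  ``cds_start`` and
    ``cds_end`` are 1-based transcript coordinates of the first base of the
    start codon and the last base of the stop codon.
    """

    transcript_id: str
    scaffold: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.transcript_id}: bad strand {self.strand!r}")
        prev_end = None
        genomic = sorted(self.exons)
        for i, (s, e) in enumerate(genomic):
            if e < s:
                raise ValidationError(f"{self.transcript_id}: invalid exon {s}-{e}")
            if i and s <= genomic[i - 1][1]:
                raise ValidationError(f"{self.transcript_id}: overlapping exons")
        ordered = sorted(self.exons, reverse=self.strand == "-")
        if tuple(ordered) != tuple(self.exons):
            raise ValidationError(
                f"{self.transcript_id}: exons must be ordered 5'->3' on the "
                "transcribed strand"
            )
        length = self.length
        if not (1 <= self.cds_start < self.cds_end <= length):
            raise ValidationError(
                f"{self.transcript_id}: CDS {self.cds_start}-{self.cds_end} outside "
                f"transcript bounds 1-{length}"
            )
        if (self.cds_end - self.cds_start + 1) % 3 != 0:
            raise ValidationError(
                f"{self.transcript_id}: CDS length not divisible by 3"
            )

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def n_codons(self) -> int:
        """CDS codons including the stop codon."""
        return (self.cds_end - self.cds_start + 1) // 3

    def genomic_to_transcript(self, pos: int) -> int | None:
        """Map a genomic position to a 1-based transcript coordinate."""
        offset = 0
        for s, e in self.exons:
            if s <= pos <= e:
                return offset + (pos - s + 1 if self.strand == "+" else e - pos + 1)
            offset += e - s + 1
        return None

    def spliced_sequence(self, genome: Mapping[str, str]) -> str:
        """Mature transcript sequence (5'->3'), given scaffold sequences."""
        chrom = str(genome[self.scaffold])
        parts = []
        for s, e in self.exons:
            seg = chrom[s - 1 : e]
            if self.strand == "-":
                seg = _revcomp(seg)
            parts.append(seg)
        return "".join(parts).upper()


_COMP = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]
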