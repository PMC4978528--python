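"""Readers and writers for the tab-separated and sequence formats the
pipeline touches.

All tables are plain TSV with a header row.  Missing values are written as
``NA``; inclusion levels are serialized with two decimals (finer precision is
meaningless at realistic junction read depths).  Every reader attaches the
offending line number to parse errors.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import (
    ASEvent,
    EventType,
    InclusionTable,
    JunctionCountMatrix,
    SampleInfo,
    SampleManifest,
    TranscriptModel,
    ValidationError,
)

logger = logging.getLogger("stemsplice")

__all__ = [
    "read_event_table",
    "write_event_table",
    "read_manifest",
    "write_manifest",
    "read_counts",
    "write_counts",
    "read_inclusion_table",
    "write_inclusion_table",
    "read_transcript_models",
    "write_transcript_models",
    "read_zscore_table",
    "write_zscore_table",
    "read_fasta",
    "write_fasta",
]

_EVENT_COLUMNS = [
    "event_id",
    "event_type",
    "gene_id",
    "scaffold",
    "strand",
    "alt_spans",
    "alt_length",
    "inclusion_junctions",
    "exclusion_junctions",
]


def _parse_spans(text: str) -> tuple[tuple[int, int], ...]:
    spans = []
    for part in text.split(","):
        start, _, end = part.partition("-")
        spans.append((int(start), int(end)))
    return tuple(spans)


def read_event_table(path: str | Path) -> list[ASEvent]:
    """Read a tab-separated event table into validated :class:`ASEvent` s."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    events: list[ASEvent] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        try:
            if row.event_id in seen:
                raise ValidationError(f"duplicate event_id {row.event_id!r}")
            seen.add(row.event_id)
            try:
                etype = EventType(row.event_type)
            except ValueError:
                raise ValidationError(
                    f"unknown event_type {row.event_type!r}; allowed: "
                    f"{[t.value for t in EventType]}"
                ) from None
            events.append(
                ASEvent(
                    event_id=row.event_id,
                    event_type=etype,
                    gene_id=row.gene_id,
                    scaffold=row.scaffold,
                    strand=row.strand,
                    alt_spans=_parse_spans(row.alt_spans),
                    alt_length=int(row.alt_length),
                    inclusion_junctions=tuple(row.inclusion_junctions.split(",")),
                    exclusion_junctions=tuple(row.exclusion_junctions.split(",")),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}, line {i}: {exc}") from None
    return events


def write_event_table(events: list[ASEvent], path: str | Path) -> None:
    rows = []
    for ev in events:
        rows.append(
            {
                "event_id": ev.event_id,
                "event_type": ev.event_type.value,
                "gene_id": ev.gene_id,
                "scaffold": ev.scaffold,
                "strand": ev.strand,
                "alt_spans": ",".join(f"{s}-{e}" for s, e in ev.alt_spans),
                "alt_length": ev.alt_length,
                "inclusion_junctions": ",".join(ev.inclusion_junctions),
                "exclusion_junctions": ",".join(ev.exclusion_junctions),
            }
        )
    pd.DataFrame(rows, columns=_EVENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> SampleManifest:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    samples = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            rep = int(getattr(row, "replicate", 1) or 1)
            samples.append(SampleInfo(row.sample_id, row.group, rep))
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}, line {i}: {exc}") from None
    return SampleManifest(samples)


def write_manifest(manifest: SampleManifest, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"sample_id": s.sample_id, "group": s.group, "replicate": s.replicate}
            for s in manifest
        ]
    ).to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path, manifest: SampleManifest) -> JunctionCountMatrix:
    """Read junction counts in long or wide format.

    Long format has columns ``junction_id, sample_id, raw_count`` and
    optionally ``corrected_count``; wide format has ``junction_id`` plus one
    raw-count column per sample.  When no corrected counts are supplied the
    corrected matrix mirrors the raw one (logged).
    """
    df = pd.read_csv(path, sep="\t")
    if "junction_id" not in df.columns:
        raise ValidationError(f"{path}: missing column 'junction_id'")
    if "sample_id" in df.columns:  # long format
        if "raw_count" not in df.columns:
            raise ValidationError(f"{path}: long format needs 'raw_count'")
        unknown = set(df["sample_id"]) - set(manifest.sample_ids)
        if unknown:
            raise ValidationError(f"{path}: samples not in manifest: {sorted(unknown)}")
        raw = df.pivot(index="junction_id", columns="sample_id", values="raw_count")
        raw = raw.fillna(0)
        if "corrected_count" in df.columns:
            corrected = df.pivot(
                index="junction_id", columns="sample_id", values="corrected_count"
            ).fillna(0)
        else:
            logger.warning(
                "%s: no corrected_count column; corrected counts mirror raw", path
            )
            corrected = raw.astype(float)
    else:  # wide format: raw counts only
        raw = df.set_index("junction_id")
        unknown = set(raw.columns) - set(manifest.sample_ids)
        if unknown:
            raise ValidationError(f"{path}: samples not in manifest: {sorted(unknown)}")
        logger.warning("%s: wide table carries raw counts only; corrected := raw", path)
        corrected = raw.astype(float)
    if (raw.to_numpy() < 0).any():
        raise ValidationError(f"{path}: negative counts")
    return JunctionCountMatrix(raw, corrected)


def write_counts(matrix: JunctionCountMatrix, path: str | Path) -> None:
    """Write counts in long format, preserving raw and corrected values."""
    raw = matrix.raw.stack()
    corr = matrix.corrected.stack()
    out = pd.DataFrame(
        {
            "junction_id": [i for i, _ in raw.index],
            "sample_id": [s for _, s in raw.index],
            "raw_count": raw.to_numpy(),
            "corrected_count": corr.to_numpy(),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def write_inclusion_table(table: InclusionTable, path: str | Path) -> None:
    """One event per row; per sample a value column (2 decimals, NA when
    undefined) and a ``<sample>.cov`` flag column (1/0)."""
    out = pd.DataFrame(index=table.events)
    out.index.name = "event_id"
    for s in table.samples:
        out[s] = table.values[s].map(lambda v: "NA" if pd.isna(v) else f"{v:.2f}")
        out[f"{s}.cov"] = table.covered[s].astype(int)
    out.to_csv(path, sep="\t")


def read_inclusion_table(path: str | Path) -> InclusionTable:
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("event_id")
    sample_cols = [c for c in df.columns if not c.endswith(".cov")]
    values = df[sample_cols].replace("NA", np.nan).astype(float)
    covered = df[[f"{s}.cov" for s in sample_cols]].astype(int).astype(bool)
    covered.columns = sample_cols
    return InclusionTable(values, covered)


# -- transcript models (GTF-like) -------------------------------------------

def read_transcript_models(path: str | Path) -> dict[str, TranscriptModel]:
    """Parse a GTF-like file with ``exon`` and ``CDS`` features.

    Exons define the transcript chain; genomic CDS intervals are converted to
    transcript coordinates.  Attribute column must carry ``transcript_id``.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValidationError(f"{path}, line {lineno}: expected 9 columns")
            scaffold, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            tid = None
            for chunk in attrs.split(";"):
                chunk = chunk.strip()
                if chunk.startswith("transcript_id"):
                    tid = chunk.split(None, 1)[1].strip().strip('"')
            if tid is None:
                raise ValidationError(f"{path}, line {lineno}: no transcript_id")
            meta.setdefault(tid, (scaffold, strand))
            if feature == "exon":
                exons.setdefault(tid, []).append((int(start), int(end)))
            elif feature == "CDS":
                cds.setdefault(tid, []).append((int(start), int(end)))
    models: dict[str, TranscriptModel] = {}
    for tid, ex in exons.items():
        scaffold, strand = meta[tid]
        ex_sorted = tuple(sorted(ex, reverse=strand == "-"))
        if tid not in cds:
            raise ValidationError(f"{path}: transcript {tid} has no CDS features")
        # genomic CDS extremes -> transcript coordinates
        g_positions = [p for s, e in cds[tid] for p in (s, e)]
        probe = TranscriptModel.__new__(TranscriptModel)
        object.__setattr__(probe, "transcript_id", tid)
        object.__setattr__(probe, "scaffold", scaffold)
        object.__setattr__(probe, "strand", strand)
        object.__setattr__(probe, "exons", ex_sorted)
        object.__setattr__(probe, "cds_start", 1)
        object.__setattr__(probe, "cds_end", 3)
        t_positions = [probe.genomic_to_transcript(p) for p in g_positions]
        if any(t is None for t in t_positions):
            raise ValidationError(f"{path}: CDS of {tid} outside its exons")
        models[tid] = TranscriptModel(
            transcript_id=tid,
            scaffold=scaffold,
            strand=strand,
            exons=ex_sorted,
            cds_start=min(t_positions),  # type: ignore[type-var]
            cds_end=max(t_positions),  # type: ignore[type-var]
        )
    return models


def write_transcript_models(
    models: Mapping[str, TranscriptModel], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for tid, tm in models.items():
            attrs = f'transcript_id "{tid}";'
            for s, e in tm.exons:
                fh.write(
                    f"{tm.scaffold}\tstemsplice\texon\t{s}\t{e}\t.\t{tm.strand}\t.\t{attrs}\n"
                )
            for s, e in _cds_genomic_intervals(tm):
                fh.write(
                    f"{tm.scaffold}\tstemsplice\tCDS\t{s}\t{e}\t.\t{tm.strand}\t.\t{attrs}\n"
                )


def _cds_genomic_intervals(tm: TranscriptModel) -> list[tuple[int, int]]:
    """Genomic intervals covered by the CDS (transcript coords -> genome)."""
    intervals = []
    offset = 0
    for s, e in tm.exons:
        exon_len = e - s + 1
        t_lo, t_hi = offset + 1, offset + exon_len
        lo = max(t_lo, tm.cds_start)
        hi = min(t_hi, tm.cds_end)
        if lo <= hi:
            if tm.strand == "+":
                intervals.append((s + (lo - t_lo), s + (hi - t_lo)))
            else:
                intervals.append((e - (hi - t_lo), e - (lo - t_lo)))
        offset += exon_len
    return sorted(intervals)


# -- motif library and sequences ---------------------------------------------

def read_zscore_table(path: str | Path) -> dict[str, dict[str, float]]:
    """RBP 7-mer affinity Z-scores: columns ``rbp_id, kmer, z``."""
    df = pd.read_csv(path, sep="\t", dtype={"rbp_id": str, "kmer": str})
    for col in ("rbp_id", "kmer", "z"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    library: dict[str, dict[str, float]] = {}
    for row in df.itertuples(index=False):
        library.setdefault(row.rbp_id, {})[row.kmer.upper().replace("T", "U")] = float(
            row.z
        )
    return library


def write_zscore_table(library: Mapping[str, Mapping[str, float]], path: str | Path) -> None:
    rows = [
        {"rbp_id": rbp, "kmer": kmer, "z": z}
        for rbp, table in library.items()
        for kmer, z in table.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
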