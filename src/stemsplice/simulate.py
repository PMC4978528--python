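"""Synthetic inputs carrying the statistical structure the pipeline assumes.

The generator emulates a FACS-fraction RNA-seq design: stem-cell (X1)
samples, mixed stem/progeny (X2) samples with intermediate inclusion levels,
and a differentiated pool (Xins plus neoblast-depleted whole worms).  Event
types mix cassette exons (including 3-27 nt microexons), intron retention
with a bimodal intron-length model (a short mode centred near 57 nt and a
long 1-10 kb mode), and alternative splice-site events.  Per event and
sample, junction depth follows a negative binomial; the sample-level
inclusion fraction is the group mean plus Gaussian noise; and each junction
is sampled binomially at that fraction (inclusion junctions at psi,
exclusion junctions at 1 - psi), the model under which the junction-count
PSI estimator is consistent.

Everything is driven by a single integer seed and is bit-for-bit
deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import (
    ASEvent,
    EventType,
    JunctionCountMatrix,
    SampleInfo,
    SampleManifest,
    TranscriptModel,
    _revcomp,
)
from .motifs import BIN_SIZE, EventSequences
from .orf import Impact, ImpactCall, Region

__all__ = [
    "SimulationConfig",
    "make_manifest",
    "simulate_events",
    "simulate_counts",
    "simulate_single_sample_counts",
    "simulate_sequences",
    "OrfCase",
    "simulate_transcripts",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic FACS-fraction design."""

    seed: int = 0
    n_events: int = 2000
    #: event-type census: intron retention dominates the global catalogue
    type_mix: tuple[tuple[str, float], ...] = (
        ("IR", 0.50),
        ("EX_SINGLE", 0.20),
        ("MIC", 0.10),
        ("EX_MULTI", 0.05),
        ("ALT3", 0.075),
        ("ALT5", 0.075),
    )
    n_x1: int = 6
    n_x2: int = 4
    n_xins: int = 6
    n_ww_depleted: int = 2
    depth_mean: float = 150.0
    depth_dispersion: float = 2.0
    depth_min: int = 50
    psi_noise_sd: float = 5.0
    n_differential: int = 200
    delta_psi: float = 40.0
    planted_motif: tuple[str, str, float] = ("GCUUGC", "BIN_D1", 3.0)
    motif_base_rate: float = 0.25
    intron_length: int = 300
    exon_length_range: tuple[int, int] = (60, 150)
    intron_short_frac: float = 0.55
    intron_short_meanlog: float = math.log(57.0)
    intron_short_sdlog: float = 0.25
    intron_long_range: tuple[int, int] = (1000, 10000)

    def __post_init__(self) -> None:
        total = sum(w for _, w in self.type_mix)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"type_mix proportions sum to {total}, not 1")
        if self.n_differential > self.n_events:
            raise ValueError("more planted differential events than events")

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "type_mix" in raw and isinstance(raw["type_mix"], dict):
            raw["type_mix"] = tuple(raw["type_mix"].items())
        for key in ("planted_motif", "exon_length_range", "intron_long_range"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def make_manifest(config: SimulationConfig) -> SampleManifest:
    samples = []
    for group, n, prefix in (
        ("X1", config.n_x1, "X1"),
        ("X2", config.n_x2, "X2"),
        ("XINS", config.n_xins, "Xins"),
        ("WW_DEPLETED", config.n_ww_depleted, "WWd"),
    ):
        for r in range(1, n + 1):
            samples.append(SampleInfo(f"{prefix}_{r}", group, r))
    return SampleManifest(samples)


def _intron_length(rng: np.random.Generator, config: SimulationConfig) -> int:
    if rng.random() < config.intron_short_frac:
        return max(30, int(round(rng.lognormal(
            config.intron_short_meanlog, config.intron_short_sdlog
        ))))
    lo, hi = config.intron_long_range
    return int(rng.integers(lo, hi + 1))


def _make_event(
    i: int, etype: EventType, rng: np.random.Generator, config: SimulationConfig
) -> ASEvent:
    eid = f"ev{i:05d}"
    scaffold = f"scaffold_{i % 20 + 1}"
    strand = "+" if rng.random() < 0.5 else "-"
    start = int(rng.integers(10_000, 1_000_000))
    if etype is EventType.MIC:
        alt_len = int(rng.integers(3, 28))
        spans = ((start, start + alt_len - 1),)
        incl = (f"{eid}_EEEJ1", f"{eid}_EEEJ2")
        excl = (f"{eid}_C1C2",)
    elif etype is EventType.EX_SINGLE:
        alt_len = int(rng.integers(28, 301))
        spans = ((start, start + alt_len - 1),)
        incl = (f"{eid}_C1A", f"{eid}_AC2")
        excl = (f"{eid}_C1C2",)
    elif etype is EventType.EX_MULTI:
        l1 = int(rng.integers(28, 201))
        l2 = int(rng.integers(28, 201))
        gap = int(rng.integers(80, 500))
        spans = (
            (start, start + l1 - 1),
            (start + l1 + gap, start + l1 + gap + l2 - 1),
        )
        alt_len = l1 + l2
        incl = (f"{eid}_C1A1", f"{eid}_A1A2", f"{eid}_A2C2")
        excl = (f"{eid}_C1C2",)
    elif etype is EventType.IR:
        alt_len = max(4, _intron_length(rng, config))
        spans = ((start, start + alt_len - 1),)
        incl = (f"{eid}_EI1", f"{eid}_EI2")
        excl = (f"{eid}_skip",)
    else:  # ALT3 / ALT5
        alt_len = int(rng.integers(3, 101))
        spans = ((start, start + alt_len - 1),)
        incl = (f"{eid}_focal",)
        excl = (f"{eid}_other",)
    return ASEvent(
        event_id=eid,
        event_type=etype,
        gene_id=f"g{i:05d}",
        scaffold=scaffold,
        strand=strand,
        alt_spans=spans,
        alt_length=alt_len,
        inclusion_junctions=incl,
        exclusion_junctions=excl,
    )


def simulate_events(
    config: SimulationConfig,
) -> tuple[list[ASEvent], pd.DataFrame]:
    """Generate the event catalogue and its ground truth.

    The returned truth table carries, per event, the true group inclusion
    levels (X2 at the midpoint of X1 and the differentiated pool), the
    planted-differential flag and its direction.
    """
    rng = np.random.default_rng([config.seed, 1])
    types = [EventType(name) for name, _ in config.type_mix]
    weights = np.array([w for _, w in config.type_mix])
    choices = rng.choice(len(types), size=config.n_events, p=weights / weights.sum())
    events = [_make_event(i, types[c], rng, config) for i, c in enumerate(choices)]

    diff_idx = set(
        rng.choice(config.n_events, size=config.n_differential, replace=False).tolist()
    )
    rows = []
    for i, ev in enumerate(events):
        if i in diff_idx:
            base = float(rng.uniform(5.0, 95.0 - config.delta_psi))
            if rng.random() < 0.5:
                psi_x1, psi_diff = base + config.delta_psi, base
                direction = "X1_INCLUDED"
            else:
                psi_x1, psi_diff = base, base + config.delta_psi
                direction = "X1_EXCLUDED"
        else:
            u = rng.random()
            if u < 0.35:
                psi_x1 = psi_diff = float(rng.uniform(15.0, 85.0))
            elif u < 0.675:
                psi_x1 = psi_diff = float(rng.uniform(0.0, 8.0))
            else:
                psi_x1 = psi_diff = float(rng.uniform(92.0, 100.0))
            direction = "NONE"
        rows.append(
            {
                "event_id": ev.event_id,
                "event_type": ev.event_type.value,
                "differential": i in diff_idx,
                "direction": direction,
                "psi_x1": psi_x1,
                "psi_x2": (psi_x1 + psi_diff) / 2.0,
                "psi_diff": psi_diff,
            }
        )
    truth = pd.DataFrame(rows).set_index("event_id")
    return events, truth


_GROUP_PSI_COLUMN = {
    "X1": "psi_x1",
    "X2": "psi_x2",
    "XINS": "psi_diff",
    "WW_DEPLETED": "psi_diff",
    "WW": "psi_diff",
}


def _draw_event_counts(
    ev: ASEvent,
    psi_true: float,
    rng: np.random.Generator,
    config: SimulationConfig,
) -> dict[str, int]:
    """Counts for all junctions of one event in one sample."""
    extra = max(config.depth_mean - config.depth_min, 0.0)
    k = config.depth_dispersion
    depth = config.depth_min + (
        int(rng.negative_binomial(k, k / (k + extra))) if extra > 0 else 0
    )
    psi = min(100.0, max(0.0, psi_true + rng.normal(0.0, config.psi_noise_sd))) / 100.0
    counts: dict[str, int] = {}
    for j in ev.inclusion_junctions:
        counts[j] = int(rng.binomial(depth, psi))
    for j in ev.exclusion_junctions:
        counts[j] = int(rng.binomial(depth, 1.0 - psi))
    return counts


def simulate_counts(
    events: Sequence[ASEvent],
    truth: pd.DataFrame,
    manifest: SampleManifest,
    config: SimulationConfig,
) -> JunctionCountMatrix:
    """Junction read counts for every sample in the manifest.

    Corrected counts equal the raw counts (unit mappability in simulation).
    """
    rng = np.random.default_rng([config.seed, 2])
    sample_ids = manifest.sample_ids
    junctions = [j for ev in events for j in ev.junctions]
    data = np.zeros((len(junctions), len(sample_ids)), dtype=int)
    row = 0
    for ev in events:
        truth_row = truth.loc[ev.event_id]
        njunc = len(ev.junctions)
        for col, s in enumerate(sample_ids):
            psi_true = float(truth_row[_GROUP_PSI_COLUMN[manifest.group_of(s)]])
            counts = _draw_event_counts(ev, psi_true, rng, config)
            for k_j, j in enumerate(ev.junctions):
                data[row + k_j, col] = counts[j]
        row += njunc
    raw = pd.DataFrame(data, index=pd.Index(junctions, name="junction_id"),
                       columns=sample_ids)
    return JunctionCountMatrix(raw, raw.astype(float))


def simulate_single_sample_counts(
    events: Sequence[ASEvent],
    psi_by_event: Mapping[str, float],
    config: SimulationConfig,
    sample_id: str,
    *,
    stream: int = 3,
) -> JunctionCountMatrix:
    """Counts for one extra sample (e.g. a knockdown or its control) at the
    given per-event true inclusion levels."""
    rng = np.random.default_rng([config.seed, stream])
    junctions = [j for ev in events for j in ev.junctions]
    values = np.zeros(len(junctions), dtype=int)
    row = 0
    for ev in events:
        counts = _draw_event_counts(ev, float(psi_by_event[ev.event_id]), rng, config)
        for k_j, j in enumerate(ev.junctions):
            values[row + k_j] = counts[j]
        row += len(ev.junctions)
    raw = pd.DataFrame(
        {sample_id: values}, index=pd.Index(junctions, name="junction_id")
    )
    return JunctionCountMatrix(raw, raw.astype(float))


# -- motif-map sequences -----------------------------------------------------

_RNA = np.frombuffer(b"ACGU", dtype=np.uint8)


def _random_rna(rng: np.random.Generator, n: int) -> str:
    return _RNA[rng.integers(0, 4, size=n)].tobytes().decode()


def _plant(seq: str, motif: str, copies: int, rng: np.random.Generator) -> str:
    """Overwrite up to ``copies`` non-overlapping occurrences of the motif."""
    m = len(motif)
    max_copies = len(seq) // m
    copies = min(copies, max_copies)
    if copies <= 0:
        return seq
    slots = len(seq) - m + 1
    chars = list(seq)
    placed: list[int] = []
    attempts = 0
    while len(placed) < copies and attempts < 200:
        pos = int(rng.integers(0, slots))
        if all(abs(pos - q) >= m for q in placed):
            placed.append(pos)
            chars[pos : pos + m] = motif
        attempts += 1
    return "".join(chars)


def simulate_sequences(
    event_ids: Sequence[str],
    planted_ids: Sequence[str],
    config: SimulationConfig,
    *,
    include_short_introns: bool = False,
    stream: int = 4,
) -> tuple[dict[str, EventSequences], pd.DataFrame]:
    """Flanking-intron and exon sequences for a motif-map analysis.

    Background sequence is i.i.d. uniform over ACGU.  Every 20-nt bin of
    every event receives Poisson(``motif_base_rate``) planted copies of the
    configured motif; for events in ``planted_ids`` the rate in the target
    bin is multiplied by the configured factor.  With
    ``include_short_introns`` a fifth of upstream introns are emitted at
    150 nt to exercise the short-intron exclusion.
    """
    motif, target_bin, multiplier = config.planted_motif
    if len(motif) > BIN_SIZE:
        raise ValueError("planted motif longer than a bin")
    rng = np.random.default_rng([config.seed, stream])
    planted = set(planted_ids)
    records = []
    out: dict[str, EventSequences] = {}
    for eid in event_ids:
        up_len = config.intron_length
        if include_short_introns and rng.random() < 0.2:
            up_len = 150
        exon_len = int(rng.integers(*config.exon_length_range))

        def _build_intron(side: str, length: int) -> str:
            if length < 160:
                return _random_rna(rng, length)
            pieces = []
            n_planted = 0
            for b in range(1, 9):
                label = f"BIN_{side}{b}"
                rate = config.motif_base_rate
                if eid in planted and label == target_bin:
                    rate *= multiplier
                copies = int(rng.poisson(rate))
                piece = _plant(_random_rna(rng, BIN_SIZE), motif, copies, rng)
                pieces.append(piece)
                n_planted += copies
                if b == 4:
                    pieces.append(_random_rna(rng, length - 160))
            records.append((eid, side, n_planted))
            return "".join(pieces)

        up = _build_intron("U", up_len)
        exon = _plant(
            _random_rna(rng, exon_len),
            motif,
            int(rng.poisson(config.motif_base_rate)),
            rng,
        )
        down = _build_intron("D", config.intron_length)
        out[eid] = EventSequences(up, exon, down)
    record = pd.DataFrame(records, columns=["event_id", "intron_side", "planted_copies"])
    return out, record


# -- ORF truth-table transcripts ---------------------------------------------

@dataclass(frozen=True)
class OrfCase:
    """One constructed transcript/event pair with its hand-derived label."""

    case_id: str
    event: ASEvent
    transcript: TranscriptModel
    genome: dict[str, str]
    expected_region: Region
    expected_impact: Impact
    expected_nmd: bool
    expected_truncation: int | None = None  # None: not asserted


_FILLER = "GCA"  # no stop codon in any frame, contains no T
_UTR5 = "GCAGCAGCA"
_UTR3 = "TTAATTAATTAA" + _FILLER * 4  # stop codons reachable in all 3 frames


def _cassette_case(
    frame: int, stop_kind: str, truncation_large: bool, strand: str
) -> OrfCase:
    """Unannotated cassette exon inserted mid-CDS between exons 1 and 2."""
    case_id = f"f{frame}_{stop_kind}_{'big' if truncation_large else 'small'}_{strand}"
    n1c = 20  # filler codons in exon 1 after ATG
    c3 = 150 if truncation_large else 20  # CDS codons in exon 3
    n2c = {"nmd": 40, "near": 10, "none": 20}[stop_kind]
    alt_len = 81 + frame

    # alternative exon content
    alt = _FILLER * (alt_len // 3) + "G" * (alt_len % 3)
    a_pre = None
    if frame == 0 and stop_kind in ("nmd", "near"):
        a_pre = 10 if stop_kind == "nmd" else 25
        alt = _FILLER * a_pre + "TAA" + _FILLER * (27 - a_pre - 1)

    # exon 2 content (may carry the shifted-frame stop)
    # a +f nt insertion puts shifted-frame codon starts at exon-2 offsets
    # congruent to (3 - f) mod 3; the six-mers below carry TAA exactly there
    # while reading as stop-free codons in the annotated frame
    exon2 = _FILLER * n2c
    if frame and stop_kind in ("nmd", "near"):
        six = "CCTAAC" if frame == 1 else "CTAACA"
        q = 30 if stop_kind == "nmd" else 18
        exon2 = exon2[:q] + six + exon2[q + 6 :]

    exon1 = _UTR5 + "ATG" + _FILLER * n1c
    exon3 = _FILLER * c3 + "TAA" + _UTR3
    intron = "CA" * 100  # no T: silent if ever read

    seq = exon1 + intron + alt + intron + exon2 + intron + exon3
    p = 1
    iv = {}
    for name, part in (
        ("exon1", exon1),
        ("i1a", intron),
        ("alt", alt),
        ("i1b", intron),
        ("exon2", exon2),
        ("i2", intron),
        ("exon3", exon3),
    ):
        iv[name] = (p, p + len(part) - 1)
        p += len(part)

    # transcript coords: CDS runs from the ATG to the end of the TAA
    cds_start = len(_UTR5) + 1
    cds_end = len(exon1) + len(exon2) + 3 * c3 + 3

    exons = (iv["exon1"], iv["exon2"], iv["exon3"])
    scaffold = f"orf_{case_id}"
    alt_span = iv["alt"]
    if strand == "-":
        L = len(seq)
        seq = _revcomp(seq)
        flip = lambda t: (L - t[1] + 1, L - t[0] + 1)
        exons = tuple(flip(e) for e in exons)  # descending order = 5'->3'
        alt_span = flip(alt_span)

    transcript = TranscriptModel(
        transcript_id=f"t_{case_id}",
        scaffold=scaffold,
        strand=strand,
        exons=exons,
        cds_start=cds_start,
        cds_end=cds_end,
    )
    event = ASEvent(
        event_id=f"e_{case_id}",
        event_type=EventType.EX_SINGLE,
        gene_id=f"g_{case_id}",
        scaffold=scaffold,
        strand=strand,
        alt_spans=(alt_span,),
        alt_length=alt_len,
        inclusion_junctions=(f"{case_id}_C1A", f"{case_id}_AC2"),
        exclusion_junctions=(f"{case_id}_C1C2",),
    )

    annotated_aa = 1 + n1c + n2c + c3
    if frame == 0:
        if stop_kind == "none":
            expected = (Impact.ORF_PRESERVING, False, 0)
        else:
            trunc = annotated_aa - (1 + n1c + a_pre)
            if stop_kind == "nmd":
                expected = (Impact.DISRUPT_ON_INCLUSION, True, trunc)
            elif trunc > 100:
                expected = (Impact.DISRUPT_ON_INCLUSION, False, trunc)
            else:
                expected = (Impact.ORF_PRESERVING, False, trunc)
    else:
        nmd = stop_kind == "nmd"
        expected = (Impact.DISRUPT_ON_INCLUSION, nmd, None)
    return OrfCase(
        case_id=case_id,
        event=event,
        transcript=transcript,
        genome={scaffold: seq},
        expected_region=Region.CDS,
        expected_impact=expected[0],
        expected_nmd=expected[1],
        expected_truncation=expected[2],
    )


def _ir_case() -> OrfCase:
    """Retained intron carrying a frame-aligned NMD-positioned stop."""
    case_id = "ir_nmd"
    n1c, n2c, c3 = 20, 40, 40
    exon1 = _UTR5 + "ATG" + _FILLER * n1c
    ir = _FILLER * 10 + "TAA" + _FILLER * 16  # 81 nt, stop at codon 11
    exon2 = _FILLER * n2c
    exon3 = _FILLER * c3 + "TAA" + _UTR3
    intron2 = "CA" * 90
    seq = exon1 + ir + exon2 + intron2 + exon3
    e1 = (1, len(exon1))
    irs = (len(exon1) + 1, len(exon1) + len(ir))
    e2 = (irs[1] + 1, irs[1] + len(exon2))
    e3 = (e2[1] + len(intron2) + 1, e2[1] + len(intron2) + len(exon3))
    scaffold = f"orf_{case_id}"
    transcript = TranscriptModel(
        transcript_id=f"t_{case_id}",
        scaffold=scaffold,
        strand="+",
        exons=(e1, e2, e3),
        cds_start=len(_UTR5) + 1,
        cds_end=len(exon1) + len(exon2) + 3 * c3 + 3,
    )
    event = ASEvent(
        event_id=f"e_{case_id}",
        event_type=EventType.IR,
        gene_id=f"g_{case_id}",
        scaffold=scaffold,
        strand="+",
        alt_spans=(irs,),
        alt_length=len(ir),
        inclusion_junctions=(f"{case_id}_EI1", f"{case_id}_EI2"),
        exclusion_junctions=(f"{case_id}_skip",),
    )
    trunc = (1 + n1c + n2c + c3) - (1 + n1c + 10)
    return OrfCase(
        case_id=case_id,
        event=event,
        transcript=transcript,
        genome={scaffold: seq},
        expected_region=Region.CDS,
        expected_impact=Impact.DISRUPT_ON_INCLUSION,
        expected_nmd=True,
        expected_truncation=trunc,
    )


def _annotated_exclusion_case() -> OrfCase:
    """Annotated frame-shifting cassette exon: exclusion disrupts the ORF."""
    case_id = "annot_excl"
    mrna_cds = "ATG" + _FILLER * 80 + "TAA"
    mrna = _UTR5 + mrna_cds + _UTR3
    # cut the mRNA into 4 exons; exon 2 (the alternative one) is 82 nt
    parts = [mrna[:60], mrna[60:142], mrna[142:220], mrna[220:]]
    intron = "CA" * 100
    seq = ""
    exons = []
    p = 1
    for i, part in enumerate(parts):
        if i:
            seq += intron
            p += len(intron)
        exons.append((p, p + len(part) - 1))
        seq += part
        p += len(part)
    scaffold = f"orf_{case_id}"
    transcript = TranscriptModel(
        transcript_id=f"t_{case_id}",
        scaffold=scaffold,
        strand="+",
        exons=tuple(exons),
        cds_start=len(_UTR5) + 1,
        cds_end=len(_UTR5) + len(mrna_cds),
    )
    event = ASEvent(
        event_id=f"e_{case_id}",
        event_type=EventType.EX_SINGLE,
        gene_id=f"g_{case_id}",
        scaffold=scaffold,
        strand="+",
        alt_spans=(exons[1],),
        alt_length=82,
        inclusion_junctions=(f"{case_id}_C1A", f"{case_id}_AC2"),
        exclusion_junctions=(f"{case_id}_C1C2",),
    )
    return OrfCase(
        case_id=case_id,
        event=event,
        transcript=transcript,
        genome={scaffold: seq},
        expected_region=Region.CDS,
        expected_impact=Impact.DISRUPT_ON_EXCLUSION,
        expected_nmd=False,
        expected_truncation=None,
    )


def _start_overlap_case() -> OrfCase:
    """Annotated alternative exon containing the start codon."""
    case_id = "start_overlap"
    mrna_cds = "ATG" + _FILLER * 40 + "TAA"
    mrna = _UTR5 + mrna_cds + _UTR3
    parts = [mrna[:6], mrna[6:48], mrna[48:]]  # exon 2 spans the ATG
    intron = "CA" * 100
    seq = ""
    exons = []
    p = 1
    for i, part in enumerate(parts):
        if i:
            seq += intron
            p += len(intron)
        exons.append((p, p + len(part) - 1))
        seq += part
        p += len(part)
    scaffold = f"orf_{case_id}"
    transcript = TranscriptModel(
        transcript_id=f"t_{case_id}",
        scaffold=scaffold,
        strand="+",
        exons=tuple(exons),
        cds_start=len(_UTR5) + 1,
        cds_end=len(_UTR5) + len(mrna_cds),
    )
    event = ASEvent(
        event_id=f"e_{case_id}",
        event_type=EventType.EX_SINGLE,
        gene_id=f"g_{case_id}",
        scaffold=scaffold,
        strand="+",
        alt_spans=(exons[1],),
        alt_length=42,
        inclusion_junctions=(f"{case_id}_C1A", f"{case_id}_AC2"),
        exclusion_junctions=(f"{case_id}_C1C2",),
    )
    return OrfCase(
        case_id=case_id,
        event=event,
        transcript=transcript,
        genome={scaffold: seq},
        expected_region=Region.MIXED,
        expected_impact=Impact.DISRUPT_ON_EXCLUSION,
        expected_nmd=False,
        expected_truncation=41,
    )


def simulate_transcripts(include_extras: bool = True) -> list[OrfCase]:
    """The full factorial of frame x stop-position x truncation x strand
    cassette cases (36), plus intron-retention, annotated-exclusion and
    start-codon-overlap extras."""
    cases = [
        _cassette_case(frame, stop_kind, big, strand)
        for frame in (0, 1, 2)
        for stop_kind in ("none", "nmd", "near")
        for big in (False, True)
        for strand in ("+", "-")
    ]
    if include_extras:
        cases += [_ir_case(), _annotated_exclusion_case(), _start_overlap_case()]
    return cases
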