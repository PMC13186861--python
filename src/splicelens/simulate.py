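"""Synthetic amplicon study generator.

Emulates a targeted long-read experiment on a single multi-exon gene:
an amplicon spanning from a forward primer near the annotated ATG to a
reverse primer in the last exon, sequenced as mostly full-length reads
with a truncated minority, across barcoded libraries.  Truth isoforms are
built from a small event grammar (exon skipping, intron retention,
alternative donor/acceptor, cryptic exon) applied to the canonical chain.

Alignments are written directly from truth as SAM (no aligner is run), so
every downstream stage is testable offline and deterministically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import pysam

from .coords import CoordinateMap
from .core import GenomeAnnotation, Genome, GenomicInterval, TranscriptModel

logger = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}
_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


# --------------------------------------------------------------------------
# event grammar


@dataclass(frozen=True)
class SkipExon:
    exon: int  # 1-based, transcription order

    def short(self) -> str:
        return f"skip_e{self.exon}"


@dataclass(frozen=True)
class RetainIntron:
    intron: int  # intron i lies between exons i and i+1

    def short(self) -> str:
        return f"ri_i{self.intron}"


@dataclass(frozen=True)
class AltDonor:
    intron: int
    delta: int  # nt, + = downstream in transcription direction (extends exon)

    def short(self) -> str:
        return f"altd_i{self.intron}{self.delta:+d}"


@dataclass(frozen=True)
class AltAcceptor:
    intron: int
    delta: int  # nt, + = downstream in transcription direction (shortens exon)

    def short(self) -> str:
        return f"alta_i{self.intron}{self.delta:+d}"


@dataclass(frozen=True)
class CrypticExon:
    intron: int
    offset: int  # nt from the intron's 5' end (transcription direction)
    length: int

    def short(self) -> str:
        return f"cx_i{self.intron}_{self.offset}_{self.length}"


Event = Union[SkipExon, RetainIntron, AltDonor, AltAcceptor, CrypticExon]


def parse_event(text: str) -> Event:
    """Parse a colon-separated event spec, e.g. ``skip_exon:3``,
    ``retain_intron:1``, ``alt_donor:2:+12``, ``cryptic_exon:4:50:127``."""
    parts = text.strip().split(":")
    kind, args = parts[0], [int(p) for p in parts[1:]]
    if kind == "skip_exon":
        return SkipExon(*args)
    if kind == "retain_intron":
        return RetainIntron(*args)
    if kind == "alt_donor":
        return AltDonor(*args)
    if kind == "alt_acceptor":
        return AltAcceptor(*args)
    if kind == "cryptic_exon":
        return CrypticExon(*args)
    raise ValueError(f"unknown event spec {text!r}")


# --------------------------------------------------------------------------
# configuration


def _default_isoforms() -> list[tuple[tuple[Event, ...], float]]:
    # one representative of each event class plus the canonical chain
    return [
        ((SkipExon(3),), 0.4),
        ((RetainIntron(1),), 0.2),
        ((AltDonor(2, 12),), 0.2),
        ((CrypticExon(4, 50, 127),), 0.1),
        ((), 0.1),
    ]


@dataclass
class SimConfig:
    """Parameters of one simulated amplicon study."""

    n_exons: int = 10
    exon_len_range: tuple[int, int] = (120, 300)
    intron_len_range: tuple[int, int] = (250, 600)
    strand: str = "+"
    seed: int = 0
    isoforms: list[tuple[tuple[Event, ...], float]] = field(default_factory=_default_isoforms)
    n_reads: int = 2000
    full_length_frac: float = 0.8
    truncation_model: str = "both"  # uniform_5p | uniform_3p | both
    junction_jitter_sd: float = 0.0
    libraries: list[tuple[str, float]] = field(
        default_factory=lambda: [("breast", 0.4), ("ovarian", 0.4), ("cervical", 0.2)]
    )
    chrom: str = "chrS"
    gene_id: str = "GENE1"
    flank: int = 200
    atg_offset: Optional[int] = None  # nt into exon 1; default exon1_len // 3

    def __post_init__(self) -> None:
        if not (0.0 <= self.full_length_frac <= 1.0):
            raise ValueError("full_length_frac must be in [0, 1]")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        weights = [w for _, w in self.isoforms]
        if any(w < 0 for w in weights) or sum(weights) <= 0:
            raise ValueError("isoform weights must be >= 0 and not all zero")
        if self.truncation_model not in ("uniform_5p", "uniform_3p", "both"):
            raise ValueError(f"unknown truncation model {self.truncation_model!r}")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be + or -")

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        data = dict(data)
        if "isoforms" in data:
            parsed = []
            for item in data["isoforms"]:
                events = tuple(parse_event(e) for e in item.get("events", []))
                parsed.append((events, float(item["weight"])))
            data["isoforms"] = parsed
        if "libraries" in data:
            data["libraries"] = [(str(l), float(w)) for l, w in data["libraries"]]
        for key in ("exon_len_range", "intron_len_range"):
            if key in data:
                data[key] = tuple(int(v) for v in data[key])
        return cls(**data)


# --------------------------------------------------------------------------
# gene construction


def build_gene(config: SimConfig) -> tuple[GenomeAnnotation, dict[str, str]]:
    """Build a random gene locus whose canonical transcript has a clean ORF.

    The sequence is drawn at random, GT..AG dinucleotides are written at
    every annotated intron boundary, ATG is written into exon 1 at a
    recorded offset, any premature in-frame stop codon in the canonical
    frame is repaired (third codon base rewritten), and a TAA stop is
    placed in-frame inside the last exon.
    """
    rng = np.random.default_rng(config.seed)
    lo_e, hi_e = config.exon_len_range
    lo_i, hi_i = config.intron_len_range
    if lo_e < 30 or lo_i < 4 or lo_e > hi_e or lo_i > hi_i:
        raise ValueError("infeasible exon/intron length ranges")
    exon_lens = rng.integers(lo_e, hi_e + 1, size=config.n_exons)
    intron_lens = rng.integers(lo_i, hi_i + 1, size=max(config.n_exons - 1, 0))

    total = 2 * config.flank + int(exon_lens.sum() + intron_lens.sum())
    seq = _BASES[rng.integers(0, 4, size=total)].copy()

    # lay out on the plus sense; mirror afterwards for minus-strand genes
    exons: list[GenomicInterval] = []
    pos = config.flank
    for k, el in enumerate(exon_lens):
        exons.append(GenomicInterval(config.chrom, pos, pos + int(el), "+"))
        pos += int(el)
        if k < len(intron_lens):
            il = int(intron_lens[k])
            seq[pos], seq[pos + 1] = "G", "T"
            seq[pos + il - 2], seq[pos + il - 1] = "A", "G"
            pos += il

    atg_offset = config.atg_offset if config.atg_offset is not None else int(exon_lens[0]) // 3
    if not (0 <= atg_offset <= int(exon_lens[0]) - 3):
        raise ValueError("atg_offset does not fit inside exon 1")
    atg_pos = exons[0].start + atg_offset
    seq[atg_pos], seq[atg_pos + 1], seq[atg_pos + 2] = "A", "T", "G"

    cmap = CoordinateMap(exons)
    t_atg = cmap.genomic_to_transcript(atg_pos)
    # in-frame stop fully inside the last exon, ~1/3 in, leaving a 3' UTR
    last_off = cmap.length - int(exon_lens[-1])
    stop_t = last_off + int(exon_lens[-1]) // 3
    stop_t += (t_atg - stop_t) % 3
    if not (last_off <= stop_t and stop_t + 3 <= cmap.length):
        raise ValueError("last exon too short to host an in-frame stop codon")

    def gpos(t: int) -> int:
        return cmap.transcript_to_genomic(t)

    for t in range(t_atg, stop_t, 3):
        codon = seq[gpos(t)] + seq[gpos(t + 1)] + seq[gpos(t + 2)]
        if codon in STOP_CODONS:
            seq[gpos(t + 2)] = "C"  # TAA->TAC, TAG->TAC, TGA->TGC: all sense
    for base, t in zip("TAA", range(stop_t, stop_t + 3)):
        seq[gpos(t)] = base

    genome_seq = "".join(seq)
    start_codon_pos = atg_pos
    if config.strand == "-":
        genome_seq = genome_seq[::-1].translate(_COMPLEMENT)
        exons = [
            GenomicInterval(config.chrom, total - e.end, total - e.start, "-") for e in exons
        ]
        start_codon_pos = total - 1 - atg_pos

    # exon 1 first: ascending genomic order on +; the mirror transform already
    # leaves the minus-strand list genomically descending (5'-most first)
    chain = tuple(exons)
    genomic = sorted(chain, key=lambda e: e.start)
    annotation = GenomeAnnotation(
        gene_id=config.gene_id,
        locus=GenomicInterval(config.chrom, genomic[0].start, genomic[-1].end, config.strand),
        exons=chain,
        start_codon_pos=start_codon_pos,
        transcripts={f"{config.gene_id}.v1": chain},
        canonical_name=f"{config.gene_id}.v1",
    )
    return annotation, {config.chrom: genome_seq}


# --------------------------------------------------------------------------
# isoform realization


def realize_isoform(
    annotation: GenomeAnnotation, events: Sequence[Event], isoform_id: Optional[str] = None
) -> TranscriptModel:
    """Apply an event list to the canonical exon chain.

    Events are indexed by annotated exon/intron number (1-based,
    transcription order).  Mutually incompatible events raise ValueError.
    """
    n = len(annotation.exons)
    strand = annotation.strand
    skipped = {e.exon for e in events if isinstance(e, SkipExon)}
    retained = {e.intron for e in events if isinstance(e, RetainIntron)}

    for e in events:
        if isinstance(e, SkipExon) and not (1 <= e.exon <= n):
            raise ValueError(f"skip_exon target {e.exon} out of range")
        if isinstance(e, (RetainIntron, AltDonor, AltAcceptor, CrypticExon)) and not (
            1 <= e.intron <= n - 1
        ):
            raise ValueError(f"intron target {e.intron} out of range")
    for i in retained:
        if i in skipped or (i + 1) in skipped:
            raise ValueError(f"retain_intron({i}) conflicts with skipping a flanking exon")
    for e in events:
        if isinstance(e, (AltDonor, AltAcceptor, CrypticExon)) and e.intron in retained:
            raise ValueError(f"event on intron {e.intron} conflicts with its retention")
        if isinstance(e, AltDonor) and e.intron in skipped:
            raise ValueError(f"alt_donor({e.intron}) conflicts with skipping exon {e.intron}")
        if isinstance(e, AltAcceptor) and (e.intron + 1) in skipped:
            raise ValueError(f"alt_acceptor({e.intron}) conflicts with skipping exon {e.intron + 1}")
    if len({e.short() for e in events}) != len(events):
        raise ValueError("duplicate events")

    # mutable [5'boundary, 3'boundary) per exon in transcription coordinates
    bounds: list[Optional[list[int]]] = []
    for e in annotation.exons:
        bounds.append([e.start, e.end] if strand == "+" else [e.end, e.start])
    # in the strand == "-" representation bounds[i] = [genomic_end, genomic_start]:
    # index 0 is the transcript-5' edge, index 1 the transcript-3' edge

    def shift_3p_edge(i: int, delta: int) -> None:  # donor of intron i = 3' edge of exon i
        bounds[i - 1][1] += delta if strand == "+" else -delta

    def shift_5p_edge(i: int, delta: int) -> None:  # acceptor of intron i = 5' edge of exon i+1
        bounds[i][0] += delta if strand == "+" else -delta

    for e in events:
        if isinstance(e, AltDonor):
            shift_3p_edge(e.intron, e.delta)
        elif isinstance(e, AltAcceptor):
            shift_5p_edge(e.intron, e.delta)

    cryptic: list[GenomicInterval] = []
    for e in events:
        if isinstance(e, CrypticExon):
            donor_edge = annotation.exons[e.intron - 1]
            if strand == "+":
                s = donor_edge.end + e.offset
                cryptic.append(GenomicInterval(annotation.chrom, s, s + e.length, "+"))
            else:
                g5 = donor_edge.start  # intron's 5' end on the minus strand
                cryptic.append(
                    GenomicInterval(annotation.chrom, g5 - e.offset - e.length, g5 - e.offset, "-")
                )

    for i in sorted(retained, reverse=True):
        a, b = bounds[i - 1], bounds[i]
        if a is None or b is None:
            raise ValueError("retained intron flanks a skipped exon")
        bounds[i - 1] = [a[0], b[1]]
        bounds[i] = None

    for i in skipped:
        bounds[i - 1] = None

    chain = []
    for b in bounds:
        if b is None:
            continue
        s, t = (b[0], b[1]) if strand == "+" else (b[1], b[0])
        if not s < t:
            raise ValueError("event produced an empty or inverted exon")
        chain.append(GenomicInterval(annotation.chrom, s, t, strand))
    chain.extend(cryptic)
    chain.sort(key=lambda e: e.start)
    for a, b in zip(chain, chain[1:]):
        if b.start <= a.end:
            raise ValueError("events produce overlapping or abutting exons")

    name = isoform_id or ("canonical" if not events else "+".join(e.short() for e in events))
    return TranscriptModel(id=name, exon_chain=tuple(chain))


# --------------------------------------------------------------------------
# read simulation


def _jitter_blocks(
    blocks: list[GenomicInterval], sd: float, rng: np.random.Generator
) -> list[GenomicInterval]:
    """Perturb each junction boundary with N(0, sd), keeping every block and
    intron at least 1 nt."""
    coords = [[b.start, b.end] for b in blocks]
    for j in range(len(coords) - 1):
        d = int(round(rng.normal(0.0, sd)))
        coords[j][1] = max(coords[j][0] + 1, min(coords[j][1] + d, coords[j + 1][0] - 1))
        d = int(round(rng.normal(0.0, sd)))
        coords[j + 1][0] = max(coords[j][1] + 1, min(coords[j + 1][0] + d, coords[j + 1][1] - 1))
    return [GenomicInterval(blocks[0].chrom, s, e, blocks[0].strand) for s, e in coords]


def simulate_alignments(
    annotation: GenomeAnnotation,
    genome: dict[str, str],
    isoforms: Sequence[TranscriptModel],
    config: SimConfig,
    sam_path: str | Path,
) -> pd.DataFrame:
    """Write truth-derived spliced alignments as SAM; return the truth table.

    Per read: isoform drawn from the (normalized) abundance weights, library
    from the library weights, full-length with probability full_length_frac,
    otherwise truncated per the truncation model; junction boundaries
    jittered with sd ``junction_jitter_sd`` (default 0 = polished reads).
    """
    rng = np.random.default_rng(config.seed + 1)
    weights = np.array([w for _, w in config.isoforms], dtype=float)
    p_iso = weights / weights.sum()
    lib_labels = [l for l, _ in config.libraries]
    lib_w = np.array([w for _, w in config.libraries], dtype=float)
    p_lib = lib_w / lib_w.sum()

    counts = rng.multinomial(config.n_reads, p_iso)
    iso_of_read = np.repeat(np.arange(len(isoforms)), counts)
    rng.shuffle(iso_of_read)
    lib_of_read = rng.choice(len(lib_labels), size=config.n_reads, p=p_lib)
    full_length = rng.random(config.n_reads) < config.full_length_frac

    genome_acc = Genome(genome)
    maps = [CoordinateMap(m.exon_chain) for m in isoforms]

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": len(genome[c])} for c in sorted(genome)],
        "RG": [{"ID": l, "SM": l, "PL": "ONT"} for l in lib_labels],
    }
    flag = 16 if annotation.strand == "-" else 0
    truth_rows = []
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as out:
        for ridx in range(config.n_reads):
            iso = isoforms[int(iso_of_read[ridx])]
            cmap = maps[int(iso_of_read[ridx])]
            L = cmap.length
            a, b = 0, L
            if not full_length[ridx] and L > 2:
                if config.truncation_model == "uniform_5p":
                    a = int(rng.integers(1, L))
                elif config.truncation_model == "uniform_3p":
                    b = int(rng.integers(1, L))
                else:
                    if rng.integers(0, 2) == 0:
                        a = int(rng.integers(1, L))
                    else:
                        b = int(rng.integers(1, L))
            blocks = list(cmap.transcript_interval_to_blocks(a, b))
            if config.junction_jitter_sd > 0 and len(blocks) > 1:
                blocks = _jitter_blocks(blocks, config.junction_jitter_sd, rng)

            read_id = f"r{ridx:06d}"
            library = lib_labels[int(lib_of_read[ridx])]
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = read_id
            seg.flag = flag
            seg.reference_id = out.header.references.index(annotation.chrom)
            seg.reference_start = blocks[0].start
            seg.mapping_quality = 60
            cig = []
            for k, blk in enumerate(blocks):
                if k:
                    cig.append((3, blk.start - blocks[k - 1].end))
                cig.append((0, len(blk)))
            seg.cigartuples = cig
            seg.query_sequence = "".join(
                genome_acc.fetch(blk.chrom, blk.start, blk.end) for blk in blocks
            )
            seg.set_tag("RG", library, "Z")
            out.write(seg)
            truth_rows.append(
                {
                    "read_id": read_id,
                    "isoform_id": iso.id,
                    "library": library,
                    "is_full_length": bool(full_length[ridx]),
                }
            )
    return pd.DataFrame(truth_rows, columns=["read_id", "isoform_id", "library", "is_full_length"])


def simulate(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Run the whole generator: genome.fa, annotation.gtf, reads.sam, truth.tsv."""
    from .io import write_annotation_gtf, write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation, genome = build_gene(config)
    isoforms = [realize_isoform(annotation, events) for events, _ in config.isoforms]

    paths = {
        "genome": outdir / "genome.fa",
        "gtf": outdir / "annotation.gtf",
        "sam": outdir / "reads.sam",
        "truth": outdir / "truth.tsv",
    }
    write_fasta([(config.chrom, genome[config.chrom])], paths["genome"])
    write_annotation_gtf(annotation, paths["gtf"])
    truth = simulate_alignments(annotation, genome, isoforms, config, paths["sam"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    logger.info("simulated %d reads over %d isoforms", config.n_reads, len(isoforms))
    return paths
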