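"""Core data model shared by every pipeline stage.

All coordinates are 0-based half-open genomic intervals; conversion to the
1-based inclusive GTF convention happens only inside the I/O layer.  Exon
numbering is strand-aware: exon 1 is the 5'-most exon of the transcript,
which is the genomically *last* exon on the minus strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "GenomicInterval",
    "GenomeAnnotation",
    "SplicedAlignment",
    "DomainDefinition",
    "IntronChain",
    "SpliceEvent",
    "TranscriptModel",
    "OrfResult",
    "DomainCall",
    "ExpressionRecord",
    "Genome",
    "introns_of",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on one strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def contains(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start <= other.start and other.end <= self.end

    def contains_pos(self, pos: int) -> bool:
        return self.start <= pos < self.end


class Genome:
    """Sequence accessor over a chrom -> sequence mapping or a pyfaidx.Fasta."""

    def __init__(self, source: Mapping[str, str]):
        self._source = source

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self._source[chrom]
        return str(seq[start:end]).upper()

    def chrom_length(self, chrom: str) -> int:
        return len(self._source[chrom])

    def chroms(self) -> list[str]:
        return list(self._source.keys())


def introns_of(exons: Sequence[GenomicInterval]) -> tuple[GenomicInterval, ...]:
    """Introns between consecutive genomically-sorted exons."""
    sorted_exons = sorted(exons, key=lambda e: e.start)
    out = []
    for a, b in zip(sorted_exons, sorted_exons[1:]):
        if b.start <= a.end:
            raise ValueError("exons overlap or abut; no intron between them")
        out.append(GenomicInterval(a.chrom, a.end, b.start, a.strand))
    return tuple(out)


@dataclass
class GenomeAnnotation:
    """Annotation of one gene locus with a designated canonical transcript.

    ``exons`` are the canonical transcript's exons in transcription order
    (exon 1 first); they double as the reference ladder against which model
    exons are classified.  ``transcripts`` maps every annotated transcript
    name to its exon chain (transcription order) for identity matching.
    """

    gene_id: str
    locus: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    start_codon_pos: int
    transcripts: dict[str, tuple[GenomicInterval, ...]] = field(default_factory=dict)
    canonical_name: str = "canonical"

    def __post_init__(self) -> None:
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if b.start < a.end:
                raise ValueError(f"annotated exons overlap: {a} / {b}")
        want = genomic if self.strand == "+" else genomic[::-1]
        if list(self.exons) != want:
            raise ValueError("exons must be given in transcription order")
        if not any(e.contains_pos(self.start_codon_pos) for e in self.exons):
            raise ValueError("start codon lies outside all canonical exons")
        if self.canonical_name not in self.transcripts:
            self.transcripts[self.canonical_name] = tuple(self.exons)

    @property
    def chrom(self) -> str:
        return self.locus.chrom

    @property
    def strand(self) -> str:
        return self.locus.strand

    @property
    def exons_genomic(self) -> tuple[GenomicInterval, ...]:
        """Canonical exons sorted by genomic coordinate."""
        return tuple(sorted(self.exons, key=lambda e: e.start))

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        """Canonical introns in transcription order (intron i follows exon i)."""
        gen = introns_of(self.exons)
        return gen if self.strand == "+" else gen[::-1]

    @property
    def last_exon(self) -> GenomicInterval:
        """3'-most canonical exon (target of the reverse amplicon primer)."""
        return self.exons[-1]

    def exon_number(self, exon: GenomicInterval) -> Optional[int]:
        """1-based strand-aware number of an annotated exon, or None."""
        for i, e in enumerate(self.exons, start=1):
            if (e.start, e.end) == (exon.start, exon.end):
                return i
        return None


@dataclass(frozen=True)
class SplicedAlignment:
    """One read's aligned blocks (gaps between blocks are introns)."""

    read_id: str
    blocks: tuple[GenomicInterval, ...]
    library: str = "default"
    mapq: int = 60

    def __post_init__(self) -> None:
        for a, b in zip(self.blocks, self.blocks[1:]):
            if b.start <= a.end:
                raise ValueError(f"{self.read_id}: blocks unsorted or gap < 1 nt")
            if a.chrom != b.chrom:
                raise ValueError(f"{self.read_id}: blocks on multiple chromosomes")

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.blocks[0].chrom, self.blocks[0].start, self.blocks[-1].end, self.blocks[0].strand
        )


@dataclass(frozen=True)
class DomainDefinition:
    """Conserved protein domain as a 1-based inclusive aa interval."""

    name: str
    aa_start: int
    aa_end: int

    def __post_init__(self) -> None:
        if not (1 <= self.aa_start <= self.aa_end):
            raise ValueError(f"domain {self.name}: invalid interval {self.aa_start}-{self.aa_end}")

    @property
    def length(self) -> int:
        return self.aa_end - self.aa_start + 1


@dataclass(frozen=True)
class IntronChain:
    """Ordered intron coordinates; identical chains define one splice variant."""

    introns: tuple[GenomicInterval, ...] = ()

    @classmethod
    def from_exons(cls, exons: Sequence[GenomicInterval]) -> "IntronChain":
        return cls(introns_of(exons))

    def key(self) -> tuple[tuple[int, int], ...]:
        return tuple((i.start, i.end) for i in self.introns)

    def __len__(self) -> int:
        return len(self.introns)


@dataclass(frozen=True)
class SpliceEvent:
    """One named splicing difference relative to the canonical transcript."""

    type: str  # exon_skipping | intron_retention | alt_donor | alt_acceptor | cryptic_exon | alt_terminal_exon
    target: Optional[int] = None  # annotated exon/intron number (1-based, strand-aware)
    delta: Optional[int] = None  # signed nt shift, transcription direction (alt sites)
    interval: Optional[GenomicInterval] = None  # cryptic exon coordinates

    def describe(self) -> str:
        if self.type == "exon_skipping":
            return f"exon_skipping(exon {self.target})"
        if self.type == "intron_retention":
            return f"intron_retention(intron {self.target})"
        if self.type in ("alt_donor", "alt_acceptor"):
            return f"{self.type}(intron {self.target}, {self.delta:+d} nt)"
        if self.type == "cryptic_exon":
            iv = self.interval
            return f"cryptic_exon({iv.chrom}:{iv.start}-{iv.end})"
        return f"{self.type}({'5prime' if self.target == 1 else '3prime'})"


@dataclass
class TranscriptModel:
    """A discovered (or simulated truth) isoform.

    ``exon_chain`` is kept in genomic order regardless of strand; transcript
    order is derived where needed from the strand.
    """

    id: str
    exon_chain: tuple[GenomicInterval, ...]
    exon_labels: tuple[str, ...] = ()
    support: dict[str, int] = field(default_factory=dict)
    events: tuple[SpliceEvent, ...] = ()

    @property
    def chrom(self) -> str:
        return self.exon_chain[0].chrom

    @property
    def strand(self) -> str:
        return self.exon_chain[0].strand

    @property
    def intron_chain(self) -> IntronChain:
        return IntronChain.from_exons(self.exon_chain)

    @property
    def length_nt(self) -> int:
        return sum(len(e) for e in self.exon_chain)

    @property
    def total_support(self) -> int:
        return sum(self.support.values())

    def exons_transcription_order(self) -> tuple[GenomicInterval, ...]:
        return self.exon_chain if self.strand == "+" else self.exon_chain[::-1]


@dataclass
class OrfResult:
    """ATG-anchored ORF call for one transcript model.

    ``stop_to_last_junction_nt`` measures from the base after the stop
    codon's last base to the final exon-exon junction (transcript coords);
    it is negative when the stop lies in the last exon and None when there
    is no stop or no junction.
    """

    transcript_id: str
    status: str  # coding | nmd_candidate | no_start | coding_no_stop
    start_tpos: Optional[int] = None
    stop_tpos: Optional[int] = None
    protein: str = ""
    stop_to_last_junction_nt: Optional[int] = None

    @property
    def protein_len_aa(self) -> int:
        return len(self.protein)


@dataclass(frozen=True)
class DomainCall:
    """Presence call for one conserved domain in one protein isoform."""

    transcript_id: str
    domain: str
    status: str  # present | partial | absent
    coverage: float

    def symbol(self) -> str:
        return {"present": "✓", "partial": "~", "absent": "–"}[self.status]


@dataclass(frozen=True)
class ExpressionRecord:
    """Per-library abundance of one transcript model."""

    transcript_id: str
    library: str
    count: int
    length_nt: int
    tpm: float
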