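"""Genomic <-> transcript coordinate mapping over an exon chain.

Transcript coordinates run 0-based 5'->3'; on the minus strand they
decrease with genomic position.  The map is a bijection restricted to
exonic positions.
"""

from __future__ import annotations

from typing import Optional, Sequence

from Bio.Seq import Seq

from .core import Genome, GenomicInterval

__all__ = ["CoordinateMap", "spliced_sequence"]


class CoordinateMap:
    """Bijection between exonic genomic positions and transcript positions."""

    def __init__(self, exon_chain: Sequence[GenomicInterval]):
        chain = sorted(exon_chain, key=lambda e: e.start)
        self.strand = chain[0].strand
        self.chrom = chain[0].chrom
        # transcription order
        self.exons = tuple(chain) if self.strand == "+" else tuple(chain[::-1])
        self.length = sum(len(e) for e in self.exons)
        offsets = []
        t = 0
        for e in self.exons:
            offsets.append(t)
            t += len(e)
        self._offsets = offsets

    def genomic_to_transcript(self, pos: int) -> Optional[int]:
        """Transcript position of a genomic position, None if intronic/outside."""
        for off, e in zip(self._offsets, self.exons):
            if e.contains_pos(pos):
                return off + (pos - e.start if self.strand == "+" else e.end - 1 - pos)
        return None

    def transcript_to_genomic(self, tpos: int) -> int:
        if not (0 <= tpos < self.length):
            raise IndexError(f"transcript position {tpos} outside [0, {self.length})")
        for off, e in zip(self._offsets, self.exons):
            if off <= tpos < off + len(e):
                d = tpos - off
                return e.start + d if self.strand == "+" else e.end - 1 - d
        raise AssertionError("unreachable")

    def transcript_interval_to_blocks(self, t_start: int, t_end: int) -> tuple[GenomicInterval, ...]:
        """Genomic blocks (genomic order) covered by transcript slice [t_start, t_end)."""
        if not (0 <= t_start < t_end <= self.length):
            raise ValueError(f"invalid transcript interval [{t_start}, {t_end})")
        blocks = []
        for off, e in zip(self._offsets, self.exons):
            lo, hi = max(t_start, off), min(t_end, off + len(e))
            if lo >= hi:
                continue
            if self.strand == "+":
                blocks.append(GenomicInterval(self.chrom, e.start + (lo - off), e.start + (hi - off), "+"))
            else:
                blocks.append(GenomicInterval(self.chrom, e.end - (hi - off), e.end - (lo - off), "-"))
        return tuple(sorted(blocks, key=lambda b: b.start))

    @property
    def last_junction_tpos(self) -> Optional[int]:
        """Transcript position of the final exon-exon junction (first base of
        the last exon), or None for mono-exonic chains."""
        if len(self.exons) < 2:
            return None
        return self.length - len(self.exons[-1])


def spliced_sequence(exon_chain: Sequence[GenomicInterval], genome: Genome) -> str:
    """5'->3' mature sequence of an exon chain (reverse-complemented on -)."""
    chain = sorted(exon_chain, key=lambda e: e.start)
    seq = "".join(genome.fetch(e.chrom, e.start, e.end) for e in chain)
    if chain[0].strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq
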