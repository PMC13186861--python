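"""Shared fixtures: a hand-built 5-exon toy gene with a clean canonical ORF.

Exons [100,200) [300,450) [600,700) [800,950) [1200,1500) on the plus
strand, ATG at genomic 150.  The genome sequence is engineered the same way
the simulator builds genes: GT..AG at intron boundaries, premature in-frame
stops repaired, TAA placed in-frame inside the last exon.
"""

from __future__ import annotations

import numpy as np
import pytest

from splicelens import (
    CoordinateMap,
    GenomeAnnotation,
    Genome,
    GenomicInterval,
    SplicedAlignment,
)

FIXTURE_EXONS = [(100, 200), (300, 450), (600, 700), (800, 950), (1200, 1500)]
FIXTURE_ATG = 150
STOPS = {"TAA", "TAG", "TGA"}


def make_fixture_genome(seed: int = 42) -> str:
    rng = np.random.default_rng(seed)
    seq = list("ACGT"[i] for i in rng.integers(0, 4, size=1600))
    exons = [GenomicInterval("chrT", s, e, "+") for s, e in FIXTURE_EXONS]
    for a, b in zip(exons, exons[1:]):
        seq[a.end], seq[a.end + 1] = "G", "T"
        seq[b.start - 2], seq[b.start - 1] = "A", "G"
    seq[150:153] = list("ATG")
    cmap = CoordinateMap(exons)
    t_atg = cmap.genomic_to_transcript(FIXTURE_ATG)
    # stop in the last exon, in frame, ~100 nt into it
    last_off = cmap.length - 300
    stop_t = last_off + 100
    stop_t += (t_atg - stop_t) % 3
    for t in range(t_atg, stop_t, 3):
        codon = "".join(seq[cmap.transcript_to_genomic(t + k)] for k in range(3))
        if codon in STOPS:
            seq[cmap.transcript_to_genomic(t + 2)] = "C"
    for base, t in zip("TAA", range(stop_t, stop_t + 3)):
        seq[cmap.transcript_to_genomic(t)] = base
    return "".join(seq)


@pytest.fixture(scope="session")
def toy_exons() -> list[GenomicInterval]:
    return [GenomicInterval("chrT", s, e, "+") for s, e in FIXTURE_EXONS]


@pytest.fixture(scope="session")
def toy_annotation(toy_exons) -> GenomeAnnotation:
    return GenomeAnnotation(
        gene_id="TOY1",
        locus=GenomicInterval("chrT", 100, 1500, "+"),
        exons=tuple(toy_exons),
        start_codon_pos=FIXTURE_ATG,
        transcripts={"TOY1.v1": tuple(toy_exons)},
        canonical_name="TOY1.v1",
    )


@pytest.fixture(scope="session")
def toy_genome_seq() -> str:
    return make_fixture_genome()


@pytest.fixture(scope="session")
def toy_genome(toy_genome_seq) -> Genome:
    return Genome({"chrT": toy_genome_seq})


def read_from_blocks(blocks, read_id="r1", library="lib1", mapq=60):
    return SplicedAlignment(
        read_id=read_id,
        blocks=tuple(GenomicInterval("chrT", s, e, "+") for s, e in blocks),
        library=library,
        mapq=mapq,
    )


@pytest.fixture
def full_length_read():
    """A read spanning the whole canonical toy transcript."""
    return read_from_blocks(FIXTURE_EXONS)


def translate(seq: str) -> str:
    """Independent brute-force standard-code translation (stops excluded)."""
    table = {}
    bases = "TCAG"
    aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
    i = 0
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                table[b1 + b2 + b3] = aas[i]
                i += 1
    out = []
    for k in range(0, len(seq) - len(seq) % 3, 3):
        aa = table[seq[k : k + 3]]
        if aa == "*":
            break
        out.append(aa)
    return "".join(out)
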