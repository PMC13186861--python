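"""Readers and writers for the external formats the pipeline touches.

GTF is parsed with gffutils and written by hand (1-based inclusive at the
boundary, 0-based half-open internally); SAM is consumed through pysam with
introns taken from N CIGAR operations; domain tables and result tables are
plain TSV via pandas.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import gffutils
import pandas as pd
import pysam
from pyfaidx import Fasta

from .core import (
    DomainDefinition,
    GenomeAnnotation,
    Genome,
    GenomicInterval,
    SplicedAlignment,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

# CIGAR operation codes (pysam numeric encoding)
_REF_CONSUMING = {0, 2, 7, 8}  # M, D, =, X extend the current block
_INTRON = 3  # N closes a block
_NO_REF = {1, 4, 5, 6}  # I, S, H, P consume no reference


def load_genome(path: str | Path) -> Genome:
    """Open an (uncompressed) genome FASTA through pyfaidx."""
    return Genome(Fasta(str(path), as_raw=True, sequence_always_upper=True))


def read_gtf(path: str | Path, canonical_transcript: Optional[str] = None) -> GenomeAnnotation:
    """Parse a single-gene GTF into a :class:`GenomeAnnotation`.

    The canonical transcript is ``canonical_transcript`` if given, otherwise
    the transcript with a start_codon feature and the longest summed exon
    length (a stand-in for longest CDS when CDS features are absent).
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons_by_tx: dict[str, list[GenomicInterval]] = {}
    start_codon_by_tx: dict[str, tuple[int, int, str]] = {}
    tx_order: list[str] = []
    gene_id = None
    for feat in db.all_features(order_by=("seqid", "start")):
        if feat.featuretype not in ("exon", "start_codon"):
            continue
        tx = feat.attributes.get("transcript_id", ["?"])[0]
        gene_id = gene_id or feat.attributes.get("gene_id", ["?"])[0]
        if feat.featuretype == "exon":
            if tx not in exons_by_tx:
                tx_order.append(tx)
            exons_by_tx.setdefault(tx, []).append(
                GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
            )
        else:
            start_codon_by_tx[tx] = (feat.start - 1, feat.end, feat.strand)

    if not exons_by_tx:
        raise ValueError(f"{path}: no exon features found")

    def tx_len(tx: str) -> int:
        return sum(len(e) for e in exons_by_tx[tx])

    if canonical_transcript is not None:
        if canonical_transcript not in exons_by_tx:
            raise ValueError(f"canonical transcript {canonical_transcript!r} not in {path}")
        canon = canonical_transcript
    else:
        with_start = [t for t in tx_order if t in start_codon_by_tx]
        candidates = with_start or tx_order
        canon = max(candidates, key=tx_len)
    if canon not in start_codon_by_tx:
        raise ValueError(f"transcript {canon!r} has no start_codon feature")

    strand = exons_by_tx[canon][0].strand
    sc_start, sc_end, sc_strand = start_codon_by_tx[canon]
    start_codon_pos = sc_start if strand == "+" else sc_end - 1

    transcripts: dict[str, tuple[GenomicInterval, ...]] = {}
    for tx in tx_order:
        exs = sorted(exons_by_tx[tx], key=lambda e: e.start)
        for a, b in zip(exs, exs[1:]):
            if b.start < a.end and tx == canon:
                raise ValueError(f"overlapping annotated exons in canonical transcript {tx}")
        transcripts[tx] = tuple(exs) if strand == "+" else tuple(exs[::-1])

    canon_exons = transcripts[canon]
    genomic = sorted(canon_exons, key=lambda e: e.start)
    locus = GenomicInterval(genomic[0].chrom, genomic[0].start, genomic[-1].end, strand)
    return GenomeAnnotation(
        gene_id=gene_id or "?",
        locus=locus,
        exons=canon_exons,
        start_codon_pos=start_codon_pos,
        transcripts=transcripts,
        canonical_name=canon,
    )


def _blocks_from_cigar(
    chrom: str, pos0: int, cigartuples: Sequence[tuple[int, int]], strand: str, read_id: str
) -> tuple[GenomicInterval, ...]:
    blocks: list[GenomicInterval] = []
    cur_start, cur = pos0, pos0
    for op, length in cigartuples:
        if op in _REF_CONSUMING:
            cur += length
        elif op == _INTRON:
            if cur > cur_start:
                blocks.append(GenomicInterval(chrom, cur_start, cur, strand))
            cur += length
            cur_start = cur
        elif op in _NO_REF:
            continue
        else:
            raise ValueError(f"{read_id}: unsupported CIGAR op code {op}")
    if cur > cur_start:
        blocks.append(GenomicInterval(chrom, cur_start, cur, strand))
    if not blocks:
        raise ValueError(f"{read_id}: CIGAR consumes no reference")
    return tuple(blocks)


def read_spliced_alignments(
    path: str | Path,
    library_tag: Optional[str] = None,
    gene_strand: str = "+",
) -> Iterator[SplicedAlignment]:
    """Stream primary alignments from a SAM/BAM file as SplicedAlignment.

    The library label comes from the read group (RG tag) by default, or from
    ``library_tag`` if given; reads lacking a label get "default" with a
    warning.  Unmapped and secondary records are skipped silently,
    supplementary records skipped with a log line.
    """
    tag = library_tag or "RG"
    warned_missing = False
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary:
                continue
            if rec.is_supplementary:
                logger.info("skipping supplementary alignment %s", rec.query_name)
                continue
            if rec.cigartuples is None:
                raise ValueError(f"{rec.query_name}: missing CIGAR")
            blocks = _blocks_from_cigar(
                rec.reference_name, rec.reference_start, rec.cigartuples, gene_strand, rec.query_name
            )
            try:
                library = str(rec.get_tag(tag))
            except KeyError:
                if not warned_missing:
                    warnings.warn(f"reads without {tag} tag assigned library 'default'")
                    warned_missing = True
                library = "default"
            yield SplicedAlignment(
                read_id=rec.query_name, blocks=blocks, library=library, mapq=rec.mapping_quality
            )


def write_transcript_gtf(
    models: Sequence[TranscriptModel],
    path: str | Path,
    gene_id: str = "gene",
    source: str = "splicelens",
) -> None:
    """Write transcript models as GTF (transcript + exon features)."""
    with open(path, "w") as fh:
        fh.write("##description: transcript models\n")
        for m in models:
            chrom, strand = m.chrom, m.strand
            span = (m.exon_chain[0].start + 1, m.exon_chain[-1].end)
            attrs = f'gene_id "{gene_id}"; transcript_id "{m.id}";'
            fh.write(
                f"{chrom}\t{source}\ttranscript\t{span[0]}\t{span[1]}\t.\t{strand}\t.\t{attrs}\n"
            )
            exons = m.exon_chain if strand == "+" else m.exon_chain[::-1]
            for n, e in enumerate(exons, start=1):
                fh.write(
                    f"{chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t{strand}\t.\t"
                    f'{attrs} exon_number "{n}";\n'
                )


def write_annotation_gtf(
    annotation: GenomeAnnotation, path: str | Path, source: str = "splicelens"
) -> None:
    """Write a GenomeAnnotation as GTF with exon and start_codon features.

    Assumes the start codon is contained in a single exon (true for the
    amplicon genes this package targets; the synthetic builder guarantees it).
    """
    chrom, strand = annotation.chrom, annotation.strand
    pos = annotation.start_codon_pos
    sc = (pos + 1, pos + 3) if strand == "+" else (pos - 1, pos + 1)
    with open(path, "w") as fh:
        fh.write(f"##description: annotation for {annotation.gene_id}\n")
        for tx, exons in annotation.transcripts.items():
            attrs = f'gene_id "{annotation.gene_id}"; transcript_id "{tx}";'
            lo = min(e.start for e in exons)
            hi = max(e.end for e in exons)
            fh.write(f"{chrom}\t{source}\ttranscript\t{lo + 1}\t{hi}\t.\t{strand}\t.\t{attrs}\n")
            for n, e in enumerate(exons, start=1):
                fh.write(
                    f"{chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t{strand}\t.\t"
                    f'{attrs} exon_number "{n}";\n'
                )
            if tx == annotation.canonical_name:
                fh.write(
                    f"{chrom}\t{source}\tstart_codon\t{sc[0]}\t{sc[1]}\t.\t{strand}\t0\t{attrs}\n"
                )


def read_transcript_models(path: str | Path) -> list[TranscriptModel]:
    """Read transcript models back from a GTF written by write_transcript_gtf."""
    exons: dict[str, list[GenomicInterval]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "exon":
                continue
            tid = f[8].split('transcript_id "')[1].split('"')[0]
            if tid not in exons:
                exons[tid] = []
                order.append(tid)
            exons[tid].append(GenomicInterval(f[0], int(f[3]) - 1, int(f[4]), f[6]))
    return [
        TranscriptModel(id=tid, exon_chain=tuple(sorted(exons[tid], key=lambda e: e.start)))
        for tid in order
    ]


def read_domains(path: str | Path) -> list[DomainDefinition]:
    """Read a 3-column (name, aa_start, aa_end) headered TSV of domains."""
    df = pd.read_csv(path, sep="\t")
    required = {"name", "aa_start", "aa_end"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: domain TSV needs columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        if int(row.aa_end) < int(row.aa_start):
            raise ValueError(f"domain row {row['name']!r}: aa_end < aa_start")
        out.append(DomainDefinition(str(row["name"]), int(row.aa_start), int(row.aa_end)))
    return sorted(out, key=lambda d: (d.aa_start, d.aa_end, d.name))


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    """Write (name, sequence) pairs as FASTA."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_cryptic_exon_bed(models: Sequence[TranscriptModel], path: str | Path) -> None:
    """BED6 of cryptic exons (0-based half-open, native)."""
    rows = []
    for m in models:
        for ev in m.events:
            if ev.type == "cryptic_exon" and ev.interval is not None:
                iv = ev.interval
                rows.append((iv.chrom, iv.start, iv.end, f"{m.id}_cryptic", 0, iv.strand))
    with open(path, "w") as fh:
        for r in sorted(set(rows), key=lambda r: (r[0], r[1], r[2], r[3])):
            fh.write("\t".join(map(str, r)) + "\n")
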