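"""Splice-variant discovery from spliced long-read alignments.

Full-length reads (covering the annotated translation initiation site and
reaching the transcript's last exon) are collapsed by identical intron
chain into transcript models; each model's exons are classified against
the annotation and named splicing events are called.  Non-full-length
reads — fragments from library preparation — never create models.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .core import (
    GenomeAnnotation,
    GenomicInterval,
    IntronChain,
    SpliceEvent,
    SplicedAlignment,
    TranscriptModel,
    introns_of,
)

logger = logging.getLogger(__name__)

EXON_LABELS = ("annotated", "truncated", "extended", "cryptic", "retained_fusion")


@dataclass
class DiscoveryStats:
    """Read bookkeeping across the discovery filters (auditable exclusions)."""

    n_parsed: int = 0
    n_mapq_failed: int = 0
    n_not_full_length: int = 0
    n_full_length: int = 0
    n_below_min_support: int = 0
    per_chain_support: dict = field(default_factory=dict)


def extract_intron_chain(aln: SplicedAlignment) -> IntronChain:
    """Introns are exactly the gaps between consecutive aligned blocks."""
    introns = []
    for a, b in zip(aln.blocks, aln.blocks[1:]):
        introns.append(GenomicInterval(a.chrom, a.end, b.start, a.strand))
    return IntronChain(tuple(introns))


def is_full_length(
    aln: SplicedAlignment,
    annotation: GenomeAnnotation,
    model_last_exon: Optional[GenomicInterval] = None,
) -> bool:
    """True iff the aligned span covers the genomic start-codon position and
    the 3'-most block overlaps the (model's or annotated) last exon."""
    last_exon = model_last_exon or annotation.last_exon
    span = aln.span
    if not span.contains_pos(annotation.start_codon_pos):
        return False
    three_prime_block = aln.blocks[-1] if annotation.strand == "+" else aln.blocks[0]
    return three_prime_block.overlaps(last_exon)


def _merge_boundaries(chains: list[tuple[IntronChain, int]], window: int) -> dict[int, int]:
    """Snap intron boundaries within ``window`` nt of each other to the most
    frequent boundary of their cluster (tie -> smaller coordinate).

    Returns a coordinate -> representative mapping.  Single-linkage greedy
    clustering over the sorted distinct boundary values; window 0 is the
    identity."""
    freq: Counter = Counter()
    for chain, n in chains:
        for iv in chain.introns:
            freq[iv.start] += n
            freq[iv.end] += n
    mapping: dict[int, int] = {}
    cluster: list[int] = []

    def flush() -> None:
        if not cluster:
            return
        rep = max(cluster, key=lambda c: (freq[c], -c))
        for c in cluster:
            mapping[c] = rep
        cluster.clear()

    for coord in sorted(freq):
        if cluster and coord - cluster[-1] > window:
            flush()
        cluster.append(coord)
    flush()
    return mapping


def _snap_chain(chain: IntronChain, mapping: dict[int, int]) -> IntronChain:
    introns = []
    for iv in chain.introns:
        s, e = mapping[iv.start], mapping[iv.end]
        if e <= s:  # degenerate after snapping; keep original boundaries
            s, e = iv.start, iv.end
        introns.append(GenomicInterval(iv.chrom, s, e, iv.strand))
    return IntronChain(tuple(introns))


def collapse(
    alignments: Iterable[SplicedAlignment],
    annotation: GenomeAnnotation,
    mapq_min: int = 1,
    min_support: int = 3,
    merge_window: int = 0,
    novel_id_start: int = 7,
) -> tuple[list[TranscriptModel], DiscoveryStats]:
    """Group full-length reads by identical intron chain into transcript models.

    Terminal exon boundaries are the modal terminal block boundaries of each
    group's reads (ties broken toward the longer exon).  Models are sorted by
    descending support, then genomic order of the first intron.  Models whose
    chain matches an annotated transcript keep that transcript's name
    (reported, not novel); novel models are named ``sv.<k>`` from
    ``novel_id_start`` upward.
    """
    stats = DiscoveryStats()
    groups: dict[tuple, list[SplicedAlignment]] = defaultdict(list)
    for aln in alignments:
        stats.n_parsed += 1
        if aln.mapq < mapq_min:
            stats.n_mapq_failed += 1
            continue
        if not is_full_length(aln, annotation):
            stats.n_not_full_length += 1
            continue
        stats.n_full_length += 1
        groups[extract_intron_chain(aln).key()].append(aln)

    if stats.n_full_length == 0:
        warnings.warn("no full-length reads retained; no models discovered")
        return [], stats

    if merge_window > 0:
        raw = [
            (IntronChain(tuple(GenomicInterval(annotation.chrom, s, e, annotation.strand) for s, e in key)), len(alns))
            for key, alns in groups.items()
        ]
        mapping = _merge_boundaries(raw, merge_window)
        merged: dict[tuple, list[SplicedAlignment]] = defaultdict(list)
        for key, alns in groups.items():
            chain = IntronChain(
                tuple(GenomicInterval(annotation.chrom, s, e, annotation.strand) for s, e in key)
            )
            merged[_snap_chain(chain, mapping).key()].extend(alns)
        groups = merged

    models: list[TranscriptModel] = []
    for key, alns in groups.items():
        if len(alns) < min_support:
            stats.n_below_min_support += len(alns)
            continue
        start_mode = _modal(
            [a.blocks[0].start for a in alns], tie_towards=min
        )
        end_mode = _modal([a.blocks[-1].end for a in alns], tie_towards=max)
        exon_chain = _exons_from_chain(annotation, key, start_mode, end_mode)
        support: dict[str, int] = defaultdict(int)
        for a in alns:
            support[a.library] += 1
        models.append(
            TranscriptModel(id="", exon_chain=exon_chain, support=dict(support))
        )
        stats.per_chain_support[key] = len(alns)

    if not models:
        warnings.warn(
            f"no intron chain reached min_support={min_support}; no models discovered"
        )

    def first_intron_pos(m: TranscriptModel) -> tuple:
        ch = m.intron_chain.key()
        return ch[0] if ch else (m.exon_chain[0].start, m.exon_chain[0].end)

    models.sort(key=lambda m: (-m.total_support, first_intron_pos(m)))

    annotated_chains = {
        IntronChain.from_exons(exons).key(): name for name, exons in annotation.transcripts.items()
    }
    next_sv = novel_id_start
    for m in models:
        match = annotated_chains.get(m.intron_chain.key())
        if match is not None:
            m.id = match
        else:
            m.id = f"sv.{next_sv}"
            next_sv += 1
        m.exon_labels = classify_exons(m, annotation)
        m.events = tuple(call_events(m, annotation))
    logger.info(
        "discovery: %d reads, %d full-length, %d models", stats.n_parsed, stats.n_full_length, len(models)
    )
    return models, stats


def _modal(values: list[int], tie_towards) -> int:
    counts = Counter(values)
    best = max(counts.values())
    return tie_towards(v for v, c in counts.items() if c == best)


def _exons_from_chain(
    annotation: GenomeAnnotation, chain_key: tuple, start: int, end: int
) -> tuple[GenomicInterval, ...]:
    """Exon chain from an intron chain plus terminal boundaries (genomic order)."""
    chrom, strand = annotation.chrom, annotation.strand
    boundaries = [start]
    for s, e in chain_key:
        boundaries.extend([s, e])
    boundaries.append(end)
    exons = []
    for i in range(0, len(boundaries), 2):
        exons.append(GenomicInterval(chrom, boundaries[i], boundaries[i + 1], strand))
    return tuple(exons)


def classify_exons(model: TranscriptModel, annotation: GenomeAnnotation) -> tuple[str, ...]:
    """Label each model exon against the canonical annotated exon ladder.

    annotated: identical to an annotated exon; truncated: proper subset of
    one; extended: extends one annotated exon into flanking intron;
    retained_fusion: spans two or more annotated exons plus the intervening
    intron(s); cryptic: overlaps no annotated exon.
    """
    labels = []
    annotated = annotation.exons_genomic
    for exon in model.exon_chain:
        hits = [a for a in annotated if a.overlaps(exon)]
        if not hits:
            labels.append("cryptic")
        elif len(hits) >= 2:
            labels.append("retained_fusion")
        else:
            a = hits[0]
            if (a.start, a.end) == (exon.start, exon.end):
                labels.append("annotated")
            elif a.contains(exon):
                labels.append("truncated")
            else:
                # proper superset, or a mixed shift past one boundary: both
                # carry intronic sequence, so the exon is extended
                labels.append("extended")
    return tuple(labels)


def call_events(model: TranscriptModel, annotation: GenomeAnnotation) -> list[SpliceEvent]:
    """Call named splicing events of a model against the canonical transcript.

    Events are reported in genomic order.  A model junction bridging one or
    more annotated exons yields exon_skipping events; a junction sharing
    exactly one boundary with an annotated junction yields an alt_donor /
    alt_acceptor with a strand-aware signed shift (positive = downstream in
    transcription direction); each annotated intron wholly inside a model
    exon yields intron_retention; each cryptic exon yields cryptic_exon.
    """
    strand = annotation.strand
    canon_exons_g = annotation.exons_genomic
    canon_introns_t = annotation.introns  # transcription order, 1-based numbering
    canon_introns_g = sorted(canon_introns_t, key=lambda i: i.start)
    labels = model.exon_labels or classify_exons(model, annotation)

    events: list[tuple[tuple, SpliceEvent]] = []

    def exon_number_genomic(a: GenomicInterval) -> int:
        return annotation.exon_number(a)

    def intron_number(iv: GenomicInterval) -> int:
        for k, it in enumerate(canon_introns_t, start=1):
            if (it.start, it.end) == (iv.start, iv.end):
                return k
        raise KeyError(iv)

    model_introns = list(model.intron_chain.introns)

    # genomic coordinate of each annotated donor/acceptor boundary
    donor_coord = {(i.start if strand == "+" else i.end): intron_number(i) for i in canon_introns_g}
    acceptor_coord = {(i.end if strand == "+" else i.start): intron_number(i) for i in canon_introns_g}
    # junction boundaries that are edges of a cryptic exon belong to the
    # cryptic_exon event, not to an alt splice-site shift
    cryptic_edges = {
        c for exon, label in zip(model.exon_chain, labels) if label == "cryptic"
        for c in (exon.start, exon.end)
    }

    for mj in model_introns:
        bridged = [a for a in canon_exons_g if mj.contains(a)]
        for a in bridged:
            events.append(((a.start, 0), SpliceEvent("exon_skipping", target=exon_number_genomic(a))))
        d_coord = mj.start if strand == "+" else mj.end
        a_coord = mj.end if strand == "+" else mj.start
        d_known = d_coord in donor_coord
        a_known = a_coord in acceptor_coord
        if d_known and a_known:
            continue
        if not d_known and a_known and d_coord not in cryptic_edges:
            ref = canon_introns_t[acceptor_coord[a_coord] - 1]
            ref_d = ref.start if strand == "+" else ref.end
            delta = (d_coord - ref_d) if strand == "+" else (ref_d - d_coord)
            events.append(
                ((min(d_coord, ref_d), 1), SpliceEvent("alt_donor", target=intron_number(ref), delta=delta))
            )
        elif d_known and not a_known and a_coord not in cryptic_edges:
            ref = canon_introns_t[donor_coord[d_coord] - 1]
            ref_a = ref.end if strand == "+" else ref.start
            delta = (a_coord - ref_a) if strand == "+" else (ref_a - a_coord)
            events.append(
                ((min(a_coord, ref_a), 1), SpliceEvent("alt_acceptor", target=intron_number(ref), delta=delta))
            )
        # neither boundary annotated: cryptic-exon flanks or wholly novel
        # junction; covered by cryptic_exon / exon labels, no alt-site event

    # intron retention: annotated intron wholly inside one model exon
    for exon in model.exon_chain:
        for it in canon_introns_g:
            if exon.contains(it):
                events.append(((it.start, 2), SpliceEvent("intron_retention", target=intron_number(it))))

    # cryptic exons
    for exon, label in zip(model.exon_chain, labels):
        if label == "cryptic":
            events.append(((exon.start, 3), SpliceEvent("cryptic_exon", interval=exon)))

    # alternative terminal exons: the model's outermost exon fails to overlap
    # the corresponding annotated terminal exon
    tx_exons = model.exons_transcription_order()
    if not tx_exons[0].overlaps(annotation.exons[0]):
        events.append(((tx_exons[0].start, 4), SpliceEvent("alt_terminal_exon", target=1)))
    if not tx_exons[-1].overlaps(annotation.exons[-1]):
        events.append(((tx_exons[-1].start, 4), SpliceEvent("alt_terminal_exon", target=len(annotation.exons))))

    events.sort(key=lambda t: t[0])
    # deduplicate (a skipped exon bridged by two jittered junctions, etc.)
    seen = set()
    out = []
    for _, ev in events:
        key = (ev.type, ev.target, ev.delta, ev.interval)
        if key not in seen:
            seen.add(key)
            out.append(ev)
    return out
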