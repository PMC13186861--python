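"""Per-library abundance (TPM) of transcript models from full-length counts.

Two TPM variants are exposed: the standard length-normalized form
(rate_i = count_i / length_i, scaled so each library sums to one million)
and a count-based form (count_i / total counts x 1e6), arguable for
full-length counting where no length bias remains.  Each library is
normalized independently.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from typing import Iterable, Optional, Sequence

import pandas as pd

from .core import ExpressionRecord, GenomeAnnotation, SplicedAlignment, TranscriptModel
from .discovery import extract_intron_chain, is_full_length

logger = logging.getLogger(__name__)

TPM_MODES = ("length_normalized", "count_based")


def count_support(
    models: Sequence[TranscriptModel],
    alignments: Iterable[SplicedAlignment],
    annotation: GenomeAnnotation,
    mapq_min: int = 1,
    libraries: Optional[Sequence[str]] = None,
) -> dict[tuple[str, str], int]:
    """Full-length read counts per (transcript_id, library).

    Reads are re-screened with the full-length filter and assigned to the
    model with an identical intron chain; reads matching no model are
    ignored (they were below the support threshold at discovery time).
    """
    by_chain = {m.intron_chain.key(): m.id for m in models}
    known = set(libraries) if libraries else None
    warned: set[str] = set()
    counts: dict[tuple[str, str], int] = defaultdict(int)
    for aln in alignments:
        if aln.mapq < mapq_min or not is_full_length(aln, annotation):
            continue
        tid = by_chain.get(extract_intron_chain(aln).key())
        if tid is None:
            continue
        if known is not None and aln.library not in known and aln.library not in warned:
            warnings.warn(f"library {aln.library!r} not in configured list; included anyway")
            warned.add(aln.library)
        counts[(tid, aln.library)] += 1
    return dict(counts)


def tpm(
    counts: dict[tuple[str, str], int],
    lengths: dict[str, int],
    mode: str = "length_normalized",
) -> list[ExpressionRecord]:
    """Transcripts-per-million per library; zero-count transcripts get tpm 0.

    Every (transcript, library) combination over the union of observed
    libraries is emitted, so absence is explicit in the output tables.
    """
    if mode not in TPM_MODES:
        raise ValueError(f"unknown TPM mode {mode!r}")
    for tid in lengths:
        if lengths[tid] <= 0:
            raise ValueError(f"{tid}: non-positive length")
    libraries = sorted({lib for _, lib in counts})
    records: list[ExpressionRecord] = []
    for lib in libraries:
        per_tx = {tid: counts.get((tid, lib), 0) for tid in lengths}
        if mode == "length_normalized":
            rates = {tid: c / lengths[tid] for tid, c in per_tx.items()}
        else:
            rates = {tid: float(c) for tid, c in per_tx.items()}
        total = sum(rates.values())
        if total == 0:
            warnings.warn(f"library {lib!r}: all-zero counts, TPM normalization skipped")
        for tid in sorted(lengths):
            value = 0.0 if total == 0 else rates[tid] / total * 1e6
            records.append(
                ExpressionRecord(
                    transcript_id=tid,
                    library=lib,
                    count=per_tx[tid],
                    length_nt=lengths[tid],
                    tpm=value,
                )
            )
    return records


def expression_table(records: Sequence[ExpressionRecord]) -> pd.DataFrame:
    """Long-form expression table (one row per transcript x library)."""
    return pd.DataFrame(
        [
            {
                "transcript_id": r.transcript_id,
                "library": r.library,
                "count": r.count,
                "length_nt": r.length_nt,
                "tpm": r.tpm,
            }
            for r in records
        ]
    )


def tpm_matrix(records: Sequence[ExpressionRecord]) -> pd.DataFrame:
    """Wide transcripts x libraries TPM matrix (heatmap-ready TSV)."""
    df = expression_table(records)
    return df.pivot(index="transcript_id", columns="library", values="tpm").sort_index()


def quantify_models(
    models: Sequence[TranscriptModel],
    alignments: Iterable[SplicedAlignment],
    annotation: GenomeAnnotation,
    mode: str = "length_normalized",
    mapq_min: int = 1,
) -> list[ExpressionRecord]:
    """Convenience wrapper: count full-length support, then compute TPM."""
    counts = count_support(models, alignments, annotation, mapq_min=mapq_min)
    lengths = {m.id: m.length_nt for m in models}
    return tpm(counts, lengths, mode=mode)
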