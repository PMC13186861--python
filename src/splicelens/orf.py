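"""ATG-anchored ORF prediction and NMD classification.

Every transcript model is translated from the annotated initiation codon of
the canonical mRNA (alternative upstream/downstream AUGs are deliberately
not scanned).  A transcript whose stop codon lies more than ``threshold_nt``
(default 50, from the mammalian 50-55 nt rule) upstream of the final
exon-exon junction is an NMD candidate; a stop in the last exon — or any
stop on a mono-exonic transcript — is coding.  Models that lose the
ATG-bearing exon are ``no_start``; models whose frame runs off the 3' end
without a stop (an artifact of model truncation) are ``coding_no_stop`` and
excluded from coding counts.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

from Bio.Seq import Seq

from .coords import CoordinateMap, spliced_sequence
from .core import Genome, GenomeAnnotation, OrfResult, TranscriptModel

logger = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}


def genomic_to_transcript(pos: int, cmap: CoordinateMap) -> Optional[int]:
    """Transcript coordinate of an exonic genomic position (None if intronic)."""
    return cmap.genomic_to_transcript(pos)


def transcript_to_genomic(tpos: int, cmap: CoordinateMap) -> int:
    return cmap.transcript_to_genomic(tpos)


def find_orf(
    model: TranscriptModel,
    annotation: GenomeAnnotation,
    genome: Genome,
    threshold_nt: int = 50,
    strict: bool = True,
) -> OrfResult:
    """Predict the ORF anchored at the annotated ATG and classify it.

    Scans codons from the mapped initiation site to the first in-frame stop;
    the protein is the standard-code translation of the codons before it.
    """
    cmap = CoordinateMap(model.exon_chain)
    t_start = cmap.genomic_to_transcript(annotation.start_codon_pos)
    if t_start is None or cmap.length - t_start < 3:
        return OrfResult(transcript_id=model.id, status="no_start")

    seq = spliced_sequence(model.exon_chain, genome)
    cds = seq[t_start:]
    cds = cds[: len(cds) - len(cds) % 3]
    stop_idx = None
    for i in range(0, len(cds), 3):
        if cds[i : i + 3] in STOP_CODONS:
            stop_idx = i
            break
    if stop_idx is None:
        protein = str(Seq(cds).translate())
        return OrfResult(
            transcript_id=model.id,
            status="coding_no_stop",
            start_tpos=t_start,
            protein=protein,
        )

    protein = str(Seq(cds[:stop_idx]).translate())
    stop_tpos = t_start + stop_idx
    result = OrfResult(
        transcript_id=model.id,
        status="coding",
        start_tpos=t_start,
        stop_tpos=stop_tpos,
        protein=protein,
    )
    last_junction = cmap.last_junction_tpos
    if last_junction is not None:
        result.stop_to_last_junction_nt = last_junction - (stop_tpos + 3)
    result.status = nmd_classify(result, model, threshold_nt=threshold_nt, strict=strict)
    return result


def nmd_classify(
    orf: OrfResult, model: TranscriptModel, threshold_nt: int = 50, strict: bool = True
) -> str:
    """Apply the 50-nt rule to an ORF with a stop codon.

    nmd_candidate iff the stop sits more than ``threshold_nt`` upstream of
    the final exon-exon junction ("more than" is strict by default); a stop
    in the last exon, or any stop on a mono-exonic model, is coding.
    """
    if orf.stop_tpos is None:
        raise ValueError("nmd_classify requires an ORF with a stop codon")
    d = orf.stop_to_last_junction_nt
    if d is None:  # mono-exonic: no junction, NMD cannot be triggered
        return "coding"
    if (d > threshold_nt) if strict else (d >= threshold_nt):
        return "nmd_candidate"
    return "coding"


def orf_table(results: Sequence[OrfResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "transcript_id": r.transcript_id,
                "status": r.status,
                "protein_len_aa": r.protein_len_aa,
                "stop_to_last_junction_nt": r.stop_to_last_junction_nt,
            }
            for r in results
        ]
    )
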