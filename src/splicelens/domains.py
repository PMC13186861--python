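"""Conserved-domain retention calls for predicted protein isoforms.

Each isoform is globally aligned to the canonical protein (affine gaps) and
every domain's coverage is the fraction of its canonical positions that are
paired with an *identical* isoform residue — robust to frameshifted tails,
which align but do not match.  Coverage >= 0.9 is present, < 0.3 absent,
otherwise partial; in strict mode partial collapses to absent, reproducing
a binary check/dash matrix.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import pandas as pd
from Bio import Align

from .core import DomainCall, DomainDefinition

logger = logging.getLogger(__name__)

PRESENT_MIN = 0.9
ABSENT_MAX = 0.3


def _aligner(match: float, mismatch: float, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def align_to_canonical(
    iso_protein: str,
    canonical_protein: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> list[tuple[int, int]]:
    """Global affine alignment; returns (iso_pos, canonical_pos) pairs (0-based).

    Ties are broken deterministically by taking the first optimal alignment
    Biopython enumerates (pairing preferred over gaps, gaps pushed later in
    the canonical sequence).
    """
    if not iso_protein or not canonical_protein:
        raise ValueError("cannot align an empty protein sequence")
    aln = _aligner(match, mismatch, gap_open, gap_extend).align(iso_protein, canonical_protein)[0]
    pairs: list[tuple[int, int]] = []
    for (q0, q1), (t0, t1) in zip(*aln.aligned):
        pairs.extend((q0 + k, t0 + k) for k in range(q1 - q0))
    return pairs


def call_domains(
    iso_protein: str,
    canonical_protein: str,
    domains: Sequence[DomainDefinition],
    transcript_id: str = "",
    present_min: float = PRESENT_MIN,
    absent_max: float = ABSENT_MAX,
    strict: bool = False,
    alignment: Optional[list[tuple[int, int]]] = None,
) -> list[DomainCall]:
    """Coverage-based present/partial/absent call for each domain.

    Coverage counts canonical domain positions paired with an identical
    isoform residue, divided by domain length.
    """
    for d in domains:
        if d.aa_end > len(canonical_protein):
            raise ValueError(f"domain {d.name} exceeds canonical protein length")
    if alignment is None:
        alignment = align_to_canonical(iso_protein, canonical_protein)
    identical_canon = {
        cpos for ipos, cpos in alignment if iso_protein[ipos] == canonical_protein[cpos]
    }
    calls = []
    for d in domains:
        span = range(d.aa_start - 1, d.aa_end)  # to 0-based
        covered = sum(1 for p in span if p in identical_canon)
        coverage = covered / d.length
        if coverage >= present_min:
            status = "present"
        elif coverage < absent_max or (strict and coverage < present_min):
            status = "absent"
        else:
            status = "partial"
        calls.append(DomainCall(transcript_id=transcript_id, domain=d.name, status=status, coverage=coverage))
    return calls


def domain_matrix(calls: Sequence[DomainCall]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Wide transcripts x domains matrices: symbols ({✓, ~, –}) and coverages."""
    df = pd.DataFrame(
        [
            {"transcript_id": c.transcript_id, "domain": c.domain, "symbol": c.symbol(), "coverage": c.coverage}
            for c in calls
        ]
    )
    domain_order = list(dict.fromkeys(c.domain for c in calls))
    symbols = df.pivot(index="transcript_id", columns="domain", values="symbol")[domain_order]
    coverage = df.pivot(index="transcript_id", columns="domain", values="coverage")[domain_order]
    return symbols, coverage
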