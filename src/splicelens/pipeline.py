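"""End-to-end orchestration: discover -> quantify -> ORF -> domains.

A single PipelineConfig drives all stages; every filter boundary is logged
(reads parsed / MAPQ-passed / full-length / per-model) so read exclusions
stay auditable, and a per-transcript summary plus a novelty report are
written at the end.  Everything downstream of the simulator is deterministic
for identical inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import discovery, domains as domains_mod, io as sio, orf as orf_mod, quantify
from .coords import spliced_sequence
from .core import GenomeAnnotation, Genome, TranscriptModel

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_CONFIG = 2
EXIT_STAGE = 3


@dataclass
class PipelineConfig:
    gtf: str
    genome: str
    sam: str
    outdir: str
    domains: Optional[str] = None
    canonical_transcript: Optional[str] = None
    mapq_min: int = 1
    min_support: int = 3
    merge_window: int = 0
    novel_id_start: int = 7
    tpm_mode: str = "length_normalized"
    nmd_threshold_nt: int = 50
    nmd_strict: bool = True
    domain_present_min: float = 0.9
    domain_absent_max: float = 0.3
    library_tag: Optional[str] = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        try:
            return cls(**data)
        except TypeError as exc:
            raise ValueError(f"invalid pipeline config {path}: {exc}") from exc

    def validate(self) -> None:
        for key in ("gtf", "genome", "sam"):
            p = getattr(self, key)
            if not Path(p).exists():
                raise FileNotFoundError(f"config path {key}={p!r} does not exist")
        if self.domains is not None and not Path(self.domains).exists():
            raise FileNotFoundError(f"config path domains={self.domains!r} does not exist")
        if self.tpm_mode not in quantify.TPM_MODES:
            raise ValueError(f"tpm_mode must be one of {quantify.TPM_MODES}")
        if not (0 <= self.domain_absent_max <= self.domain_present_min <= 1):
            raise ValueError("domain thresholds must satisfy 0 <= absent_max <= present_min <= 1")


def compare_to_annotation(
    models: Sequence[TranscriptModel], annotation: GenomeAnnotation
) -> pd.DataFrame:
    """Novelty category per model: matches an annotated transcript, novel
    from annotated exons only, or novel carrying cryptic exon(s)."""
    from .core import IntronChain

    annotated = {
        IntronChain.from_exons(exons).key(): name
        for name, exons in annotation.transcripts.items()
    }
    rows = []
    for m in models:
        match = annotated.get(m.intron_chain.key())
        if match is not None:
            category = "matches_annotated"
        elif any(lbl == "cryptic" for lbl in m.exon_labels):
            category = "novel_with_cryptic_exons"
        else:
            category = "novel_annotated_exons_only"
        rows.append({"transcript_id": m.id, "category": category, "matches": match or ""})
    return pd.DataFrame(rows, columns=["transcript_id", "category", "matches"])


def run_all(config: PipelineConfig) -> pd.DataFrame:
    """Run every stage and write all report files; returns the summary table."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    annotation = sio.read_gtf(config.gtf, canonical_transcript=config.canonical_transcript)
    genome = sio.load_genome(config.genome)

    def read_alignments():
        return sio.read_spliced_alignments(
            config.sam, library_tag=config.library_tag, gene_strand=annotation.strand
        )

    models, stats = discovery.collapse(
        read_alignments(),
        annotation,
        mapq_min=config.mapq_min,
        min_support=config.min_support,
        merge_window=config.merge_window,
        novel_id_start=config.novel_id_start,
    )
    logger.info(
        "reads parsed=%d mapq_failed=%d not_full_length=%d full_length=%d models=%d",
        stats.n_parsed, stats.n_mapq_failed, stats.n_not_full_length,
        stats.n_full_length, len(models),
    )
    if not models:
        summary = pd.DataFrame(
            columns=["transcript_id", "n_exons", "events", "orf_status", "protein_len_aa"]
        )
        summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
        return summary

    sio.write_transcript_gtf(models, outdir / "models.gtf", gene_id=annotation.gene_id)
    sio.write_cryptic_exon_bed(models, outdir / "cryptic_exons.bed")
    events_rows = [
        {"transcript_id": m.id, "event": ev.type, "target": ev.target,
         "delta": ev.delta, "description": ev.describe()}
        for m in models for ev in m.events
    ]
    pd.DataFrame(events_rows, columns=["transcript_id", "event", "target", "delta", "description"]).to_csv(
        outdir / "events.tsv", sep="\t", index=False
    )
    support_rows = [
        {"transcript_id": m.id, "library": lib, "full_length_reads": n}
        for m in models for lib, n in sorted(m.support.items())
    ]
    pd.DataFrame(support_rows, columns=["transcript_id", "library", "full_length_reads"]).to_csv(
        outdir / "support.tsv", sep="\t", index=False
    )

    records = quantify.quantify_models(
        models, read_alignments(), annotation, mode=config.tpm_mode, mapq_min=config.mapq_min
    )
    quantify.expression_table(records).to_csv(outdir / "expression.tsv", sep="\t", index=False)
    tpm_wide = quantify.tpm_matrix(records)
    tpm_wide.to_csv(outdir / "tpm_matrix.tsv", sep="\t")

    orf_results = [
        orf_mod.find_orf(m, annotation, genome,
                         threshold_nt=config.nmd_threshold_nt, strict=config.nmd_strict)
        for m in models
    ]
    orf_mod.orf_table(orf_results).to_csv(outdir / "orf_results.tsv", sep="\t", index=False)
    sio.write_fasta(
        [(r.transcript_id, r.protein) for r in orf_results if r.protein],
        outdir / "proteins.fa",
    )

    domain_strings = {m.id: "" for m in models}
    if config.domains is not None:
        domain_defs = sio.read_domains(config.domains)
        canonical_orf = orf_mod.find_orf(
            TranscriptModel(id=annotation.canonical_name, exon_chain=tuple(annotation.exons_genomic)),
            annotation, genome,
        )
        calls = []
        for r in orf_results:
            if not r.protein:
                continue
            calls.extend(
                domains_mod.call_domains(
                    r.protein, canonical_orf.protein, domain_defs, transcript_id=r.transcript_id,
                    present_min=config.domain_present_min, absent_max=config.domain_absent_max,
                )
            )
        if calls:
            symbols, coverage = domains_mod.domain_matrix(calls)
            symbols.to_csv(outdir / "domain_matrix.tsv", sep="\t")
            coverage.to_csv(outdir / "domain_coverage.tsv", sep="\t")
            domain_strings.update(
                {tid: "".join(symbols.loc[tid]) for tid in symbols.index}
            )

    novelty = compare_to_annotation(models, annotation)
    novelty.to_csv(outdir / "novelty.tsv", sep="\t", index=False)

    orf_by_id = {r.transcript_id: r for r in orf_results}
    summary_rows = []
    for m in models:
        r = orf_by_id[m.id]
        row = {
            "transcript_id": m.id,
            "n_exons": len(m.exon_chain),
            "length_nt": m.length_nt,
            "events": ";".join(ev.describe() for ev in m.events) or "canonical",
            "category": novelty.set_index("transcript_id").loc[m.id, "category"],
            "orf_status": r.status,
            "protein_len_aa": r.protein_len_aa,
            "domains": domain_strings.get(m.id, ""),
        }
        for lib in sorted({lib for rec in records for lib in [rec.library]}):
            row[f"tpm_{lib}"] = float(tpm_wide.loc[m.id, lib])
        summary_rows.append(row)
    summary = pd.DataFrame(summary_rows)
    summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)

    _write_report(outdir / "report.md", annotation, stats, models, novelty, orf_results, config)
    return summary


def _write_report(path, annotation, stats, models, novelty, orf_results, config) -> None:
    counts = novelty["category"].value_counts().to_dict()
    coding = sum(1 for r in orf_results if r.status == "coding")
    nmd = sum(1 for r in orf_results if r.status == "nmd_candidate")
    lines = [
        f"# splicelens report: {annotation.gene_id}",
        "",
        f"- reads parsed: {stats.n_parsed}",
        f"- failed MAPQ >= {config.mapq_min}: {stats.n_mapq_failed}",
        f"- excluded as not full-length (fragments): {stats.n_not_full_length}",
        f"- full-length reads retained: {stats.n_full_length}",
        f"- reads in groups below min_support={config.min_support}: {stats.n_below_min_support}",
        f"- transcript models: {len(models)}",
        f"- novelty: {counts}",
        f"- coding models: {coding}; NMD candidates: {nmd}",
        f"- TPM mode: {config.tpm_mode}; NMD threshold: {config.nmd_threshold_nt} nt "
        f"({'strict' if config.nmd_strict else 'inclusive'})",
        "",
    ]
    Path(path).write_text("\n".join(lines))
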