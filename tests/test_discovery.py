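"""Discovery: chain extraction, full-length filter, collapsing, event calls."""

from __future__ import annotations

import pytest

from splicelens import (
    GenomeAnnotation,
    GenomicInterval,
    SimConfig,
    SkipExon,
    RetainIntron,
    AltDonor,
    CrypticExon,
    TranscriptModel,
    build_gene,
    call_events,
    classify_exons,
    collapse,
    extract_intron_chain,
    is_full_length,
    read_spliced_alignments,
    realize_isoform,
    simulate_alignments,
)
from splicelens.discovery import EXON_LABELS

from conftest import FIXTURE_EXONS, read_from_blocks


class TestIntronChain:
    def test_gaps_are_introns(self):
        aln = read_from_blocks([(0, 10), (60, 70)])
        assert [(i.start, i.end) for i in extract_intron_chain(aln).introns] == [(10, 60)]

    def test_single_block_empty_chain(self):
        aln = read_from_blocks([(0, 10)])
        assert len(extract_intron_chain(aln)) == 0

    def test_full_length_fixture_read(self):
        aln = read_from_blocks(FIXTURE_EXONS)
        assert [(i.start, i.end) for i in extract_intron_chain(aln).introns] == [
            (200, 300), (450, 600), (700, 800), (950, 1200)
        ]


class TestFullLengthFilter:
    def test_spanning_read_is_full_length(self, toy_annotation, full_length_read):
        assert is_full_length(full_length_read, toy_annotation)

    def test_read_missing_initiation_site(self, toy_annotation):
        aln = read_from_blocks([(160, 200), (300, 450), (600, 700), (800, 950), (1200, 1500)])
        assert not is_full_length(aln, toy_annotation)

    def test_read_not_reaching_last_exon(self, toy_annotation):
        aln = read_from_blocks([(100, 200), (300, 450), (600, 700), (800, 940)])
        assert not is_full_length(aln, toy_annotation)


class TestCollapse:
    def test_identical_reads_one_model(self, toy_annotation):
        reads = [read_from_blocks(FIXTURE_EXONS, read_id=f"r{i}") for i in range(100)]
        models, stats = collapse(reads, toy_annotation)
        assert len(models) == 1
        assert models[0].total_support == 100
        assert stats.n_full_length == 100
        assert models[0].id == "TOY1.v1"  # matches the annotated transcript

    def test_support_ordering(self, toy_annotation):
        skip = [(100, 200), (300, 450), (800, 950), (1200, 1500)]
        reads = [read_from_blocks(FIXTURE_EXONS, read_id=f"a{i}") for i in range(40)]
        reads += [read_from_blocks(skip, read_id=f"b{i}") for i in range(60)]
        models, _ = collapse(reads, toy_annotation)
        assert [m.total_support for m in models] == [60, 40]
        assert models[0].id == "sv.7"  # first novel id

    def test_fragments_never_create_models(self, toy_annotation):
        frag = [(620, 700), (800, 950), (1200, 1400)]  # misses the ATG
        reads = [read_from_blocks(FIXTURE_EXONS, read_id=f"a{i}") for i in range(5)]
        reads += [read_from_blocks(frag, read_id=f"f{i}") for i in range(50)]
        models, stats = collapse(reads, toy_annotation)
        assert len(models) == 1
        assert stats.n_not_full_length == 50

    def test_mapq_filter(self, toy_annotation):
        reads = [read_from_blocks(FIXTURE_EXONS, read_id=f"r{i}", mapq=0) for i in range(10)]
        with pytest.warns(UserWarning, match="no full-length"):
            models, stats = collapse(reads, toy_annotation, mapq_min=1)
        assert models == [] and stats.n_mapq_failed == 10

    def test_terminal_boundaries_are_modal(self, toy_annotation):
        """Terminal exon ends come from the most frequent read boundary."""
        blocks_a = [(100, 200), (300, 450), (600, 700), (800, 950), (1200, 1500)]
        blocks_b = [(110, 200), (300, 450), (600, 700), (800, 950), (1200, 1480)]
        reads = [read_from_blocks(blocks_a, read_id=f"a{i}") for i in range(7)]
        reads += [read_from_blocks(blocks_b, read_id=f"b{i}") for i in range(3)]
        models, _ = collapse(reads, toy_annotation)
        assert len(models) == 1
        assert (models[0].exon_chain[0].start, models[0].exon_chain[-1].end) == (100, 1500)
        assert models[0].total_support == 10

    def test_partition_invariant(self, toy_annotation):
        """Every retained full-length read lands in exactly one model."""
        skip = [(100, 200), (300, 450), (800, 950), (1200, 1500)]
        reads = [read_from_blocks(FIXTURE_EXONS, read_id=f"a{i}") for i in range(8)]
        reads += [read_from_blocks(skip, read_id=f"b{i}") for i in range(5)]
        models, stats = collapse(reads, toy_annotation, min_support=1)
        assert sum(m.total_support for m in models) == stats.n_full_length == 13

    def test_simulation_truth_recovery(self, tmp_path):
        cfg = SimConfig(
            n_reads=600, seed=13, full_length_frac=1.0,
            isoforms=[((SkipExon(3),), 0.5), ((RetainIntron(1),), 0.3), ((), 0.2)],
        )
        ann, genome = build_gene(cfg)
        iso = [realize_isoform(ann, ev) for ev, _ in cfg.isoforms]
        simulate_alignments(ann, genome, iso, cfg, tmp_path / "r.sam")
        models, _ = collapse(read_spliced_alignments(tmp_path / "r.sam"), ann)
        assert {m.intron_chain.key() for m in models} == {m.intron_chain.key() for m in iso}

    def test_jitter_merge_monotone(self, tmp_path):
        """With jitter and merge_window >= 3*sd, the number of recovered
        models is <= the number at window 0."""
        cfg = SimConfig(
            n_reads=400, seed=21, full_length_frac=1.0, junction_jitter_sd=2.0,
            isoforms=[((SkipExon(3),), 0.5), ((), 0.5)],
        )
        ann, genome = build_gene(cfg)
        iso = [realize_isoform(ann, ev) for ev, _ in cfg.isoforms]
        simulate_alignments(ann, genome, iso, cfg, tmp_path / "r.sam")
        m0, _ = collapse(
            read_spliced_alignments(tmp_path / "r.sam"), ann, merge_window=0, min_support=1
        )
        m6, _ = collapse(
            read_spliced_alignments(tmp_path / "r.sam"), ann, merge_window=6, min_support=1
        )
        assert len(m6) <= len(m0)
        assert len(m6) >= 2  # the two truth chains stay distinct


def _model(chain, toy_annotation):
    m = TranscriptModel(
        id="m", exon_chain=tuple(GenomicInterval("chrT", s, e, "+") for s, e in chain)
    )
    m.exon_labels = classify_exons(m, toy_annotation)
    return m


class TestClassifyExons:
    @pytest.mark.parametrize(
        "exon,label",
        [
            ((300, 450), "annotated"),
            ((1000, 1100), "cryptic"),
            ((300, 700), "retained_fusion"),
            ((320, 400), "truncated"),
            ((300, 470), "extended"),
            ((280, 450), "extended"),
        ],
    )
    def test_single_exon_labels(self, toy_annotation, exon, label):
        m = _model([(100, 200), exon] if exon[0] > 200 else [exon], toy_annotation)
        assert m.exon_labels[-1] == label

    def test_label_exclusivity(self, toy_annotation):
        """Every exon gets exactly one of the five labels."""
        m = _model([(100, 200), (300, 470), (600, 950), (1000, 1100), (1200, 1500)], toy_annotation)
        assert all(lbl in EXON_LABELS for lbl in m.exon_labels)
        assert len(m.exon_labels) == len(m.exon_chain)


class TestCallEvents:
    def test_skip_event(self, toy_annotation):
        m = _model([(100, 200), (300, 450), (800, 950), (1200, 1500)], toy_annotation)
        evs = call_events(m, toy_annotation)
        assert [(e.type, e.target) for e in evs] == [("exon_skipping", 3)]

    def test_alt_donor_delta(self, toy_annotation):
        m = _model([(100, 200), (300, 470), (600, 700), (800, 950), (1200, 1500)], toy_annotation)
        evs = call_events(m, toy_annotation)
        assert [(e.type, e.target, e.delta) for e in evs] == [("alt_donor", 2, 20)]

    def test_alt_acceptor_delta(self, toy_annotation):
        m = _model([(100, 200), (300, 450), (590, 700), (800, 950), (1200, 1500)], toy_annotation)
        evs = call_events(m, toy_annotation)
        assert [(e.type, e.target, e.delta) for e in evs] == [("alt_acceptor", 2, -10)]

    def test_canonical_no_events(self, toy_annotation):
        m = _model(FIXTURE_EXONS, toy_annotation)
        assert call_events(m, toy_annotation) == []

    def test_intron_retention(self, toy_annotation):
        m = _model([(100, 200), (300, 700), (800, 950), (1200, 1500)], toy_annotation)
        evs = call_events(m, toy_annotation)
        assert [(e.type, e.target) for e in evs] == [("intron_retention", 2)]

    def test_cryptic_event_iff_cryptic_label(self, toy_annotation):
        """A model has a cryptic_exon event iff it has a cryptic-labeled exon."""
        with_cx = _model(
            [(100, 200), (300, 450), (600, 700), (800, 950), (1000, 1100), (1200, 1500)],
            toy_annotation,
        )
        evs = call_events(with_cx, toy_annotation)
        cx = [e for e in evs if e.type == "cryptic_exon"]
        assert len(cx) == 1 and (cx[0].interval.start, cx[0].interval.end) == (1000, 1100)
        without = _model(FIXTURE_EXONS, toy_annotation)
        assert all(e.type != "cryptic_exon" for e in call_events(without, toy_annotation))

    def test_events_on_simulated_models_match_grammar(self, tmp_path):
        """Event calls on discovered models mirror the events that generated
        the truth isoforms (event/label consistency on minus strand too)."""
        for strand in "+-":
            cfg = SimConfig(
                n_reads=300, seed=31, strand=strand, full_length_frac=1.0,
                isoforms=[
                    ((SkipExon(3),), 0.3),
                    ((AltDonor(2, 12),), 0.3),
                    ((CrypticExon(4, 50, 90),), 0.2),
                    ((), 0.2),
                ],
            )
            ann, genome = build_gene(cfg)
            iso = [realize_isoform(ann, ev) for ev, _ in cfg.isoforms]
            simulate_alignments(ann, genome, iso, cfg, tmp_path / f"r{strand}.sam")
            models, _ = collapse(
                read_spliced_alignments(tmp_path / f"r{strand}.sam", gene_strand=strand), ann
            )
            called = {
                frozenset((e.type, e.target, e.delta) for e in m.events) for m in models
            }
            expected = {
                frozenset({("exon_skipping", 3, None)}),
                frozenset({("alt_donor", 2, 12)}),
                frozenset({("cryptic_exon", None, None)}),
                frozenset(),
            }
            assert called == expected


def test_strand_reversal_reverses_numbering(toy_exons):
    """Same genomic intervals on the minus strand number 5'->3' the other way."""
    flipped = tuple(
        GenomicInterval(e.chrom, e.start, e.end, "-") for e in reversed(toy_exons)
    )
    ann = GenomeAnnotation(
        gene_id="TOY1",
        locus=GenomicInterval("chrT", 100, 1500, "-"),
        exons=flipped,
        start_codon_pos=1400,
    )
    assert (ann.exons[0].start, ann.exons[0].end) == (1200, 1500)
    assert {(e.start, e.end) for e in ann.exons} == {(e.start, e.end) for e in toy_exons}
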