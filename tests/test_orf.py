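"""Coordinate mapping, ORF prediction and the 50-nt NMD rule."""

from __future__ import annotations

import numpy as np
import pytest

from splicelens import (
    CoordinateMap,
    Genome,
    GenomicInterval,
    OrfResult,
    SimConfig,
    SkipExon,
    RetainIntron,
    AltAcceptor,
    AltDonor,
    CrypticExon,
    TranscriptModel,
    build_gene,
    find_orf,
    nmd_classify,
    realize_isoform,
    spliced_sequence,
)

from conftest import FIXTURE_EXONS, translate


class TestCoordinateMap:
    @pytest.fixture
    def cmap(self, toy_exons):
        return CoordinateMap(toy_exons)

    @pytest.mark.parametrize("gpos,tpos", [(150, 50), (250, None), (300, 100), (100, 0)])
    def test_fixture_positions(self, cmap, gpos, tpos):
        assert cmap.genomic_to_transcript(gpos) == tpos

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_bijectivity(self, strand):
        """transcript<->genomic maps are mutual inverses on all exonic
        positions, both strands."""
        exons = [GenomicInterval("c", s, e, strand) for s, e in FIXTURE_EXONS]
        cmap = CoordinateMap(exons)
        for t in range(cmap.length):
            g = cmap.transcript_to_genomic(t)
            assert cmap.genomic_to_transcript(g) == t
        # monotone: increasing for +, decreasing for -
        gs = [cmap.transcript_to_genomic(t) for t in range(cmap.length)]
        diffs = np.diff(gs)
        assert all(d > 0 for d in diffs) if strand == "+" else all(d < 0 for d in diffs)

    def test_out_of_range(self, cmap):
        with pytest.raises(IndexError):
            cmap.transcript_to_genomic(cmap.length)
        assert cmap.genomic_to_transcript(50) is None  # upstream of the gene


def _orf_with(stop_to_junction):
    return OrfResult(transcript_id="m", status="coding", start_tpos=0, stop_tpos=30,
                     stop_to_last_junction_nt=stop_to_junction)


MODEL = TranscriptModel(id="m", exon_chain=(GenomicInterval("c", 0, 100), GenomicInterval("c", 200, 300)))


class TestNmdRule:
    def test_far_upstream_stop_is_nmd(self):
        assert nmd_classify(_orf_with(100), MODEL, threshold_nt=50) == "nmd_candidate"

    def test_exactly_threshold_is_coding(self):
        """'More than 50 nt' is strict: a stop exactly 50 nt upstream codes."""
        assert nmd_classify(_orf_with(50), MODEL, threshold_nt=50) == "coding"
        assert nmd_classify(_orf_with(50), MODEL, threshold_nt=50, strict=False) == "nmd_candidate"

    def test_stop_in_last_exon_is_coding(self):
        assert nmd_classify(_orf_with(-20), MODEL, threshold_nt=50) == "coding"

    def test_mono_exonic_is_coding(self):
        assert nmd_classify(_orf_with(None), MODEL) == "coding"

    def test_threshold_monotonicity(self):
        """Raising threshold_nt never converts coding -> nmd_candidate."""
        for d in (-10, 0, 30, 50, 51, 80, 200):
            statuses = [
                nmd_classify(_orf_with(d), MODEL, threshold_nt=t) for t in (40, 50, 55, 100)
            ]
            # once coding at some threshold, coding at every larger threshold
            seen_coding = False
            for s in statuses:
                if s == "coding":
                    seen_coding = True
                assert not (seen_coding and s == "nmd_candidate")

    def test_requires_stop(self):
        with pytest.raises(ValueError):
            nmd_classify(OrfResult(transcript_id="m", status="coding_no_stop"), MODEL)


@pytest.fixture(scope="module")
def sim_gene():
    cfg = SimConfig(n_exons=6, seed=8)
    ann, genome = build_gene(cfg)
    return ann, Genome(genome)


class TestFindOrf:
    def test_canonical_is_coding_and_matches_oracle(self, sim_gene):
        ann, genome = sim_gene
        model = realize_isoform(ann, [])
        r = find_orf(model, ann, genome)
        assert r.status == "coding"
        seq = spliced_sequence(model.exon_chain, genome)
        assert r.protein == translate(seq[r.start_tpos:])
        assert r.stop_to_last_junction_nt < 0  # stop inside the last exon
        assert "*" not in r.protein

    def test_model_lacking_atg_exon_is_no_start(self, sim_gene):
        ann, genome = sim_gene
        model = realize_isoform(ann, [SkipExon(1)])
        assert find_orf(model, ann, genome).status == "no_start"

    def test_frameshifting_skip_is_nmd_candidate(self, sim_gene):
        """Skipping an internal exon of length not divisible by 3 shifts the
        frame and almost surely raises a PTC upstream of the last junction."""
        ann, genome = sim_gene
        target = next(
            i for i, e in enumerate(ann.exons[1:-1], start=2) if len(e) % 3 != 0
        )
        model = realize_isoform(ann, [SkipExon(target)])
        r = find_orf(model, ann, genome)
        seq = spliced_sequence(model.exon_chain, genome)
        assert r.protein == translate(seq[r.start_tpos:])
        assert r.status == "nmd_candidate"
        assert r.stop_to_last_junction_nt > 50

    def test_frame_conservation_mod3_skip(self, sim_gene):
        """Removing an in-frame exon upstream of the stop leaves the
        downstream reading frame (and the protein tail) unchanged."""
        ann, genome = sim_gene
        canonical = find_orf(realize_isoform(ann, []), ann, genome)
        mod3 = [i for i, e in enumerate(ann.exons[1:-1], start=2) if len(e) % 3 == 0]
        assert mod3, "fixture seed provides an internal exon of in-frame length"
        r = find_orf(realize_isoform(ann, [SkipExon(mod3[0])]), ann, genome)
        # frame downstream of the skip is preserved, so the tail survives
        assert canonical.protein[-25:] == r.protein[-25:]

    def test_translation_oracle_random_models(self):
        """Protein output equals brute-force codon-table translation of the
        spliced sequence for 100 random simulated models."""
        rng = np.random.default_rng(99)
        checked = 0
        seed = 0
        while checked < 100:
            seed += 1
            cfg = SimConfig(n_exons=int(rng.integers(4, 9)), seed=seed)
            ann, genome_d = build_gene(cfg)
            genome = Genome(genome_d)
            events = _random_events(ann, rng)
            try:
                model = realize_isoform(ann, events)
            except ValueError:
                continue
            r = find_orf(model, ann, genome)
            if r.status == "no_start":
                assert CoordinateMap(model.exon_chain).genomic_to_transcript(
                    ann.start_codon_pos
                ) is None or CoordinateMap(model.exon_chain).length - CoordinateMap(
                    model.exon_chain
                ).genomic_to_transcript(ann.start_codon_pos) < 3
            else:
                seq = spliced_sequence(model.exon_chain, genome)
                assert r.protein == translate(seq[r.start_tpos:])
                assert "*" not in r.protein
            checked += 1


def _random_events(ann, rng):
    n = len(ann.exons)
    kind = rng.integers(0, 5)
    if kind == 0:
        return [SkipExon(int(rng.integers(2, n)))]
    if kind == 1:
        return [RetainIntron(int(rng.integers(1, n)))]
    if kind == 2:
        return [AltDonor(int(rng.integers(1, n)), int(rng.integers(-20, 40)) or 3)]
    if kind == 3:
        return [AltAcceptor(int(rng.integers(1, n)), int(rng.integers(-20, 40)) or 3)]
    return [CrypticExon(int(rng.integers(1, n)), 30, int(rng.integers(20, 120)))]
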