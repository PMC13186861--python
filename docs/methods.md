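# Methods

## Problem setting and model

The package analyzes targeted amplicon long-read data for one gene. The
amplicon design pins both transcript ends: the forward primer sits just
upstream of the annotated translation initiation site, the reverse primer
inside the last annotated exon. Under that design, a read is informative
about splice structure only if it covers the whole coding span; shorter
reads are fragmentation artifacts of library preparation. The pipeline
therefore defines a **full-length read** as one whose aligned span contains
the genomic position of the annotated ATG and whose 3'-most aligned block
overlaps the last exon, and discards everything else from model building
and quantification (the counts in and out of every filter are logged and
reported, so the exclusions are auditable).

**Variant identity is the intron chain**: the ordered set of intron
coordinates extracted from the gaps (`N` CIGAR operations) between aligned
blocks. Two reads with identical chains are the same splice variant. This
is exact by default because the intended input is polished/corrected long
reads; an optional junction merge window `w` snaps intron boundaries within
`w` nt of each other to the most frequent boundary of their cluster
(single-linkage, tie toward the smaller coordinate), for noisier inputs.
Merging is monotone: a larger window can only reduce the number of distinct
chains.

Terminal exon boundaries are not part of the chain; they are set to the
modal terminal block boundary over each group's reads (ties broken toward
the longer exon). With both amplicon ends fixed by primers the mode is
stable; with 20% simulated truncation it is dominated by the full-length
majority.

Models sort by descending full-length support, then genomic position of
the first intron. A model whose chain matches an annotated transcript keeps
the annotated name and is reported as non-novel; novel models are numbered
`sv.<k>` starting at 7 by default (configurable), reflecting the common
convention of reserving low numbers for annotated variants of a well-studied
gene.

## Event classification

Each model exon is labelled against the canonical exon ladder:
`annotated` (exact match), `truncated` (proper subset of one annotated
exon), `extended` (carries intronic sequence beyond an annotated boundary —
this label also covers the mixed case of an exon that extends past one
boundary while receding from the other, since it too contains intronic
sequence), `retained_fusion` (spans ≥ 2 annotated exons plus intervening
intron(s)), `cryptic` (overlaps no annotated exon). The five labels are
exhaustive and mutually exclusive.

Events are called per model junction and exon, in genomic order:

- **exon_skipping** — a model junction fully contains an annotated exon.
- **alt_donor / alt_acceptor** — a junction shares exactly one boundary
  with an annotated junction; the shift `Δ` of the other boundary is signed
  in transcription direction (positive = downstream), strand-aware
  (donor = 5' splice site). Junction boundaries that coincide with a
  cryptic exon's edge are attributed to the cryptic_exon event, not to an
  alt-site shift.
- **intron_retention** — an annotated intron lies wholly inside one model
  exon (one event per retained intron).
- **cryptic_exon** — one event per cryptic-labelled exon, with its
  interval; written to BED as well.
- **alt_terminal_exon** — the model's outermost exon fails to overlap the
  corresponding annotated terminal exon.

## Quantification

TPM per library from full-length counts. Default mode is the standard
length-normalized TPM (`rate_i = c_i / l_i`, scaled to 1e6); a count-based
mode (`c_i / Σc · 1e6`) is offered because full-length counting of an
amplicon arguably needs no length correction — a full-length read is one
molecule regardless of isoform length. Reports state the mode. Transcripts
unseen in a library are emitted with TPM 0 so absence is explicit. Sums per
library equal 1e6 (relative tolerance 1e-6) whenever any count is nonzero;
an all-zero library warns and reports zeros.

## ORF and NMD

Translation starts only at the annotated initiation codon of the canonical
mRNA, mapped through the model's genomic↔transcript coordinate bijection
(strictly increasing on +, decreasing on −). If the ATG position is
unmapped (its exon skipped or truncated away) the model is `no_start`.
Otherwise codons are scanned 5'→3' to the first stop (standard nuclear
code, via Biopython). The distance from the base after the stop codon to
the final exon–exon junction drives the NMD call: more than 50 nt upstream
(strict inequality; threshold and strictness configurable, reflecting the
50–55 nt range quoted in the NMD literature) → `nmd_candidate`; otherwise
`coding`. Mono-exonic models have no junction and are always coding. Models
with no in-frame stop — possible for 3'-truncated chains — are reported as
`coding_no_stop` and excluded from coding counts, since they are artifacts
of model truncation rather than genuine ORFs. Alternative upstream or
downstream AUGs, readthrough and selenocysteine are deliberately out of
scope.

## Domain retention

Each predicted protein is globally aligned to the canonical protein with
affine gap scoring (match +1, mismatch −1, gap open −10, gap extend −0.5;
configurable). A domain's **coverage** is the fraction of its canonical
positions paired with an *identical* isoform residue. Counting identity
rather than mere pairing makes the measure robust to frameshifted tails,
which align but do not match. Thresholds: ≥ 0.9 present, < 0.3 absent,
otherwise partial; strict mode collapses partial to absent, reproducing a
binary check/dash matrix. For clean in-frame deletions, coordinate
bookkeeping and alignment give identical answers; they can differ for
frameshifts, where the alignment-based measure is the one implemented.
Domain coordinates ship as a user-editable TSV;
`examples/brca2_domains.synthetic.tsv` is a synthetic placeholder showing
the layout, to be replaced with curated coordinates before interpretation.

## Synthetic data generator

The generator emulates the amplicon design: a random multi-exon gene
(defaults: 10 exons of 120–300 nt, introns of 250–600 nt) with canonical
`GT..AG` dinucleotides at every annotated intron boundary, an ATG written
into exon 1 at a recorded offset, and a clean canonical ORF. Rather than
rejection-sampling sequences, any premature in-frame stop codon is repaired
deterministically (its third base rewritten to a non-stop base through the
coordinate map, handling junction-spanning codons) and a TAA stop is placed
in frame inside the last exon — same guarantee, one pass, fully
deterministic. Minus-strand genes are built on the plus sense and mirrored
(reverse-complement plus coordinate reflection), so both strands exercise
identical logic.

Truth isoforms come from the event grammar (skip, intron retention, alt
donor/acceptor with signed transcription-direction shifts, cryptic exon at
an offset from the intron's 5' end); incompatible combinations raise.
Reads are drawn multinomially from abundance weights; libraries from
library weights; each read is full-length with probability
`full_length_frac`, otherwise it loses a uniform-random prefix or suffix
(the `both` model picks a side at random). Junction jitter (normal,
rounded, clamped to keep blocks and introns ≥ 1 nt) is the only error
knob — aligned block sequences are exact, because the intended input is
polished reads. Alignments are written directly from truth as SAM (no
aligner is invoked), with read-group library tags; outputs are
byte-deterministic given the seed.

Default study conditions mirror a five-isoform design — exon skip, intron
retention, +12 nt donor shift, a 127-nt cryptic exon, canonical — at
abundances 0.4/0.2/0.2/0.1/0.1, 2000 reads, 80% full-length, jitter 0,
three libraries named for cancer-type pools (breast 0.4, ovarian 0.4,
cervical 0.2). What the simulator does **not** model: base-level sequencing
errors inside blocks, PCR chimeras, internal fragments missing both ends,
quality scores, homopolymer artifacts. Passing tests therefore demonstrate
correctness of the pipeline's logic on polished, single-locus data, not
robustness to raw-read error profiles or off-target alignment.

## Numerical and design choices

- Coordinates are 0-based half-open internally; GTF converts at the I/O
  boundary; BED is native half-open.
- Library labels come from SAM read groups by default (a configurable tag
  overrides), since native-barcoding workflows have no single convention;
  missing labels fall back to `default` with a warning.
- Secondary and supplementary alignments are excluded everywhere: one
  molecule, one vote. Default MAPQ threshold is 1 (single-locus amplicon;
  configurable).
- Minimum model support defaults to 3 full-length reads (configurable).
- Pipeline exit codes: 0 success, 2 config error, 3 stage failure.
- Problem sizes in the test and acceptance runs (2000 reads, 10 exons,
  up to 100 random models for the translation oracle) were chosen as the
  smallest sizes at which the binomial recovery bounds are meaningful.

## Known limitations

Single-gene scope (no fusions, no multi-locus); no genome-free assembly;
no EM-style assignment (full-length chains are unambiguous by
construction); no uORF/Kozak analysis; heatmap data are emitted as TSV
only. The discovery step assumes the annotation's canonical transcript is
a sound reference ladder — genes whose annotated transcripts disagree
wildly on exon boundaries would need a chosen reference transcript.
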