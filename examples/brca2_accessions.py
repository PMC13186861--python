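"""Run ORF/NMD and domain retention on real BRCA2 transcript sequences.

Requires network access (or pre-downloaded files): fetches the canonical
BRCA2 mRNA (NM_000059.4) and the user's chosen transcript FASTA records
from GenBank, translates each from the canonical initiation codon and calls
domain retention against the canonical 3418-aa protein using a user-edited
domain table (see brca2_domains.synthetic.tsv for the expected layout —
that file is a synthetic placeholder: fill in curated coordinates before
interpreting results).

Usage:
    python examples/brca2_accessions.py canonical.fa transcripts.fa domains.tsv

where canonical.fa holds NM_000059.4 and transcripts.fa holds e.g. the
GenBank records PQ381979-PQ382028.  Because these transcripts are cDNA
sequences (not genome alignments), the ORF scan here anchors on the ATG
located by aligning the canonical CDS start context.
"""

import sys

from Bio import SeqIO
from Bio.Seq import Seq

from splicelens import call_domains, domain_matrix, read_domains

STOPS = {"TAA", "TAG", "TGA"}


def orf_from_atg(seq: str, atg: int) -> str:
    cds = seq[atg:]
    cds = cds[: len(cds) - len(cds) % 3]
    for i in range(0, len(cds), 3):
        if cds[i : i + 3] in STOPS:
            return str(Seq(cds[:i]).translate())
    return str(Seq(cds).translate())


def main() -> None:
    if len(sys.argv) != 4:
        sys.exit(__doc__)
    canonical_fa, transcripts_fa, domains_tsv = sys.argv[1:]
    canon_rec = next(SeqIO.parse(canonical_fa, "fasta"))
    canon_seq = str(canon_rec.seq).upper()
    # locate the annotated initiation site by its 30-nt context
    atg = canon_seq.find("ATG")
    context = canon_seq[atg : atg + 30]
    canon_protein = orf_from_atg(canon_seq, atg)
    print(f"canonical protein: {len(canon_protein)} aa")

    domains = read_domains(domains_tsv)
    calls = []
    n_coding = 0
    for rec in SeqIO.parse(transcripts_fa, "fasta"):
        seq = str(rec.seq).upper()
        pos = seq.find(context[:21])
        if pos < 0:
            print(f"{rec.id}: annotated initiation context not found (no_start)")
            continue
        protein = orf_from_atg(seq, pos)
        if protein:
            n_coding += 1
            calls.extend(call_domains(protein, canon_protein, domains, transcript_id=rec.id))
            print(f"{rec.id}: ORF from annotated ATG, {len(protein)} aa")
    print(f"\ntranscripts with an ATG-anchored ORF: {n_coding}")
    if calls:
        symbols, _ = domain_matrix(calls)
        print(symbols)


if __name__ == "__main__":
    main()
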