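"""Per-library TPM of discovered isoforms from full-length read counts.

Prints the wide transcripts x libraries TPM matrix (the heatmap-ready
table); each library column sums to one million.
"""

import tempfile
from pathlib import Path

from splicelens import (
    SimConfig, collapse, quantify_models, read_gtf, read_spliced_alignments, simulate, tpm_matrix,
)

outdir = Path(tempfile.mkdtemp())
paths = simulate(SimConfig(seed=1), outdir)
annotation = read_gtf(paths["gtf"])
models, _ = collapse(read_spliced_alignments(paths["sam"]), annotation)

records = quantify_models(
    models, read_spliced_alignments(paths["sam"]), annotation, mode="count_based"
)
matrix = tpm_matrix(records)
print(matrix.round(1))
print("\ncolumn sums:", matrix.sum().round(1).to_dict())
# TPM is normalized per library, so each column sums to 1e6; a cell of 0
# means the variant was never seen full-length in that library.
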