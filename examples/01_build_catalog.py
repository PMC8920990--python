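"""Build a tRNA gene catalog from BED6 annotations + a genome FASTA.

Writes a tiny two-gene toy input, loads it, and prints each gene's genomic
3'-terminal group.  A gene whose genomic sequence already ends in CCA (or CC)
makes reads ending in CCA (CC) ambiguous — they could be immature transcripts
rather than mature, CCA-added tRNAs — which is why the downstream
classification is always stratified by this group.
"""

import tempfile
from pathlib import Path

import numpy as np

from trnaterm import load_catalog, three_prime_window

rng = np.random.default_rng(1)
genome = "".join(rng.choice(list("ACGT"), size=2_000))
# force geneA to end in genomic CCA; geneB (minus strand) ends wherever it ends
genome = genome[:497] + "CCA" + genome[500:]

with tempfile.TemporaryDirectory() as d:
    fa = Path(d) / "toy.fa"
    fa.write_text(f">chrT\n{genome}\n")
    bed = Path(d) / "toy.bed"
    bed.write_text(
        "chrT\t428\t500\tgeneA\t0\t+\n"   # [428, 500): ends ...CCA
        "chrT\t700\t772\tgeneB\t0\t-\n"
    )
    catalog = load_catalog(bed, fa)

print(f"{len(catalog)} genes; group sizes: {catalog.group_sizes()}")
for gene in catalog:
    chrom, ws, we, strand = three_prime_window(gene, k=5)
    print(f"  {gene.gene_id} ({gene.strand}) ends ...{gene.seq[-6:]} -> "
          f"group {gene.terminal_group}; 3'-end window {chrom}:{ws}-{we}")
# geneA lands in group CCA (its genome encodes the CCA), so CCA-ending reads
# from geneA are ambiguous; geneB's group depends on its random terminal bases.
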