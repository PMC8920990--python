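"""tRNA gene catalog: annotations, genomic sequences and 3'-terminal groups.

A mature tRNA acquires its 3'-CCA post-transcriptionally, but some tRNA gene
loci already *encode* CCA (or CC) at their genomic 3' end.  A sequenced read
ending in CCA is therefore only unambiguous evidence of post-transcriptional
addition when its source gene does not itself end in CCA.  The catalog
classifies every gene into one of three terminal groups (CCA / CC / OTHER) so
that downstream read classification can be stratified by this genomic
ambiguity.

Coordinates are 0-based half-open (BED convention) throughout; gene sequences
are stored 5'->3' on the gene strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from pyfaidx import Fasta

__all__ = [
    "TRNAGene",
    "GeneCatalog",
    "terminal_group",
    "three_prime_window",
    "load_catalog",
    "read_catalog_tsv",
    "write_catalog_tsv",
    "revcomp",
]

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N passes through)."""
    return seq.translate(_COMP)[::-1]


class CatalogError(ValueError):
    """Malformed annotation or reference mismatch."""


def terminal_group(seq: str) -> str:
    """Classify a gene sequence by its genomic 3'-terminal bases.

    Longest suffix wins: ``CCA`` is checked before ``CC``; anything else is
    ``OTHER``.  Case-insensitive.
    """
    if not seq:
        raise CatalogError("terminal_group: empty sequence")
    s = seq.upper()
    if s.endswith("CCA"):
        return "CCA"
    if s.endswith("CC"):
        return "CC"
    return "OTHER"


@dataclass(frozen=True)
class TRNAGene:
    """An annotated tRNA locus.

    ``seq`` is the genomic sequence 5'->3' on the gene strand, i.e. already
    reverse-complemented for minus-strand genes.  ``terminal_group`` is
    recomputable from ``seq`` (an invariant the tests assert).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    seq: str
    terminal_group: str
    is_mito: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CatalogError(
                f"{self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise CatalogError(f"{self.gene_id}: strand must be '+' or '-'")
        if len(self.seq) != self.end - self.start:
            raise CatalogError(
                f"{self.gene_id}: sequence length {len(self.seq)} != interval "
                f"length {self.end - self.start}"
            )

    def __len__(self) -> int:
        return self.end - self.start


def three_prime_window(gene: TRNAGene, k: int = 5) -> tuple[str, int, int, str]:
    """Genomic interval of the last ``k`` bases of the gene, strand-aware.

    Returns ``(chrom, start, end, strand)`` in 0-based half-open coordinates.
    On the plus strand the 3' end is the right edge of the interval; on the
    minus strand it is the left edge.
    """
    if k < 1 or k > len(gene):
        raise CatalogError(
            f"{gene.gene_id}: window size {k} outside [1, {len(gene)}]"
        )
    if gene.strand == "+":
        return (gene.chrom, gene.end - k, gene.end, "+")
    return (gene.chrom, gene.start, gene.start + k, "-")


@dataclass
class GeneCatalog:
    """Ordered collection of :class:`TRNAGene` plus the genome it lives on.

    ``genome`` keeps the reference sequences in memory (desk-scale genomes);
    it is used by the simulator for 3'-trailer bases and by closed-form truth
    computations.  ``genome_ids`` always reflects the reference names present.
    """

    genes: list[TRNAGene]
    genome_ids: set[str] = field(default_factory=set)
    genome: dict[str, str] | None = None

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CatalogError(f"duplicate gene ids: {dupes}")
        if self.genome is not None and not self.genome_ids:
            self.genome_ids = set(self.genome)
        missing = {g.chrom for g in self.genes} - self.genome_ids
        if missing:
            raise CatalogError(f"genes reference unknown sequences: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def group_sizes(self) -> dict[str, int]:
        sizes = {"CCA": 0, "CC": 0, "OTHER": 0}
        for g in self.genes:
            sizes[g.terminal_group] += 1
        return sizes

    def downstream(self, gene: TRNAGene, n: int) -> str:
        """Up to ``n`` genomic bases immediately 3' of the gene, on the gene
        strand (pre-tRNA trailer sequence)."""
        if self.genome is None:
            raise CatalogError("catalog carries no genome sequences")
        ref = self.genome[gene.chrom]
        if gene.strand == "+":
            return ref[gene.end : gene.end + n].upper()
        lo = max(0, gene.start - n)
        return revcomp(ref[lo : gene.start].upper())


def _gene_from_interval(
    gene_id: str,
    chrom: str,
    start: int,
    end: int,
    strand: str,
    genome: dict[str, str],
    is_mito: bool,
) -> TRNAGene:
    if chrom not in genome:
        raise CatalogError(f"{gene_id}: unknown reference sequence {chrom!r}")
    ref = genome[chrom]
    if start < 0 or end > len(ref) or start >= end:
        raise CatalogError(
            f"{gene_id}: interval [{start}, {end}) outside {chrom} "
            f"(length {len(ref)})"
        )
    sub = ref[start:end].upper()
    seq = sub if strand == "+" else revcomp(sub)
    return TRNAGene(
        gene_id=gene_id,
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        seq=seq,
        terminal_group=terminal_group(seq),
        is_mito=is_mito,
    )


_BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def _read_bed6(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=range(6),
        names=_BED6_COLS,
        dtype={"chrom": str, "start": int, "end": int, "name": str, "strand": str},
    )
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise CatalogError(f"BED strand column must be +/-: {df[bad].iloc[0].tolist()}")
    return df


def load_catalog(bed, fasta, mito_bed=None) -> GeneCatalog:
    """Build a :class:`GeneCatalog` from BED6 annotations and a genome FASTA.

    Parameters
    ----------
    bed : path or file-like
        BED6 records of tRNA gene loci (cytoplasmic genes).
    fasta : path
        Genome FASTA containing every chromosome named in the BED.
    mito_bed : path or file-like, optional
        Extra BED6 records flagged ``is_mito`` (e.g. the mitochondrial
        tRNA-Ser-GCT locus), resolved against the same FASTA.
    """
    with Fasta(str(fasta), as_raw=True, sequence_always_upper=True) as fa:
        genome = {name: str(fa[name][:]) for name in fa.keys()}
    genes: list[TRNAGene] = []
    for source, mito in ((bed, False), (mito_bed, True)):
        if source is None:
            continue
        for row in _read_bed6(source).itertuples(index=False):
            genes.append(
                _gene_from_interval(
                    row.name, row.chrom, row.start, row.end, row.strand, genome, mito
                )
            )
    return GeneCatalog(genes=genes, genome_ids=set(genome), genome=genome)


_TSV_COLS = [
    "gene_id", "chrom", "start", "end", "strand",
    "terminal_group", "is_mito", "seq",
]


def write_catalog_tsv(catalog: GeneCatalog, path) -> None:
    rows = [
        (g.gene_id, g.chrom, g.start, g.end, g.strand, g.terminal_group,
         int(g.is_mito), g.seq)
        for g in catalog
    ]
    pd.DataFrame(rows, columns=_TSV_COLS).to_csv(path, sep="\t", index=False)


def read_catalog_tsv(path) -> GeneCatalog:
    """Read a catalog TSV written by :func:`write_catalog_tsv`.

    The genome itself is not stored in the TSV, so the returned catalog has
    ``genome=None`` and ``genome_ids`` inferred from the gene rows.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    genes = [
        TRNAGene(
            gene_id=str(r.gene_id), chrom=r.chrom, start=int(r.start),
            end=int(r.end), strand=r.strand, seq=str(r.seq),
            terminal_group=str(r.terminal_group), is_mito=bool(r.is_mito),
        )
        for r in df.itertuples(index=False)
    ]
    return GeneCatalog(genes=genes, genome_ids={g.chrom for g in genes})
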