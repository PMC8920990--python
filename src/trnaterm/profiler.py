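"""3'-end read extraction, ID re-join and terminal-status calling.

After the CCA-trimmed set is aligned, only alignments overlapping the last 5
genomic bases of a tRNA gene (strand-matched) are kept — these are the
"3'-end containing reads".  Each is re-joined by read ID to its
adapter-trimmed-only sequence, and classified from the suffix recorded at
trimming time:

* suffix CCA  -> ``CCA_added``
* suffix CC   -> ``CC_terminating``
* suffix none -> ``other`` (immature genomic ends, 3'-trailer reads, ...)

Every call carries the source gene's genomic terminal group (CCA / CC /
OTHER) because a CCA-suffix read from a gene whose genome already ends in
CCA is ambiguous — the stratification, not the call, resolves that.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd
import pysam

from .align import AlignmentHit
from .catalog import GeneCatalog, three_prime_window
from .trimming import TrimmedRead

__all__ = [
    "EndRead",
    "TerminalCall",
    "extract_end_reads",
    "match_original",
    "call_terminus",
    "tally",
    "CALL_BY_SUFFIX",
]

GROUPS = ("CCA", "CC", "OTHER")
CALL_BY_SUFFIX = {"CCA": "CCA_added", "CC": "CC_terminating", "none": "other"}


class IntegrityError(RuntimeError):
    """Bookkeeping violation between pipeline stages (a bug, not bad data)."""


@dataclass(frozen=True)
class EndRead:
    read_id: str
    gene_id: str
    overlap_len: int
    alignment: AlignmentHit
    suffix: str          # CCA | CC | none, from the trimming sidecar
    ambiguous: bool = False


@dataclass(frozen=True)
class TerminalCall:
    read_id: str
    gene_id: str
    group: str           # gene's genomic terminal group
    call: str            # CCA_added | CC_terminating | other
    is_mito: bool = False


def _hits_from_sam(sam_path) -> list[AlignmentHit]:
    hits = []
    with pysam.AlignmentFile(str(sam_path)) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            hits.append(
                AlignmentHit(
                    read_id=rec.query_name,
                    ref=rec.reference_name,
                    pos=rec.reference_start,
                    strand="-" if rec.is_reverse else "+",
                    n_mismatch=int(rec.get_tag("NM")) if rec.has_tag("NM") else 0,
                    aln_len=rec.reference_end - rec.reference_start,
                    n_equal_best=int(rec.get_tag("XE")) if rec.has_tag("XE") else 1,
                )
            )
    return hits


def extract_end_reads(
    alignments: Iterable[AlignmentHit] | str,
    catalog: GeneCatalog,
    suffixes: dict[str, str],
    window_k: int = 5,
) -> list[EndRead]:
    """Select alignments overlapping a gene's 3'-end window by >= 1 base.

    ``alignments`` is an iterable of hits or a SAM path.  Strand must match
    the gene strand (ligation-based libraries are stranded).  A read
    overlapping windows of several genes goes to the larger overlap; ties go
    to the first gene in catalog order and are flagged ambiguous.
    ``suffixes`` maps read_id -> terminal suffix from the trimming sidecar.
    """
    if isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__"):
        alignments = _hits_from_sam(alignments)
    else:
        alignments = list(alignments)
    known_refs = catalog.genome_ids
    windows: dict[str, list[tuple[int, int, str, int]]] = {}
    for gi, gene in enumerate(catalog.genes):
        chrom, ws, we, strand = three_prime_window(gene, k=window_k)
        windows.setdefault(chrom, []).append((ws, we, strand, gi))

    out: list[EndRead] = []
    for hit in alignments:
        if hit.ref not in known_refs:
            raise IntegrityError(
                f"alignment reference {hit.ref!r} absent from catalog genome"
            )
        best_gi, best_ov, n_best = -1, 0, 0
        for ws, we, strand, gi in windows.get(hit.ref, ()):
            if strand != hit.strand:
                continue
            ov = min(hit.pos + hit.aln_len, we) - max(hit.pos, ws)
            if ov >= 1:
                if ov > best_ov:
                    best_gi, best_ov, n_best = gi, ov, 1
                elif ov == best_ov:
                    n_best += 1
        if best_gi < 0:
            continue
        gene = catalog.genes[best_gi]
        out.append(
            EndRead(
                read_id=hit.read_id,
                gene_id=gene.gene_id,
                overlap_len=best_ov,
                alignment=hit,
                suffix=suffixes.get(hit.read_id, "none"),
                ambiguous=n_best > 1,
            )
        )
    return out


def match_original(
    end_reads: list[EndRead],
    only_adapter: dict[str, TrimmedRead],
) -> list[tuple[EndRead, TrimmedRead]]:
    """Join every 3'-end read to its adapter-trimmed-only sequence by ID.

    The join must be total: a missing ID means the trimming/alignment
    bookkeeping is broken, and raises :class:`IntegrityError`.
    """
    joined = []
    for er in end_reads:
        orig = only_adapter.get(er.read_id)
        if orig is None:
            raise IntegrityError(f"read {er.read_id} missing from Only-Adapter set")
        joined.append((er, orig))
    return joined


def call_terminus(end_read: EndRead, original: TrimmedRead,
                  catalog_by_id: dict[str, object]) -> TerminalCall:
    """Classify one joined record from its recorded suffix.

    Consistency check: the adapter-trimmed-only sequence must still end with
    the recorded suffix (the CCA-trimmed sequence plus suffix reconstructs
    it); violation raises :class:`IntegrityError`.
    """
    if end_read.suffix != "none" and not original.seq.upper().endswith(end_read.suffix):
        raise IntegrityError(
            f"read {end_read.read_id}: recorded suffix {end_read.suffix} not "
            f"present at the 3' end of the untrimmed sequence"
        )
    gene = catalog_by_id[end_read.gene_id]
    return TerminalCall(
        read_id=end_read.read_id,
        gene_id=end_read.gene_id,
        group=gene.terminal_group,
        call=CALL_BY_SUFFIX[end_read.suffix],
        is_mito=gene.is_mito,
    )


def classify(end_reads: list[EndRead], only_adapter: dict[str, TrimmedRead],
             catalog: GeneCatalog) -> list[TerminalCall]:
    """match_original + call_terminus over a library."""
    by_id = {g.gene_id: g for g in catalog.genes}
    return [call_terminus(er, orig, by_id)
            for er, orig in match_original(end_reads, only_adapter)]


def tally(calls: list[TerminalCall], catalog: GeneCatalog,
          condition: str, replicate: int) -> pd.DataFrame:
    """Per-group (and per-gene, and mito) counts of the three call classes.

    Returns a tidy frame with columns (condition, replicate, level, key,
    n_cca_added, n_cc_terminating, n_other, n_total) where level is one of
    ``group`` (the three genomic terminal groups), ``gene`` or ``mito`` (all
    mitochondrial-flagged genes pooled, reported separately even when empty).
    """
    call_col = {"CCA_added": "n_cca_added", "CC_terminating": "n_cc_terminating",
                "other": "n_other"}
    rows: dict[tuple[str, str], dict[str, int]] = {}

    def bump(level: str, key: str, call: str | None) -> None:
        r = rows.setdefault((level, key), {v: 0 for v in call_col.values()})
        if call is not None:
            r[call_col[call]] += 1

    for grp in GROUPS:
        bump("group", grp, None)
    bump("mito", "mito", None)
    for g in catalog.genes:
        bump("gene", g.gene_id, None)
    for c in calls:
        bump("group", c.group, c.call)
        bump("gene", c.gene_id, c.call)
        if c.is_mito:
            bump("mito", "mito", c.call)
    records = []
    for (level, key), r in rows.items():
        n_total = sum(r.values())
        records.append({"condition": condition, "replicate": replicate,
                        "level": level, "key": key, **r, "n_total": n_total})
    return pd.DataFrame.from_records(records)
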