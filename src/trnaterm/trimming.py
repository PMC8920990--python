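"""Adapter and 3'-terminal (CCA/CC) trimming with per-read provenance.

The terminal-status analysis needs *two* trimmed versions of every library:

* ``Only Adapter-trimmed`` — the 3' sequencing adapter removed, nothing else;
  this set preserves the molecule's true 3' end and serves as the lookup
  table when reads are re-joined by ID after alignment.
* ``CCA-trimmed`` — adapter removed, then a single-pass removal of a terminal
  ``CCA`` (3 bases) or, failing that, ``CC`` (2 bases); this set is what gets
  aligned, because a post-transcriptional CCA has no genomic template and
  would otherwise cost mismatches at the read's 3' end.

Which suffix was removed is recorded on each read (``terminal_suffix``) and
drives the downstream CCA-added / CC-terminating / other call.

Adapter matching is semi-global in the cutadapt sense: the best occurrence of
the adapter (or of an adapter prefix running off the read's 3' end) is found
allowing substitutions and indels, up to ``max_error_rate`` errors per
matched adapter base and requiring at least ``min_overlap`` adapter bases.
Everything from the occurrence start to the end of the read is removed.
Occurrences are scored by ``matched_adapter_bases - 2 * errors``; among
equal-score occurrences the leftmost wins.  The exhaustive enumeration oracle
in the test suite pins this definition down.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Iterator

import numpy as np
from numba import njit

__all__ = [
    "RawRead",
    "TrimmedRead",
    "trim_adapter",
    "trim_terminal",
    "make_dual_sets",
    "DEFAULT_ADAPTER",
]

# Illumina TruSeq small-RNA 3' adapter (RA3); configurable everywhere.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


@dataclass(frozen=True)
class RawRead:
    read_id: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if not self.seq or len(self.seq) != len(self.qual):
            raise ValueError(f"{self.read_id}: seq/qual length mismatch or empty")


@dataclass(frozen=True)
class TrimmedRead:
    """A read with its trimming provenance.

    Invariant: original length == len(seq) + adapter_bases_removed +
    terminal_bases_removed, and terminal_suffix <-> terminal_bases_removed
    (CCA<->3, CC<->2, none<->0).
    """

    read_id: str
    seq: str
    qual: str
    adapter_found: bool
    adapter_bases_removed: int
    terminal_suffix: str = "none"      # CCA | CC | none
    terminal_bases_removed: int = 0

    @property
    def droppable(self) -> bool:
        return len(self.seq) == 0


@njit(cache=False)
def _adapter_dp(read: np.ndarray, adapter: np.ndarray,
                max_error_rate: float, min_overlap: int) -> int:
    """Best semi-global adapter occurrence; returns the cut position in the
    read (bases [cut:] are removed), or -1 if no occurrence qualifies.

    D[i, j]: minimum edits aligning adapter[:j] to a suffix of read[:i] whose
    start is free; S[i, j]: smallest such start among cost-optimal paths.
    """
    n = read.shape[0]
    m = adapter.shape[0]
    D = np.empty((n + 1, m + 1), dtype=np.int32)
    S = np.empty((n + 1, m + 1), dtype=np.int32)
    for i in range(n + 1):
        D[i, 0] = 0
        S[i, 0] = i
    for j in range(1, m + 1):
        D[0, j] = j
        S[0, j] = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cd = D[i - 1, j - 1] + (1 if read[i - 1] != adapter[j - 1] else 0)
            sd = S[i - 1, j - 1]
            cu = D[i - 1, j] + 1
            su = S[i - 1, j]
            cl = D[i, j - 1] + 1
            sl = S[i, j - 1]
            c, s = cd, sd
            if cu < c or (cu == c and su < s):
                c, s = cu, su
            if cl < c or (cl == c and sl < s):
                c, s = cl, sl
            D[i, j] = c
            S[i, j] = s
    best_score = -(1 << 30)
    best_start = -1
    # Full-adapter occurrences ending anywhere in the read.
    if m >= min_overlap:
        for i in range(n + 1):
            e = D[i, m]
            if e <= int(max_error_rate * m):
                score = m - 2 * e
                s = S[i, m]
                if score > best_score or (score == best_score and s < best_start):
                    best_score = score
                    best_start = s
    # Adapter-prefix occurrences running off the read's 3' end.
    for j in range(min_overlap, m):
        e = D[n, j]
        if e <= int(max_error_rate * j):
            score = j - 2 * e
            s = S[n, j]
            if score > best_score or (score == best_score and s < best_start):
                best_score = score
                best_start = s
    return best_start


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def trim_adapter(read: RawRead, adapter: str, max_error_rate: float = 0.1,
                 min_overlap: int = 3) -> TrimmedRead:
    """Remove the best-scoring 3' adapter occurrence and everything after it.

    If no occurrence qualifies the read passes through unchanged with
    ``adapter_found=False``.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    cut = _adapter_dp(_encode(read.seq), _encode(adapter),
                      float(max_error_rate), int(min_overlap))
    if cut < 0:
        return TrimmedRead(read.read_id, read.seq, read.qual,
                           adapter_found=False, adapter_bases_removed=0)
    return TrimmedRead(read.read_id, read.seq[:cut], read.qual[:cut],
                       adapter_found=True,
                       adapter_bases_removed=len(read.seq) - cut)


def trim_terminal(read: TrimmedRead) -> TrimmedRead:
    """Single-pass removal of a terminal CCA (3 nt) or CC (2 nt).

    CCA takes precedence over CC, and exactly one pass is made ("...CCACCA"
    loses one CCA, not two).  A read that becomes empty is returned marked
    droppable rather than raising.
    """
    s = read.seq.upper()
    if s.endswith("CCA"):
        suffix, k = "CCA", 3
    elif s.endswith("CC"):
        suffix, k = "CC", 2
    else:
        return replace(read, terminal_suffix="none", terminal_bases_removed=0)
    return replace(read, seq=read.seq[:-k], qual=read.qual[:-k],
                   terminal_suffix=suffix, terminal_bases_removed=k)


def make_dual_sets(
    library: Iterable[RawRead],
    adapter: str = DEFAULT_ADAPTER,
    min_len: int = 15,
    max_error_rate: float = 0.1,
    min_overlap: int = 3,
) -> tuple[dict[str, TrimmedRead], list[TrimmedRead]]:
    """Produce the two read sets the analysis requires.

    Returns ``(only_adapter, cca_trimmed)`` where ``only_adapter`` maps
    read_id -> adapter-trimmed read (unfiltered lookup table) and
    ``cca_trimmed`` is the adapter+terminal-trimmed alignment input, filtered
    to length >= ``min_len``.  Raises on duplicate read IDs.
    """
    only_adapter: dict[str, TrimmedRead] = {}
    cca_trimmed: list[TrimmedRead] = []
    for raw in library:
        if raw.read_id in only_adapter:
            raise ValueError(f"duplicate read id: {raw.read_id}")
        at = trim_adapter(raw, adapter, max_error_rate=max_error_rate,
                          min_overlap=min_overlap)
        only_adapter[raw.read_id] = at
        ct = trim_terminal(at)
        if len(ct.seq) >= min_len:
            cca_trimmed.append(ct)
    return only_adapter, cca_trimmed


def read_fastq(path) -> Iterator[RawRead]:
    """Stream a (plain-text) FASTQ file as :class:`RawRead` records."""
    import pysam

    with pysam.FastxFile(str(path)) as fx:
        for rec in fx:
            yield RawRead(rec.name, rec.sequence, rec.quality or "I" * len(rec.sequence))


def write_fastq(reads: Iterable[TrimmedRead | RawRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{r.qual}\n")


def write_suffix_tsv(only_adapter: dict[str, TrimmedRead],
                     cca_trimmed: list[TrimmedRead], path) -> None:
    """Sidecar TSV of per-read provenance (FASTQ has no standard tag field)."""
    suffixes = {t.read_id: t for t in cca_trimmed}
    with open(path, "w") as fh:
        fh.write("read_id\tadapter_found\tterminal_suffix\n")
        for rid, at in only_adapter.items():
            t = suffixes.get(rid)
            suffix = t.terminal_suffix if t is not None else "none"
            fh.write(f"{rid}\t{int(at.adapter_found)}\t{suffix}\n")
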