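"""Synthetic small-RNA-seq libraries with known 3'-terminal-status truth.

The generator emulates the population structure a stress-induced tRNA
cleavage experiment produces:

* mature tRNAs carrying a post-transcriptionally added 3'-CCA;
* a minority whose CCA has been cleaved back to CC (``p_ccloss``);
* immature molecules that end at the genomic 3' end or run into a short
  genomic 3'-trailer (``p_immature``, shifted-geometric trailer length);
* anticodon-loop cleavage splitting a molecule into a 5'-half and a 3'-half
  (probability ``p_frag_base`` x a per-condition fold multiplier; the 3'-half
  keeps the parent molecule's 3' terminus);
* a non-tRNA background population (``background_weight``) standing in for
  the miRNAs and other small RNAs that dominate real libraries — without it,
  per-million normalisation could not register an absolute increase in tRNA
  halves;
* gel size selection (20-50 nt tiRNA fraction, 50-110 nt tRNA fraction),
  a ligated 3' sequencing adapter, fixed-length reads and a uniform
  substitution error rate standing in for modification-site
  misincorporations.

``expected_truth`` gives the closed-form expectation of what an idealised
pipeline measures on such a library, per (condition, gene terminal-group):
class proportions among 3'-end-containing reads and expected read fractions,
accounting exactly for the size window, the discrete cleavage-site and
trailer-length distributions and the first-order effect of sequencing errors
on the terminal bases.  It assumes every in-window 3'-end fragment maps
(the 3-mismatch budget absorbs terminal mismatches; see docs/methods.md).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from math import erf, sqrt
from typing import NamedTuple

import numpy as np

from .catalog import GeneCatalog, TRNAGene, revcomp, terminal_group
from .trimming import DEFAULT_ADAPTER

__all__ = [
    "SimConfig",
    "SimTruth",
    "ConditionTruth",
    "generate_reference",
    "simulate_library",
    "expected_truth",
    "TIRNA_WINDOW",
    "TRNA_WINDOW",
]

TIRNA_WINDOW = (20, 50)   # gel fraction, nt, inclusive
TRNA_WINDOW = (50, 110)

CALL_CCA = "CCA_added"
CALL_CC = "CC_terminating"
CALL_OTHER = "other"
CALLS = (CALL_CCA, CALL_CC, CALL_OTHER)


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of a simulated experiment.

    Defaults describe a recombinant-ANG-treatment design: a control condition
    and a treated condition in which anticodon cleavage is 6.3-fold more
    likely, three replicates each, with ~95% of mature 3' ends intact (CCA),
    ~1% CCA-cleaved to CC and 4% immature.
    """

    n_reads: int = 100_000
    conditions: tuple[tuple[str, float], ...] = (("control", 1.0), ("ANG", 6.3))
    n_replicates: int = 3
    p_frag_base: float = 0.08
    p_ccloss: float = 0.01
    p_immature: float = 0.04
    p_trailer: float = 1.0 / 3.0     # shifted geometric: P(T=t)=p(1-p)^t, mean 2
    trailer_max: int = 30
    cleavage_site_mean: float = 34.0
    cleavage_site_sd: float = 1.0
    cleavage_site_min: int = 30
    cleavage_site_max: int = 40
    error_rate: float = 0.001
    read_length: int = 150
    adapter: str = DEFAULT_ADAPTER
    size_window: tuple[int, int] = TRNA_WINDOW
    background_weight: float = 0.95
    gene_abundances: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_frag_base", "p_ccloss", "p_immature", "p_trailer",
                     "error_rate", "background_weight"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if not self.adapter:
            raise ValueError("adapter must be non-empty")
        if not self.size_window[0] < self.size_window[1]:
            raise ValueError("size_window must satisfy min < max")
        if self.n_replicates < 1 or not self.conditions:
            raise ValueError("need >=1 replicate and >=1 condition")

    def frag_prob(self, condition: str) -> float:
        for name, fold in self.conditions:
            if name == condition:
                return min(1.0, self.p_frag_base * fold)
        raise KeyError(f"unknown condition {condition!r}")

    def condition_index(self, condition: str) -> int:
        for i, (name, _) in enumerate(self.conditions):
            if name == condition:
                return i
        raise KeyError(f"unknown condition {condition!r}")

    def abundances(self, catalog: GeneCatalog) -> np.ndarray:
        if self.gene_abundances is None:
            a = np.ones(len(catalog))
        else:
            a = np.asarray(self.gene_abundances, dtype=float)
            if len(a) != len(catalog):
                raise ValueError("gene_abundances length != number of genes")
        return a / a.sum()


@dataclass
class ConditionTruth:
    """Closed-form expectations for one condition (replicate-independent)."""

    condition: str
    frag_prob: float
    # {group: {call: proportion}} among 3'-end-containing reads
    group_props: dict[str, dict[str, float]]
    # {group: expected fraction of library reads that are 3'-end reads}
    group_end_fraction: dict[str, float]
    # {group: expected 3'-end read count at the configured depth}
    expected_end_counts: dict[str, float]
    # per-molecule expected 3'-half yield, unconditioned on the size window;
    # the ratio of this quantity between conditions is exactly frag_fold
    three_prime_half_mass: float
    expected_total_reads: int


@dataclass
class SimTruth:
    conditions: dict[str, ConditionTruth]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({k: asdict(v) for k, v in self.conditions.items()}, fh, indent=2)


class FastqRead(NamedTuple):
    read_id: str
    seq: str
    qual: str


class _Fragment(NamedTuple):
    """Internal fragment record; never serialised into read output."""

    seq: str
    kind: str        # bg | full | 5p | 3p
    gene_idx: int    # -1 for background
    state: str       # CCA | CC | IMM | "" for background


def generate_reference(
    n_genes: int,
    n_cca_ending: int,
    n_cc_ending: int,
    gene_len: int = 72,
    genome_len: int = 20_000,
    seed: int = 0,
    n_mito: int = 0,
    chrom: str = "chrSim",
) -> tuple[dict[str, str], GeneCatalog]:
    """Random toy genome plus an intronless tRNA catalog with forced terminal
    groups.

    Exactly ``n_cca_ending`` genes end in genomic CCA and ``n_cc_ending`` in
    CC (but not CCA); the remainder are forced to end in T so their group is
    unambiguously OTHER.  Genes occupy the first 60% of the genome with >=50
    nt spacing (clearance for 3'-trailers and windows) on alternating
    strands; the last 30% stays gene-free as a background-locus region.
    Deterministic for a fixed seed.
    """
    if n_cca_ending + n_cc_ending > n_genes:
        raise ValueError("terminal-group counts exceed n_genes")
    if n_mito > n_genes:
        raise ValueError("n_mito exceeds n_genes")
    gap, margin = 50, 50
    region_end = int(0.6 * genome_len)
    need = margin + n_genes * (gene_len + gap)
    if need > region_end:
        raise ValueError(
            f"cannot pack {n_genes} genes of {gene_len} nt into "
            f"[{margin}, {region_end}): need {need}"
        )
    rng = np.random.default_rng(seed)
    genome = rng.integers(0, 4, size=genome_len)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    arr = bases[genome].copy()

    groups = ["CCA"] * n_cca_ending + ["CC"] * n_cc_ending
    groups += ["OTHER"] * (n_genes - len(groups))
    genes: list[TRNAGene] = []
    pos = margin
    for i, grp in enumerate(groups):
        start, end = pos, pos + gene_len
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            if grp == "CCA":
                arr[end - 3 : end] = np.frombuffer(b"CCA", dtype=np.uint8)
            elif grp == "CC":
                arr[end - 2 : end] = np.frombuffer(b"CC", dtype=np.uint8)
            else:
                arr[end - 1] = ord("T")
        else:
            if grp == "CCA":
                arr[start : start + 3] = np.frombuffer(b"TGG", dtype=np.uint8)
            elif grp == "CC":
                arr[start : start + 2] = np.frombuffer(b"GG", dtype=np.uint8)
            else:
                arr[start] = ord("A")
        sub = arr[start:end].tobytes().decode("ascii")
        seq = sub if strand == "+" else revcomp(sub)
        genes.append(
            TRNAGene(
                gene_id=f"tgene{i:03d}",
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                seq=seq,
                terminal_group=terminal_group(seq),
                is_mito=i >= n_genes - n_mito,
            )
        )
        pos = end + gap
    genome_seq = arr.tobytes().decode("ascii")
    references = {chrom: genome_seq}
    catalog = GeneCatalog(genes=genes, genome_ids={chrom}, genome=references)
    return references, catalog


def write_reference(references: dict[str, str], catalog: GeneCatalog,
                    fasta_path, bed_path) -> None:
    with open(fasta_path, "w") as fh:
        for name, seq in references.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(bed_path, "w") as fh:
        for g in catalog:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


# ---------------------------------------------------------------------------
# fragment pool
# ---------------------------------------------------------------------------

def _background_region(catalog: GeneCatalog, chrom: str) -> tuple[int, int]:
    glen = len(catalog.genome[chrom])
    return int(0.7 * glen), glen


def _draw_fragments(catalog: GeneCatalog, cfg: SimConfig, p_c: float,
                    rng: np.random.Generator, n_molecules: int) -> list[_Fragment]:
    """Draw ``n_molecules`` library molecules and expand cleaved ones into
    their two halves.  No size filtering here (conservation: one cleaved
    molecule -> exactly one 5'-half + one 3'-half)."""
    genes = catalog.genes
    a = cfg.abundances(catalog)
    chrom = genes[0].chrom if genes else next(iter(catalog.genome))
    bg_lo, bg_hi = _background_region(catalog, chrom)
    gref = catalog.genome[chrom]
    wmin, wmax = cfg.size_window

    is_bg = rng.random(n_molecules) < cfg.background_weight
    gene_idx = rng.choice(len(genes), size=n_molecules, p=a)
    u_state = rng.random(n_molecules)
    cleave = rng.random(n_molecules) < p_c
    cuts = np.rint(rng.normal(cfg.cleavage_site_mean, cfg.cleavage_site_sd,
                              size=n_molecules)).astype(int)
    cuts = np.clip(cuts, cfg.cleavage_site_min, cfg.cleavage_site_max)
    trailers = np.minimum(rng.geometric(cfg.p_trailer, size=n_molecules) - 1,
                          cfg.trailer_max)
    bg_len = rng.integers(wmin, wmax + 1, size=n_molecules)
    bg_pos = rng.integers(bg_lo, bg_hi - wmax, size=n_molecules)
    bg_strand = rng.random(n_molecules) < 0.5

    downstream = [catalog.downstream(g, cfg.trailer_max) for g in genes]
    out: list[_Fragment] = []
    for i in range(n_molecules):
        if is_bg[i]:
            s = gref[bg_pos[i] : bg_pos[i] + bg_len[i]].upper()
            if bg_strand[i]:
                s = revcomp(s)
            out.append(_Fragment(s, "bg", -1, ""))
            continue
        gi = int(gene_idx[i])
        g = genes[gi]
        if u_state[i] < cfg.p_immature:
            state = "IMM"
            mol = g.seq + downstream[gi][: trailers[i]]
        elif u_state[i] < cfg.p_immature + (1 - cfg.p_immature) * cfg.p_ccloss:
            state = "CC"
            mol = g.seq + "CC"
        else:
            state = "CCA"
            mol = g.seq + "CCA"
        if cleave[i]:
            c = int(cuts[i])
            out.append(_Fragment(mol[:c], "5p", gi, state))
            out.append(_Fragment(mol[c:], "3p", gi, state))
        else:
            out.append(_Fragment(mol, "full", gi, state))
    return out


def _in_window(length: int, cfg: SimConfig) -> bool:
    return cfg.size_window[0] <= length <= cfg.size_window[1]


def simulate_library(
    catalog: GeneCatalog,
    config: SimConfig,
    condition: str,
    replicate: int,
) -> tuple[list[FastqRead], ConditionTruth]:
    """Simulate one size-selected, adapter-ligated FASTQ library.

    Molecules are drawn in batches, expanded into fragments, filtered by the
    gel size window and sequenced (adapter appended, padded with A to the
    fixed read length, uniform substitution errors applied) until ``n_reads``
    reads are collected.  Read IDs encode only (condition, replicate, serial)
    — no truth leakage.  Returns the reads plus this condition's closed-form
    truth slice.
    """
    if len(catalog) == 0:
        raise ValueError("catalog is empty")
    cidx = config.condition_index(condition)
    p_c = config.frag_prob(condition)
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, cidx, replicate,
                                config.size_window[0]])
    )
    accepted: list[str] = []
    attempts = 0
    while len(accepted) < config.n_reads:
        batch = max(config.n_reads - len(accepted), 1000)
        frags = _draw_fragments(catalog, config, p_c, rng, batch)
        kept = [f.seq for f in frags if _in_window(len(f.seq), config)]
        accepted.extend(kept)
        attempts += 1
        if attempts >= 50 and not accepted:
            warnings.warn(
                "no molecule class fits the size window; returning empty library",
                stacklevel=2,
            )
            truth = expected_truth(config, catalog)
            return [], truth.conditions[condition]
    accepted = accepted[: config.n_reads]

    R = config.read_length
    reads: list[FastqRead] = []
    qual = "I" * R
    n_err = rng.binomial(R, config.error_rate, size=len(accepted))
    for i, frag in enumerate(accepted):
        s = (frag + config.adapter)[:R]
        if len(s) < R:
            s = s + "A" * (R - len(s))
        if n_err[i]:
            s_arr = list(s)
            for p in rng.integers(0, R, size=n_err[i]):
                cur = s_arr[p]
                choices = [b for b in "ACGT" if b != cur]
                s_arr[p] = choices[rng.integers(0, 3)]
            s = "".join(s_arr)
        reads.append(FastqRead(f"{condition}.{replicate}.{i:07d}", s, qual))
    truth = expected_truth(config, catalog)
    return reads, truth.conditions[condition]


# ---------------------------------------------------------------------------
# closed-form truth
# ---------------------------------------------------------------------------

def _norm_cdf(x: float) -> float:
    return 0.5 * (1.0 + erf(x / sqrt(2.0)))


def _cut_pmf(cfg: SimConfig) -> dict[int, float]:
    """pmf of the rounded, clamped Normal cleavage site."""
    mu, sd = cfg.cleavage_site_mean, cfg.cleavage_site_sd
    lo, hi = cfg.cleavage_site_min, cfg.cleavage_site_max
    pmf = {}
    for c in range(lo, hi + 1):
        pmf[c] = _norm_cdf((c + 0.5 - mu) / sd) - _norm_cdf((c - 0.5 - mu) / sd)
    pmf[lo] += _norm_cdf((lo - 0.5 - mu) / sd)
    pmf[hi] += 1.0 - _norm_cdf((hi + 0.5 - mu) / sd)
    return pmf


def _trailer_pmf(cfg: SimConfig) -> dict[int, float]:
    """Shifted-geometric trailer length, tail mass lumped at the cap
    (mirroring the generator's clip)."""
    p = cfg.p_trailer
    pmf = {t: p * (1 - p) ** t for t in range(cfg.trailer_max)}
    pmf[cfg.trailer_max] = (1 - p) ** cfg.trailer_max
    return pmf


def _class_probs(last3: str, q: float) -> dict[str, float]:
    """P(classified CCA_added / CC_terminating / other) for a fragment whose
    true final three bases are ``last3``, under iid substitution errors."""

    def pb(true: str, want: str) -> float:
        return (1.0 - q) if true == want else q / 3.0

    b1, b2, b3 = last3[-3], last3[-2], last3[-1]
    p_cca = pb(b1, "C") * pb(b2, "C") * pb(b3, "A")
    p_cc = pb(b2, "C") * pb(b3, "C")
    return {CALL_CCA: p_cca, CALL_CC: p_cc, CALL_OTHER: 1.0 - p_cca - p_cc}


def _last3(mol_end: str) -> str:
    if len(mol_end) < 3:
        raise ValueError("fragment shorter than 3 nt at window sizes is impossible")
    return mol_end[-3:]


def expected_truth(config: SimConfig, catalog: GeneCatalog) -> SimTruth:
    """Closed-form per-condition expectations (see module docstring)."""
    if catalog.genome is None:
        raise ValueError("expected_truth needs a catalog with genome sequences")
    a = config.abundances(catalog)
    w = config.background_weight
    q = config.error_rate
    cut_pmf = _cut_pmf(config)
    tr_pmf = _trailer_pmf(config)
    conds: dict[str, ConditionTruth] = {}
    for condition, fold in config.conditions:
        p_c = config.frag_prob(condition)
        group_mass = {g: {c: 0.0 for c in CALLS} for g in ("CCA", "CC", "OTHER")}
        total_in_window = w  # background length always drawn inside the window
        for gi, gene in enumerate(catalog.genes):
            wt = (1.0 - w) * a[gi]
            L = len(gene)
            down = catalog.downstream(gene, config.trailer_max)
            # state -> (probability, molecule length pmf, terminal 3 bases)
            states: list[tuple[float, dict[int, float], str]] = [
                ((1 - config.p_immature) * (1 - config.p_ccloss),
                 {L + 3: 1.0}, _last3(gene.seq + "CCA")),
                ((1 - config.p_immature) * config.p_ccloss,
                 {L + 2: 1.0}, _last3(gene.seq + "CC")),
            ]
            for t, pt in tr_pmf.items():
                tail = (gene.seq + down[:t])
                states.append((config.p_immature * pt, {L + t: 1.0}, _last3(tail)))
            for p_state, len_pmf, last3 in states:
                cls = _class_probs(last3, q)
                for mol_len, p_len in len_pmf.items():
                    base = wt * p_state * p_len
                    # uncleaved full-length molecule
                    if _in_window(mol_len, config):
                        m = base * (1.0 - p_c)
                        total_in_window += m
                        for call in CALLS:
                            group_mass[gene.terminal_group][call] += m * cls[call]
                    # cleaved: 5'-half and 3'-half
                    for c, pc_site in cut_pmf.items():
                        m5 = base * p_c * pc_site
                        if _in_window(c, config):
                            total_in_window += m5          # 5'-half, never a 3'-end read
                        if _in_window(mol_len - c, config):
                            m3 = base * p_c * pc_site
                            total_in_window += m3
                            for call in CALLS:
                                group_mass[gene.terminal_group][call] += m3 * cls[call]
        group_props: dict[str, dict[str, float]] = {}
        group_end_fraction: dict[str, float] = {}
        expected_counts: dict[str, float] = {}
        for grp, masses in group_mass.items():
            tot = sum(masses.values())
            # an all-out-of-window configuration yields an empty library
            group_end_fraction[grp] = tot / total_in_window if total_in_window else 0.0
            expected_counts[grp] = config.n_reads * group_end_fraction[grp]
            if tot > 0:
                group_props[grp] = {c: masses[c] / tot for c in CALLS}
            else:
                group_props[grp] = {c: float("nan") for c in CALLS}
        conds[condition] = ConditionTruth(
            condition=condition,
            frag_prob=p_c,
            group_props=group_props,
            group_end_fraction=group_end_fraction,
            expected_end_counts=expected_counts,
            three_prime_half_mass=(1.0 - w) * p_c,
            expected_total_reads=config.n_reads,
        )
    return SimTruth(conditions=conds)
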