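# Methods

## The measurement

A small-RNA-seq read derived from a tRNA (or a tRNA half) is informative
about the molecule's 3′ terminus only after three confounders are handled:
the ligated 3′ sequencing adapter, the fact that a post-transcriptional CCA
has no genomic template (it would cost alignment mismatches), and tRNA genes
whose genomic sequence itself ends in CCA or CC (immature transcripts of
those genes mimic mature or CCA-cleaved molecules).

The pipeline therefore (i) trims every library twice — adapter-only, and
adapter + one terminal `CCA`/`CC` (single pass, longest suffix first, with
the removed suffix recorded per read); (ii) aligns the suffix-trimmed set
ungapped, end-to-end, single best hit, ≤3 mismatches; (iii) keeps alignments
overlapping the last k = 5 genomic bases of a tRNA gene on the matching
strand; (iv) classifies each such read from its recorded suffix
(`CCA_added` / `CC_terminating` / `other`) and stratifies by the source
gene's genomic terminal group. Only the OTHER-group stratum is free of the
immature-read ambiguity; the CCA- and CC-group strata are reported to make
the ambiguity visible, not to resolve it.

Counts are reported as within-group percentages and as reads per million
mapped reads (PMMR = 10⁶·count/total_mapped). `total_mapped` defaults to
every read of the library's CCA-trimmed set that received an alignment —
the most literal reading of "mapped reads"; a tRNA-assigned-only denominator
would make PMMR a within-tRNA composition measure and would suppress
abundance fold changes, so it is not the default.

## Aligner

"-v-mode" semantics: no indels, the whole read must fit, mismatch count is
the only score, quality values are ignored. Candidate placements are
generated by pigeonhole seeding — the read is split into `max_mismatch + 1`
chunks, so any qualifying placement contains at least one exact chunk, whose
k-mer prefix (k = min(12, chunk length)) is found by exact lookup; seed
tables for the needed k are built lazily in one pass over the forward
genome, and minus-strand placements are found by seeding the
reverse-complemented read. This makes the search *complete*, which the test
suite verifies against an exhaustive scan of every placement on both
strands. Reads shorter than the seed length (12 nt) are reported unmapped.

Ties among equal-best placements are broken deterministically — reference
order, then leftmost coordinate, then + before − — and the multiplicity is
recorded in a SAM `XE` tag (mismatch count in `NM`). Widely used short-read
aligners break such ties pseudo-randomly; determinism was chosen here so
that runs are bit-reproducible, at the cost of a systematic (but recorded)
preference among identical tRNA gene copies.

## Adapter trimming

Semi-global dynamic programming in the cutadapt sense: occurrences of the
full adapter anywhere in the read, and of adapter *prefixes* running off the
read's 3′ end, with substitutions and indels allowed up to
`floor(max_error_rate × matched_adapter_bases)` errors (default rate 0.1),
minimum overlap 3. Occurrences are scored `matched_bases − 2·errors`;
the best score wins and ties go to the leftmost start. Everything from the
occurrence start onward is removed. The DP tracks, per cell, the minimal
start among cost-optimal paths, so the leftmost rule is exact; an
enumeration oracle (every start × every matched length, plain Levenshtein)
pins the definition down in tests. The inner loop is numba-compiled.

Terminal trimming runs *after* adapter removal (the molecule's 3′ end is
adjacent to the adapter only post-trim) and from every post-adapter 3′ end,
whether or not an adapter was found; `adapter_found` is recorded so a
stricter rule could be applied downstream. The alignment input keeps reads
≥15 nt (shorter reads cannot place reliably under a 3-mismatch budget);
the adapter-only set is never filtered, keeping the ID join total.

## Synthetic libraries

Each library molecule is, with probability `background_weight`, a non-tRNA
background locus (length uniform in the gel window, drawn from a gene-free
genome region), else a tRNA molecule: immature with probability
`p_immature` (genomic 3′ end plus a genomic-trailer of shifted-geometric
length, mean 2 nt, capped at 30), otherwise mature with CCA, or with CC
after CCA cleavage (probability `p_ccloss`). Independently, the molecule is
anticodon-cleaved with probability `p_frag_base × frag_fold(condition)` at a
site ~ round(Normal(34, 1)) clamped to [30, 40] nt from the 5′ end; cleavage
yields exactly one 5′-half and one 3′-half, the 3′-half keeping the parent's
terminus (cleavage and CCA loss are independent). Fragments are filtered by
the gel window (20–50 nt tiRNA fraction or 50–110 nt tRNA fraction),
ligated to the 3′ adapter, padded with A to the fixed read length (75 or
150 nt) and given iid substitution errors. Base qualities are written as
constant Q40 and never used. End chemistry (2′,3′-cyclic phosphate vs
hydroxyl) is not modelled in sequence space: the emulated protocol
end-repairs with CIP/PNK before ligation, which erases the distinction;
libraries are assumed already end-repaired.

Defaults (the study conditions): conditions control (fold 1.0) vs ANG
(fold 6.3), 3 replicates, 100,000 reads/library, `p_frag_base` 0.08,
`p_ccloss` 0.01, `p_immature` 0.04, error rate 0.001/base,
`background_weight` 0.95, uniform gene abundances, reference of 12 genes
(2 genomically CCA-ending, 1 CC-ending, 9 other; 72 nt, intronless, both
strands, ≥50 nt apart on a 20 kb toy genome). These give a closed-form
truth of ≈94.8% CCA-added and ≈1.1% CC-terminating among OTHER-group
3′-end reads — a mostly-intact mature pool with a small CCA-cleaved
minority — and a tiRNA-fraction composition in which tRNA halves are ~1% of
control libraries, mirroring real libraries that are dominated by other
small RNAs. The background component is what lets PMMR register an absolute
increase of tRNA halves: with a fixed sequencing depth, per-million counts
track abundance only against a stable background. Because the halves
themselves enter the mapped-read denominator, the expected measured PMMR
ratio between conditions is slightly below the configured fold
(≈6.0 vs 6.3 at these defaults); the pool-level 3′-half expectation, whose
ratio is exactly the configured fold, is reported separately in `SimTruth`.

`expected_truth` computes, per condition and terminal group, the expected
class proportions among 3′-end reads and the expected fraction of library
reads they occupy, summing exactly over the discrete cleavage-site and
trailer-length distributions and the window indicator, with the terminal
three bases of every fragment class perturbed analytically by the error
rate. It assumes every in-window 3′-end fragment maps: a read whose
terminal bases were mis-sequenced still aligns because the 3-mismatch
budget absorbs up to three terminal mismatches, and the residual loss
(a terminal misread combined with additional body errors) is O(10⁻⁵) at the
default error rate. Simulated read IDs carry only condition, replicate and
serial number; ground truth is recoverable only through `SimTruth`.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: ligation sequence bias, PCR duplicates, RT
misincorporation concentrated at specific modified positions (a uniform
error rate stands in), per-isoacceptor cleavage-site preferences, intron-
containing genes, and multi-mapping across identical tRNA gene copies
(toy-genome loci are unique; on a real genome the `XE` tag exposes the
ambiguity rather than resolving it).

## Statistics

Tests operate on per-replicate proportions or PMMR values (n = 3-scale
designs), untransformed. `two_group` is the equal-variance unpaired
Student's t; `vs_control` is one-way ANOVA followed by Dunnett's test
against the designated control (multivariate-t formulation, as implemented
in scipy; p-values good to ~±0.002 from the QMC integration); `all_pairs`
is Tukey–Kramer. No correction is applied across groups or gel fractions
beyond the named procedures. A Monte-Carlo calibration utility simulates
the global null with the pooled-variance statistics vectorised and rejects
at the multivariate-t critical value (solved by bisection on the rectangle
probability); at 10⁵ resamples both the t-test and the Dunnett family-wise
rejection rates land within Monte-Carlo error of the nominal 0.05.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere; conversions only at I/O.
- `terminal_group` checks the longest suffix first, so "…CCA" is never
  recorded as CC; groups partition any catalog.
- Multi-gene 3′-window overlaps resolve to the larger overlap, then catalog
  order, with an `ambiguous` flag (real tRNA genes are almost never within
  5 nt of each other).
- Reads aligning past the gene 3′ end (genomic trailers) stay in class
  `other` via suffix `none`; trailer lengths are not subclassified.
- Degenerate inputs: empty adapter, empty genome, k outside [1, gene
  length], total_mapped = 0, <2 replicates per group and all-zero variance
  raise typed errors; a size window no molecule class fits yields a warning
  and an empty library; groups with zero 3′-end reads carry null (not zero)
  percentages.
- Problem sizes in the whole-pipeline tests and the acceptance script —
  100,000 reads/library, 3 replicates × 2 conditions per gel fraction,
  1,000 oracle reads on a 10 kb genome, 10⁵ null resamples — were chosen as
  the smallest sizes at which binomial/Monte-Carlo error bands are tight
  enough to be informative (3 SE bands of a fraction of a percentage point).

## Known limitations

- The ungapped aligner is deliberately indel-blind; reads with true indels
  (rare in short small-RNA reads) go unmapped rather than mis-placed.
- Deterministic tie-breaking among identical gene copies concentrates
  multi-mapped reads on the first copy in reference order; per-gene counts
  for duplicated tRNAs should be interpreted through the `XE` multiplicity.
- PMMR denominators differ between the two gel fractions (independently
  sequenced libraries), so values are comparable within, not across,
  fractions.
- The CCA/CC-group strata remain intrinsically ambiguous; the pipeline
  quantifies but cannot remove that ambiguity.
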