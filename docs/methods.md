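# Methods

## Problem setting

CRISPR/Cas9 editing of one-cell embryos with long donor templates
produces mosaic founder (G0) animals: the targeted locus can carry the
correct knock-in or floxed allele alongside wild type, partial donor
integrations, deletions, duplications and otherwise-correct alleles with
unintended point mutations in cis. Nanopore amplicon sequencing reads
span the whole edited interval in single molecules, so each read reports
one allele — but the per-read error rate (several percent) exceeds the
sequence difference between wild type and, say, a floxed allele (two
34 bp loxP insertions in a kilobase-scale amplicon). `mosaicscreen`
implements the screening logic that makes such data decisive: filter
reads, keep only reads that can only derive from the designed mutant,
and quantify how well the surviving reads recall the mutant reference.

## Pipeline stages

1. **Barcode demultiplexing and chimera exclusion** (`readprep`). A read
   is kept iff a barcode (either orientation, edit distance <=
   `max_mismatches`, default 3) matches within the first and within the
   last `end_window` bases (default 150), and no barcode matches
   strictly inside. Artificial chimeras — concatenations of two
   molecules — carry a barcode at the junction and are discarded with
   reason `internal_barcode`. Kept reads are trimmed of their terminal
   barcode segments. Matching uses edit distance (edlib) rather than a
   vendor demultiplexer; only the acceptance rule (both ends, none
   internal) is the method.

2. **Relative quality filtering.** Each read is scored as
   `-10*log10(mean per-base error probability)` from its Phred string;
   the filter keeps reads scoring at or above the `q`-th percentile of
   the score distribution (upper interpolation, ties kept). This is a
   percentile-rank proxy for tools that score reads relative to the
   rest of the dataset; the exact vendor formula is not public, so the
   proxy is stated rather than imitated. The default operating point is
   q90. The filter is monotone in the threshold by construction.

3. **Seeded subsampling.** Depth titration uses Bernoulli per-read
   retention with a fixed seed (default 100), matching seqtk-style
   thinning semantics; an exact-count mode exists for fixtures.

4. **Alignment** (`targetalign`). Reads are aligned semi-globally (read
   consumed end to end, reference overhangs free) with affine gaps
   (match +2, mismatch -4, gap open 4, gap extend 2; a gap of length L
   costs open + L*extend) on both strands; the better strand is kept.
   Standard mapping quality is ill-defined for a single-reference
   two-strand problem, so each record carries a 0-100 *confidence*:
   `100 * (1 - second_strand_score / best_score)`, clipped, 0 when the
   best score is non-positive. The default filter keeps confidence >=
   90. The DP kernel is numba-jitted; an optional band (|j - i*m/n| <=
   band) accelerates full-length amplicon alignment and is exact for
   these reads at band >= 150 (verified against the full DP in tests);
   the default is the full DP. Ties prefer the + strand, then the
   leftmost end anchor.

5. **Pileup.** One column per reference position; M ops add base counts,
   deletions add to a deletion count *and to depth* (they are evidence
   against the reference base), insertions anchor to the preceding
   column and never create columns. This keeps the recall denominator
   equal to the reference length.

6. **Consensus-threshold recall** (`recallstats`). A position is
   *recalled* iff depth > 0 and `100 * ref_match_fraction >=
   consensus_threshold` (inclusive, "met or surpassed"). Recall is the
   percentage of unmasked positions recalled. The homopolymer mask
   excludes positions inside maximal single-base runs of length >= k
   (k = 4 or 5), where nanopore indel error concentrates, from both
   numerator and denominator. Zero-depth unmasked positions stay in the
   denominator and are never recalled — this inclusive definition is
   what makes recall drop when aggressive quality filtering leaves too
   few reads for complete coverage; it is togglable only by masking.

7. **Mutant determinants** (`refmodel`, `allelecall`). A determinant is
   a subsequence of the designed mutant absent from wild type on both
   strands (verified by exhaustive substring scan). Derivation:
   - point mutations: a 30 nt window centered on the edited base
     (truncated, not shifted, at reference ends);
   - insertions/substitutions ("insert" mode): the whole inserted
     segment plus 15 bp junction flanks per side.
   Candidates still present in WT are extended symmetrically until
   exclusive or the reference is exhausted (error).

   Reads are scanned by *determinant-global* (infix) affine alignment on
   both strands: the whole determinant is forced into the alignment, so
   identity = matches over all alignment columns and coverage = the
   fraction of determinant bases inside the read bounds. A hit requires
   identity >= 0.80 and coverage >= 0.90. Two deliberate choices here:
   - *No local end-trimming.* A Smith-Waterman scan trims mismatching
     determinant ends, which at ~10% read error silently drops coverage
     below any usable threshold for ~half the true hits, while a trimmed
     core hit can look perfect. Forcing the full determinant makes the
     identity statistic honest about end errors.
   - *15 bp flanks.* The two loxP determinants of a floxed design share
     their 34 bp core; only the junction flanks distinguish the 5' from
     the 3' site. With F-bp flanks a wrong-site hit has expected
     identity ~ (34 + F/2) / (34 + 2F); F = 15 puts that at ~0.65,
     comfortably below the 0.80 threshold even with chance flank
     matches, whereas F = 5 puts it at ~0.83 — indistinguishable from a
     noisy true hit. Measured on the synthetic floxed locus: both-
     determinant sensitivity ~0.95-1.0 at 10% total read error, zero
     noiseless wrong-site hits, partial-integration false-pass rate
     well below 1%.

   With `require_all` (default) a read passes only if every determinant
   hits (e.g. both loxP determinants); `require_all=False` is the
   second-pass mode for spotting useful intermediate alleles.

8. **Variant calls.** The SNV caller emits a call wherever the most
   frequent non-reference base reaches `min_alt_fraction` (default 0.3)
   at depth >= 20; ties break lexicographically; calls inside the
   homopolymer mask are annotated low-confidence, not suppressed. The
   SV detector clusters per-read CIGAR indels >= 30 bp by position
   (+-20 bp) and length (+-20%), calling clusters with >= 5 supporting
   reads; long insertions whose sequence echoes the adjacent reference
   (edit distance <= 20% of length) are labelled DUP. Both are simple,
   transparent stand-ins for external consensus-polishing and SV
   callers: screen output, not inferential statistics, so no
   multiple-testing control is applied. The 0.3 alt-fraction default
   reflects that mosaicism dilutes variant alleles while i.i.d. ONT
   noise stays near a few percent per base.

9. **Classification.** NO_CONFORMING_ALLELE if no read passes the
   determinant filter; INSUFFICIENT_DATA below 20 passed reads;
   CORRECT_WITH_CIS_VARIANT if any SNV/SV is called on the passed set
   (or if masked consensus-60 recall of the mutant reference is below
   100%, with a note); else CORRECT_ALLELE_PRESENT. The rule is a pure
   function of its inputs.

## The simulator and what it does (not) emulate

`mosaicsim` generates the study conditions end to end: alleles built by
declared string surgery on the locus (correct, wild type, partial
integration via exact edit reversion, deletion, duplication, SNV in
cis), reads drawn multinomially per allele fraction, each read spanning
its whole allele (PCR amplicon model, products ~1-3 kb) on a uniform
strand. Errors are i.i.d. per base — defaults substitution 3%,
insertion 2%, deletion 2% — with a per-read lognormal error scale
(sigma 0.3, mean 1) so relative-quality ranking is meaningful, and an
optional homopolymer indel multiplier (default 2 inside runs >= 4).
Per-base Phred values are emitted as `-10*log10(expected error)` capped
at 93. Barcodes (standard 24 bp nanopore barcodes by default) are
attached clean; chimeras are injected as concatenations of two barcoded
reads at an exact rounded rate. One integer seed drives a single numpy
generator with a fixed stream order (allele assignment, then per read:
strand, error scale, deletions, substitutions, insertions, inserted
bases, substitution targets; chimeras last), so outputs are
byte-reproducible.

Not emulated: signal-level behaviour, context-dependent (k-mer) error
profiles, PCR amplification bias beyond allele fractions, read-length
truncation, and basecaller artefacts. Passing tests therefore
demonstrate the *logic* of the screen under controlled noise, not
performance on any particular real flow cell; real-data accuracy
claims require real runs.

## Numerical and degenerate-input choices

- All internal coordinates are 0-based half-open; 1-based only at
  SAM/VCF/TSV boundaries.
- Alignment tie-breaks: + strand first, then smallest end column in the
  DP, making outputs deterministic.
- `N` bases never match (scored as mismatch) and are excluded from
  pileup base counts; reference `N` positions have undefined match
  fraction and can never be recalled.
- Empty read sets propagate as empty outputs (with a warning), not
  errors; a read longer than twice the reference is rejected as
  misconfigured input (unfiltered chimeras).
- Zero-depth pileup columns have undefined (NaN/None) match fraction.
- Determinants longer than the read return "no hit" rather than error.

## Problem sizes

Tests and the acceptance script use a 2 kb synthetic floxed locus
(seeded random WT, two loxP insertions), 60-300x simulated depth for
recall and classification checks, 1,000-read mosaics for partition
metrics, 10-50 seeded replicates for SNV-recovery rates, and 100-200 bp
random pairs for brute-force aligner oracles. These sizes give stable
binomial/multinomial margins (3 SD tolerances) at desk scale.

## Known limitations

- The mapping-confidence score is a strand-discrimination statistic,
  not a multi-locus mapping quality; it says nothing about paralogs.
- The SNV caller reports per-position marginals; it does not phase
  variants across reads and cannot separate two variant alleles that
  pass the same determinants (full mosaic haplotype reconstruction is
  out of scope).
- Recall at consensus thresholds near 100% is sensitive to single
  aberrant reads at low depth; the statistic is designed for >= 100x.
- The error model's i.i.d. assumption understates clustered errors in
  low-complexity sequence other than homopolymers (e.g. dinucleotide
  repeats).
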