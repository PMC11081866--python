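# Methods

This note documents the models, conventions and numerical choices behind
`bequant`, in the order data flows through the pipeline.

## Coordinates and locus geometry

All internal coordinates are 0-based, half-open intervals on the amplicon
reference; 1-based HGVS c. positions exist only inside the consequence
module (`codon_number = ceil(c/3)`, `position_in_codon = ((c−1) mod 3)+1`).
An `AmpliconSpec` is validated eagerly: every protospacer must match the
reference at its stated offset and strand, the PAM (IUPAC pattern, e.g.
NGN for SpG, NNNRRT for SaKKH) must sit immediately 3′ of the protospacer
on its strand, and the target position must read A on the protospacer
strand. Mixed-strand protospacers at one locus are rejected.

Default windows, where the configuration does not override them:

* `quant_window` = the combined (union) protospacer interval. Scoping
  "only the desired edit" to this window rather than the whole amplicon
  keeps the desired-only denominator from being dominated by sequencing
  errors in the ~200 bp of flanking sequence; a `--strict-whole-amplicon`
  switch widens the window to the full amplicon for sensitivity analyses.
* `nick_offset` = the junction between protospacer positions 17 and 18
  (3 bp 5′ of the PAM), the canonical SpCas9-nickase cut.
* `indel_window` = the combined protospacer interval extended to cover
  `[nick − 3, nick + 3)` — a window covering both the deamination
  positions and the nick site.

## Read simulator

The simulator is first-class, tested code: it defines the ground truth
against which the quantifier is validated. A `TruthManifest` lists
alleles (substitution sets plus an optional single indel), their
proportions (must sum to 1 within 1e-9), the read count, a per-base
substitution error rate, a constant Phred quality, paired/single mode and
one seed. A single `numpy.random.default_rng(seed)` (PCG64; identity
recorded in the manifest echo) drives allele assignment, error placement
and error identity, so identical seeds give byte-identical FASTQ. Errors
substitute uniformly among the three non-reference bases — the simplest
symmetric model, sufficient to stress classification. Paired mode emits
perfectly overlapping full-length mates from opposite strands with
independent errors, exercising the merger's quality arbitration.

The `spiked_truth` defaults are the study conditions this package is
built around: 45.9% desired-edit allele, 4.8% bystander allele (desired
edit plus one nonsynonymous protospacer A→G), 0.1% 1-bp deletion at the
nick, the remainder wildtype; 20 000 reads at 0.5% per-base error.

Not modelled: PCR chimeras, amplification bias, position-dependent
instrument error spectra, base-quality miscalibration. Passing tests
therefore demonstrate correctness of the quantification arithmetic under
an idealised error channel, not robustness to every artefact of real
libraries.

**What "truth" means under noise.** The quantifier classifies *reads*.
A read from the desired allele that catches an error inside the 20-nt
quantification window is, as a read, no longer desired-edit-only — with
0.5% error the expected desired-only fraction is 0.459 × 0.995²⁰ ≈ 0.415,
several binomial standard errors below the allele proportion. Recovery is
therefore tested against `expected_outcome_rates`, the closed-form
push-forward of the allele mixture through the independent per-base error
channel (per allele: the product over window positions of
P(final base = required base), with P = 1−e when the allele already
carries the base and e/3 otherwise; bystander-class probabilities via the
complement-product over the nonsynonymous and synonymous adenine sets).
At error 0 these reduce exactly to the allele proportions, which is the
exact round-trip the acceptance tests assert.

## Pair merging

The reverse-complemented mate is slid along read 1 without gaps; the
chosen offset maximises matches − mismatches over the overlap (N columns
score 0), requiring both overlap length and net score ≥ `min_overlap`
(default 10). Agreeing positions get the summed Phred capped at 41;
disagreeing positions take the higher-quality base with its own quality.
Pairs without an acceptable overlap are rejected and counted
(`no_overlap`) in the run metadata.

## Alignment

Affine-gap Needleman–Wunsch/Gotoh, global in the read and end-gap-free on
the reference side of the read ("glocal"): a shorter read may start and
end anywhere on the reference without penalty, but must itself be fully
explained. A gap of length k costs `gap_open + k·gap_extend`. Defaults
match = +2, mismatch = −2, gap_open = −10, gap_extend = −1,
`min_identity` = 0.6: under these a 1-bp indel (−11 plus the lost match)
is preferred to three scattered mismatches, matching the intent of
windowed indel calling. N scores 0 against anything so no-calls neither
support nor oppose an edit.

The kernel (numba-compiled) runs banded around the main diagonal with
half-width `|len(ref) − len(read)| + 30`; the band collapses to the full
matrix for short sequences, and any banded alignment that fails the
identity threshold is recomputed unbanded before the read is rejected.
The exhaustive-oracle tests exercise the unbanded regime directly; for
amplicon reads (full-length, expensive gaps) the optimum never approaches
the band edge. Reads failing identity in the forward orientation are
tried as reverse complements and flagged `strand='-'` when accepted.

Tie-breaking is deterministic: the traceback prefers diagonal moves and
gap extension over gap opening, and a post-pass left-aligns every indel
run within homopolymers/repeats — window membership of an indel must not
depend on aligner internals. Identity = matches / read length. Alignment
depends only on the base string, so the batch aligner deduplicates
identical reads (a large win for error-free or low-error data).

Reads that merge or align unacceptably are excluded from "total aligned
reads" (the formula denominators) and accounted per reason in the run
metadata, as are aligned reads that do not span the analysis windows
(`window_excluded`).

## Quantification

Accepted alignments are digested to their gapped sequence over the
quantification window (uppercase calls, `-` for deletions, lowercase for
insertions at their junction) and grouped into the allele table; the
frequencies sum to 1 over aligned window-spanning reads. Outcome classes
partition the reads, with precedence:

1. **indel** — any insertion or deletion whose left-aligned placement
   overlaps the indel window (a deletion `[a,b)` overlaps `[s,e)` iff
   `a<e` and `b>s`; an insertion at junction p iff `s<p<e`). Indel reads
   are counted once and never enter substitution classes — the two
   rates are reported as parallel, non-overlapping categories.
2. **nonsynonymous_bystander** / **synonymous_bystander** — ≥1 non-target
   protospacer A→G of that consequence class (nonsynonymous, including
   stop gained/lost, dominates; bystanders falling outside the annotated
   CDS segment are grouped with the synonymous class).
3. **on_target_only** — exactly the target A→G and nothing else in the
   window (this is the desired-edit-only numerator).
4. **other** — any remaining non-reference pattern (e.g. a lone
   sequencing error, or the target edit plus a non-A→G substitution).
5. **wildtype**.

Per-adenine rates count reads with G (protospacer-strand sense) at each
A_x position; reads whose deletion covers the position, and N no-calls at
the position, are excluded from numerator and denominator alike. The
desired-only rate is bounded above by the target adenine's per-position
rate by construction.

Whether published "total aligned reads" denominators excluded indel reads
is ambiguous; both behaviours are computed
(`exclude_indels_from_denominator`, default off, logged in run metadata).
Supplementary per-allele breakdowns in heterozygotes would require a
phasing rule that is not described anywhere; no genotype phasing is
implemented — the allele table itself is the per-allele report.

The 0.20% display cutoff (`min_freq = 0.002`, frequency ≥ cutoff kept)
applies to rendered allele tables only; summary statistics always use
the unfiltered table.

## Consequence calls

Reference offsets map to c. positions through a single anchored base and
the coding strand; on a '−' coding strand the substitution is
complemented before the codon is rebuilt. Only the intra-exonic CDS
segment overlapping the amplicon is required; positions outside it (or
codons truncated by the segment boundary) are reported `noncoding` with a
warning. Translation uses the standard genetic code only (table 1; mouse
nuclear loci). The bundled demonstration locus is synthetic — it mirrors
the geometry of a pathogenic Arg→His transition (mutant CAC at c.584,
codon 195, restored to CGC by the target A→G) with nonsynonymous and
synonymous bystander adenines in the protospacer — and is not a published
amplicon sequence.

## Off-target search

Desk-scale scanning of provided sequences (not genome-scale indexing):
every position on either strand whose Hamming distance to the
protospacer is ≤ `max_mismatches` (default 6, the threshold used when
verifying nominated sites by targeted amplicons) and whose adjacent PAM
matches the IUPAC pattern is reported; hits whose starts fall within
`window_size` bp (default 3) are merged keeping the lower-mismatch one;
ranking is by (mismatches, contig, start). `window_size = -1` disables
merging (used when comparing against the brute-force oracle). With
`allow_gaps`, bulged sites up to `gap_threshold` (default 3) are admitted
via bounded edit distance (edlib) and flagged `gapped`. Read-level
parameters of the wet discovery pipeline (mapq_threshold 50,
start_threshold 1) concern sequencing data and have no in-silico
counterpart here. Editing at a nominated site is quantified by deriving
an amplicon spec from the site and running the ordinary quantifier (no
consequence call for intronic/noncoding sites).

## Phenotype statistics

* Pearson r by product-moment; two-sided p from `t = r√((n−2)/(1−r²))` on
  n−2 df; 95% CI via Fisher z (`tanh(atanh r ± 1.96/√(n−3))`), degenerate
  |r| = 1 collapsing to a point interval and n = 3 to (−1, 1).
* Welch's t with Satterthwaite df (scipy), two-sided.
* `percent_change = 100·(treated − control)/control`;
  `fold_ratio = a/b`. Reporting rounds half away from zero to one decimal
  (1.25 renders 1.3); stored values are unrounded. Note the published
  female 6-week figure (5.7%) differs from the arithmetic on the printed
  means 16.2 vs 15.3 g (5.9%) — it evidently derives from unrounded
  underlying data; this package asserts only the arithmetic on printed
  means.
* ΔΔCt: per sample dCt = Ct(gene) − Ct(reference); ΔΔCt = mean dCt(group)
  − mean dCt(calibrator); fold = 2^(−ΔΔCt). The calibrator against itself
  is exactly 1 for any table.
* Composite ataxia score: hindlimb clasping, gait, kyphosis and ledge
  walking each 0–3, pelvic tilt 0/1, summed to 0–13 with eager range
  validation.
* Omnibus ANOVA-family tests are deliberately not re-derived; they are
  off-the-shelf procedures outside this package's surface.

The cohort generator plants Pearson correlations *exactly* in the sample
(noise is projected orthogonally to the editing vector before mixing), so
planted-correlation tests are deterministic rather than approximate. The
qPCR generator shifts the target-gene Ct of the treated group by
−log2(fold) under 0.15-cycle technical noise.

## Problem sizes and determinism

The validation suites run the full chain at n = 20 000 reads (exact
round trip) and 20 seeds × 10 000 reads (noisy recovery), sizes at which
binomial standard errors are small relative to the planted effects while
the whole suite stays interactive on a single core. All randomness in
tests and in `scripts/acceptance.py` derives from explicit seeds
(sub-streams spawned via `numpy.random.SeedSequence`); fixed seed + fixed
inputs gives byte-identical outputs end to end.

## Known limitations

No base-quality-weighted calling or UMI deduplication; C→T (cytosine
editor) chemistry is structurally supported but untested; multi-exon CDS
stitching and splice-site effects are out of scope; demultiplexing and
BAM/SAM ingestion are not provided (instrument demultiplexers and
plain FASTQ are assumed). Real-data mode requires the user to supply the
amplicon references and FASTQ files; no download tooling is included.
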