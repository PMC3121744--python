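# Methods

## Model and assumptions

The pipeline detects parent-of-origin expression bias from reciprocal
crosses between two sequence-diverged subspecies. Its core assumptions:

- The two parental genomes are colinear and differ at a known table of
  single-base substitutions (SNPs). Reads are assignable to a parent only
  where they overlap exactly one such SNP and align uniquely; everything
  else is discarded with an explicit reason so that read accounting is
  exact.
- In the absence of imprinting, allelic transcript ratios follow genome
  dosage: 2 maternal : 1 paternal in the triploid endosperm, 1:1 in the
  diploid embryo. Departures are tested per feature with a Pearson
  chi-square (df = 1) against those expectations, with no continuity
  correction and no multiple-testing adjustment of the calls themselves
  (a Benjamini–Hochberg column is emitted as supplementary output only);
  the per-feature cutoff is −log10 P ≥ 1.3, with ties at the threshold
  counted as significant.
- Imprinting must be concordant across the reciprocal crosses in the
  parental-*gender* direction. A significant bias whose direction flips
  between crosses but consistently favours one subspecies *allele* is
  classified as subspecies bias, not imprinting. Combined bias and
  −log10 P are the minimum (least significant) of the two crosses — a
  conservative AND-combination, so the combined evidence never exceeds
  either cross's.
- Allelic sampling at a feature is binomial given its total read count.
  An optional beta-binomial overdispersion parameter exists in the
  simulator (default off) because no dispersion beyond binomial is assumed
  by the test.

## Read preprocessing and assignment

Reads are 3′-adaptor trimmed (longest exact suffix–prefix overlap, minimum
5 bases), dropped if shorter than 18 bases or more than half covered by
tandem repeats, and embryo reads are truncated to their first 36 bases so
the multi-SNP exclusion risk matches the shorter endosperm libraries.
"Repetitive" is operationalized as the fraction of bases inside maximal
tandem runs of period 1–3 with at least three repeat units; the three-unit
minimum keeps the expected covered fraction of random 36-mers near 0.16, so
essentially no complex read is lost (<0.5% measured), while homopolymer and
dinucleotide reads are always removed.

Assignment uses an exact-match hash index over both haplotypes (18-mer
seeds, full-length verification, both strands via reverse-complement
queries). Because the haplotypes are colinear, the homologous position in
the other genome is the same coordinate, and the accept rules — unique
perfect hit in one genome, exactly one mismatch against the other, mismatch
on a reported SNP, exactly one SNP under the read — are evaluated directly.
Reads containing N cannot match exactly and are rejected. This assigner has
the same accept/reject semantics as a short-read aligner constrained to
perfect/one-mismatch hits, but is exhaustive and deterministic at the
simulated genome scale the package targets.

Counts are normalized between crosses by conversion to reads per million of
each cross's assigned-read total and multiplication by C = mean library
total / 10⁶, rounding half-up to integers. This choice of C (the fixed
constant is otherwise arbitrary) returns values on the scale of the raw
data and leaves counts unchanged when library totals are equal. Because the
per-cross scale factor mean/total is always ≥ 1/2 for two libraries, no
nonzero raw count can normalize to zero, and each record's maternal
fraction moves by at most 1/total under rounding.

## Scans

Physical windows are 1 kb every 0.5 kb. Window starts are 0 and multiples
of 500 with at least 500 bp remaining, and the last window ends at the
chromosome end, so no window shorter than 500 bp exists and a 3,000 bp
chromosome yields exactly five windows; every interior position is covered
by exactly two windows. A read participates in a window or feature through
its SNP position (a single point), making window totals exactly twice the
interior SNP-read total.

Annotated units are: each transcript isoform (its exon set) independently;
one intron unit per gene (gene span minus the exon union over isoforms);
and intergenic complements split into ≤10 kb pieces for reporting. Isoforms
of a gene with identical per-SNP support are indistinguishable and are
collapsed under a compound id. For conservation accounting each SNP read is
allocated to exactly one of exon-union > intron > intergenic (precedence
for nested annotation); the three totals must equal the total normalized
SNP reads on every run, and the pipeline aborts if they do not. SNPs inside
overlapping gene models contribute to both genes' units and the units are
flagged ambiguous.

The reconciliation step labels each significant window by overlap with
significant annotated candidates, with annotation (±2 kb flank, the
"within several kb of a gene" notion), or as intergenic, and reports
feature-only candidates (significant as an aggregate but diffuse at window
resolution). The splicing screen flags genes with at least one maternal and
one paternal call among their sub-features (isoforms, intron unit, windows
fully inside the gene span).

## Synthetic data

The generator emulates the study design: two colinear random genomes with
uniformly placed SNPs (default rate 1/200 bp, a transcribed-region density
plausible for two rice subspecies), random gene models (2–5 exons, ~30%
with a second exon-skipping isoform), and one single-end read library per
cross per tissue (36 bp endosperm, 75 bp embryo; no replicates, matching
the one-library-per-cross design). Planted truth classes: maternal and
paternal imprints (favoured-origin fraction `bias_level`, default 0.95),
subspecies-biased loci (fixed favoured allele, so the parental direction
flips between crosses), biallelic background at the tissue baseline,
low-coverage loci (~3 reads per cross), and splicing loci with maternally
favoured introns and paternally favoured exons. Splicing loci are planted
only on genes with SNPs in both exons and introns, since the signature is
unobservable otherwise; a planted locus whose span contains no SNP at all
is marked untestable with a warning.

Depth is long-tailed: each locus draws a per-SNP mean from a log-normal
(median 35 endosperm / 59 embryo, σ = 0.5 on the log scale) and each SNP a
Poisson count around it. Each read's parental origin is Bernoulli; reads
are exact substrings of the originating haplotype on a random strand, a
configurable fraction (default 5%) carrying a 3′ adaptor fill after a
shortened insert that still covers the SNP, so trimming is exercised
without destroying assignability. Read ids carry locus/origin/allele labels
as the oracle for assignment-accuracy tests. A counts-level entry point
draws per-locus binomial counts directly for large simulations where
individual reads add nothing.

What the simulator does *not* model — sequencing error, quality variation,
paired ends, indels and structural divergence between the genomes, mapping
bias of a heuristic aligner, and contamination of maternal seed tissue —
bounds what passing tests show: recovery results demonstrate correctness of
the statistics and bookkeeping under the design's own assumptions, not
robustness to real-library artefacts.

## Numerical choices

- −log10 P is computed in log space as −(log 2 + log Φ(−√χ²))/ln 10, exact
  for df = 1 and finite far beyond double-precision underflow of the
  survival function.
- χ² at the exact expectation is snapped to zero below 1e−18 (the smallest
  genuine deviation with integer counts is orders of magnitude larger), so
  "observed equals expected" is exactly non-significant.
- The uncorrected Pearson chi-square tracks the *mid-P* version of the
  exact two-sided binomial test: agreement is within 0.01 in P for totals
  ≥ 100 everywhere in the outcome space, whereas the conventional exact P
  differs from any continuous approximation by the half-probability of the
  observed outcome (O(1/√n), ~0.06 at n = 100) near the mode. Tests
  therefore use the exact-distribution mid-P as the oracle.
- Direction when the maternal fraction equals the expectation exactly is
  "none" (χ² = 0, never significant). Rounding in normalization is
  half-up. Windows shorter than 500 bp are never created (tail merged
  backward).
- Micro-clusters (no formal rule exists in the field's reports, which list
  near-adjacent locus-id pairs): two imprinted genes with at most one
  intervening annotated gene or a gap ≤ 20 kb.
- Repeat proximity uses a two-sided permutation test (10,000 same-size
  random gene sets, +1-corrected empirical P) on mean nearest-repeat
  distance and mean repeat-bp within ±5 kb, overall and per repeat class —
  distribution-free, since no parametric form is defensible for those
  statistics.
- GO enrichment is the upper-tail hypergeometric against the expressed
  (≥10-read) background, BH-adjusted q-values reported.

## Problem sizes

Default simulated genomes are 2 × 100 kb (~60 gene models, ~1,000 SNPs,
~20k assigned reads per cross); the test suite's largest runs use 2 × 150 kb
with 40 planted loci for the splicing screen and 1,000–2,500 count-level
loci for calibration and recovery checks. These sizes give every statistic
enough events to be measured at its stated tolerance while keeping a full
test run around ten seconds.

## Known limitations

- The exact-match assigner requires colinear equal-length genome pairs; it
  is not a general aligner and does not handle indels between subspecies.
- Single-cross candidates are flagged but never promoted to calls without
  coverage in both crosses, so genes expressed from only one subspecies
  allele (presence/absence variation) are invisible.
- The splicing screen is annotation-driven plus in-gene windows; fully
  novel isoforms outside annotated gene spans surface only as intergenic
  or window candidates, not as splicing candidates.
- With one library per cross, biological replication is absent by design;
  the chi-square treats reads as independent draws, so PCR duplicates or
  allele-specific mapping artefacts would inflate significance in real
  data.
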