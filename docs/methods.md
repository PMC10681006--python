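# Methods

## The allele model

A single reference locus (0-based coordinates) carries candidate insertion
sites; an insertion at position *p* sits between bases *p*−1 and *p*, which
is unambiguous at both sequence ends. An allele is the subset of insertions
it carries, and a diploid genotype an unordered allele pair. The default
lattice is F1 (no insertion), F2 (intron-1 300-bp insertion), F3 (both the
intronic and the exon-2 9-bp insertion), with the *nested* constraint —
every allele carrying the exonic insert also carries the intronic one —
enforced at model construction (configurable off). The constraint reflects
the observed germplasm: no exon-insert-only haplotype has been found, which
also supports F3 having diverged from F2 by gaining the exonic insert.

When an allele carries several insertions they are spliced in descending
coordinate order, so stored positions are always reference coordinates.
Sequences are strict uppercase A/C/G/T; ambiguity codes (including N) are
rejected at load rather than silently handled.

## Junction probes

For site at position *p* with flank length *f* and window *W* (default 60):

- presence probe = `ref[p−f:p] + (insert + ref[p:])[:W−f]`
- absence probe = `ref[p−f:p] + ref[p:p+W−f]`

Both probes share the *f*-base upstream flank. In the default
`fixed_window` mode both probes are exactly *W* bases. `published_compat` mode
shortens the absence probe by the insert length when the insert fits inside
the window, reproducing byte-exactly the published 51-base exon-2 reference
sequence alongside 60-base presence probes; whether that 51-mer was
intentional or a transcription artifact is unknowable, so both behaviors
are provided and neither is asserted as intent. Published flank lengths are
30 bp (intron-1) and 32 bp (exon-2); both are overridable.

## Read screening and genotype calling

A read supports a probe only if it contains the probe as an exact,
full-length, contiguous substring; any mismatch, gap or N in the span
disqualifies it. Matching checks both the probe and its reverse complement
by default, because shotgun reads sample both strands (a forward-only flag
restores literal containment). A probe longer than a read is a
configuration error, not a silent zero. Exact containment is implemented as
substring search rather than delegated to an aligner: 100 % identity over
the full probe makes alignment scoring unnecessary and keeps results
bit-reproducible.

Support counts reduce to site states under a minimum support *m*
(default 1; *m* = 2 recommended for error-bearing data): both supports
≥ *m* → HET; only presence → HOM_INS; only absence → REF; neither →
NO_CALL. Conflicting evidence with both sides ≥ *m* is still HET — no
ratio heuristics — with a warning logged when the minor fraction is below
0.1. Per-site states map to genotypes by enumerating the allele model's
genotype space and computing each genotype's expected state vector; a
vector reachable by exactly one genotype yields that call, an unreachable
vector (e.g. exonic insertion without intronic, under the nested model) is
INCONSISTENT, and any NO_CALL input propagates. The recessive phenotype
rule predicts red only for the double-insertion homozygote.

### Known failure mode of thresholded calling

The per-side support of a heterozygous junction is the number of reads
fully containing one haplotype's 60-mer: mean
(C/2)·(L−W+1)/L·(1−e)^W ≈ 8.8 reads at C = 30×, L = 150, e = 0.001. When
the minor side of a true heterozygote draws fewer than *m* supporting
reads, the threshold rule collapses the site to a homozygous state — a
concrete miscall, not a NO_CALL (and with minor support exactly 0 no rule
could distinguish it from a true homozygote). At the defaults this happens
with probability ≈ 1.4×10⁻³ per heterozygous junction side, i.e. a few
tenths of an event per 192-accession panel, so a given seeded panel run
recovers either 192/192 or, occasionally, 190–191/192 genotypes. Such
events are always auditable from the emitted per-site support counts, stay
within the pink phenotype class (an F1F2→F1F1 collapse does not change the
predicted phenotype), and never touch the F3F3/red determination, whose
junctions are homozygous with twice the support. The test suite asserts
exactly this contract; the acceptance panel check is run at a fixed,
pre-registered seed and reports the realized concordance.

## Synthetic data

The generator emulates the study design: a ~5-kb locus (GC 0.38, matching
the genome-wide GC content) carrying the intron-1 and exon-2 sites at 1/3
and 2/3 of its length; the published junction fragments spliced in verbatim
(`published_fragments=True`) so probe design reproduces the printed sequences;
a panel of 23 red F3F3 accessions plus 169 pink accessions split
34/34/34/34/33 over F1F1/F1F2/F1F3/F2F2/F2F3 (the germplasm total is
reported as 169 pink in the genotyping panel and 168 in the validation
set; the fixture uses 169, and the per-class split is this package's
declared default since only the red/pink totals are reported). Only the
first 30 bp of the 300-bp intronic insert are published; the remaining
270 bp are synthetic filler and are not presented as the real sequence.
The 9-bp exonic insert is constructed as a tandem duplication of the
9 bases preceding its insertion point.

Loci are rejection-sampled (bounded attempts) so that every probe, in
either orientation, occurs exactly at its own junction and nowhere else in
any allele sequence, making support counts interpretable as junction
coverage.

Reads are fixed-length (150 bp), uniform-start, substitution-only
(error rate 0.001 by default — substitutions suffice because the matching
criterion is full-length exact identity, so indel errors would exercise the
same failure path), with constant quality symbols and no Ns (N handling is
tested with hand-built reads). Read count is
round(coverage × mean haplotype length / L); each read's haplotype is a
fair coin rather than an exact 50/50 split, deliberately modelling the
sampling noise the genotyper must tolerate. Paired mode draws
round(.../2L) fixed 2L fragments (mate 2 reverse-complemented), honoring
the same base yield. Per-read truth (`allele:start`) is recorded. All
randomness flows from a single integer seed (per-individual streams are
derived from the seed plus a CRC of the individual id, so outputs are
byte-stable).

What the generator does *not* emulate: quality-score error profiles, PCR
duplicates, indels, coverage biases, contamination, or insert-size
distributions. Passing tests therefore demonstrate correctness of the
probe/screening/calling logic under the stated error model, not robustness
to every artifact of real sequencing data.

## Association and Mendelian analysis

The cross-tabulation is F3F3-vs-other against red-vs-pink; individuals
with unknown phenotype or non-concrete genotype are excluded with a logged
count. The two-sided exact p-value sums, over all tables with the observed
margins, the hypergeometric probabilities no greater than the observed
table's (the standard "at least as extreme" convention, stated explicitly
because conventions differ), computed in exact rational arithmetic so
N = 192 is stable; under perfect cosegregation the observed table is the
unique most extreme one and p = 1/C(192, 23) ≈ 3.1×10⁻³⁰. The variant scan
ranks tables passing p < 10⁻²⁰ (the genome-wide threshold; Bonferroni
correction is exposed as an option without asserting which convention the
original analysis used), with deterministic tie-breaks. This exact test is
a deliberately simplified analogue of a mixed-model association scan:
kinship/structure correction is out of scope, and the acceptance surface is
cosegregation on synthetic panels. The odds ratio applies the
Haldane–Anscombe 0.5 correction only when a zero cell would make it
undefined, and flags that it did. The Mendelian report collapses F1/F2 → R
and F3 → r and checks "RR/Rr pink, rr red" exactly, listing violating
individuals; with no informative individual, consistency is undefined
rather than vacuously true.

## Insert characterization and closed forms

The tandem-duplication test is suffix equality: the insert equals the
|insert| reference bases immediately preceding the insertion point. No
rotation-equivalence or longer-period detection is attempted. In-frame
means length divisible by 3; the reading frame of the exonic insert is a
declared parameter (0 for the fixture, giving codons GGC-CTC-CAG → GLQ).
Translation uses the standard genetic code, renders stops as `*`, and
drops a trailing partial codon with a warning.

LTR insertion age is T = K/(2r) with K a Kimura 2-parameter distance and
r = 7.7×10⁻⁹ substitutions·site⁻¹·yr⁻¹ for peach (K estimation from
alignments is out of scope; K is an input). Enzyme activity follows the
unit definition (product µg / protein mg) × (100 / minutes); note that the
reported 78.66 % activity decrease is arithmetically 79.92 % when computed
from the rounded printed activities 20.62 → 4.14 U — the discrepancy
presumably stems from unrounded measurements, so the package computes the
formula and never hard-codes the printed percentage.

## Problem sizes and numerical choices

The panel analyses use a 5-kb locus, 192 accessions, 30× coverage — about
2×10⁵ reads per run, a few seconds end to end; the oracle cross-check uses
50 independent 900-bp loci at 20× error-free coverage, six accessions each
(one per genotype class). The exact test is validated exhaustively against
an independent implementation on all 2×2 tables with N ≤ 12 and by the
closed form at N = 192. Floating comparisons use relative tolerances of
10⁻⁹ (vs the independent exact-test implementation) and 10⁻¹²–10⁻¹⁴ for
closed-form identities; probe and sequence checks are byte-exact.
Pipeline outputs embed the seed and a parameter fingerprint and contain no
timestamps, so identical configurations produce byte-identical artifacts.
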