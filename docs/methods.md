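# Methods

## Overview

`juncture` detects differential alternative splicing and intron retention
between two RNA-seq conditions from aligned reads, using a junction-centric
approach: every splice junction (a CIGAR N gap) is tested on its own
evidence, normalised against neighbouring junctions of the same gene, so
novel and aberrant junctions — common after perturbations of the splicing
machinery — are handled on the same footing as annotated ones. A companion
analysis relates retained introns to the distance between their 5' splice
site and branch site, and a small geometry module carries the
spliceosome-structure arithmetic that rationalises why very short 5'SS–BS
distances block activation of the pre-catalytic (B) complex.

## Junction model and differential usage

Junction reads are reads mapping discontinuously within one gene. Each N gap
of an alignment is one observation for the junction spanning exactly that
gap; a read with several gaps contributes one observation per gap. The
overhang — the reference length of the M block immediately flanking the gap,
taking the smaller side — must reach 3 nt for annotated junctions (gaps that
equal a derived intron) and 6 nt for novel junctions (gaps inside a gene
span that match no intron). Insertions and deletions between the gap and the
nearest M block do not count toward the overhang. Novel junctions are
assigned to the gene whose span contains both gap endpoints; among
overlapping genes, a strand-matching gene wins when junction strand is
known, then the smallest span, then lexicographic id.

Junction N qualifies as a *neighbour* of junction J iff (i) every transcript
whose intron set contains N span-subsumes J, (ii) every transcript
containing J span-subsumes N, and (iii) the minimum genomic gap between the
two intervals is ≤ 5 kb (0 when they overlap). "Contains" means the junction
interval equals one of the transcript's introns; a novel junction is
contained in no transcript and satisfies its side of (i)/(ii) vacuously.

Differential usage of junction J is Fisher's exact test (two-sided,
probability-mass ordering) on the 2×2 table of (J's counts, summed neighbour
counts) across the two conditions. Any zero margin makes the table
degenerate and returns p = 1. Percent spliced in uses only the
boundary-sharing neighbours:

    PSI = mean( J / (J_sameStart + J),  J / (J_sameEnd + J) )

a term with zero denominator is dropped; with both dropped PSI is undefined
and the junction is reported but never called. A junction is called
differential when p < 0.001, |ΔPSI| > 0.15 (strict inequalities) and at
least 7 reads support it in one of the conditions. No multiple-testing
correction is applied in the calls, matching the raw-threshold regime of
the method; Benjamini–Hochberg-adjusted values can be computed from the
report but play no role in calling.

Differential junctions are classified by a greedy closure over competing
junctions: starting from the seed, any detected junction within the ±5 kb
window sharing a start or end coordinate with a closure member is absorbed
until a fixed point (bounded by the number of junctions in the window). One
competitor sharing the donor-side boundary (interval start on '+', end on
'−') is an alternative 3'SS event; the acceptor side, an alternative 5'SS.
A three-junction closure of two inclusion junctions plus their spanning skip
junction is a cassette exon; other closures are complex.

## Intron retention

Retention calls combine two lines of evidence. First, the junction exactly
matching the intron's boundaries must be differentially used on the
*p*-value criterion (p < 0.001) and have an empty competitor set — such a
junction has no boundary-sharing neighbours, its PSI is 1 in both conditions
and ΔPSI is identically 0, so the ΔPSI and read-count thresholds of the
alternative-splicing call do not apply here; demanding them would make
retention structurally uncallable. Second, the intron-retention ratio must
change at least 2-fold with Fisher p < 0.001.

The IR of an intron segment is its strictly-intronic per-nucleotide read
density divided by the pooled density of the neighbouring introns (those
whose junctions pass rules (i)–(iii)), within one condition. Strictly
intronic reads have no N gap and lie entirely inside the intron interval;
each is assigned to the segment containing its aligned midpoint. Introns are
cut into max(2, floor(L/500)) equal-width segments (the last absorbs the
remainder) and the single robust IR is the median over segments (mean of the
middle two for even counts), which ignores coverage spikes confined to fewer
than half the segments — unannotated exons, nested transcription units,
transposable elements. A pseudocount of 0.5 reads is added to each raw
segment count and to the neighbour sum before densities are formed
(Haldane), stabilising zero-count segments; at counts ≥ 10 its effect on
fold changes is below 5%. Intronic reads can also be expressed per million
intronic reads of the experiment for reporting; the scale cancels in every
IR ratio. The differential-IR Fisher test uses raw integer sums (intron
segments vs neighbour introns, across conditions) — exact tests need
integers — while densities enter only the IR and fold values. The per-length
density correction is applied because segment and neighbour spans differ in
length; a literal read-count-ratio mode (no length correction) is available
behind a flag for sensitivity analysis.

## 5'SS–branch-site distances

When several branch sites are annotated for one intron, the one with the
most lariat reads carrying the reverse-transcription mismatch at the branch
adenosine wins; ties go to the candidate nearest the 3'SS, then to the
lowest coordinate. High- and moderate-confidence records are pooled. The
5'SS–BS distance is the number of intron nucleotides strictly 5' of the
branch adenosine, measured from the intron's transcriptional 5' end; the
convention is inclusive/exclusive-agnostic to within 1 nt and reproduces the
construct arithmetic below. Retained short introns (< 250 nt by default) are
compared against unaffected introns with branch-site annotation via a
length-matched background: retained lengths are cut at their deciles and
each retained intron draws 5 background introns (the oversampling factor)
with replacement from its decile bin, falling back to the nearest non-empty
bin. The two distance samples are compared with the two-sided two-sample
Kolmogorov–Smirnov test using the asymptotic p-value — every use here has
n ≥ 40, where the asymptotic form is adequate.

## B-complex geometry

With a 17-nt 5'SS/U6 helix, a 14-nt BS/U2 helix, a 15-nm inter-helix gap and
0.7 nm per nt of extended RNA, the gap corresponds to round(15/0.7) = 21 nt
and the minimal 5'SS–BS span to 17 + 21 + 14 = 52 nt. Construct distances
follow from conservation of the BS-to-3'SS block: a construct of length
L_new derived from a reference of length L_ref with distance d_ref has
distance L_new − (L_ref − d_ref); lengths that cannot conserve the block are
an error.

## Synthetic data generator

The generator emits an annotation (GTF), already-aligned single-end reads
(SAM, M/N CIGARs only) for two conditions, and a branch-site table, so the
full pipeline runs without external data. Five gene templates cover cassette
exons (inclusion + skipping transcripts), alternative 5'/3' splice sites
(two transcripts shifted by 30 nt at the relevant boundary, strand-aware),
retained introns (a single transcript whose short 70–200 nt middle intron is
flanked by two constitutive introns, giving the IR denominator two stable
neighbours) and constitutive genes. Generic intron lengths come from a
mixture — 70–200 nt (30%), 200–1000 nt (40%), 1–5 kb (30%) — chosen so the
branch-site detection model (below) lands near its target overall rate.

Junction read counts are Poisson with mean depth × isoform fraction, where
the isoform fraction follows the per-condition inclusion PSI (alternative
events) or 1 − retention fraction (RI introns; default retention 0.2 vs 0.8,
a 4-fold IR contrast strong enough to shift the junction as well). The left
aligned block of each junction read is uniform on [1, read_length − 1], so
the overhang filter sees its full range. Strictly intronic read counts are
Poisson with mean retention × depth × 0.02 × (number of read start
positions); non-RI introns carry a constant retention noise of 0.15 in both
conditions so neighbour denominators are informative. Reads are 50 nt so
they fit strictly inside even the shortest (70 nt) introns. Branch-site
detection probability is logistic in log intron length through the two
anchor points p(100 nt) = 0.27 and p(250 nt) = 0.45 — with the default
length mixture the expected cohort-wide annotated fraction is ≈ 0.58 — and
the branch adenosine sits uniformly 18–44 nt upstream of the 3'SS; ~10% of
annotated introns get a second candidate to exercise tie-breaking. Base
sequences and qualities are filler; only coordinates and CIGARs matter.

The generator does not model sequencing error, fragment-length or positional
bias, paired-end structure, multi-mapping, expression-level differences
between genes, or overlap between genes. Passing tests therefore demonstrate
the statistical machinery — error control, power, recovery — under clean
Poisson sampling, not robustness to alignment artefacts or mappability
structure in real libraries. Single-end records suffice because every
statistic consumes junction-gap and intronic counts only.

## Problem sizes and numerical choices

The behavioural test suite uses cohorts of 150–667 genes: ~2,000 null
junctions at depth 50 for the type-I check (observed false-call rate ≤
0.2%), 200 cassette events at depth 100 for power and ΔPSI recovery, and 300
retained introns at depth 100 (≥ 30 intronic reads each) for IR recovery,
with a same-size null cohort for false retention calls. Fisher p-values are
validated against exhaustive hypergeometric enumeration over random tables
with totals up to 300 at 1e−7 relative tolerance. Thresholds are applied
with strict inequalities exactly as stated (p = 0.001 or ΔPSI = 0.15 are not
called). floor() is used in the segment formula for non-integer L/500.
ΔPSI is reported as an absolute difference. All randomness flows from
explicit integer seeds through numpy Generators; outputs are byte-identical
across runs with the same seed.

## Known limitations

- Gene assignment of novel junctions ignores read strand unless supplied;
  antisense junctions inside a gene span are attributed to that gene.
- Reads are never collapsed for duplicates, and mapping quality is ignored.
- A read spanning two intron segments is counted once, in its midpoint
  segment; a fractional "covering" rule would differ slightly for reads
  straddling a boundary.
- The IR denominator requires at least one qualifying neighbour intron;
  single-intron genes are reported as not callable.
- The branch-site detection asymmetry means short-distance enrichment among
  retained introns is, if anything, underestimated; no corrected estimator
  is attempted.
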