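# Methods

This note records the models, conventions and numerical choices behind
`exodecay`, and what the simulated tests do and do not establish.

## Coordinates and formats

All internal coordinates are 0-based half-open `[start, end)`; GTF/GFF3
(1-based closed) is converted at the parsing boundary only. Strand is
`+`, `-` or `.` (unstranded); unstranded tracks answer queries for either
strand, with a single logged warning. Reads are consumed as BED6
intervals (one per aligned read, score = MAPQ); the MAPQ filter discards
reads with score < 20, keeping 20 exactly. Coverage is stored as sorted
disjoint runs per (chromosome, strand) with an implicit zero elsewhere;
integer-valued tracks round-trip through bedGraph bit-identically, and a
`# exodecay` comment line carries library size and normalisation state so
tracks cannot be silently double-normalised.

## Interval algebra and intron annotation

`merge_intervals` and `subtract_intervals` operate on base sets; touching
intervals (`[a,b)`, `[b,c)`) merge, so bookended exons never create
zero-length introns. A gene's synthetic transcript is the merged exon set
over all isoforms; its introns are the gene span minus that set, numbered
in transcription order — index 1 is promoter-proximal, so on the minus
strand the genomically rightmost intron is intron 1. This reading (rather
than numbering by genomic coordinate regardless of strand) is the one
under which "first intron" means the biologically first intron, which is
where premature cleavage-and-polyadenylation products accumulate; both
the tests and a per-base brute-force oracle pin it down. The gene span
comes from the annotation's gene record when present (widened to the exon
hull if exons poke out), else the exon hull, so UTR-flanking gaps inside
a declared span become introns only if they lie outside every exon.

`gap_distance` counts bases strictly between two intervals: 0 for overlap
or touching, +inf across chromosomes. It is symmetric by construction.

## PROMPT / eRNA designation

De novo transcripts overlapping any annotated gene span by ≥ 1 bp (any
strand, any biotype by default; a biotype restriction is available) are
dropped as known. Survivors take the nearest gene by span-to-span gap on
their chromosome, with distance ties broken by the lexicographically
smaller gene id so the call is order-invariant. The class rule is strict:
gap < 3000 bp → PROMPT; gap ≥ 3000 bp (including exactly 3000) → eRNA.
Span-to-span distance and the 3-kb boundary convention are package
choices where the field's usage is loose; both are configurable
(`prompt_max_distance`, and a TSS-anchored variant can be built from the
same primitives). The bidirectionality check calls a locus bidirectional
when each strand carries at least `min_frac` (default 0.1, inclusive) of
its total signal; zero signal is not bidirectional.

## Differential accumulation

Counting: a read increments every interval it overlaps by ≥ 1 bp
(de novo loci are essentially disjoint); a unique-assignment switch gives
multi-overlap reads to the largest overlap, ties to the leftmost.

Normalisation: median-of-ratios size factors over intervals with nonzero
counts in all samples. When the tested loci are exactly the loci expected
to change (as for PROMPT/eRNA sets under depletion), factors must be
anchored on a stable reference — the pipeline uses annotated gene-body
counts — otherwise the composition effect normalises the signal away.

Test: per interval, normalised condition means m_c, m_d;
log2FC = log2((m_d + 0.5)/(m_c + 0.5)) (pseudocount 0.5 stabilises empty
loci); NB dispersion α by pooled within-condition method of moments,
Σ(v_c − m_c)/Σ m_c², floored at 1e-8; Wald z from the delta-method
standard error with Var(mean) = (m + αm²)/n per condition; two-sided
normal p; Benjamini–Hochberg adjustment over all tested intervals.
All-zero intervals report p = 1, log2FC = 0. "Upregulated" means
log2FC ≥ 1 and padj < 0.05 (strict). With one replicate per condition the
dispersion cannot be estimated and p-values are not meaningful; the
moment estimator at n = 3 is noisy and the raw Wald p is mildly
anticonservative, but the BH-adjusted call rate under a complete null
stays below 5 % (measured ≈ 2–3 % at 2,000 intervals), and planted 8-fold
effects at base mean ≥ 50, dispersion 0.05, 3 vs 3 are recovered
essentially completely with empirical FDR ≈ 0. This transparent test is a
deliberate stand-in for shrinkage-based NB GLMs: thresholds and call
semantics are identical, p-values are not expected to match any
particular implementation.

## Metagene profiling

Expressed genes are those with strictly more than 50 reads. The extended
window is 3 kb upstream of the TSS and 7 kb downstream of the TES in
transcription direction; windows leaving the chromosome are discarded,
and any window overlapping another (≥ 1 bp, strand-agnostic) removes
*both* members — the strictest reading of "no double counting", applied
as a pairwise rule so overlap chains vanish entirely. Profiles bin
per-base signal via the exact cumulative integral, so fractional bin
edges (bodies shorter than the bin count) are weighted exactly: uniform
coverage is flat to < 1e-9 and fixed-mode bin means conserve window mass
to < 1e-6 relative. Defaults — 50-bp flank bins, 100 body bins — are
configurable; the field's plotting tools use comparable grids but no
specific values are claimed. eRNA and PROMPT regions are profiled in
fixed mode with no extension. The promoter-upstream profile bins
`[TSS−3 kb, TSS)` separately on the gene's strand and its opposite
(PROMPT) strand; the antisense series is returned positive and may be
sign-flipped for display. RPKM is count·10⁹/(library·length); for
base-resolution tracks "RPKM profiles" are RPM-scaled per-base signal,
and the matrix records which.

## ChIP peaks and enhancer classification

The genome is tiled in 200-bp windows (window = step by default). The
expectation for a window is max(depth-normalised input count in the
window, genome-wide input rate × window, 0.1); the max with the global
rate keeps the test conservative where the input is sparse, and the 0.1
floor prevents zero-λ infinities. p = P(Poisson(λ) ≥ k) via the survival
function (checked in tests against direct summation to 1e-8 relative);
"q-values" are BH-adjusted p-values (the estimator is recorded in
output); windows with q < 0.05 merge into peaks when adjacent, a peak
taking its members' summed counts and minimum p/q. This windowed caller
is intentionally simpler than sliding local-λ machinery; equivalence to
any specific peak caller is a non-goal. The H3K4me1/H3K4me3 comparison is
log2((me1 + 1)/(me3 + 1)) on 200-bp binned counts of depth-matched
tracks — binning keeps sparse per-base counts from being drowned by the
pseudocount — and a locus is enhancer-like when its mean ratio ≥ 1,
promoter-like ≤ −1, else ambiguous.

## iCLIP footprints

Crosslink sites follow the truncation convention: the site is the base
immediately 5′ of the read 5′ end in transcription direction (plus-strand
read `[s,e)` → site s−1; minus-strand → site e); a "read 5′ end itself"
convention is a switch. Tracks are normalised to reads per million
mapped; the library size is the full read count (including reads whose
site falls off the chromosome start). The footprint window is the 30 nt
immediately downstream of a feature's annotated 3′ end, excluding the
mature end base; windows clipped at chromosome ends are computed over the
clipped range and flagged. Enrichment = (RPM_mut + 0.1)/(RPM_WT + 0.1);
the 0.1-RPM pseudocount keeps empty WT windows finite without distorting
real signal. The width estimate is the smallest w such that the first w
downstream bases hold ≥ 90 % of the downstream signal within 100 nt; it
is a property of the mutant track alone, so it is only meaningful where
the footprint dominates background readthrough (at 33-fold planted
enrichment the estimate is 29–30 nt; at ~10-fold it is background-
dominated by construction). snoRNA targets are flagged by ≥ 1 mutant
crosslink *site* within 50 nt downstream (an any-read-overlap variant is
a switch); reads inside the gene body never flag.

## Simulator

One toy chromosome (default 2 Mb) carries 100 protein-coding genes
(2–5 exons, 1–3 isoforms, exons 150–500 bp, introns 400–1200 bp),
20 snoRNAs (70–200 bp; half intronic, half intergenic) and 20 enhancer
loci (1 kb), all ≥ 10 kb apart, so enhancers are automatically > 3 kb
from genes and upstream PROMPT windows are unambiguous. The generator
raises with the required length when features cannot fit.

RNA-seq: per-locus counts are NB with variance μ + αμ² (α = 0.05);
gene-body means (lognormal, median 300) are constant across conditions;
PROMPT windows (antisense, 0.5–2.5 kb upstream), eRNA loci (bidirectional
~50/50) and first introns are multiplied by 8×, 8× and 4× respectively in
the depleted condition. Reads are unspliced fixed-length 50-bp intervals
placed uniformly — within merged exons for gene/snoRNA bodies (mature
RNA), within the locus for PROMPT/eRNA/intron species. iCLIP: a uniform
crosslink background (0.5 sites/nt) over gene spans plus 100 nt of
3′ readthrough, merged per strand; the catalytic-mutant sample adds a
30-nt downstream block per snoRNA sized so the expected windowed mut/WT
RPM ratio — including the mutant's library-size inflation — equals the
planted enrichment (default 33). ChIP: per-base Poisson background at
5 counts/200 bp, H3K4me1 ×5 over enhancers, H3K4me3 ×5 over ±500 bp
promoter windows, flat input. Identical seeds give byte-identical
outputs; every planted feature appears exactly once in the truth table.

What the simulation does not emulate: spliced reads, sequence content and
mappability structure, PCR duplicates, batch effects, overlapping gene
architecture, and the heavy-tailed expression and binding heterogeneity
of real genomes. Passing tests therefore establish the correctness and
calibration of the statistics under their stated model, not performance
on real libraries.

## Problem sizes and runtime

Tests and the acceptance script use the default 2-Mb study (plus a
3.5-Mb, 150-gene layout for the 200-transcript classification check,
2,000 intervals × 3 vs 3 for differential calibration, and 600-kb
Poisson backgrounds for peak-caller calibration); the full suite and the
acceptance script each run in well under a minute on one CPU. These sizes
were chosen so Monte-Carlo error is small relative to every asserted
margin.

## Known limitations

- The NB Wald p-values are asymptotic; with 3 replicates the raw test is
  mildly liberal (the BH-adjusted calls are what the pipeline reports).
- The peak caller's global-rate floor makes it conservative in sparse
  input regions; it does not model fragment-size shifts.
- Distance-based PROMPT/eRNA designation cannot distinguish an eRNA from
  any other gene-distal unstable transcript; the bidirectionality check
  is an additional filter, not proof of enhancer origin.
- BAM/CRAM, bigWig and spliced-coverage reconstruction are out of scope;
  convert alignments to BED6/bedGraph upstream.
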