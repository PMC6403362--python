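# exodecay

Analysis pipeline for characterising nuclear RNA decay substrates from
rapid-depletion sequencing experiments. When a nuclear exoribonuclease
(e.g. the RNA exosome subunits DIS3 or EXOSC10, or XRN2) is acutely
degraded, its normally short-lived substrates accumulate: promoter
upstream transcripts (PROMPTs), enhancer RNAs (eRNAs), prematurely
cleaved-and-polyadenylated first-intron species, and 3′-extended snoRNA /
5.8S rRNA precursors. `exodecay` implements the computational side of such
a study end to end, for bench scientists and computational biologists who
have coverage tracks and read intervals and want the substrate calls:

- **synthetic intron annotation** — per gene, exons of all isoforms are
  merged into a synthetic transcript, subtracted from the gene span, and
  the resulting introns numbered in transcription order (intron 1 is
  promoter-proximal on either strand);
- **PROMPT / eRNA designation** — de novo transcripts overlapping known
  genes are dropped; the rest are PROMPTs when the gap to the nearest
  annotated gene is < 3 kb and eRNAs otherwise, with an optional
  bidirectionality check;
- **differential accumulation** — reads are counted per interval, samples
  normalised by median-of-ratios size factors, and each interval tested
  with a negative-binomial Wald test (variance μ + αμ², method-of-moments
  dispersion, Benjamini–Hochberg adjustment). An interval is *upregulated*
  when fold ≥ 2 and padj < 0.05;
- **metagene profiling** — expressed genes (> 50 reads) get a −3 kb/+7 kb
  extended window; overlapping or out-of-bounds windows are discarded and
  RPKM/RPM coverage is averaged on a scaled-body or fixed bin grid
  (eRNA/PROMPT regions use fixed bins with no extension);
- **ChIP peak calling and enhancer classification** — fixed windows are
  tested against a depth-normalised input with a Poisson tail test
  P(X ≥ k | λ), BH-adjusted to q-values (q < 0.05), and loci are labelled
  enhancer-like or promoter-like by the binned log2(H3K4me1/H3K4me3) ratio;
- **iCLIP footprint detection** — reads collapse to crosslink sites (the
  base preceding the read 5′ end), tracks are RPM-normalised, and each
  feature's 30-nt downstream window is scored as
  enrichment = (RPM_mut + 0.1)/(RPM_WT + 0.1), with a 90 %-mass width
  estimate and a snoRNA-target flag for any mutant crosslink within 50 nt
  downstream of the mature 3′ end;
- **a ground-truth simulator** — toy genomes with planted PROMPT/eRNA/
  first-intron fold changes, iCLIP footprints of known width and
  enrichment, and Poisson ChIP backgrounds, so every stage is verifiable
  without any external data.

## Worked example

The numbered scripts under `analysis/` run the whole study on simulated
data and write tables under `results/`:

```sh
python analysis/01_simulate.py          # toy genome + all inputs
python analysis/02_intron_annotation.py
python analysis/03_classify_denovo.py
python analysis/04_differential.py
python analysis/05_metagene.py
python analysis/06_chip_peaks.py
python analysis/07_iclip_footprints.py
```

Representative output (seed 1):

```
120 de novo transcripts: 0 dropped as known, 100 PROMPT, 20 eRNA
agreement with planted classes: 100.0%

208 of 220 loci called upregulated -> results/diff/results.tsv
planted-effect recall: 94.5%; false calls: 0

depleted: ... upstream antisense mean RPM 48.70 vs sense 0.00
first-intron/first-exon density ratio, median depleted/control fold: 3.50

26 H3K4me1 peaks (q < 0.05); planted-enhancer recall 20/20

CAT/WT window enrichment: median 34.7 (range 24.6-56.3)
estimated footprint width: median 29 nt
flagged as targets (crosslink within 50 nt downstream): 20/20
```

Reading: every planted PROMPT and eRNA is designated correctly; the NB
test recovers 94.5 % of the planted 8×/4× accumulations with no false
calls; PROMPT transcription appears only antisense, upstream of promoters,
and rises ~5× upon depletion; the first-intron signal rises ~3.5×
(planted 4×, NB noise); all 20 planted enhancers are recovered as
H3K4me1 peaks and classified enhancer-like; and the catalytic-mutant
iCLIP shows a ~33-fold, ~30-nt crosslink footprint immediately 3′ of
every snoRNA.

The same stages are exposed as a CLI (`exodecay simulate | introns |
classify | diff | metagene | chip | footprint | run`) over GTF/GFF3,
BED6, bedGraph and chrom.sizes files; `exodecay run --config run.yaml`
executes all stages and writes a `summary.json`.

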