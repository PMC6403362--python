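#!/usr/bin/env python
"""Poisson peak calling and H3K4me1/me3 enhancer classification.

Depth-normalizes the input control, tiles the genome in 200-bp windows,
calls H3K4me1 peaks at q < 0.05, builds the binned log2(me1/me3) ratio
track and classifies the planted enhancer loci and gene promoters.
Writes results/chip/.
"""

import os
import sys

import pandas as pd

sys.path.insert(0, os.path.dirname(__file__))
from common import RESULTS, ensure, need_sim

from exodecay.chip import classify_loci, depth_normalize, log2_ratio, poisson_peaks
from exodecay.coverage import read_bedgraph, write_bedgraph
from exodecay.intervals import GenomicInterval, read_annotation, read_chrom_sizes

sim = need_sim()
out = ensure(os.path.join(RESULTS, "chip"))

genome = read_chrom_sizes(f"{sim}/chrom.sizes")
genes = read_annotation(f"{sim}/genes.gtf")
truth = pd.read_csv(f"{sim}/truth.tsv", sep="\t")
me1 = read_bedgraph(f"{sim}/chip_me1.bedgraph")
me3 = read_bedgraph(f"{sim}/chip_me3.bedgraph")
inp = read_bedgraph(f"{sim}/chip_input.bedgraph")

peaks = poisson_peaks(me1, depth_normalize(me1, inp), genome)
with open(f"{out}/me1_peaks.bed", "w") as fh:
    for p in peaks:
        fh.write(f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\t"
                 f"peak\t0\t.\t{p.pvalue:.3e}\t{p.qvalue:.3e}\n")

enh = truth[truth["kind"] == "enhancer"]
hit = sum(1 for r in enh.itertuples()
          if any(p.interval.start < r.end and r.start < p.interval.end for p in peaks))
print(f"{len(peaks)} H3K4me1 peaks (q < 0.05); planted-enhancer recall "
      f"{hit}/{len(enh)}")

ratio = log2_ratio(me1, depth_normalize(me1, me3))
write_bedgraph(ratio, f"{out}/log2_me1_me3.bedgraph")
loci = [(r.locus_id, GenomicInterval(r.chrom, r.start, r.end)) for r in enh.itertuples()]
loci += [(f"prom_{g.gene_id}", GenomicInterval(g.chrom, max(0, g.tss - 500), g.tss + 500))
         for g in genes if g.biotype == "protein_coding"]
labels = classify_loci(loci, ratio)
labels.to_csv(f"{out}/locus_classes.tsv", sep="\t", index=False)
print(labels.groupby(labels["locus"].str.startswith("prom_"))["label"]
      .value_counts().rename_axis(["is_promoter", "label"]).to_string())
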