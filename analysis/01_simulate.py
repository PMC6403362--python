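#!/usr/bin/env python
"""Generate the simulated study: annotation, RNA-seq, iCLIP and ChIP inputs.

Writes a toy chromosome with 100 protein-coding genes, 20 snoRNAs and 20
enhancer loci, plus all downstream inputs (stranded read sets for 3+3
control/depleted RNA-seq replicates, WT and catalytic-mutant iCLIP reads,
H3K4me1/H3K4me3/input ChIP bedGraphs) and the planted-truth table, under
results/sim/. Later scripts read from there.
"""

import os
import sys

sys.path.insert(0, os.path.dirname(__file__))
from common import RESULTS, SEED, ensure

from exodecay import simulate
from exodecay.coverage import reads_to_coverage, write_bedgraph
from exodecay.intervals import write_annotation, write_chrom_sizes

out = ensure(os.path.join(RESULTS, "sim"))

genome, genes, truth = simulate.make_annotation(seed=SEED)
write_annotation(genes, f"{out}/genes.gtf")
write_chrom_sizes(genome, f"{out}/chrom.sizes")

n_reads = {}
for cond in ("control", "depleted"):
    batch = simulate.simulate_rnaseq(genome, genes, truth, cond, seed=SEED)
    for sid, reads in batch.items():
        simulate.write_reads_bed(reads, f"{out}/{sid}.bed")
        write_bedgraph(reads_to_coverage(reads),
                       {"+": f"{out}/{sid}.plus.bedgraph", "-": f"{out}/{sid}.minus.bedgraph"})
        n_reads[sid] = len(reads)

for sample in ("WT", "CAT"):
    reads = simulate.simulate_iclip(genome, genes, truth, sample, seed=SEED)
    simulate.write_reads_bed(reads, f"{out}/iclip_{sample}.bed")
    n_reads[f"iclip_{sample}"] = len(reads)

for name, trk in simulate.simulate_chip(genome, genes, truth, seed=SEED).items():
    write_bedgraph(trk, f"{out}/chip_{name}.bedgraph")

truth.to_tsv(f"{out}/truth.tsv")

print(f"wrote simulated study to {out}")
print(f"  {len(genes)} annotated genes "
      f"({sum(1 for g in genes if g.biotype == 'snoRNA')} snoRNAs), "
      f"{len(truth.of_kind('enhancer'))} enhancer loci")
for sid, n in sorted(n_reads.items()):
    print(f"  {sid}: {n} reads")
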