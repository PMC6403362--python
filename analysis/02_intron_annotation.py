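#!/usr/bin/env python
"""Build the synthetic intron annotation from the simulated gene models.

Merges all exon isoforms per gene into a synthetic transcript, subtracts
it from the gene span and numbers the remaining introns in transcription
order. Writes results/introns/introns.bed.
"""

import os
import sys

sys.path.insert(0, os.path.dirname(__file__))
from common import RESULTS, ensure, need_sim

from exodecay.intervals import read_annotation
from exodecay.introns import build_intron_annotation, write_intron_bed

sim = need_sim()
out = ensure(os.path.join(RESULTS, "introns"))

genes = read_annotation(f"{sim}/genes.gtf")
introns = build_intron_annotation(genes)
write_intron_bed(introns, f"{out}/introns.bed")

per_gene = {}
for it in introns:
    per_gene[it.gene_id] = max(per_gene.get(it.gene_id, 0), it.index)
print(f"{len(introns)} synthetic introns across {len(per_gene)} genes -> {out}/introns.bed")
print(f"  max intron index: {max(per_gene.values())}; "
      f"single-exon genes (no introns): {len(genes) - len(per_gene)}")
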