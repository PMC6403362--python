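#!/usr/bin/env python
"""Designate de novo transcripts as PROMPTs or eRNAs.

Takes the simulator's planted novel transcripts as the assembled de novo
set, drops any that overlap annotated genes, and classifies the rest by
distance to the nearest gene (< 3 kb PROMPT, otherwise eRNA), checking the
calls against the planted truth. Writes results/classify/denovo_calls.bed.
"""

import os
import sys

import pandas as pd

sys.path.insert(0, os.path.dirname(__file__))
from common import RESULTS, ensure, need_sim

from exodecay.denovo import classify_all, write_calls_bed
from exodecay.intervals import GenomicInterval, read_annotation

sim = need_sim()
out = ensure(os.path.join(RESULTS, "classify"))

genes = read_annotation(f"{sim}/genes.gtf")
truth = pd.read_csv(f"{sim}/truth.tsv", sep="\t")
want = truth[truth["kind"].isin(["PROMPT", "eRNA"])]
ivs = [GenomicInterval(r.chrom, r.start, r.end, r.strand) for r in want.itertuples()]

calls, dropped = classify_all(ivs, genes)
write_calls_bed(calls, f"{out}/denovo_calls.bed")

by_pos = {(r.start, r.end): r.kind for r in want.itertuples()}
acc = sum(by_pos[(c.interval.start, c.interval.end)] == c.klass for c in calls) / len(calls)
n_p = sum(1 for c in calls if c.klass == "PROMPT")
print(f"{len(ivs)} de novo transcripts: {len(dropped)} dropped as known, "
      f"{n_p} PROMPT, {len(calls) - n_p} eRNA")
print(f"agreement with planted classes: {acc:.1%}")
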