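"""Shared fixtures and independent brute-force oracles.

The oracles work on explicit per-base masks and never call the interval
algebra they are used to check.
"""

from __future__ import annotations

import numpy as np
import pytest

from exodecay.intervals import GeneModel, GenomicInterval, TranscriptModel

CHROM = "chrT"


# ---------------------------------------------------------------------------
# per-base oracles
# ---------------------------------------------------------------------------

def base_mask(intervals, size: int) -> np.ndarray:
    mask = np.zeros(size, dtype=bool)
    for iv in intervals:
        mask[iv.start : iv.end] = True
    return mask


def mask_to_intervals(mask: np.ndarray, chrom: str, strand: str) -> list[GenomicInterval]:
    """Contiguous True blocks of a mask, left to right."""
    out = []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(int))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    for s, e in zip(starts, ends):
        out.append(GenomicInterval(chrom, int(s), int(e), strand))
    return out


def oracle_merge(intervals, size: int = 20_000) -> list[GenomicInterval]:
    return mask_to_intervals(base_mask(intervals, size), intervals[0].chrom, intervals[0].strand)


def oracle_subtract(a, b, size: int = 20_000) -> list[GenomicInterval]:
    mask = base_mask([a], size) & ~base_mask(b, size)
    return mask_to_intervals(mask, a.chrom, a.strand)


def oracle_introns(gene: GeneModel, size: int = 20_000):
    """(interval, index) pairs: span minus exons, numbered along transcription."""
    mask = base_mask([gene.span], size) & ~base_mask(gene.all_exons(), size)
    blocks = mask_to_intervals(mask, gene.chrom, gene.strand)
    if gene.strand == "-":
        blocks = blocks[::-1]
    return [(iv, i + 1) for i, iv in enumerate(blocks)]


# ---------------------------------------------------------------------------
# random gene models
# ---------------------------------------------------------------------------

def random_gene(rng: np.random.Generator, gene_id: str, chrom_len: int = 10_000) -> GeneModel:
    strand = "+" if rng.random() < 0.5 else "-"
    span_start = int(rng.integers(0, chrom_len - 2_000))
    span_len = int(rng.integers(500, min(5_000, chrom_len - span_start)))
    span = GenomicInterval(CHROM, span_start, span_start + span_len, strand)
    transcripts = []
    for t in range(int(rng.integers(1, 11))):
        n_exons = int(rng.integers(1, 13))
        cuts = np.sort(rng.integers(0, span_len + 1, size=2 * n_exons))
        exons = []
        for k in range(n_exons):
            s, e = int(cuts[2 * k]), int(cuts[2 * k + 1])
            if e > s:
                exons.append(GenomicInterval(CHROM, span_start + s, span_start + e, strand))
        if not exons:
            exons = [GenomicInterval(CHROM, span_start, span_start + 1, strand)]
        # enforce per-isoform disjointness by merging cut overlaps manually
        exons.sort(key=lambda iv: iv.start)
        clean = [exons[0]]
        for iv in exons[1:]:
            if iv.start < clean[-1].end:
                clean[-1] = GenomicInterval(CHROM, clean[-1].start, max(clean[-1].end, iv.end), strand)
            else:
                clean.append(iv)
        transcripts.append(TranscriptModel(f"{gene_id}.t{t}", gene_id, strand, clean))
    return GeneModel(gene_id, "protein_coding", span, transcripts)


@pytest.fixture(scope="session")
def sim_bundle():
    """One mid-sized simulated study shared by read-level tests."""
    from exodecay import simulate

    genome, genes, truth = simulate.make_annotation(
        n_genes=40, n_snornas=10, n_enhancers=10, chrom_len=1_000_000, seed=5
    )
    rnaseq = {}
    for cond in ("control", "depleted"):
        rnaseq.update(simulate.simulate_rnaseq(genome, genes, truth, cond, seed=5))
    return {"genome": genome, "genes": genes, "truth": truth, "rnaseq": rnaseq}
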