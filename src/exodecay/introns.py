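"""Synthetic transcript and intron annotation.

For every gene, all exon intervals from all isoforms are merged into one
"synthetic transcript"; the merged exons are subtracted from the gene span,
and the remaining blocks are the gene's synthetic introns, numbered in
transcription order (intron 1 is promoter-proximal: ascending with genomic
coordinate on the plus strand, descending on the minus strand).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .intervals import (
    Bed6Record,
    GeneModel,
    GenomicInterval,
    merge_intervals,
    subtract_intervals,
    write_bed6,
)


@dataclass(frozen=True)
class SyntheticIntron:
    gene_id: str
    index: int  # 1-based, transcription order
    interval: GenomicInterval
    strand: str

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError("intron index is 1-based")

    @property
    def name(self) -> str:
        return f"{self.gene_id}:intron_{self.index}"


def synthetic_transcript(gene: GeneModel) -> list[GenomicInterval]:
    """Merged, disjoint exon set over all isoforms of one gene."""
    exons = gene.all_exons()
    if not exons:
        raise ValueError(f"gene {gene.gene_id} has no exons")
    return merge_intervals(exons)


def gene_introns(gene: GeneModel) -> list[SyntheticIntron]:
    """Gene span minus merged exons, numbered in transcription order.

    Single-exon genes (and genes whose merged exons tile the span) yield an
    empty list. Bookended exons merge first, so zero-length gaps never
    become introns.
    """
    merged = synthetic_transcript(gene)
    gaps = subtract_intervals(gene.span, merged)
    if gene.strand == "-":
        gaps = gaps[::-1]  # rightmost gap is intron 1 on the minus strand
    return [
        SyntheticIntron(gene.gene_id, i, iv, gene.strand)
        for i, iv in enumerate(gaps, start=1)
    ]


def build_intron_annotation(genes: Iterable[GeneModel]) -> list[SyntheticIntron]:
    """All genes' introns, sorted by (chrom, start); duplicate gene_id is an error."""
    seen: set[str] = set()
    out: list[SyntheticIntron] = []
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene_id {g.gene_id}")
        seen.add(g.gene_id)
        out.extend(gene_introns(g))
    out.sort(key=lambda it: (it.interval.chrom, it.interval.start, it.gene_id, it.index))
    return out


def write_intron_bed(introns: Iterable[SyntheticIntron], path: str) -> None:
    write_bed6(
        (Bed6Record(it.interval, it.name, 0) for it in introns), path
    )


def select_intron(genes: Iterable[GeneModel], k: int) -> dict[str, GenomicInterval]:
    """The k-th intron (transcription order) per gene; genes lacking one are omitted."""
    if k < 1:
        raise ValueError("k is 1-based")
    out: dict[str, GenomicInterval] = {}
    for g in genes:
        introns = gene_introns(g)
        if len(introns) >= k:
            out[g.gene_id] = introns[k - 1].interval
    return out


def first_exon(gene: GeneModel) -> GenomicInterval:
    """The transcription-first merged exon (leftmost on +, rightmost on -)."""
    merged = synthetic_transcript(gene)
    return merged[0] if gene.strand != "-" else merged[-1]
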