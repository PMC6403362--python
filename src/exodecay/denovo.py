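"""PROMPT / eRNA designation of de novo transcripts.

Assembled intervals that overlap any annotated gene are dropped as "known";
each survivor is assigned its nearest annotated gene by span-to-span gap
distance and designated a PROMPT (gap < 3 kb) or an eRNA (gap >= 3 kb —
the < 3 kb PROMPT rule is strict, so exactly 3,000 bp falls to eRNA).
An optional bidirectionality check asks whether both strands carry at
least a minimum fraction of a locus's signal, the signature of enhancer
transcription.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .coverage import CoverageTrack
from .intervals import Bed6Record, GeneModel, GenomicInterval, gap_distance, write_bed6

PROMPT_MAX_DISTANCE = 3000  # bp; strictly-less-than threshold


@dataclass(frozen=True)
class DeNovoCall:
    interval: GenomicInterval
    nearest_gene_id: str
    distance_bp: float  # math.inf when no gene shares the chromosome
    klass: str  # "PROMPT" | "eRNA"
    bidirectional: bool | None = None

    def __post_init__(self) -> None:
        expected = "PROMPT" if self.distance_bp < PROMPT_MAX_DISTANCE else "eRNA"
        if self.klass != expected:
            raise ValueError(f"class {self.klass} inconsistent with distance {self.distance_bp}")


def drop_known(
    denovo: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    biotypes: set[str] | None = None,
) -> list[GenomicInterval]:
    """Remove de novo intervals overlapping any annotated gene span by >=1 bp.

    Overlap is strand-agnostic. ``biotypes`` optionally restricts which
    annotated genes count as "known" (default: all).
    """
    spans = [g.span for g in genes if biotypes is None or g.biotype in biotypes]
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for s in spans:
        by_chrom.setdefault(s.chrom, []).append(s)
    kept = []
    for iv in denovo:
        if not any(iv.overlaps(s) for s in by_chrom.get(iv.chrom, ())):
            kept.append(iv)
    return kept


def classify(
    interval: GenomicInterval,
    genes: Sequence[GeneModel],
    prompt_max_distance: int = PROMPT_MAX_DISTANCE,
) -> DeNovoCall:
    """Designate one novel interval PROMPT or eRNA by nearest-gene distance.

    The nearest gene minimizes the span-to-span gap on the same chromosome;
    distance ties break on the lexicographically smaller gene_id so the call
    is invariant to gene-list order. A chromosome with no annotated gene
    yields an eRNA with an infinite-distance sentinel and empty gene id.
    """
    best_id, best_d = "", math.inf
    for g in genes:
        d = gap_distance(interval, g.span)
        if d < best_d or (d == best_d and best_d < math.inf and g.gene_id < best_id):
            best_id, best_d = g.gene_id, d
    klass = "PROMPT" if best_d < prompt_max_distance else "eRNA"
    return DeNovoCall(interval, best_id, best_d, klass)


def classify_all(
    denovo: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    prompt_max_distance: int = PROMPT_MAX_DISTANCE,
    biotypes: set[str] | None = None,
) -> tuple[list[DeNovoCall], list[GenomicInterval]]:
    """drop_known then classify; returns (calls, dropped)."""
    kept = drop_known(denovo, genes, biotypes)
    kept_set = {(iv.chrom, iv.start, iv.end, iv.strand) for iv in kept}
    dropped = [iv for iv in denovo if (iv.chrom, iv.start, iv.end, iv.strand) not in kept_set]
    calls = [classify(iv, genes, prompt_max_distance) for iv in kept]
    return calls, dropped


def bidirectionality(
    locus: GenomicInterval,
    plus: CoverageTrack,
    minus: CoverageTrack,
    min_frac: float = 0.1,
) -> bool:
    """True iff each strand carries >= ``min_frac`` of the locus's total signal.

    Zero total signal is not bidirectional.
    """
    p = plus.window_sum(locus.chrom, locus.start, locus.end, "+")
    m = minus.window_sum(locus.chrom, locus.start, locus.end, "-")
    total = p + m
    if total <= 0:
        return False
    return bool(p / total >= min_frac and m / total >= min_frac)


def write_calls_bed(calls: Iterable[DeNovoCall], path: str) -> None:
    records = []
    for c in calls:
        d = "inf" if math.isinf(c.distance_bp) else str(int(c.distance_bp))
        records.append(Bed6Record(c.interval, f"{c.klass}:{c.nearest_gene_id}:{d}", 0))
    write_bed6(records, path)
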