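"""Metagene coverage profiling.

Genes passing an expression filter (> 50 reads) receive an extended
transcriptional window (3 kb upstream of the TSS, 7 kb downstream of the
TES); windows that overlap another window or run off a chromosome end are
discarded so no read is counted twice. Profiles are computed on a common
bin grid — fixed-width flank bins plus a length-rescaled gene body
(``scale_body``), or a single fixed grid over the whole region (``fixed``,
used for eRNA and PROMPT loci, which get no extension). Minus-strand rows
are reversed so column 0 is always 5'-most.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .intervals import GeneModel, Genome, GenomicInterval


def select_expressed(gene_counts: Mapping[str, float], min_reads: int = 50) -> set[str]:
    """Genes with strictly more than ``min_reads`` reads (50 is dropped)."""
    return {g for g, c in gene_counts.items() if c > min_reads}


def extend_window(
    gene: GeneModel, genome: Genome, up: int = 3000, down: int = 7000
) -> GenomicInterval | None:
    """Extended transcriptional window, or None when it leaves the chromosome.

    Upstream/downstream follow transcription: a minus-strand gene is
    extended ``down`` to the left and ``up`` to the right.
    """
    if gene.strand == "-":
        left, right = down, up
    else:
        left, right = up, down
    start = gene.span.start - left
    end = gene.span.end + right
    if start < 0 or end > genome.length(gene.chrom):
        return None
    return GenomicInterval(gene.chrom, start, end, gene.strand)


def discard_overlapping(
    windows: Mapping[str, GenomicInterval]
) -> dict[str, GenomicInterval]:
    """Drop every window overlapping any other window (both members go).

    Overlap is strand-agnostic; the rule is applied pairwise, so an overlap
    chain A-B, B-C removes all three.
    """
    items = sorted(windows.items(), key=lambda kv: (kv[1].chrom, kv[1].start))
    bad: set[str] = set()
    # sweep with an active set: adjacency alone is not enough (windows nest)
    active: list[tuple[str, GenomicInterval]] = []
    for wid, iv in items:
        active = [(j, w) for j, w in active if w.chrom == iv.chrom and w.end > iv.start]
        for j, w in active:
            bad.add(j)
            bad.add(wid)
        active.append((wid, iv))
    return {wid: iv for wid, iv in windows.items() if wid not in bad}


@dataclass
class MetageneMatrix:
    region_ids: list[str]
    values: np.ndarray  # regions x bins, transcription-oriented
    up_bins: int
    body_bins: int
    down_bins: int
    flank_bin_bp: int
    mode: str
    normalization: str = "RPKM"

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.region_ids)


def _binned_means(vals: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Mean signal between fractional bin edges via the cumulative integral."""
    cum = np.concatenate(([0.0], np.cumsum(vals)))
    sums = np.interp(edges, np.arange(cum.size, dtype=float), cum)
    widths = np.diff(edges)
    return np.diff(sums) / widths


def _region_values(
    track: CoverageTrack, chrom: str, start: int, end: int, strand: str, strand_mode: str
) -> np.ndarray:
    if strand_mode == "both":
        if any(k[1] == "." for k in track.runs):
            return track.values(chrom, start, end, ".")
        return track.values(chrom, start, end, "+") + track.values(chrom, start, end, "-")
    query = strand if strand_mode == "sense" else _flip(strand)
    return track.values(chrom, start, end, query)


def _flip(strand: str) -> str:
    return {"+": "-", "-": "+", ".": "."}[strand]


def profile(
    regions: Sequence[tuple[str, GenomicInterval]],
    track: CoverageTrack,
    up: int = 3000,
    down: int = 7000,
    flank_bin_bp: int = 50,
    body_bins: int = 100,
    mode: str = "scale_body",
    strand_mode: str = "both",
) -> MetageneMatrix:
    """Bin signal over regions onto a common transcription-oriented grid.

    ``scale_body``: ``up``/``down`` flanks at fixed ``flank_bin_bp`` bins
    around a body rescaled to ``body_bins`` equal-fraction bins (fractional
    bases are weighted, so short regions are handled exactly).
    ``fixed``: the region alone, cut into ``body_bins`` equal bins with no
    flanks — the mode used for eRNA and PROMPT loci.
    Bin values are per-base means; minus-strand rows are reversed.
    """
    if mode not in ("scale_body", "fixed"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "scale_body" and (up % flank_bin_bp or down % flank_bin_bp):
        raise ValueError("flank lengths must be multiples of flank_bin_bp")
    up_bins = up // flank_bin_bp if mode == "scale_body" else 0
    down_bins = down // flank_bin_bp if mode == "scale_body" else 0

    ids, rows = [], []
    for rid, iv in regions:
        if mode == "scale_body":
            vals = _region_values(track, iv.chrom, iv.start - up if iv.strand != "-" else iv.start - down,
                                  iv.end + down if iv.strand != "-" else iv.end + up,
                                  iv.strand, strand_mode)
            if iv.strand == "-":
                vals = vals[::-1]
            body_len = len(iv)
            edges = np.concatenate(
                [
                    np.arange(0, up + 1, flank_bin_bp, dtype=float),
                    up + np.linspace(0, body_len, body_bins + 1)[1:],
                    up + body_len + np.arange(flank_bin_bp, down + 1, flank_bin_bp, dtype=float),
                ]
            )
        else:
            vals = _region_values(track, iv.chrom, iv.start, iv.end, iv.strand, strand_mode)
            if iv.strand == "-":
                vals = vals[::-1]
            edges = np.linspace(0, len(iv), body_bins + 1)
        rows.append(_binned_means(vals, edges))
        ids.append(rid)
    values = np.vstack(rows) if rows else np.empty((0, up_bins + body_bins + down_bins))
    return MetageneMatrix(
        ids, values, up_bins, body_bins, down_bins, flank_bin_bp, mode,
        normalization=track.normalization,
    )


def average_profile(matrix: MetageneMatrix, median: bool = False) -> pd.DataFrame:
    """Per-bin mean (and optionally median) across regions."""
    if matrix.values.shape[0] == 0:
        raise ValueError("no regions to average")
    out = pd.DataFrame({"bin": np.arange(matrix.n_bins), "mean": matrix.values.mean(axis=0)})
    if median:
        out["median"] = np.median(matrix.values, axis=0)
    out.attrs["n_regions"] = matrix.values.shape[0]
    return out


def prompt_region_profile(
    genes: Sequence[GeneModel],
    plus: CoverageTrack,
    minus: CoverageTrack,
    upstream: int = 3000,
    bins: int = 60,
) -> pd.DataFrame:
    """Sense and antisense profiles over the 3-kb promoter-upstream window.

    For each gene the ``[TSS - upstream, TSS)`` window (transcription
    oriented) is binned on the gene's own strand (sense) and on the
    opposite strand, where PROMPT transcription runs. The antisense series
    is returned positive; plotting conventions may sign-flip it.
    """
    sense_rows, anti_rows = [], []
    for g in genes:
        if g.strand == "-":
            start, end = g.span.end, g.span.end + upstream
        else:
            start, end = g.span.start - upstream, g.span.start
        if start < 0:
            continue
        strand_track = {"+": plus, "-": minus}
        sense = strand_track.get(g.strand, plus).values(g.chrom, start, end, g.strand)
        anti = strand_track.get(_flip(g.strand), minus).values(g.chrom, start, end, _flip(g.strand))
        if g.strand == "-":
            sense, anti = sense[::-1], anti[::-1]
        edges = np.linspace(0, end - start, bins + 1)
        sense_rows.append(_binned_means(sense, edges))
        anti_rows.append(_binned_means(anti, edges))
    if not sense_rows:
        raise ValueError("no gene had an in-bounds upstream window")
    return pd.DataFrame(
        {
            "bin": np.arange(bins),
            "sense": np.vstack(sense_rows).mean(axis=0),
            "antisense": np.vstack(anti_rows).mean(axis=0),
        }
    )


def intron_exon_ratio(
    intron_counts: Mapping[str, tuple[float, int]],
    exon1_counts: Mapping[str, tuple[float, int]],
) -> dict[str, float]:
    """Per-gene first-intron / first-exon read-density ratio.

    Inputs map gene_id -> (read count, feature length bp); densities are
    counts per kb, so the ratio is length-corrected. Genes missing from
    either table or with a zero exon-1 count are omitted.
    """
    out: dict[str, float] = {}
    for gid, (icount, ilen) in intron_counts.items():
        if gid not in exon1_counts:
            continue
        ecount, elen = exon1_counts[gid]
        if ecount <= 0:
            continue
        out[gid] = (icount / (ilen / 1e3)) / (ecount / (elen / 1e3))
    return out


def rpkm(count: float, length_bp: int, library_size: int) -> float:
    """Reads per kilobase per million mapped reads."""
    return count * 1e9 / (library_size * length_bp)
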